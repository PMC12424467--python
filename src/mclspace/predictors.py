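"""Pluggable mobility / LogIE / retention-index predictors.

Two kinds are supported:

* ``passthrough`` — the intended production mode: values produced by the
  published external prediction models are ingested as precomputed columns
  and returned unchanged.
* ``baseline`` — simple, fully documented surrogates so the pipeline runs
  end-to-end without the external packages. Surrogate outputs are labeled as
  such and must not be mistaken for the published models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .descriptors import PhyschemDescriptors
from .errors import ConfigurationError, PredictorError
from .io import CompoundRecord

MOBILITY_LABELS = {1: "Non-mobile", 2: "Mobile", 3: "Very mobile"}
MOBILITY_CODES = {label: code for code, label in MOBILITY_LABELS.items()}


@dataclass(frozen=True)
class MobilityClass:
    code: int
    label: str

    def __post_init__(self):
        if MOBILITY_LABELS.get(self.code) != self.label:
            raise ValueError(f"inconsistent mobility code/label: {self.code}/{self.label!r}")

    @classmethod
    def from_code(cls, code: int) -> "MobilityClass":
        if code not in MOBILITY_LABELS:
            raise ValueError(f"mobility code must be 1, 2 or 3, got {code!r}")
        return cls(code=code, label=MOBILITY_LABELS[code])

    @classmethod
    def from_label(cls, label: str) -> "MobilityClass":
        if label not in MOBILITY_CODES:
            raise ValueError(f"unknown mobility label {label!r}")
        return cls(code=MOBILITY_CODES[label], label=label)


@dataclass(frozen=True)
class PredictorSpec:
    """How one quantity is obtained: precomputed-column passthrough or surrogate."""

    kind: str  # "passthrough" | "baseline"
    parameters: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("passthrough", "baseline"):
            raise ConfigurationError(f"unknown predictor kind {self.kind!r}")

    def param(self, name: str, default: float) -> float:
        return float(self.parameters.get(name, default))


# surrogate defaults, chosen for plausible ranges only — NOT the published models
_BASELINE_LOGIE = {"intercept": 2.0, "c_xlogp": 0.5, "c_tpsa": -0.01, "c_hbd": -0.2, "c_hba": 0.1}
_BASELINE_RI = {"intercept": 100.0, "c_xlogp": 150.0}


def predict_mobility(
    record: CompoundRecord, physchem: PhyschemDescriptors, spec: PredictorSpec
) -> MobilityClass:
    """Mobility class 1/2/3 (Non-mobile / Mobile / Very mobile).

    Baseline surrogate: two xlogp cutpoints; below the lower one the compound
    is Very mobile, above the upper one Non-mobile.
    """
    if spec.kind == "passthrough":
        code = record.precomputed.get("mobility_class")
        if code is None:
            raise PredictorError(
                f"record {record.id!r}: passthrough mobility requires a mobility_class column"
            )
        return MobilityClass.from_code(int(code))
    lo = spec.param("xlogp_very_mobile_max", 0.0)
    hi = spec.param("xlogp_mobile_max", 3.0)
    x = physchem.xlogp
    if x < lo:
        return MobilityClass.from_code(3)
    if x < hi:
        return MobilityClass.from_code(2)
    return MobilityClass.from_code(1)


def predict_log_ie(
    record: CompoundRecord, physchem: PhyschemDescriptors, spec: PredictorSpec
) -> float:
    """LogIE (log10 ionization-efficiency scale).

    Baseline surrogate: linear form
    ``intercept + c_xlogp*xlogp + c_tpsa*tpsa + c_hbd*hbd + c_hba*hba``.
    """
    if spec.kind == "passthrough":
        value = record.precomputed.get("log_ie")
        if value is None:
            raise PredictorError(
                f"record {record.id!r}: passthrough LogIE requires a log_ie column"
            )
        return float(value)
    p = {k: spec.param(k, v) for k, v in _BASELINE_LOGIE.items()}
    return (
        p["intercept"]
        + p["c_xlogp"] * physchem.xlogp
        + p["c_tpsa"] * physchem.tpsa
        + p["c_hbd"] * physchem.hbd
        + p["c_hba"] * physchem.hba
    )


def predict_ri(
    record: CompoundRecord, physchem: PhyschemDescriptors, spec: PredictorSpec
) -> float:
    """Retention index on the cocamide scale (surrogate: linear in xlogp)."""
    if spec.kind == "passthrough":
        value = record.precomputed.get("ri")
        if value is None:
            raise PredictorError(f"record {record.id!r}: passthrough RI requires an ri column")
        return float(value)
    p = {k: spec.param(k, v) for k, v in _BASELINE_RI.items()}
    return p["intercept"] + p["c_xlogp"] * physchem.xlogp


DEFAULT_RPLC_BOUNDS = (0.0, 50.0, 950.0, 1000.0)


def classify_rplc(ri: float, bounds: tuple[float, float, float, float] = DEFAULT_RPLC_BOUNDS) -> int:
    """Classify an RI against the RPLC domain: -1 outside, 0 maybe, 1 inside.

    ``bounds = (lo, lo_margin, hi_margin, hi)``: outside [lo, hi] -> -1; the
    margin strips [lo, lo_margin) and (hi_margin, hi] -> 0; the interior -> 1.
    """
    lo, lo_margin, hi_margin, hi = bounds
    if not (lo < lo_margin < hi_margin < hi):
        raise ConfigurationError(f"RPLC bounds must be strictly increasing, got {bounds}")
    if ri < lo or ri > hi:
        return -1
    if ri < lo_margin or ri > hi_margin:
        return 0
    return 1
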