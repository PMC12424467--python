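"""Seeded synthetic-data generators.

Two generators:

* :func:`generate_feature_table` — a 13-column feature table with Gaussian
  cluster structure in a 3-dimensional latent subspace, mobility classes
  drawn from given proportions, and LogIE drawn from three disjoint segments
  so a known fraction of records falls strictly above the positive-mode
  threshold and strictly below the negative-mode one. Ground-truth labels
  (cluster id, class, per-polarity eligibility) are emitted alongside and are
  decided at draw time, independently of the filter code.
* :func:`generate_smiles_set` — records from a small embedded library of
  real, valid SMILES covering donors/non-donors and halogenated structures.

All randomness flows through one ``numpy.random.default_rng(seed)``; no
global state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CompoundRecord

POS_THRESHOLD = 3.5
NEG_THRESHOLD = 1.5

#: continuous feature block (latent-embedded); hbd/hba/mobility/log_ie are drawn separately
CONTINUOUS_COLUMNS = (
    "mw",
    "xlogp",
    "tpsa",
    "emd_CH2",
    "emd_CO",
    "emd_CCl",
    "emd_CN",
    "emd_CF2",
    "emd_CS",
)
FEATURE_COLUMNS = (
    "mw",
    "xlogp",
    "tpsa",
    "hbd",
    "hba",
    "emd_CH2",
    "emd_CO",
    "emd_CCl",
    "emd_CN",
    "emd_CF2",
    "emd_CS",
    "mobility_class",
    "log_ie",
)

# offsets/scales moving latent coordinates into plausible descriptor ranges
_COLUMN_SHIFT = {"mw": 300.0, "xlogp": 2.0, "tpsa": 80.0}
_COLUMN_SCALE = {"mw": 80.0, "xlogp": 1.5, "tpsa": 25.0}


@dataclass(frozen=True)
class FixtureSpec:
    n: int
    seed: int
    n_clusters: int = 5
    cluster_spread: float = 0.5
    logie_range: tuple[float, float] = (-2.0, 7.0)
    class_proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    fraction_hbd_zero: float = 0.3
    frac_logie_pos: float = 0.3  # fraction strictly above POS_THRESHOLD
    frac_logie_neg: float = 0.3  # fraction strictly below NEG_THRESHOLD

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValidationError("class_proportions must sum to 1")
        if any(p < 0 for p in self.class_proportions):
            raise ValidationError("class_proportions must be non-negative")
        if not 0.0 <= self.fraction_hbd_zero <= 1.0:
            raise ValidationError("fraction_hbd_zero must be in [0, 1]")
        if self.frac_logie_pos + self.frac_logie_neg > 1.0:
            raise ValidationError("LogIE segment fractions must sum to <= 1")
        lo, hi = self.logie_range
        if not (lo < NEG_THRESHOLD and hi > POS_THRESHOLD):
            raise ValidationError(
                f"logie_range must bracket ({NEG_THRESHOLD}, {POS_THRESHOLD}), got {self.logie_range}"
            )


def generate_feature_table(spec: FixtureSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic synthetic feature table + ground-truth labels.

    Returns (features, truth); both are indexed by id. ``truth`` columns:
    cluster, mobility_class, eligible_pos, eligible_neg.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    ids = [f"SYN{i:06d}" for i in range(n)]

    # 3-D latent cluster structure embedded linearly into the continuous block
    centers = rng.normal(0.0, 3.0, size=(spec.n_clusters, 3))
    cluster = rng.integers(0, spec.n_clusters, size=n)
    latent = centers[cluster] + rng.normal(0.0, spec.cluster_spread, size=(n, 3))
    embedding = rng.normal(0.0, 1.0, size=(3, len(CONTINUOUS_COLUMNS)))
    block = latent @ embedding + rng.normal(0.0, 0.05, size=(n, len(CONTINUOUS_COLUMNS)))

    features = pd.DataFrame(index=pd.Index(ids, name="id"))
    for j, col in enumerate(CONTINUOUS_COLUMNS):
        scale = _COLUMN_SCALE.get(col, 0.1)
        shift = _COLUMN_SHIFT.get(col, 0.0)
        features[col] = shift + scale * block[:, j]

    hbd = 1 + rng.poisson(2.0, size=n)
    hbd[rng.random(n) < spec.fraction_hbd_zero] = 0
    features["hbd"] = hbd
    features["hba"] = rng.poisson(3.0, size=n)

    features["mobility_class"] = rng.choice([1, 2, 3], size=n, p=spec.class_proportions)

    lo, hi = spec.logie_range
    p_mid = 1.0 - spec.frac_logie_pos - spec.frac_logie_neg
    segment = rng.choice(["neg", "mid", "pos"], size=n, p=[spec.frac_logie_neg, p_mid, spec.frac_logie_pos])
    log_ie = np.empty(n)
    u = rng.random(n)
    # open segments: draws can never land exactly on a threshold
    eps = 1e-9
    log_ie[segment == "neg"] = lo + u[segment == "neg"] * (NEG_THRESHOLD - eps - lo)
    log_ie[segment == "mid"] = NEG_THRESHOLD + u[segment == "mid"] * (POS_THRESHOLD - NEG_THRESHOLD)
    log_ie[segment == "pos"] = POS_THRESHOLD + eps + u[segment == "pos"] * (hi - POS_THRESHOLD - eps)
    features["log_ie"] = log_ie

    features = features[list(FEATURE_COLUMNS)]

    truth = pd.DataFrame(
        {
            "cluster": cluster,
            "mobility_class": features["mobility_class"],
            "eligible_pos": segment == "pos",
            "eligible_neg": (segment == "neg") & (hbd > 0),
        },
        index=features.index,
    )
    return features, truth


def generate_planted_matrix(
    n: int, seed: int, spread: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Matrix with one dominant planted direction, for PCA recovery checks.

    The direction has equal-magnitude random-sign entries so that per-column
    standardization preserves it (up to the overall sign convention).
    """
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=13)
    direction = signs / math.sqrt(13.0)
    t = rng.normal(0.0, 1.0, size=n)
    X = np.outer(t, direction) + rng.normal(0.0, spread, size=(n, 13))
    return X, direction


@dataclass(frozen=True)
class _LibraryEntry:
    name: str
    smiles: str


_SMILES_LIBRARY: tuple[_LibraryEntry, ...] = tuple(
    _LibraryEntry(*pair)
    for pair in [
        ("water", "O"),
        ("methanol", "CO"),
        ("ethanol", "CCO"),
        ("acetic acid", "CC(=O)O"),
        ("acetone", "CC(C)=O"),
        ("acetonitrile", "CC#N"),
        ("dimethyl sulfoxide", "CS(C)=O"),
        ("hexane", "CCCCCC"),
        ("heptane", "CCCCCCC"),
        ("octane", "CCCCCCCC"),
        ("benzene", "c1ccccc1"),
        ("toluene", "Cc1ccccc1"),
        ("phenol", "Oc1ccccc1"),
        ("aniline", "Nc1ccccc1"),
        ("pyridine", "c1ccncc1"),
        ("naphthalene", "c1ccc2ccccc2c1"),
        ("chlorobenzene", "Clc1ccccc1"),
        ("chloroform", "ClC(Cl)Cl"),
        ("1,2-dichloroethane", "ClCCCl"),
        ("trifluoroacetic acid", "OC(=O)C(F)(F)F"),
        ("perfluorobutanoic acid", "OC(=O)C(F)(F)C(F)(F)C(F)(F)F"),
        ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
        ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
        ("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"),
        ("glucose", "OCC1OC(O)C(O)C(O)C1O"),
        ("atrazine", "CCNc1nc(Cl)nc(NC(C)C)n1"),
        ("diuron", "CN(C)C(=O)Nc1ccc(Cl)c(Cl)c1"),
    ]
)


def generate_smiles_set(size: int | None = None) -> list[CompoundRecord]:
    """Records from the embedded SMILES library (size=None -> the full set)."""
    if size is None:
        size = len(_SMILES_LIBRARY)
    if size > len(_SMILES_LIBRARY):
        raise ValidationError(
            f"requested {size} records but the embedded library holds {len(_SMILES_LIBRARY)}"
        )
    return [
        CompoundRecord(id=f"LIB{i:03d}", smiles=entry.smiles)
        for i, entry in enumerate(_SMILES_LIBRARY[:size])
    ]


def library_names() -> list[str]:
    return [e.name for e in _SMILES_LIBRARY]
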