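"""One config document (YAML) drives the whole pipeline."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from .descriptors import DEFAULT_EMD_UNIT_LABELS
from .errors import ConfigurationError
from .predictors import DEFAULT_RPLC_BOUNDS
from .sampler import METRIC_FEATURES, METRIC_FINGERPRINTS, SelectionConfig


class GridSettings(BaseModel):
    k: int = 3
    bins_per_axis: int = 20


class PredictorSettings(BaseModel):
    kind: Literal["passthrough", "baseline"] = "passthrough"
    parameters: dict[str, float] = Field(default_factory=dict)


class SelectionSettings(BaseModel):
    per_cell_cap: Optional[int] = None
    distance_threshold: float = 0.15
    distance_metric: str = METRIC_FEATURES
    logie_pos_min: float = 3.5
    logie_neg_max: float = 1.5
    hbd_min_neg: int = 1
    per_class_n: int = 50

    @field_validator("distance_metric")
    @classmethod
    def _known_metric(cls, v: str) -> str:
        if v not in (METRIC_FEATURES, METRIC_FINGERPRINTS):
            raise ValueError(f"unknown distance metric {v!r}")
        return v

    def to_selection_config(self) -> SelectionConfig:
        return SelectionConfig(
            per_cell_cap=self.per_cell_cap,
            distance_threshold=self.distance_threshold,
            distance_metric=self.distance_metric,
            logie_pos_min=self.logie_pos_min,
            logie_neg_max=self.logie_neg_max,
            hbd_min_neg=self.hbd_min_neg,
            per_class_n=self.per_class_n,
        )


class AppConfig(BaseModel):
    columns: dict[str, str] = Field(default_factory=lambda: {"id": "id", "smiles": "smiles"})
    emd_units: list[str] = Field(default_factory=lambda: list(DEFAULT_EMD_UNIT_LABELS))
    grid: GridSettings = Field(default_factory=GridSettings)
    selection: SelectionSettings = Field(default_factory=SelectionSettings)
    predictors: dict[str, PredictorSettings] = Field(
        default_factory=lambda: {
            "mobility": PredictorSettings(),
            "log_ie": PredictorSettings(),
            "ri": PredictorSettings(),
        }
    )
    rplc_bounds: tuple[float, float, float, float] = DEFAULT_RPLC_BOUNDS
    delimiter: Optional[str] = None

    @field_validator("emd_units")
    @classmethod
    def _six_units(cls, v: list[str]) -> list[str]:
        if len(v) != 6:
            raise ValueError(f"exactly 6 mass-defect units required, got {len(v)}")
        return v

    @field_validator("rplc_bounds")
    @classmethod
    def _monotone(cls, v):
        if not (v[0] < v[1] < v[2] < v[3]):
            raise ValueError(f"rplc_bounds must be strictly increasing, got {v}")
        return v


def load_config(path: str | Path | None) -> AppConfig:
    """Load the YAML config; a missing path yields all defaults."""
    if path is None:
        return AppConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    doc = yaml.safe_load(path.read_text()) or {}
    return AppConfig.model_validate(doc)
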