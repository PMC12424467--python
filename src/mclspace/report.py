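"""Coverage and applicability diagnostics for emitted MCLs.

Chemical-space coverage is quantified as the fraction of occupied grid cells
(on the same grid used for sampling) that a list hits. Retention/mass
diagnostics summarize the RI and monoisotopic-mass ranges and fit an
ordinary-least-squares RI-vs-mass line.
"""

from __future__ import annotations

import csv
import json
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chemspace import GridSpec, assign_cells
from .errors import ValidationError


@dataclass(frozen=True)
class CoverageReport:
    occupied_cells_total: int
    cells_hit_by_list: int
    coverage_fraction: float
    per_class_counts: dict[int, int]
    mass_range: tuple[float, float] | None
    ri_range: tuple[float, float] | None
    rplc_class_counts: dict[int, int]

    def as_dict(self) -> dict:
        return {
            "occupied_cells_total": self.occupied_cells_total,
            "cells_hit_by_list": self.cells_hit_by_list,
            "coverage_fraction": self.coverage_fraction,
            "per_class_counts": {str(k): v for k, v in self.per_class_counts.items()},
            "mass_range": list(self.mass_range) if self.mass_range else None,
            "ri_range": list(self.ri_range) if self.ri_range else None,
            "rplc_class_counts": {str(k): v for k, v in self.rplc_class_counts.items()},
        }


def _cell_sets(
    list_ids: Sequence[str], score_ids: Sequence[str], scores: np.ndarray, grid: GridSpec
) -> tuple[set[tuple[int, ...]], set[tuple[int, ...]]]:
    cells, _ = assign_cells(scores, grid)
    cell_of = {str(sid): tuple(int(c) for c in cells[i]) for i, sid in enumerate(score_ids)}
    unknown = [cid for cid in list_ids if str(cid) not in cell_of]
    if unknown:
        raise ValidationError(f"ids not present in the scored table: {unknown[:5]}")
    occupied = set(cell_of.values())
    hit = {cell_of[str(cid)] for cid in list_ids}
    return occupied, hit


def coverage_metrics(
    list_ids: Sequence[str],
    score_ids: Sequence[str],
    scores: np.ndarray,
    grid: GridSpec,
    features: pd.DataFrame | None = None,
) -> CoverageReport:
    """Grid-cell coverage of a compound list, plus per-class / mass / RI summaries.

    `features` (indexed by id) optionally supplies mobility_class, mw,
    predicted_ri and rplc_class columns for the summary fields.
    """
    occupied, hit = _cell_sets(list_ids, score_ids, scores, grid)
    per_class: dict[int, int] = {}
    mass_range = ri_range = None
    rplc_counts: dict[int, int] = {}
    if features is not None and len(list_ids):
        feats = features.copy()
        feats.index = feats.index.astype(str)
        sub = feats.loc[[str(c) for c in list_ids]]
        if "mobility_class" in sub.columns:
            per_class = {int(k): int(v) for k, v in sub["mobility_class"].value_counts().items()}
        if "mw" in sub.columns and sub["mw"].notna().any():
            mass_range = (float(sub["mw"].min()), float(sub["mw"].max()))
        if "predicted_ri" in sub.columns and sub["predicted_ri"].notna().any():
            ri_range = (float(sub["predicted_ri"].min()), float(sub["predicted_ri"].max()))
        if "rplc_class" in sub.columns:
            rplc_counts = {
                int(k): int(v) for k, v in sub["rplc_class"].dropna().value_counts().items()
            }
    return CoverageReport(
        occupied_cells_total=len(occupied),
        cells_hit_by_list=len(hit),
        coverage_fraction=len(hit) / len(occupied) if occupied else 0.0,
        per_class_counts=per_class,
        mass_range=mass_range,
        ri_range=ri_range,
        rplc_class_counts=rplc_counts,
    )


def compare_lists(
    list_a: Sequence[str],
    list_b: Sequence[str],
    score_ids: Sequence[str],
    scores: np.ndarray,
    grid: GridSpec,
    features: pd.DataFrame | None = None,
) -> dict:
    """Paired coverage reports plus the cells covered by list A but not list B."""
    occupied, hit_a = _cell_sets(list_a, score_ids, scores, grid)
    _, hit_b = _cell_sets(list_b, score_ids, scores, grid)
    return {
        "a": coverage_metrics(list_a, score_ids, scores, grid, features).as_dict(),
        "b": coverage_metrics(list_b, score_ids, scores, grid, features).as_dict(),
        "cells_a_not_b": len(hit_a - hit_b),
        "cells_b_not_a": len(hit_b - hit_a),
        "cells_shared": len(hit_a & hit_b),
    }


def ri_mass_regression(mass: Sequence[float], ri: Sequence[float]) -> dict:
    """OLS of retention index on monoisotopic mass: {slope, intercept, r_squared}."""
    mass = np.asarray(mass, dtype=float)
    ri = np.asarray(ri, dtype=float)
    ok = np.isfinite(mass) & np.isfinite(ri)
    mass, ri = mass[ok], ri[ok]
    if mass.size < 3:
        raise ValidationError("regression requires at least 3 finite (mass, RI) points")
    if np.ptp(mass) == 0.0:
        raise ValidationError("regression undefined: zero variance in mass")
    fit = stats.linregress(mass, ri)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
    }


class OfflineAvailabilitySource:
    """Patent/literature counts from a local CSV (columns id,patent_count,literature_count)."""

    def __init__(self, counts: Mapping[str, tuple[int, int]]):
        self._counts = dict(counts)

    @classmethod
    def from_csv(cls, path: str | Path) -> "OfflineAvailabilitySource":
        counts = {}
        with Path(path).open(newline="") as handle:
            for row in csv.DictReader(handle):
                counts[row["id"]] = (int(row["patent_count"]), int(row["literature_count"]))
        return cls(counts)

    def lookup(self, cid: str) -> tuple[int, int]:
        return self._counts[cid]


class PubChemAvailabilitySource:
    """Live PubChem adapter (never used in tests; results cached to disk)."""

    def __init__(self, cache_path: str | Path):
        self.cache_path = Path(cache_path)
        self._cache = (
            json.loads(self.cache_path.read_text()) if self.cache_path.exists() else {}
        )

    def lookup(self, cid: str) -> tuple[int, int]:
        if cid in self._cache:
            return tuple(self._cache[cid])
        url = (
            "https://pubchem.ncbi.nlm.nih.gov/rest/pug/compound/cid/"
            f"{cid}/xrefs/PatentID/JSON"
        )
        with urllib.request.urlopen(url, timeout=30) as resp:  # pragma: no cover - network
            doc = json.load(resp)
        patents = len(doc.get("InformationList", {}).get("Information", [{}])[0].get("PatentID", []))
        self._cache[cid] = (patents, 0)
        self.cache_path.write_text(json.dumps(self._cache))
        return (patents, 0)


def availability_counts(ids: Sequence[str], source) -> dict[str, dict]:
    """Per-id patent/literature counts with an availability flag.

    ``available`` is true iff either count is positive. Lookup failures mark
    the id ``unknown`` and the run continues.
    """
    out: dict[str, dict] = {}
    for cid in ids:
        try:
            patents, literature = source.lookup(cid)
        except Exception:
            out[cid] = {"status": "unknown"}
            continue
        out[cid] = {
            "status": "ok",
            "patent_count": int(patents),
            "literature_count": int(literature),
            "available": bool(patents > 0 or literature > 0),
        }
    return out


def availability_fraction(results: Mapping[str, dict]) -> float:
    known = [r for r in results.values() if r.get("status") == "ok"]
    if not known:
        return 0.0
    return sum(r["available"] for r in known) / len(known)
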