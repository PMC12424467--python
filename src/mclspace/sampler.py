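"""The selection cascade: grid sampling -> dissimilarity filter -> ESI
eligibility filters -> mobility grouping and ranking -> MCL assembly.

Stage order and thresholds follow the workflow defaults: retain structures
whose pairwise distance exceeds 0.15; keep LogIE > 3.5 for positive mode and
LogIE < 1.5 with at least one H-bond donor for negative mode (all thresholds
strict); group by mobility class and rank by descending LogIE, taking a
user-defined number per class. All ties are broken by id so repeated runs
are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemspace import GridSpec, assign_cells
from .errors import ValidationError
from .fingerprints import pairwise_continuous_tanimoto, pairwise_jaccard
from .io import MCLEntry

POSITIVE = "positive"
NEGATIVE = "negative"

METRIC_FEATURES = "continuous_tanimoto_on_features"
METRIC_FINGERPRINTS = "jaccard_on_fingerprints"


@dataclass(frozen=True)
class SelectionConfig:
    per_cell_cap: int | None = None  # None = unlimited
    distance_threshold: float = 0.15
    distance_metric: str = METRIC_FEATURES
    logie_pos_min: float = 3.5
    logie_neg_max: float = 1.5
    hbd_min_neg: int = 1
    per_class_n: int = 50

    def __post_init__(self):
        if self.distance_metric not in (METRIC_FEATURES, METRIC_FINGERPRINTS):
            raise ValidationError(f"unknown distance metric {self.distance_metric!r}")
        if self.per_class_n < 1:
            raise ValidationError("per_class_n must be >= 1")
        if self.per_cell_cap is not None and self.per_cell_cap < 1:
            raise ValidationError("per_cell_cap must be >= 1 or None")


@dataclass
class StageReport:
    """Counts surviving each stage plus warning tallies, for the run report."""

    n_input: int = 0
    n_grid_sampled: int = 0
    n_dissimilar: int = 0
    n_esi: dict = field(default_factory=dict)
    n_selected: dict = field(default_factory=dict)
    warnings: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_grid_sampled": self.n_grid_sampled,
            "n_dissimilar": self.n_dissimilar,
            "n_esi": dict(self.n_esi),
            "n_selected": dict(self.n_selected),
            "warnings": dict(self.warnings),
        }


def grid_sample(
    ids: Sequence[str],
    scores: np.ndarray,
    grid: GridSpec,
    per_cell_cap: int | None = None,
) -> list[str]:
    """Sample up to `per_cell_cap` members from every occupied grid cell.

    Within a cell, members are ordered by ascending Euclidean distance to the
    cell centroid (ties by id); cells are visited in lexicographic order of
    their index, making the output deterministic.
    """
    ids = list(ids)
    scores = np.asarray(scores, dtype=float)
    if len(ids) != scores.shape[0]:
        raise ValidationError("ids and scores must have the same length")
    if not ids:
        return []
    cells, _ = assign_cells(scores, grid)
    by_cell: dict[tuple[int, ...], list[int]] = {}
    for i, cell in enumerate(map(tuple, cells.tolist())):
        by_cell.setdefault(cell, []).append(i)
    out: list[str] = []
    for cell in sorted(by_cell):
        members = by_cell[cell]
        centroid = grid.centroid(cell)
        dists = np.linalg.norm(scores[members] - centroid, axis=1)
        order = sorted(range(len(members)), key=lambda j: (dists[j], ids[members[j]]))
        if per_cell_cap is not None:
            order = order[:per_cell_cap]
        out.extend(ids[members[j]] for j in order)
    return out


def dissimilarity_filter(
    candidates: Sequence[str],
    vectors: Mapping[str, np.ndarray] | pd.DataFrame,
    threshold: float,
    metric: str = METRIC_FEATURES,
) -> tuple[list[str], int]:
    """Greedy diversity filter: scan candidates in order, keeping each one iff
    its distance to EVERY previously kept candidate exceeds `threshold`.

    Returns (retained ids, count of candidates skipped because their distance
    was undefined, i.e. an all-zero vector under either metric).
    The retained set satisfies the all-pairs property, and every rejected
    candidate is within `threshold` of at least one retained candidate.
    """
    if metric == METRIC_FEATURES:
        pairwise = pairwise_continuous_tanimoto
    elif metric == METRIC_FINGERPRINTS:
        pairwise = pairwise_jaccard
    else:
        raise ValidationError(f"unknown distance metric {metric!r}")

    def vec(cid: str) -> np.ndarray:
        v = vectors.loc[cid] if isinstance(vectors, pd.DataFrame) else vectors[cid]
        return np.asarray(v, dtype=float)

    retained: list[str] = []
    kept = None  # preallocated buffer of kept vectors
    n_kept = 0
    skipped = 0
    for cid in candidates:
        x = vec(cid)
        if not np.any(x):
            skipped += 1
            continue
        if kept is None:
            kept = np.empty((len(candidates), x.size), dtype=float)
        if n_kept:
            d = pairwise(x, kept[:n_kept])
            if np.any(np.nan_to_num(d, nan=np.inf) <= threshold):
                continue
        retained.append(cid)
        kept[n_kept] = x
        n_kept += 1
    return retained, skipped


def esi_filter(
    candidates: Sequence[str],
    log_ie: Mapping[str, float],
    hbd: Mapping[str, int],
    polarity: str,
    config: SelectionConfig,
) -> tuple[list[str], int]:
    """Ionization-compatibility filter (strict inequalities).

    positive: LogIE > logie_pos_min;
    negative: LogIE < logie_neg_max AND hbd >= hbd_min_neg.
    Candidates with missing LogIE are dropped and counted.
    """
    if polarity not in (POSITIVE, NEGATIVE):
        raise ValidationError(f"unknown polarity {polarity!r}")
    kept: list[str] = []
    missing = 0
    for cid in candidates:
        ie = log_ie.get(cid)
        if ie is None or not np.isfinite(ie):
            missing += 1
            continue
        if polarity == POSITIVE:
            if ie > config.logie_pos_min:
                kept.append(cid)
        else:
            h = hbd.get(cid)
            if ie < config.logie_neg_max and h is not None and h >= config.hbd_min_neg:
                kept.append(cid)
    return kept, missing


def rank_and_select(
    candidates: Sequence[str],
    mobility: Mapping[str, int],
    log_ie: Mapping[str, float],
    per_class_n: int,
) -> tuple[list[tuple[str, int]], dict[int, int]]:
    """Group by mobility class (1, 2, 3), rank each group by descending LogIE
    (ties by id), keep the top `per_class_n` per class, and assign a single
    contiguous 1-based rank over the concatenation.

    Returns (list of (id, rank)) plus a shortfall map {class: missing count}
    for classes with fewer than `per_class_n` eligible members.
    """
    ranked: list[tuple[str, int]] = []
    shortfall: dict[int, int] = {}
    rank = 1
    for cls in (1, 2, 3):
        members = [cid for cid in candidates if mobility[cid] == cls]
        members.sort(key=lambda cid: (-log_ie[cid], cid))
        if len(members) < per_class_n:
            shortfall[cls] = per_class_n - len(members)
        for cid in members[:per_class_n]:
            ranked.append((cid, rank))
            rank += 1
    return ranked, shortfall


def _column_map(features: pd.DataFrame, name: str) -> dict:
    return features[name].to_dict() if name in features.columns else {}


def build_mcl(
    features: pd.DataFrame,
    scores: np.ndarray,
    grid: GridSpec,
    config: SelectionConfig,
    vectors: pd.DataFrame | None = None,
) -> tuple[dict[str, list[MCLEntry]], StageReport]:
    """Run the whole cascade and assemble both polarity lists.

    `features` must be indexed by id and carry at least mobility_class,
    log_ie and hbd columns (smiles / predicted_ri / rplc_class are copied
    into the output when present). `scores` rows align with `features` rows.
    `vectors` are the dissimilarity-filter operands, indexed by id; by
    default the feature columns are standardized in-place and used
    (continuous-Tanimoto on scaled model variables).
    """
    features = features.copy()
    features.index = features.index.astype(str)
    if features.index.has_duplicates:
        raise ValidationError("feature table ids must be unique")
    if vectors is not None:
        vectors = vectors.copy()
        vectors.index = vectors.index.astype(str)
    report = StageReport(n_input=len(features))
    if len(features) == 0:
        return {POSITIVE: [], NEGATIVE: []}, report
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != len(features):
        raise ValidationError("scores and features must align row-by-row")

    if vectors is None:
        from .chemspace import apply_scaling, fit_scaling  # local to avoid cycle at import

        numeric = features.select_dtypes("number").drop(
            columns=[c for c in ("predicted_ri", "rplc_class") if c in features.columns],
            errors="ignore",
        )
        if len(features) >= 2:
            keep = [c for c in numeric.columns if numeric[c].nunique() > 1]
            scal = fit_scaling(numeric[keep].to_numpy(), names=keep)
            vectors = pd.DataFrame(
                apply_scaling(numeric[keep].to_numpy(), scal), index=features.index, columns=keep
            )
        else:
            vectors = numeric

    ids = [str(i) for i in features.index]
    sampled = grid_sample(ids, scores, grid, config.per_cell_cap)
    report.n_grid_sampled = len(sampled)

    retained, skipped = dissimilarity_filter(
        sampled, vectors, config.distance_threshold, config.distance_metric
    )
    report.n_dissimilar = len(retained)
    report.warnings["undefined_distance_skipped"] = skipped

    log_ie = _column_map(features, "log_ie")
    hbd = {k: int(v) for k, v in _column_map(features, "hbd").items()}
    mobility = {k: int(v) for k, v in _column_map(features, "mobility_class").items()}
    smiles = _column_map(features, "smiles")
    ri = _column_map(features, "predicted_ri")
    rplc = _column_map(features, "rplc_class")
    cells, _ = assign_cells(scores, grid)
    cell_of = {cid: tuple(int(c) for c in cells[i]) for i, cid in enumerate(ids)}

    result: dict[str, list[MCLEntry]] = {}
    for polarity in (POSITIVE, NEGATIVE):
        eligible, missing = esi_filter(retained, log_ie, hbd, polarity, config)
        report.n_esi[polarity] = len(eligible)
        report.warnings[f"missing_log_ie_{polarity}"] = missing
        ranked, shortfall = rank_and_select(eligible, mobility, log_ie, config.per_class_n)
        if shortfall:
            report.warnings[f"shortfall_{polarity}"] = {
                str(cls): n for cls, n in sorted(shortfall.items())
            }
        entries = []
        for cid, rank in ranked:
            ri_val = ri.get(cid)
            rplc_val = rplc.get(cid)
            entries.append(
                MCLEntry(
                    id=cid,
                    smiles=str(smiles.get(cid, "")),
                    polarity=polarity,
                    mobility_class=mobility[cid],
                    log_ie=float(log_ie[cid]),
                    predicted_ri=None if ri_val is None or not np.isfinite(ri_val) else float(ri_val),
                    rplc_class=None if rplc_val is None or not np.isfinite(rplc_val) else int(rplc_val),
                    cell_index=cell_of[cid],
                    rank=rank,
                )
            )
        report.n_selected[polarity] = len(entries)
        result[polarity] = entries

    if config.logie_pos_min >= config.logie_neg_max:
        overlap = {e.id for e in result[POSITIVE]} & {e.id for e in result[NEGATIVE]}
        assert not overlap, f"polarity filters should be mutually exclusive, overlap: {overlap}"
    return result, report
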