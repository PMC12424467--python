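import numpy as np
import pandas as pd
import pytest

from mclspace.chemspace import apply_scaling, assign_cells, build_grid, fit_scaling
from mclspace.errors import ValidationError
from mclspace.fingerprints import continuous_tanimoto_distance
from mclspace.sampler import (
    METRIC_FEATURES,
    NEGATIVE,
    POSITIVE,
    SelectionConfig,
    build_mcl,
    dissimilarity_filter,
    esi_filter,
    grid_sample,
    rank_and_select,
)


class TestGridSample:
    def test_unlimited_cap_is_permutation(self, rng):
        ids = [f"c{i}" for i in range(200)]
        scores = rng.normal(size=(200, 2))
        grid = build_grid(scores, 5)
        out = grid_sample(ids, scores, grid, per_cell_cap=None)
        assert sorted(out) == sorted(ids)

    def test_grouped_by_cell_in_lex_order(self, rng):
        ids = [f"c{i}" for i in range(100)]
        scores = rng.normal(size=(100, 2))
        grid = build_grid(scores, 4)
        cells, _ = assign_cells(scores, grid)
        cell_of = {cid: tuple(c) for cid, c in zip(ids, cells)}
        out = grid_sample(ids, scores, grid)
        seen_cells = [cell_of[cid] for cid in out]
        # cells appear in contiguous lexicographically sorted runs
        boundaries = [c for i, c in enumerate(seen_cells) if i == 0 or c != seen_cells[i - 1]]
        assert boundaries == sorted(boundaries)
        assert len(boundaries) == len(set(boundaries))

    def test_cap_one_keeps_nearest_to_centroid(self):
        # one cell spanning [0,10): two points, p1 closer to centroid 5
        ids = ["near", "far_low", "far_high"]
        scores = np.array([[4.9], [0.2], [9.9]])
        grid = build_grid(np.array([[0.0], [10.0]]), 1)
        out = grid_sample(ids, scores, grid, per_cell_cap=1)
        centroid = 5.0
        dists = {i: abs(s[0] - centroid) for i, s in zip(ids, scores)}
        assert out == [min(dists, key=dists.get)]

    def test_deterministic(self, rng):
        ids = [f"c{i}" for i in range(300)]
        scores = rng.normal(size=(300, 3))
        grid = build_grid(scores, 4)
        assert grid_sample(ids, scores, grid, 2) == grid_sample(ids, scores, grid, 2)

    def test_tie_broken_by_id(self):
        # two points equidistant from the centroid: lexicographically smaller id first
        scores = np.array([[4.0], [6.0]])
        grid = build_grid(np.array([[0.0], [10.0]]), 1)
        assert grid_sample(["b", "a"], scores, grid) == ["a", "b"]

    def test_empty(self):
        grid = build_grid(np.array([[0.0], [1.0]]), 2)
        assert grid_sample([], np.empty((0, 1)), grid) == []


def oracle_all_pairs_check(retained, vectors, threshold):
    for i, a in enumerate(retained):
        for b in retained[i + 1 :]:
            d = continuous_tanimoto_distance(vectors.loc[a], vectors.loc[b])
            if d <= threshold:
                return False
    return True


def oracle_maximality(candidates, retained, vectors, threshold):
    kept = set(retained)
    for cid in candidates:
        if cid in kept:
            continue
        close = any(
            continuous_tanimoto_distance(vectors.loc[cid], vectors.loc[r]) <= threshold
            for r in retained
        )
        if not close:
            return False
    return True


class TestDissimilarityFilter:
    def vectors(self, rows, ids=None):
        rows = np.asarray(rows, dtype=float)
        ids = ids or [f"c{i}" for i in range(len(rows))]
        return pd.DataFrame(rows, index=ids)

    def test_all_identical_keeps_one(self):
        v = self.vectors(np.tile([1.0, 2.0, 3.0], (10, 1)))
        retained, skipped = dissimilarity_filter(list(v.index), v, 0.15)
        assert retained == ["c0"]
        assert skipped == 0

    def test_all_far_apart_keeps_all(self, rng):
        rows = np.eye(20) * 5.0  # orthogonal -> pairwise distance 1
        v = self.vectors(rows)
        retained, _ = dissimilarity_filter(list(v.index), v, 0.15)
        assert retained == list(v.index)

    def test_brute_force_oracle_200(self, rng):
        rows = rng.normal(size=(200, 13)) + rng.normal(size=(1, 13))
        v = self.vectors(rows)
        retained, _ = dissimilarity_filter(list(v.index), v, 0.15)
        assert oracle_all_pairs_check(retained, v, 0.15)
        assert oracle_maximality(list(v.index), retained, v, 0.15)
        assert 0 < len(retained) <= 200

    def test_degenerate_vector_skipped(self):
        rows = [[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]
        v = self.vectors(rows)
        retained, skipped = dissimilarity_filter(list(v.index), v, 0.15)
        assert skipped == 1
        assert retained == ["c1", "c2"]

    def test_greedy_prefix_property(self, rng):
        # lowering the threshold can only retain a superset under greedy order
        rows = rng.normal(size=(100, 13))
        v = self.vectors(rows)
        loose, _ = dissimilarity_filter(list(v.index), v, 0.05)
        tight, _ = dissimilarity_filter(list(v.index), v, 0.3)
        assert set(tight) <= set(loose)

    def test_unknown_metric(self):
        v = self.vectors([[1.0, 0.0]])
        with pytest.raises(ValidationError):
            dissimilarity_filter(["c0"], v, 0.15, metric="nope")


class TestEsiFilter:
    CONFIG = SelectionConfig()

    def run(self, log_ie, hbd, polarity):
        ids = list(log_ie)
        return esi_filter(ids, log_ie, hbd, polarity, self.CONFIG)

    def test_positive_boundary_excluded(self):
        kept, _ = self.run({"a": 3.5}, {"a": 1}, POSITIVE)
        assert kept == []  # strict >

    def test_positive_above_included(self):
        kept, _ = self.run({"a": 3.50001}, {"a": 0}, POSITIVE)
        assert kept == ["a"]

    def test_negative_boundary_excluded(self):
        kept, _ = self.run({"a": 1.5}, {"a": 2}, NEGATIVE)
        assert kept == []  # strict <

    def test_negative_no_donor_excluded(self):
        kept, _ = self.run({"a": 1.2}, {"a": 0}, NEGATIVE)
        assert kept == []

    def test_negative_both_criteria_included(self):
        kept, _ = self.run({"a": 1.2}, {"a": 2}, NEGATIVE)
        assert kept == ["a"]

    def test_missing_log_ie_dropped_with_count(self):
        kept, missing = esi_filter(["a", "b"], {"b": 4.0}, {"a": 1, "b": 1}, POSITIVE, self.CONFIG)
        assert kept == ["b"]
        assert missing == 1

    def test_monotone_in_threshold(self, rng):
        ids = [f"c{i}" for i in range(100)]
        log_ie = {i: float(v) for i, v in zip(ids, rng.uniform(0, 7, 100))}
        hbd = {i: 1 for i in ids}
        lo_cfg = SelectionConfig(logie_pos_min=3.0)
        hi_cfg = SelectionConfig(logie_pos_min=4.0)
        kept_lo, _ = esi_filter(ids, log_ie, hbd, POSITIVE, lo_cfg)
        kept_hi, _ = esi_filter(ids, log_ie, hbd, POSITIVE, hi_cfg)
        assert set(kept_hi) <= set(kept_lo)


class TestRankAndSelect:
    def test_descending_log_ie(self):
        ranked, _ = rank_and_select(["a", "b"], {"a": 1, "b": 1}, {"a": 4.2, "b": 4.8}, 50)
        assert ranked == [("b", 1), ("a", 2)]

    def test_per_class_counts(self, rng):
        ids = [f"c{i:03d}" for i in range(300)]
        mobility = {i: 1 + (n % 3) for n, i in enumerate(ids)}
        log_ie = {i: float(v) for i, v in zip(ids, rng.uniform(0, 7, 300))}
        ranked, shortfall = rank_and_select(ids, mobility, log_ie, 50)
        assert len(ranked) == 150
        assert shortfall == {}
        assert [r for _, r in ranked] == list(range(1, 151))

    def test_class_order_then_logie(self):
        ids = ["p", "q", "r", "s"]
        mobility = {"p": 2, "q": 1, "r": 2, "s": 3}
        log_ie = {"p": 5.0, "q": 0.1, "r": 6.0, "s": 9.9}
        ranked, _ = rank_and_select(ids, mobility, log_ie, 50)
        assert ranked == [("q", 1), ("r", 2), ("p", 3), ("s", 4)]

    def test_shortfall_warning(self):
        ids = [f"c{i}" for i in range(10)]
        mobility = {i: 1 for i in ids}
        log_ie = {i: 4.0 for i in ids}
        ranked, shortfall = rank_and_select(ids, mobility, log_ie, 50)
        assert len(ranked) == 10
        assert shortfall == {1: 40, 2: 50, 3: 50}

    def test_tie_broken_by_id(self):
        ranked, _ = rank_and_select(["z", "a"], {"z": 1, "a": 1}, {"z": 4.0, "a": 4.0}, 50)
        assert ranked == [("a", 1), ("z", 2)]


def brute_force_cascade(features, scores, grid, config):
    """Independent reimplementation of the full cascade (plain loops/sets)."""
    ids = list(features.index)
    cells, _ = assign_cells(scores, grid)
    cell_of = dict(zip(ids, map(tuple, cells)))
    # stage 1: per-cell ordering by centroid distance, lex cell order
    ordered = []
    for cell in sorted(set(cell_of.values())):
        members = [i for i in ids if cell_of[i] == cell]
        centroid = grid.centroid(cell)
        members.sort(
            key=lambda i: (
                float(np.linalg.norm(scores[ids.index(i)] - centroid)),
                i,
            )
        )
        if config.per_cell_cap is not None:
            members = members[: config.per_cell_cap]
        ordered.extend(members)
    # stage 2: greedy dissimilarity on standardized features
    numeric = features[[c for c in features.columns if c != "smiles"]]
    scal = fit_scaling(numeric.to_numpy(), names=list(numeric.columns))
    Z = pd.DataFrame(apply_scaling(numeric.to_numpy(), scal), index=features.index)
    kept = []
    for cid in ordered:
        x = Z.loc[cid].to_numpy()
        if not x.any():
            continue
        if all(continuous_tanimoto_distance(x, Z.loc[r].to_numpy()) > config.distance_threshold for r in kept):
            kept.append(cid)
    # stage 3+4 per polarity
    out = {}
    for polarity in (POSITIVE, NEGATIVE):
        eligible = []
        for cid in kept:
            ie = features.loc[cid, "log_ie"]
            if polarity == POSITIVE and ie > config.logie_pos_min:
                eligible.append(cid)
            if (
                polarity == NEGATIVE
                and ie < config.logie_neg_max
                and features.loc[cid, "hbd"] >= config.hbd_min_neg
            ):
                eligible.append(cid)
        selected = []
        for cls in (1, 2, 3):
            members = [c for c in eligible if features.loc[c, "mobility_class"] == cls]
            members.sort(key=lambda c: (-features.loc[c, "log_ie"], c))
            selected.extend(members[: config.per_class_n])
        out[polarity] = selected
    return out


class TestBuildMcl:
    def run(self, features, bins=4, k=2, config=None):
        config = config or SelectionConfig(per_class_n=10)
        names = [c for c in features.columns if c != "smiles"]
        X = features[names].to_numpy(dtype=float)
        scal = fit_scaling(X, names=names)
        Z = apply_scaling(X, scal)
        from mclspace.chemspace import fit_pca, project

        pca = fit_pca(Z, k)
        scores = project(Z, pca)
        grid = build_grid(scores, bins)
        return build_mcl(features, scores, grid, config), scores, grid, config

    def test_polarity_lists_disjoint(self, small_feature_table):
        features, _ = small_feature_table
        (result, report), *_ = self.run(features)
        pos = {e.id for e in result[POSITIVE]}
        neg = {e.id for e in result[NEGATIVE]}
        assert pos.isdisjoint(neg)

    def test_empty_input(self):
        features = pd.DataFrame(columns=["mw", "hbd", "mobility_class", "log_ie"]).astype(float)
        grid = build_grid(np.array([[0.0], [1.0]]), 2)
        result, report = build_mcl(features, np.empty((0, 1)), grid, SelectionConfig())
        assert result[POSITIVE] == [] and result[NEGATIVE] == []
        assert report.n_input == 0

    def test_matches_brute_force_cascade(self, small_feature_table):
        features, _ = small_feature_table
        (result, _), scores, grid, config = self.run(features)
        expected = brute_force_cascade(features, scores, grid, config)
        assert [e.id for e in result[POSITIVE]] == expected[POSITIVE]
        assert [e.id for e in result[NEGATIVE]] == expected[NEGATIVE]

    def test_all_pairs_property_on_output(self, small_feature_table):
        features, _ = small_feature_table
        (result, _), scores, grid, config = self.run(features)
        names = [c for c in features.columns if c != "smiles"]
        X = features[names].to_numpy(dtype=float)
        Z = pd.DataFrame(
            apply_scaling(X, fit_scaling(X, names=names)), index=features.index
        )
        emitted = [e.id for e in result[POSITIVE]] + [e.id for e in result[NEGATIVE]]
        sub = Z.loc[emitted]
        assert oracle_all_pairs_check(emitted, sub, config.distance_threshold)

    def test_entries_well_formed(self, small_feature_table):
        features, _ = small_feature_table
        (result, report), scores, grid, _ = self.run(features)
        for polarity, entries in result.items():
            ranks = [e.rank for e in entries]
            assert ranks == list(range(1, len(entries) + 1))
            ids = [e.id for e in entries]
            assert len(set(ids)) == len(ids)
            assert all(i in features.index for i in ids)
            for e in entries:
                assert e.polarity == polarity
                assert e.log_ie == pytest.approx(float(features.loc[e.id, "log_ie"]))

    def test_deterministic_repeat(self, small_feature_table):
        features, _ = small_feature_table
        (r1, _), *_ = self.run(features)
        (r2, _), *_ = self.run(features)
        assert r1 == r2

    def test_stage_report_counts(self, small_feature_table):
        features, _ = small_feature_table
        (result, report), *_ = self.run(features)
        assert report.n_input == len(features)
        assert report.n_grid_sampled == len(features)  # unlimited cap
        assert report.n_dissimilar <= report.n_grid_sampled
        for polarity in (POSITIVE, NEGATIVE):
            assert report.n_selected[polarity] == len(result[polarity])
            assert report.n_esi[polarity] >= report.n_selected[polarity]
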