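"""Assumption mappings, bicluster derivation, and the search loop."""

from dataclasses import replace as _replace
from fractions import Fraction

import numpy as np
import pytest

from patbic import (
    Bicluster,
    NumericDataset,
    SearchConfig,
    compute_coverage,
    derive_biclusters,
    discretize,
    evaluate_quality,
    generate,
    map_for_assumption,
    match_score,
    mine_itemsets,
    run,
)
from patbic.core import _mask_most_covered
from patbic.errors import ConfigError
from patbic.synthetic import PlantSpec, PlantedBlock


def _symbolic(grid, n_items, symmetric=False):
    grid = np.asarray(grid, dtype=float)
    d = NumericDataset([f"x{i+1}" for i in range(grid.shape[0])],
                       [f"y{j+1}" for j in range(grid.shape[1])],
                       grid)
    return discretize(d, n_items, "none", symmetric=symmetric)


class TestMapForAssumption:
    def test_constant_transaction_count(self, rng):
        sym = _symbolic(rng.integers(0, 5, (6, 4)), 5)
        db = map_for_assumption(sym, "constant", SearchConfig())
        assert len(db) == 6

    def test_additive_shift_variants(self):
        # two rows agreeing up to shifts 5 and 1 share the pattern (1,0,1,0)
        sym = _symbolic([[6, 5, 6, 5], [2, 1, 2, 1]], 8)
        db = map_for_assumption(sym, "additive", SearchConfig())
        shifted = {}
        for t, (row, gamma) in zip(db.transactions, db.provenance):
            decoded = tuple(s for _, s in sorted(db.decode(i) for i in t))
            shifted.setdefault(decoded, set()).add((row, gamma))
        assert (1, 0, 1, 0) in shifted
        assert {(0, 5), (1, 1)} <= shifted[(1, 0, 1, 0)]

    def test_symmetric_equivariance(self, rng):
        grid = rng.integers(-2, 3, (5, 4))
        pos = map_for_assumption(_symbolic(grid, 5, True), "symmetric", SearchConfig())
        neg = map_for_assumption(_symbolic(-grid, 5, True), "symmetric", SearchConfig())
        # same transactions up to sign tags
        a = {(r, tag): t for t, (r, tag) in zip(pos.transactions, pos.provenance)}
        b = {(r, -tag): t for t, (r, tag) in zip(neg.transactions, neg.provenance)}
        assert a == b

    def test_symmetric_needs_symmetric_alphabet(self, rng):
        sym = _symbolic(rng.integers(0, 5, (3, 3)), 5, symmetric=False)
        with pytest.raises(ConfigError):
            map_for_assumption(sym, "symmetric", SearchConfig())

    def test_multiplicative_scale_variants(self):
        # row (2,4,2) is twice the pattern (1,2,1)
        sym = _symbolic([[1, 2, 1], [2, 4, 2]], 5)
        db = map_for_assumption(sym, "multiplicative", SearchConfig())
        patterns = {}
        for t, (row, scale) in zip(db.transactions, db.provenance):
            decoded = tuple(s for _, s in sorted(db.decode(i) for i in t))
            patterns.setdefault(decoded, set()).add((row, scale))
        assert (1, 2, 1) in patterns
        assert {(0, Fraction(1)), (1, Fraction(2))} <= patterns[(1, 2, 1)]

    def test_order_preserving_sequences(self):
        sym = _symbolic([[2, 0, 1], [2, 0, 1]], 3)
        db = map_for_assumption(sym, "order_preserving", SearchConfig())
        assert db.sequences[0] == ((1,), (2,), (0,))


class TestDeriveBiclusters:
    def test_additive_worked_example(self):
        """Rows built from pattern (1,0,1,0) with shifts 5 and 1 over columns
        y1,y2,y4,y5 yield exactly that additive bicluster (y3 differs)."""
        sym = _symbolic([[6, 5, 9, 6, 5], [2, 1, 3, 2, 1]], 10)
        cfg = SearchConfig(min_cols=4, representation="closed")
        db = map_for_assumption(sym, "additive", cfg)
        patterns = mine_itemsets(db, 2, "closed", "charm_diffsets")
        bics = derive_biclusters(patterns, db, "additive", cfg, symbolic=sym)
        assert len(bics) == 1
        b = bics[0]
        assert set(b.rows) == {"x1", "x2"}
        assert set(b.cols) == {"y1", "y2", "y4", "y5"}
        assert b.pattern == (1, 0, 1, 0)
        assert b.adjustments == {"x1": 5, "x2": 1}
        assert b.noisy_fraction == 0.0

    def test_min_cols_filter(self):
        sym = _symbolic([[1, 2], [1, 2]], 5)
        cfg = SearchConfig(min_cols=3)
        db = map_for_assumption(sym, "constant", cfg)
        patterns = mine_itemsets(db, 2, "closed", "charm_diffsets")
        assert derive_biclusters(patterns, db, "constant", cfg) == []

    def test_planted_constant_recovered_exactly(self, rng):
        spec = PlantSpec(n_rows=30, n_cols=12, n_items=5, seed=11,
                         planted=[PlantedBlock(8, 5, "constant")])
        data, truth = generate(spec)
        sym = discretize(data, 5, "none")
        cfg = SearchConfig(min_cols=4)
        db = map_for_assumption(sym, "constant", cfg)
        patterns = mine_itemsets(db, 8, "closed", "charm_diffsets")
        bics = derive_biclusters(patterns, db, "constant", cfg)
        keys = {b.key() for b in bics}
        assert truth[0].key() in keys


class TestEvaluateQuality:
    def test_noise_free_constant(self):
        sym = _symbolic([[1, 2], [1, 2]], 5)
        b = Bicluster(rows=("x1", "x2"), cols=("y1", "y2"),
                      pattern=(1, 2), assumption="constant")
        evaluate_quality(b, sym)
        assert b.noisy_fraction == 0.0 and b.missing_fraction == 0.0

    def test_counts_noisy_and_missing(self):
        grid = np.array([[1.0, 2.0], [1.0, np.nan], [0.0, 2.0]])
        d = NumericDataset(["x1", "x2", "x3"], ["y1", "y2"], grid)
        sym = discretize(d, 5, "none")
        b = Bicluster(rows=("x1", "x2", "x3"), cols=("y1", "y2"),
                      pattern=(1, 2), assumption="constant")
        evaluate_quality(b, sym)
        assert b.missing_fraction == pytest.approx(1 / 6)
        assert b.noisy_fraction == pytest.approx(1 / 6)

    def test_order_preserving_row_violations(self):
        sym = _symbolic([[0, 1, 2], [2, 1, 0]], 3)
        b = Bicluster(rows=("x1", "x2"), cols=("y1", "y2", "y3"),
                      pattern=(0, 1, 2), assumption="order_preserving")
        evaluate_quality(b, sym)
        # x1 follows the order; x2 reverses it (keep 1 of 3 cells)
        assert b.noisy_fraction == pytest.approx(2 / 6)


class TestRun:
    def test_stop_at_one_bicluster(self):
        spec = PlantSpec(n_rows=40, n_cols=15, n_items=5, seed=5,
                         planted=[PlantedBlock(10, 6, "constant")])
        data, truth = generate(spec)
        cfg = SearchConfig(normalization="none", discretization="none",
                           stop="nbics", stop_value=1, n_iterations=1,
                           quality=1.0, seed=2)
        sol = run(data, cfg)
        assert len(sol) >= 1
        rec, _ = match_score(sol, truth)
        assert rec == 1.0

    def test_coverage_criterion_met(self):
        spec = PlantSpec(n_rows=40, n_cols=15, n_items=3, seed=6,
                         planted=[PlantedBlock(12, 6, "constant")])
        data, _ = generate(spec)
        cfg = SearchConfig(normalization="none", discretization="none",
                           n_items=3, stop="coverage", stop_value=0.2,
                           n_iterations=1, min_cols=2, seed=2)
        sol = run(data, cfg)
        assert compute_coverage(sol, data) >= 0.2

    def test_masking_reveals_second_module(self):
        spec = PlantSpec(n_rows=60, n_cols=20, n_items=5, seed=9,
                         planted=[PlantedBlock(20, 8, "constant"),
                                  PlantedBlock(8, 5, "constant")])
        data, truth = generate(spec)
        cfg = SearchConfig(normalization="none", discretization="none",
                           stop="nbics", stop_value=2, n_iterations=2,
                           min_cols=4, quality=1.0, seed=3)
        sol = run(data, cfg)
        rec, _ = match_score(sol, truth)
        assert rec == 1.0  # both planted modules present
        # control: a single iteration saturates on the dominant module
        single = run(data, _replace(cfg, n_iterations=1, stop_value=1))
        rec1, _ = match_score(single, truth)
        assert rec1 < 1.0

    def test_deterministic_under_seed(self):
        spec = PlantSpec(n_rows=30, n_cols=12, n_items=5, seed=4,
                         planted=[PlantedBlock(8, 5, "constant")])
        data, _ = generate(spec)
        cfg = SearchConfig(normalization="none", discretization="none",
                           stop="nbics", stop_value=3, seed=17)
        a = run(data, cfg)
        b = run(data, cfg)
        assert [(x.rows, x.cols, x.pattern) for x in a] == \
            [(y.rows, y.cols, y.pattern) for y in b]

    def test_plaid_rejected(self, small_matrix):
        with pytest.raises(NotImplementedError):
            run(small_matrix, SearchConfig(assumption="plaid"))


class TestMasking:
    def test_quarter_of_covered_cells_masked(self):
        d = NumericDataset([f"r{i}" for i in range(10)],
                           [f"c{j}" for j in range(10)],
                           np.zeros((10, 10)))
        bics = [Bicluster(rows=tuple(f"r{i}" for i in range(6)),
                          cols=tuple(f"c{j}" for j in range(6)),
                          pattern=(0,) * 6, assumption="constant")]
        rng = np.random.default_rng(0)
        masked, n = _mask_most_covered(d, bics, rng)
        covered = 36
        assert abs(n - round(0.25 * covered)) <= 1
        assert masked.n_nonmissing == 100 - n

    def test_most_covered_masked_first(self):
        d = NumericDataset(["r0", "r1"], ["c0", "c1", "c2", "c3"],
                           np.zeros((2, 4)))
        overlap = [
            Bicluster(rows=("r0",), cols=("c0", "c1", "c2", "c3"),
                      pattern=(0,) * 4, assumption="constant"),
            Bicluster(rows=("r0", "r1"), cols=("c0",),
                      pattern=(0,), assumption="constant"),
        ]
        masked, n = _mask_most_covered(d, overlap, np.random.default_rng(0))
        assert n == 1
        assert masked.is_missing(0, 0)  # (r0, c0) covered twice


class TestComputeCoverage:
    def test_empty_solution(self, small_matrix):
        assert compute_coverage([], small_matrix) == 0.0

    def test_full_cover(self):
        d = NumericDataset(["r0", "r1"], ["c0", "c1"], np.ones((2, 2)))
        b = Bicluster(rows=("r0", "r1"), cols=("c0", "c1"),
                      pattern=(1, 1), assumption="constant")
        assert compute_coverage([b], d) == 1.0

    def test_overlap_counts_union(self):
        d = NumericDataset(["r0", "r1"], ["c0", "c1"], np.ones((2, 2)))
        b1 = Bicluster(rows=("r0",), cols=("c0", "c1"),
                       pattern=(1, 1), assumption="constant")
        b2 = Bicluster(rows=("r0", "r1"), cols=("c0",),
                       pattern=(1,), assumption="constant")
        assert compute_coverage([b1, b2], d) == pytest.approx(3 / 4)


class TestMonotonicity:
    def test_lower_support_never_fewer_pre_closing_biclusters(self, rng):
        spec = PlantSpec(n_rows=40, n_cols=15, n_items=3, seed=14,
                         planted=[PlantedBlock(10, 6, "constant")])
        data, _ = generate(spec)
        sym = discretize(data, 3, "none")
        cfg = SearchConfig(min_cols=2)
        db = map_for_assumption(sym, "constant", cfg)
        counts = []
        for support in (12, 8, 5, 3):
            patterns = mine_itemsets(db, support, "closed", "charm_diffsets")
            counts.append(len(derive_biclusters(patterns, db, "constant", cfg)))
        assert counts == sorted(counts)


class TestConfigValidation:
    def test_additive_symmetric_needs_odd_items(self):
        cfg = SearchConfig(assumption="additive", n_items=4, symmetries=True)
        with pytest.raises(ConfigError):
            cfg.resolve(True, 10)

    def test_multiplicative_symmetric_needs_even_items(self):
        cfg = SearchConfig(assumption="multiplicative", n_items=5, symmetries=True)
        with pytest.raises(ConfigError):
            cfg.resolve(True, 10)

    def test_dynamic_symmetries_follow_negatives(self):
        assert SearchConfig().resolve(True, 10).symmetries is True
        assert SearchConfig().resolve(False, 10).symmetries is False

    def test_dynamic_miner_by_representation(self):
        assert SearchConfig().resolve(False, 10).miner == "charm_diffsets"
        assert SearchConfig(representation="maximal").resolve(False, 10).miner == "charm_mfi"
        assert SearchConfig(representation="simple").resolve(False, 10).miner == "fpgrowth"
        assert SearchConfig(assumption="order_preserving").resolve(False, 10).miner == "bide"

    def test_auto_min_cols(self):
        assert SearchConfig(min_cols="auto").resolve(False, 30).min_cols == 6
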