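"""Merging, filtering, extension/reduction and significance annotation."""

import numpy as np
import pytest
from scipy import stats

from patbic import (
    Bicluster,
    NumericDataset,
    discretize,
    extend_reduce,
    filter_biclusters,
    merge,
    significance,
)
from patbic.errors import ConfigError


def _bic(rows, cols, pattern=None, assumption="constant"):
    rows = tuple(rows)
    cols = tuple(cols)
    return Bicluster(rows=rows, cols=cols,
                     pattern=pattern or (0,) * len(cols),
                     assumption=assumption)


def _grid_bic(r0, r1, c0, c1):
    return _bic([f"r{i}" for i in range(r0, r1)],
                [f"c{j}" for j in range(c0, c1)])


class TestMerge:
    def test_disjoint_pair_unchanged(self):
        out = merge([_grid_bic(0, 3, 0, 3), _grid_bic(5, 8, 5, 8)], 0.8)
        assert len(out) == 2

    def test_identical_pair_collapses(self):
        out = merge([_grid_bic(0, 3, 0, 3), _grid_bic(0, 3, 0, 3)], 0.8)
        assert len(out) == 1

    def test_85_percent_overlap_merges_at_08(self):
        # smaller: 2x20=40 elements, 34 shared with the larger (85%)
        big = _grid_bic(0, 10, 0, 17)
        small = Bicluster(
            rows=("r0", "r1"),
            cols=tuple(f"c{j}" for j in range(17)) + ("w0", "w1", "w2"),
            pattern=(0,) * 20, assumption="constant")
        assert len(small.elements() & big.elements()) / 40 == 0.85
        out = merge([big, small], 0.8)
        assert len(out) == 1
        assert set(out[0].rows) == set(big.rows) | set(small.rows)
        assert set(out[0].cols) == set(big.cols) | set(small.cols)

    def test_threshold_one_never_fuses_partial_overlaps(self):
        # non-nested pair sharing most elements: untouched at threshold 1.0
        a = _grid_bic(0, 3, 0, 4)
        b = Bicluster(rows=("r0", "r1", "r2"),
                      cols=("c0", "c1", "c2", "w0"),
                      pattern=(0,) * 4, assumption="constant")
        assert len(merge([a, b], 1.0)) == 2
        # a nested pair collapses onto the superset (100% overlap of the
        # smaller by the min-denominator definition)
        sub = _grid_bic(0, 2, 0, 4)
        out = merge([a, sub], 1.0)
        assert len(out) == 1 and out[0].key() == a.key()

    def test_strategies_agree_on_simple_input(self):
        bics = [_grid_bic(0, 4, 0, 4), _grid_bic(0, 4, 0, 5),
                _grid_bic(8, 12, 8, 12)]
        a = merge(bics, 0.8, strategy="heuristic")
        b = merge(bics, 0.8, strategy="combinatorial")
        assert {x.key() for x in a} == {y.key() for y in b}

    def test_never_increases_cardinality(self, rng):
        bics = [
            _grid_bic(int(a), int(a) + 3, int(b), int(b) + 3)
            for a, b in rng.integers(0, 8, size=(12, 2))
        ]
        assert len(merge(bics, 0.8)) <= len(bics)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ConfigError):
            merge([_grid_bic(0, 2, 0, 2)], 0.0)

    def test_quality_veto_blocks_noisy_fusion(self):
        # two biclusters with conflicting patterns overlap heavily: the
        # merged block would violate a strict quality bound
        grid = np.zeros((6, 5))
        grid[5, :] = 4.0
        d = NumericDataset([f"r{i}" for i in range(6)],
                           [f"c{j}" for j in range(5)], grid)
        sym = discretize(d, 5, "none")
        a = _grid_bic(0, 5, 0, 5)               # all-zero block
        b = Bicluster(rows=tuple(f"r{i}" for i in [0, 1, 2, 3, 5]),
                      cols=tuple(f"c{j}" for j in range(5)),
                      pattern=(0,) * 5, assumption="constant")
        merged_free = merge([a, b], 0.8)
        assert len(merged_free) == 1
        vetoed = merge([a, b], 0.8, symbolic=sym, quality=1.0)
        assert len(vetoed) == 2


class TestFilter:
    @staticmethod
    def _small(n_shared_cols, n_outside_cols):
        """2-row bicluster sharing 2 x n_shared_cols elements with a grid
        bicluster over rows r0.. and columns c0.. ."""
        return Bicluster(
            rows=("r0", "r1"),
            cols=tuple(f"c{j}" for j in range(n_shared_cols))
            + tuple(f"w{k}" for k in range(n_outside_cols)),
            pattern=(0,) * (n_shared_cols + n_outside_cols),
            assumption="constant")

    def test_removal_strictly_above_80_at_20_dissimilarity(self):
        big = _grid_bic(0, 20, 0, 20)  # 400 elements
        small_80 = self._small(16, 4)  # 32 of 40 shared = exactly 80%
        assert len(filter_biclusters([big, small_80], "elements", 0.2)) == 2
        small_85 = self._small(17, 3)  # 34 of 40 shared = 85%
        out = filter_biclusters([big, small_85], "elements", 0.2)
        assert [b.key() for b in out] == [big.key()]

    def test_default_removes_above_60(self):
        big = _grid_bic(0, 20, 0, 10)
        small = Bicluster(  # 10 elements, 7 shared = 70%
            rows=("r0",),
            cols=tuple(f"c{j}" for j in range(7)) + ("w0", "w1", "w2"),
            pattern=(0,) * 10, assumption="constant")
        assert len(filter_biclusters([big, small], "elements", 0.4)) == 1
        small_60 = Bicluster(  # 10 elements, 6 shared = 60%: retained
            rows=("r0",),
            cols=tuple(f"c{j}" for j in range(6)) + ("w0", "w1", "w2", "w3"),
            pattern=(0,) * 10, assumption="constant")
        assert len(filter_biclusters([big, small_60], "elements", 0.4)) == 2

    def test_disjoint_unchanged(self):
        bics = [_grid_bic(0, 3, 0, 3), _grid_bic(5, 9, 5, 9)]
        assert len(filter_biclusters(bics, "elements", 0.4)) == 2

    def test_largest_never_removed(self, rng):
        bics = [
            _grid_bic(int(a), int(a) + int(s), int(b), int(b) + int(s))
            for a, b, s in zip(rng.integers(0, 5, 10), rng.integers(0, 5, 10),
                               rng.integers(2, 6, 10))
        ]
        largest = max(bics, key=lambda b: b.n_elements)
        out = filter_biclusters(bics, "elements", 0.4)
        assert largest.key() in {b.key() for b in out}

    def test_rows_criterion(self):
        big = _grid_bic(0, 10, 0, 10)
        small = _bic([f"r{i}" for i in range(8)], ["w0", "w1"])
        # shares 100% of its rows, 0% of its elements
        assert len(filter_biclusters([big, small], "rows", 0.4)) == 1
        assert len(filter_biclusters([big, small], "elements", 0.4)) == 2

    def test_output_pairwise_dissimilar(self, rng):
        bics = [
            _grid_bic(int(a), int(a) + int(s), int(b), int(b) + int(s))
            for a, b, s in zip(rng.integers(0, 6, 15), rng.integers(0, 6, 15),
                               rng.integers(2, 7, 15))
        ]
        out = filter_biclusters(bics, "elements", 0.4)
        for i, b in enumerate(out):
            for r in out:
                if r.n_elements > b.n_elements:
                    share = len(b.elements() & r.elements()) / b.n_elements
                    assert share <= 0.6 + 1e-12


class TestExtendReduce:
    def _fixture(self):
        """8x5 coherent block inside a 12x8 grid; r8 matches 90% of it."""
        rng = np.random.default_rng(42)
        grid = rng.integers(0, 5, size=(12, 8)).astype(float)
        grid[:8, :5] = 2.0
        grid[8, :5] = 2.0
        grid[8, 0] = 4.0  # one mismatching cell in the candidate row: 20% of 5
        # make sure non-block columns do not accidentally extend
        d = NumericDataset([f"r{i}" for i in range(12)],
                           [f"c{j}" for j in range(8)], grid)
        return discretize(d, 5, "none")

    def test_noise_free_maximal_identity_at_quality_one(self):
        sym = self._fixture()
        b = _bic([f"r{i}" for i in range(8)], [f"c{j}" for j in range(5)],
                 pattern=(2,) * 5)
        out = extend_reduce(b, sym, quality=1.0)
        assert set(out.rows) >= set(b.rows) and set(out.cols) >= set(b.cols)
        assert out.noisy_fraction == 0.0

    def test_tolerant_quality_adds_noisy_row(self):
        sym = self._fixture()
        b = _bic([f"r{i}" for i in range(8)], [f"c{j}" for j in range(5)],
                 pattern=(2,) * 5)
        out = extend_reduce(b, sym, quality=0.8)
        assert "r8" in out.rows

    def test_strict_quality_excludes_noisy_row(self):
        sym = self._fixture()
        b = _bic([f"r{i}" for i in range(8)], [f"c{j}" for j in range(5)],
                 pattern=(2,) * 5)
        out = extend_reduce(b, sym, quality=1.0)
        assert "r8" not in out.rows


class TestSignificance:
    def _uniform_symbolic(self, rng, n=100, m=20, L=5):
        grid = rng.integers(0, L, size=(n, m)).astype(float)
        d = NumericDataset([f"r{i}" for i in range(n)],
                           [f"c{j}" for j in range(m)], grid)
        return d, discretize(d, L, "none")

    def test_pattern_in_all_rows_gives_one(self):
        d = NumericDataset(["r0", "r1"], ["c0", "c1"], np.ones((2, 2)))
        sym = discretize(d, 5, "none")
        b = _bic(["r0", "r1"], ["c0", "c1"], pattern=(1, 1))
        assert significance(b, sym) == 1.0

    def test_planted_block_highly_significant(self, rng):
        d, _ = self._uniform_symbolic(rng)
        dense = d.to_dense()
        dense[:10, :5] = 2.0
        d2 = NumericDataset(d.row_ids, d.col_ids, dense)
        sym = discretize(d2, 5, "none")
        b = _bic([f"r{i}" for i in range(10)], [f"c{j}" for j in range(5)],
                 pattern=(2,) * 5)
        assert significance(b, sym) < 1e-4

    def test_matches_binomial_tail(self, rng):
        """The closed form equals the binomial tail at the empirical
        per-row probability (Monte-Carlo cross-check of the model)."""
        d, sym = self._uniform_symbolic(rng, n=50, m=6, L=3)
        b = _bic([f"r{i}" for i in range(12)], ["c0", "c1"], pattern=(1, 1))
        # empirical marginals
        f0 = np.mean([1 in sym.cells[(i, 0)] for i in range(50)])
        f1 = np.mean([1 in sym.cells[(i, 1)] for i in range(50)])
        expected = stats.binom.sf(11, 50, f0 * f1)
        assert significance(b, sym) == pytest.approx(expected, rel=1e-9)

    def test_matches_monte_carlo_null(self, rng):
        """The closed form agrees with the empirical tail frequency over
        simulated datasets drawn from the model's null (cells i.i.d. from
        the empirical column marginals) within 3 Monte-Carlo sd."""
        n, m, L, n_sim = 30, 3, 2, 10000
        grid = rng.integers(0, L, size=(n, m)).astype(float)
        d = NumericDataset([f"r{i}" for i in range(n)],
                           [f"c{j}" for j in range(m)], grid)
        sym = discretize(d, L, "none")
        support = 10
        b = _bic([f"r{i}" for i in range(support)], ("c0", "c1"),
                 pattern=(1, 1))
        p_model = significance(b, sym)
        f0 = np.mean(grid[:, 0] == 1)
        f1 = np.mean(grid[:, 1] == 1)
        hits = 0
        for _ in range(n_sim):
            a = rng.random(n) < f0
            c = rng.random(n) < f1
            if int(np.sum(a & c)) >= support:
                hits += 1
        p_emp = hits / n_sim
        mc_sd = np.sqrt(max(p_model * (1 - p_model), 1e-12) / n_sim)
        assert abs(p_emp - p_model) <= 3 * mc_sd

    def test_monotone_in_support(self, rng):
        d, sym = self._uniform_symbolic(rng)
        ps = []
        for k in (5, 10, 20):
            b = _bic([f"r{i}" for i in range(k)], ["c0", "c1", "c2"],
                     pattern=(1, 1, 1))
            ps.append(significance(b, sym))
        assert ps[0] >= ps[1] >= ps[2]
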