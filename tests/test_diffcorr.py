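"""Differential correlation: preprocessing, the Fisher z test, BH FDR,
and the all-pairs driver."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iopgenes import diffcorr as dc
from iopgenes import synthetic as syn
from iopgenes.records import GeneSet, GroupedExpressionMatrix


def _matrix(values, groups):
    df = pd.DataFrame(values)
    return GroupedExpressionMatrix(values=df, groups=groups)


def _toy_groups(n1=5, n2=5):
    cols = [f"c{i}" for i in range(n1)] + [f"p{i}" for i in range(n2)]
    groups = {c: ("ctl" if c.startswith("c") else "poag") for c in cols}
    return cols, groups


def bh_oracle(p):
    """Brute-force min-over-tail definition of the BH step-up adjustment."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        running = min(running, p[order[rank]] * m / (rank + 1))
        adj_sorted[rank] = running
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestPreprocess:
    def _base(self, extra_rows=None):
        rng = np.random.default_rng(0)
        cols, groups = _toy_groups()
        data = {g: rng.normal(size=10) for g in "ABC"}
        df = pd.DataFrame(data, index=cols).T
        if extra_rows is not None:
            df = pd.concat([df, extra_rows])
        return GroupedExpressionMatrix(values=df, groups=groups)

    def test_duplicate_rows_keep_first(self):
        cols, groups = _toy_groups()
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(3, 10)), index=["A", "A", "B"], columns=cols)
        out = dc.preprocess(GroupedExpressionMatrix(values=df, groups=groups))
        assert list(out.values.index) == ["A", "B"]
        assert np.allclose(out.values.loc["A"], df.iloc[0])

    def test_all_zero_gene_removed(self):
        cols, groups = _toy_groups()
        zero = pd.DataFrame([np.zeros(10)], index=["Z"], columns=cols)
        out = dc.preprocess(self._base(zero))
        assert "Z" not in out.values.index

    def test_within_group_constant_removed(self):
        """A gene constant in one group has undefined correlation there."""
        cols, groups = _toy_groups()
        row = np.concatenate([np.full(5, 7.0), np.random.default_rng(2).normal(size=5)])
        const = pd.DataFrame([row], index=["K"], columns=cols)
        out = dc.preprocess(self._base(const))
        assert "K" not in out.values.index
        # brute-force check: variance in the ctl group really is zero
        assert np.var(row[:5]) == 0.0

    def test_small_group_is_hard_error(self):
        cols, groups = _toy_groups(n1=3, n2=5)
        df = pd.DataFrame(np.random.default_rng(3).normal(size=(2, 8)), index=["A", "B"], columns=cols)
        with pytest.raises(ValueError, match="ctl"):
            dc.preprocess(GroupedExpressionMatrix(values=df, groups=groups))


class TestPearson:
    def test_perfect_and_anti(self):
        x = [1.0, 2.0, 4.0, 7.0]
        assert dc.pearson_r(x, x) == pytest.approx(1.0)
        assert dc.pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # cov = 0.75, sd_x * sd_y = 1.25 -> r = 0.6
        assert dc.pearson_r([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            dc.pearson_r([1, 1, 1, 1], [1, 2, 3, 4])


class TestFisherZ:
    def test_zero_and_closed_form(self):
        assert dc.fisher_z(0.0) == 0.0
        assert dc.fisher_z(0.5) == pytest.approx(0.5 * math.log(3), rel=1e-15)

    @given(st.floats(-0.999, 0.999))
    @settings(deadline=None, derandomize=True)
    def test_odd_function(self, r):
        assert dc.fisher_z(-r) == pytest.approx(-dc.fisher_z(r), abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            dc.fisher_z(1.0)


class TestZDifference:
    def test_equal_correlations_null(self):
        z, p = dc.z_difference_test(0.4, 13, 0.4, 14)
        assert z == 0.0 and p == 1.0

    def test_antisymmetry(self):
        z1, p1 = dc.z_difference_test(0.5, 13, -0.2, 14)
        z2, p2 = dc.z_difference_test(-0.2, 14, 0.5, 13)
        assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)

    def test_against_direct_formula(self):
        z, p = dc.z_difference_test(0.5, 13, 0.0, 14)
        se = math.sqrt(1 / 10 + 1 / 11)
        z_expected = math.atanh(0.5) / se
        assert z == pytest.approx(z_expected, rel=1e-14)
        p_expected = math.erfc(abs(z_expected) / math.sqrt(2))
        assert p == pytest.approx(p_expected, rel=1e-12)

    def test_degenerate_n_rejected(self):
        with pytest.raises(ValueError):
            dc.z_difference_test(0.5, 3, 0.0, 14)


class TestBH:
    def test_single_p_unchanged(self):
        assert dc.bh_fdr([0.03]) == pytest.approx([0.03])

    def test_all_ones(self):
        assert np.all(dc.bh_fdr([1.0] * 5) == 1.0)

    def test_step_up_small_example(self):
        assert dc.bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx(bh_oracle([0.01, 0.02, 0.03, 0.04]))

    def test_ties_share_adjusted_value(self):
        adj = dc.bh_fdr([0.02, 0.02, 0.5])
        assert adj[0] == adj[1]

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(dc.bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=50)
        adj = dc.bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestAllPairs:
    def _planted_matrix(self, seed=11):
        spec = syn.SimulationSpec(
            n_genes=3, n_group1=15, n_group2=15,
            planted_pairs=[(0, 1, 0.95, -0.95)], seed=seed, gaussian=True,
        )
        return syn.simulate_grouped_expression(spec)

    def test_planted_pair_is_top(self):
        results = dc.all_pairs_diffcorr(self._planted_matrix(), fdr_threshold=1.0)
        assert (results[0].gene_a, results[0].gene_b) == ("G0000", "G0001")
        # brute-force recomputation of the top pair's statistic; group1 is
        # the lexicographically first level ("case" here)
        mat = self._planted_matrix()
        g1 = mat.submatrix(mat.levels[0]).loc[["G0000", "G0001"]].to_numpy()
        g2 = mat.submatrix(mat.levels[1]).loc[["G0000", "G0001"]].to_numpy()
        r1 = np.corrcoef(g1)[0, 1]
        r2 = np.corrcoef(g2)[0, 1]
        z, p = dc.z_difference_test(r1, 15, r2, 15)
        assert results[0].z_stat == pytest.approx(z, rel=1e-9)

    def test_duplicated_samples_yield_null(self):
        rng = np.random.default_rng(3)
        block = rng.normal(size=(4, 8))
        cols = [f"c{i}" for i in range(8)] + [f"p{i}" for i in range(8)]
        df = pd.DataFrame(np.hstack([block, block]), index=list("ABCD"), columns=cols)
        groups = {c: ("ctl" if c.startswith("c") else "poag") for c in cols}
        results = dc.all_pairs_diffcorr(GroupedExpressionMatrix(values=df, groups=groups), fdr_threshold=1.0)
        assert all(abs(r.z_stat) < 1e-9 for r in results)

    def test_bh_over_all_enumerated_pairs(self):
        mat = self._planted_matrix()
        results = dc.all_pairs_diffcorr(mat, fdr_threshold=1.0)
        assert len(results) == 3  # C(3,2), every pair reported at threshold 1
        raw = sorted(r.p_value for r in results)
        assert results[0].fdr == pytest.approx(bh_oracle([r.p_value for r in results]).min())

    def test_focus_annotation(self):
        focus = GeneSet(["G0000"])
        results = dc.all_pairs_diffcorr(self._planted_matrix(), focus_set=focus, fdr_threshold=1.0)
        top = results[0]
        assert top.n_focus_members == 1

    def test_group_swap_negates_z_keeps_significance(self):
        mat = self._planted_matrix()
        swapped = GroupedExpressionMatrix(
            values=mat.values,
            groups={s: ("case" if g == "control" else "control") for s, g in mat.groups.items()},
        )
        a = dc.all_pairs_diffcorr(mat, fdr_threshold=0.1)
        b = dc.all_pairs_diffcorr(swapped, fdr_threshold=0.1)
        assert {(r.gene_a, r.gene_b) for r in a} == {(r.gene_a, r.gene_b) for r in b}
        za = {(r.gene_a, r.gene_b): r.z_stat for r in a}
        for r in b:
            assert r.z_stat == pytest.approx(-za[(r.gene_a, r.gene_b)], rel=1e-9)
            assert r.fdr == pytest.approx(
                next(x.fdr for x in a if (x.gene_a, x.gene_b) == (r.gene_a, r.gene_b)), rel=1e-9
            )

    def test_deterministic_ordering(self):
        mat = self._planted_matrix()
        r1 = dc.all_pairs_diffcorr(mat, fdr_threshold=1.0)
        r2 = dc.all_pairs_diffcorr(mat, fdr_threshold=1.0)
        assert [(x.gene_a, x.gene_b) for x in r1] == [(x.gene_a, x.gene_b) for x in r2]


class TestUniqueGeneCount:
    def _pair(self, a, b):
        return dc.CorrelationPairResult(a, b, 0.5, -0.5, 13, 14, 3.0, 0.001, 0.01)

    def test_small_example(self):
        pairs = [self._pair("A", "B"), self._pair("B", "C")]
        assert dc.unique_gene_count(pairs, GeneSet(["B"])) == (2, 3, 1)

    def test_empty(self):
        assert dc.unique_gene_count([]) == (0, 0, 0)

    def test_random_pairs_match_set_construction(self):
        rng = np.random.default_rng(5)
        genes = [f"X{i}" for i in range(8)]
        pairs = []
        seen = set()
        while len(pairs) < 10:
            a, b = sorted(rng.choice(genes, 2, replace=False))
            if (a, b) not in seen:
                seen.add((a, b))
                pairs.append(self._pair(a, b))
        n_pairs, n_genes, _ = dc.unique_gene_count(pairs)
        assert n_pairs == 10
        assert n_genes == len({g for ab in seen for g in ab})
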