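"""Abundance estimators, presence filter, t and rank-product tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from repdab.abundance import (
    RANKPROD_EPS,
    abundance_matrix,
    da_test,
    filter_presence,
    rank_product_test,
)
from repdab.cluster import ClusterAssignment
from repdab.io import Clonotype, RepertoireSample
from repdab.matching import SubRepertoire


def _sample(sid, counts):
    s = RepertoireSample(sample_id=sid)
    for i, c in enumerate(counts):
        s.add(Clonotype(nt_seq=f"NT{i:03d}", aa_seq="X", count=c, v_gene="V", j_gene="J"))
    return s


def _setup_one_subrep(counts, total_counts):
    """One sub-repertoire holding the first len(counts) clonotypes of sample A."""
    sample = _sample("A", total_counts)
    keys = sorted(sample.clonotypes)[: len(counts)]
    # overwrite counts for the member keys for clarity
    members = {0: keys}
    assign = ClusterAssignment(
        sample_id="A", labels={k: 0 for k in keys}, centroids={0: np.zeros(4)}, members=members
    )
    sr = SubRepertoire(id=0, members={"A": {0}})
    return sample, sr, assign


class TestAbundanceMatrix:
    def test_sum_mode(self):
        sample = _sample("A", [3, 2, 45])
        assign = ClusterAssignment(
            sample_id="A",
            labels={},
            centroids={0: np.zeros(4)},
            members={0: sorted(sample.clonotypes)[:2]},
        )
        sr = SubRepertoire(id=0, members={"A": {0}})
        m = abundance_matrix({"A": sample}, [sr], {"A": assign}, mode="sum")
        assert m.loc[0, "A"] == 5

    def test_relative_mode(self):
        sample = _sample("A", [3, 2, 45])
        assign = ClusterAssignment(
            sample_id="A",
            labels={},
            centroids={0: np.zeros(4)},
            members={0: sorted(sample.clonotypes)[:2]},
        )
        sr = SubRepertoire(id=0, members={"A": {0}})
        m = abundance_matrix({"A": sample}, [sr], {"A": assign}, mode="relative")
        assert m.loc[0, "A"] == pytest.approx(0.1)

    def test_relative_clone_size_mode(self):
        # members {3,2}: mean 2.5; sample mean (3+2+2.5+2.5)/4 = 2.5 -> ratio 1
        sample = _sample("A", [3, 2, 2, 3])
        assign = ClusterAssignment(
            sample_id="A",
            labels={},
            centroids={0: np.zeros(4)},
            members={0: sorted(sample.clonotypes)[:2]},
        )
        sr = SubRepertoire(id=0, members={"A": {0}})
        m = abundance_matrix({"A": sample}, [sr], {"A": assign}, mode="relative_clone_size")
        member_counts = [sample.clonotypes[k].count for k in sorted(sample.clonotypes)[:2]]
        expected = (np.mean(member_counts)) / (sample.total_abundance / 4)
        assert m.loc[0, "A"] == pytest.approx(expected)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            abundance_matrix({}, [], {}, mode="bogus")

    def test_missing_subrep_is_zero_and_column_conservation(self):
        a, b = _sample("A", [4, 6]), _sample("B", [5, 5])
        assign_a = ClusterAssignment(
            sample_id="A",
            labels={},
            centroids={0: np.zeros(4)},
            members={0: sorted(a.clonotypes)},
        )
        sr0 = SubRepertoire(id=0, members={"A": {0}})
        m = abundance_matrix({"A": a, "B": b}, [sr0], {"A": assign_a}, mode="sum")
        assert m.loc[0, "B"] == 0
        assert m["A"].sum() == a.total_abundance


class TestFilterPresence:
    def _matrix(self, rows):
        cols = [f"S{i}" for i in range(8)]
        return pd.DataFrame(rows, columns=cols)

    def _groups(self):
        return {f"S{i}": ("control" if i < 4 else "condition") for i in range(8)}

    def test_retained_at_three_per_group(self):
        m = self._matrix([[1, 1, 1, 0, 2, 2, 2, 0]])
        out = filter_presence(m, self._groups(), 3)
        assert len(out) == 1

    def test_dropped_when_one_group_sparse(self):
        m = self._matrix([[1, 1, 1, 1, 0, 0, 2, 2]])  # 4 control, 2 condition
        out = filter_presence(m, self._groups(), 3)
        assert len(out) == 0

    def test_min_one_keeps_rows_present_in_both_groups(self):
        m = self._matrix([[1, 0, 0, 0, 1, 0, 0, 0], [0, 0, 0, 0, 1, 1, 1, 1]])
        out = filter_presence(m, self._groups(), 1)
        assert list(out.index) == [0]


class TestTTest:
    def _groups(self, n=3):
        g = {}
        for i in range(n):
            g[f"C{i}"] = "control"
            g[f"T{i}"] = "condition"
        return g

    def test_clear_difference_passes_enriched(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(
            {**{f"C{i}": [1 + 0.01 * rng.normal()] for i in range(3)},
             **{f"T{i}": [10 + 0.01 * rng.normal()] for i in range(3)}}
        )
        # closed-form check on the same numbers
        t_ref, p_ref = stats.ttest_ind(m[[f"T{i}" for i in range(3)]].iloc[0],
                                       m[[f"C{i}" for i in range(3)]].iloc[0])
        (res,) = da_test(m, self._groups(), condition="condition", test="t")
        assert res.passed and res.direction == "enriched"
        assert res.p_value == pytest.approx(p_ref)

    def test_identical_groups_do_not_pass(self):
        m = pd.DataFrame({c: [5.0] for c in self._groups()})
        (res,) = da_test(m, self._groups(), condition="condition", test="t")
        assert not res.passed
        assert res.p_value == 1.0 and res.flagged

    def test_paired_uses_pairs(self):
        groups = self._groups()
        pairs = [(f"C{i}", f"T{i}") for i in range(3)]
        m = pd.DataFrame(
            {**{f"C{i}": [float(i)] for i in range(3)}, **{f"T{i}": [i + 2.0] for i in range(3)}}
        )
        (res,) = da_test(m, groups, condition="condition", test="t", paired=True, pairs=pairs)
        # constant difference of 2 -> paired t is degenerate-perfect; flagged p=1 not expected
        ref = stats.ttest_rel([2.0, 3.0, 4.0], [0.0, 1.0, 2.0])
        assert res.flagged or res.p_value == pytest.approx(ref.pvalue)


def brute_force_rankprod(Xc, Xt, n_rows):
    """Oracle: enumerate all label assignments, recompute rank products."""
    pooled = np.hstack([Xc, Xt])
    n_cond = Xc.shape[1]
    n = pooled.shape[1]

    def rp(cond, ctrl):
        up = np.zeros(n_rows)
        down = np.zeros(n_rows)
        m = 0
        for a in range(cond.shape[1]):
            for b in range(ctrl.shape[1]):
                ratio = (cond[:, a] + RANKPROD_EPS) / (ctrl[:, b] + RANKPROD_EPS)
                up += np.log(stats.rankdata(-ratio))
                down += np.log(stats.rankdata(ratio))
                m += 1
        return np.exp(up / m), np.exp(down / m)

    obs_up, obs_down = rp(Xc, Xt)
    perm_up, perm_down = [], []
    for combo in itertools.combinations(range(n), n_cond):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        u, d = rp(pooled[:, mask], pooled[:, ~mask])
        perm_up.append(u)
        perm_down.append(d)
    perm_up = np.concatenate(perm_up)
    perm_down = np.concatenate(perm_down)
    p_up = np.array([(perm_up <= v).mean() for v in obs_up])
    p_down = np.array([(perm_down <= v).mean() for v in obs_down])
    return p_up, p_down


class TestRankProduct:
    def test_exhaustive_enumeration_matches_oracle(self, rng):
        Xc = rng.integers(0, 20, size=(3, 2)).astype(float)
        Xt = rng.integers(0, 20, size=(3, 2)).astype(float)
        res = rank_product_test(Xc, Xt, n_perm=None, seed=0)
        p_up, p_down = brute_force_rankprod(Xc, Xt, 3)
        assert np.allclose(res["p_up"], p_up)
        assert np.allclose(res["p_down"], p_down)

    def test_distinct_permutation_count_le_10000_always_exhaustive(self, rng):
        # 3 vs 3 -> C(6,3) = 20 distinct assignments, far below the bound
        Xc = rng.random(size=(4, 3))
        Xt = rng.random(size=(4, 3))
        a = rank_product_test(Xc, Xt, n_perm=10_000, seed=1)
        b = rank_product_test(Xc, Xt, n_perm=10_000, seed=2)
        assert np.allclose(a["p_up"], b["p_up"])  # exhaustive -> seed-independent

    def test_da_test_rankprod_directions(self):
        groups = {f"C{i}": "control" for i in range(2)} | {f"T{i}": "condition" for i in range(2)}
        m = pd.DataFrame(
            {
                "C0": [1.0, 10.0, 5.0],
                "C1": [2.0, 11.0, 5.1],
                "T0": [10.0, 1.0, 5.2],
                "T1": [11.0, 2.0, 4.9],
            }
        )
        res = da_test(m, groups, condition="condition", test="rankprod", n_perm=None)
        assert res[0].direction == "enriched"
        assert res[1].direction == "de-enriched"

    def test_null_calibration_fraction(self, rng):
        """Under a null matrix, ~10% of rows pass at cutoff 0.1."""
        n_rows = 200
        Xc = rng.lognormal(size=(n_rows, 4))
        Xt = rng.lognormal(size=(n_rows, 4))
        res = rank_product_test(Xc, Xt, n_perm=None, seed=0)
        frac = (np.minimum(res["p_up"], res["p_down"]) < 0.05).mean()
        # two one-sided tests at 0.05 -> nominal ~0.1; allow binomial slack
        assert frac < 0.2


def test_group_permutation_calibration(rng):
    """Fraction of null rows with t-test p < 0.1 is near 0.1."""
    cols = {f"C{i}": "control" for i in range(4)} | {f"T{i}": "condition" for i in range(4)}
    m = pd.DataFrame(rng.normal(size=(400, 8)), columns=list(cols))
    res = da_test(m, cols, condition="condition", test="t", p_cutoff=0.1)
    frac = np.mean([r.passed for r in res])
    se = math.sqrt(0.1 * 0.9 / 400)
    assert abs(frac - 0.1) < 4 * se
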