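"""Rank factors, rank-sum scoring, permutation p and decoy q-values."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from repdab.io import Clonotype, RepertoireSample
from repdab.ranking import (
    FACTOR_NAMES,
    decoy_fdr,
    detection_factor,
    fisher_factors,
    nt_aa_factor,
    permutation_pvalue,
    publicness_factor,
    rank_and_score,
    rf_importance_factor,
)


def _dataset(patterns, depth_filler=2000):
    """8 samples (4 control, 4 condition); patterns: key -> counts per sample."""
    sids = [f"C{i}" for i in range(4)] + [f"T{i}" for i in range(4)]
    groups = {s: ("condition" if s.startswith("T") else "control") for s in sids}
    samples = {}
    for i, sid in enumerate(sids):
        s = RepertoireSample(sample_id=sid)
        for key, counts in patterns.items():
            if counts[i] > 0:
                nt, v, j = key
                s.add(Clonotype(nt_seq=nt, aa_seq="X" * (len(nt) // 3), count=counts[i], v_gene=v, j_gene=j))
        # filler clonotype fixes the sample depth
        s.add(Clonotype(nt_seq="GGG" * 10, aa_seq="G" * 10, count=depth_filler, v_gene="VF", j_gene="JF"))
        samples[sid] = s
    return samples, groups


class TestRfImportance:
    def test_informative_beats_constant(self):
        patterns = {
            ("AAAGGGTTTCCC", "V1", "J1"): [0, 0, 0, 0, 50, 60, 55, 45],  # perfect separator
            ("CCCGGGTTTAAA", "V2", "J1"): [10, 10, 10, 10, 10, 10, 10, 10],  # constant
        }
        samples, groups = _dataset(patterns)
        keys = list(patterns)
        imp = rf_importance_factor(keys, samples, groups, seed=0)
        assert imp[0] > imp[1]

    def test_constant_relative_frequency_never_used(self):
        # filler compensates the separator so depth is constant; the second
        # feature then has identical relative frequency everywhere and can
        # never split a tree
        sids = [f"C{i}" for i in range(4)] + [f"T{i}" for i in range(4)]
        groups = {s: ("condition" if s.startswith("T") else "control") for s in sids}
        samples = {}
        sep = [0, 0, 0, 0, 50, 50, 50, 50]
        for i, sid in enumerate(sids):
            s = RepertoireSample(sample_id=sid)
            if sep[i]:
                s.add(Clonotype(nt_seq="AAAGGG", aa_seq="KG", count=sep[i], v_gene="V1", j_gene="J1"))
            s.add(Clonotype(nt_seq="CCCGGG", aa_seq="PG", count=10, v_gene="V2", j_gene="J1"))
            s.add(Clonotype(nt_seq="TTTGGG", aa_seq="FG", count=1990 - sep[i], v_gene="VF", j_gene="JF"))
            samples[sid] = s
        keys = [("AAAGGG", "V1", "J1"), ("CCCGGG", "V2", "J1")]
        imp = rf_importance_factor(keys, samples, groups, seed=0)
        assert imp[0] > 0
        assert imp[1] == 0.0

    def test_label_permutation_control(self, rng):
        """With random group labels, mean importance is not clearly positive."""
        patterns = {
            (f"AAA{i:03d}".replace("0", "A").replace("1", "C").replace("2", "G")
             + "TTT", f"V{i}", "J1"): list(rng.integers(0, 20, size=8))
            for i in range(10)
        }
        samples, groups = _dataset(patterns)
        imps = []
        for perm_seed in range(5):
            prng = np.random.default_rng(perm_seed)
            sids = list(groups)
            labels = prng.permutation([groups[s] for s in sids])
            pg = dict(zip(sids, labels))
            if len(set(pg.values())) < 2:
                continue
            imps.append(rf_importance_factor(list(patterns), samples, pg, seed=1).mean())
        assert np.mean(imps) < 0.05

    def test_single_class_rejected(self):
        patterns = {("AAATTT", "V", "J"): [1] * 8}
        samples, groups = _dataset(patterns)
        with pytest.raises(ValueError):
            rf_importance_factor(list(patterns), samples, {s: "x" for s in samples}, seed=0)


class TestFisherFactors:
    def test_hypergeometric_oracle(self):
        key = ("AAATTTGGGCCC", "V1", "J1")
        patterns = {key: [0, 0, 0, 0, 10, 0, 0, 0]}
        samples, groups = _dataset(patterns, depth_filler=4990)
        p, orr = fisher_factors([key], samples, groups, "condition")
        # 4 of the 16 cross-group comparisons carry the candidate (T0 vs
        # each control, table [10, 4990; 0, 4990]); the other 12 are
        # neutral (p = 1, OR = 1) and enter the mean as such
        p_hyper = stats.fisher_exact([[10, 4990], [0, 4990]])[1]
        assert p[0] == pytest.approx((4 * p_hyper + 12 * 1.0) / 16)
        or_haldane = (10.5 * 4990.5) / (0.5 * 4990.5)
        assert orr[0] == pytest.approx((4 * or_haldane + 12 * 1.0) / 16)

    def test_symmetric_table_neutral(self):
        key = ("AAATTTGGGCCC", "V1", "J1")
        patterns = {key: [5, 5, 5, 5, 5, 5, 5, 5]}
        samples, groups = _dataset(patterns)
        p, orr = fisher_factors([key], samples, groups, "condition")
        assert p[0] == pytest.approx(1.0)
        assert orr[0] == pytest.approx(1.0, rel=0.05)  # Haldane correction, ~1

    def test_absent_everywhere_neutral(self):
        key = ("AAATTTGGGCCC", "V1", "J1")
        other = ("CCCTTTGGGAAA", "V2", "J1")
        patterns = {other: [1] * 8}
        samples, groups = _dataset(patterns)
        p, orr = fisher_factors([key], samples, groups, "condition")
        assert p[0] == 1.0 and orr[0] == 1.0


class TestNtAaFactor:
    def _with_variants(self, cond_variants, ctrl_variants):
        samples = {}
        groups = {}
        for i in range(8):
            sid = f"S{i}"
            cond = i >= 4
            groups[sid] = "condition" if cond else "control"
            s = RepertoireSample(sample_id=sid)
            n_var = cond_variants if cond else ctrl_variants
            for v in range(n_var):
                nt = "TGTGCA" + ["GCT", "GCC", "GCA", "GCG"][v] + "TTT"
                s.add(Clonotype(nt_seq=nt, aa_seq="CAAF", count=2, v_gene="V1", j_gene="J1"))
            s.add(Clonotype(nt_seq="AAAAAA", aa_seq="KK", count=10, v_gene="V9", j_gene="J9"))
            samples[sid] = s
        key = ("TGTGCAGCTTTT", "V1", "J1")
        return [key], samples, groups

    def test_three_vs_one_gives_three(self):
        keys, samples, groups = self._with_variants(3, 1)
        r4 = nt_aa_factor(keys, samples, groups, "condition")
        assert r4[0] == pytest.approx(3.0)

    def test_equal_variants_give_one(self):
        keys, samples, groups = self._with_variants(2, 2)
        r4 = nt_aa_factor(keys, samples, groups, "condition")
        assert r4[0] == pytest.approx(1.0)

    def test_pseudocount_on_zero_denominator(self):
        keys, samples, groups = self._with_variants(2, 0)
        r4 = nt_aa_factor(keys, samples, groups, "condition")
        assert r4[0] == pytest.approx(3.0)  # (2+1)/(0+1)


class TestPublicness:
    def test_examples(self):
        patterns = {
            ("AAATTTGGGCCC", "V1", "J1"): [0, 0, 0, 0, 1, 1, 1, 1],
            ("CCCTTTGGGAAA", "V2", "J1"): [1] * 8,
            ("GGGTTTAAACCC", "V3", "J1"): [1, 1, 1, 0, 1, 0, 0, 0],
        }
        samples, groups = _dataset(patterns)
        r5 = publicness_factor(list(patterns), samples, groups, "condition")
        assert list(r5) == [4, 0, -2]


def test_detection_factor_counts_and_ties():
    counts = {("A", "V", "J"): 87, ("B", "V", "J"): 1, ("C", "V", "J"): 87}
    keys = sorted(counts)
    r6 = detection_factor(keys, counts)
    assert list(r6) == [87, 1, 87]
    ranks = stats.rankdata(-r6)
    assert ranks[0] == ranks[2] == 1.5  # average-tie convention


class TestRankAndScore:
    def _raw(self, values):
        return pd.DataFrame({n: v for n, v in zip(FACTOR_NAMES, np.array(values).T)})

    def test_best_in_all_six_has_zero_c(self):
        raw = self._raw([
            [1.0, 0.001, 9.0, 3.0, 4, 10],   # best everywhere (enrichment)
            [0.1, 0.5, 1.0, 1.0, 0, 2],
            [0.0, 0.9, 0.5, 0.8, -1, 1],
        ])
        out = rank_and_score(raw, "enriched")
        assert out["C"].iloc[0] == 0.0
        assert out["C"].idxmin() == 0

    def test_worst_in_all_six_has_c_six(self):
        raw = self._raw([
            [1.0, 0.001, 9.0, 3.0, 4, 10],
            [0.0, 0.9, 0.5, 0.8, -1, 1],
        ])
        out = rank_and_score(raw, "enriched")
        assert out["C"].iloc[1] == 6.0

    def test_symmetric_split_gives_three_each(self):
        raw = self._raw([
            [1.0, 0.001, 9.0, 1.0, 0, 1],
            [0.0, 0.9, 0.5, 3.0, 4, 10],
        ])
        out = rank_and_score(raw, "enriched")
        assert list(out["C"]) == [3.0, 3.0]

    def test_deenrichment_flips_or_ntaa_presence(self):
        raw = self._raw([
            [0.5, 0.5, 9.0, 3.0, 4, 5],
            [0.5, 0.5, 0.1, 0.3, -4, 5],
        ])
        enr = rank_and_score(raw, "enriched")
        de = rank_and_score(raw, "de-enriched")
        assert enr["R3_scaled"].iloc[0] == 0.0 and de["R3_scaled"].iloc[0] == 1.0
        assert enr["R5_scaled"].iloc[1] == 1.0 and de["R5_scaled"].iloc[1] == 0.0

    def test_constant_factor_scales_to_zero(self):
        raw = self._raw([
            [0.5, 0.5, 1.0, 1.0, 2, 5],
            [0.5, 0.5, 2.0, 1.0, 1, 5],
        ])
        out = rank_and_score(raw, "enriched")
        assert (out["R1_scaled"] == 0).all()
        assert (out["R6_scaled"] == 0).all()
        assert out["C"].equals(out[[f"{n}_scaled" for n in FACTOR_NAMES]].sum(axis=1))


def brute_force_permutation_p(scaled_cols):
    """Exhaustive oracle over all independent per-factor shufflings."""
    m = scaled_cols.shape[0]
    C = scaled_cols.sum(axis=1)
    perms = list(itertools.permutations(range(m)))
    sums = []
    for combo in itertools.product(perms, repeat=scaled_cols.shape[1]):
        total = np.zeros(m)
        for f, perm in enumerate(combo):
            total += scaled_cols[list(perm), f]
        sums.extend(total)
    sums = np.sort(sums)
    return np.searchsorted(sums, C, side="right") / len(sums)


class TestPermutationP:
    def test_matches_exhaustive_enumeration_two_candidates_three_factors(self, rng):
        # 2 candidates x 3 factors: (2!)^3 = 8 shufflings, tractable exactly
        scaled = rng.random(size=(2, 3))
        df = pd.DataFrame(
            np.hstack([scaled, np.zeros((2, 3))]),
            columns=[f"{n}_scaled" for n in FACTOR_NAMES],
        )
        expected = brute_force_permutation_p(df.to_numpy())
        p = permutation_pvalue(df, n_perm=40_000, seed=3)
        assert np.abs(p - expected).max() < 0.02

    def test_all_identical_factors_give_p_one(self):
        df = pd.DataFrame(
            np.ones((4, 6)) * 0.3, columns=[f"{n}_scaled" for n in FACTOR_NAMES]
        )
        p = permutation_pvalue(df, n_perm=200, seed=0)
        assert np.allclose(p, 1.0)

    def test_dominant_candidate_gets_minimal_p(self, rng):
        X = rng.uniform(0.3, 1.0, size=(20, 6))
        X[7] = 0.0  # best in every factor
        df = pd.DataFrame(X, columns=[f"{n}_scaled" for n in FACTOR_NAMES])
        p = permutation_pvalue(df, n_perm=500, seed=1)
        assert p[7] == p.min()
        assert p[7] < 0.01

    def test_single_candidate_rejected(self):
        df = pd.DataFrame(np.zeros((1, 6)), columns=[f"{n}_scaled" for n in FACTOR_NAMES])
        with pytest.raises(ValueError):
            permutation_pvalue(df)


class TestDecoyFdr:
    def test_hand_tabulated_six_record_fixture(self):
        # 4 real (p = .01, .02, .04, .5) and 2 decoy (p = .03, .06), ratio 0.5
        p = np.array([0.01, 0.02, 0.04, 0.5, 0.03, 0.06])
        dec = np.array([False, False, False, False, True, True])
        q = decoy_fdr(p, dec, decoy_ratio=0.5)
        # FDR by threshold: .01->0, .02->0, .03->(1/.5)/2=1, .04->(1/.5)/3=2/3,
        # .06->min(1,(2/.5)/3)=1, .5->(2/.5)/4=1 ; monotone min from the right:
        assert q[0] == 0.0 and q[1] == 0.0
        assert q[2] == pytest.approx(2 / 3)
        assert q[3] == pytest.approx(1.0)
        assert q[4] == pytest.approx(2 / 3)  # decoy at .03: min FDR beyond is 2/3

    def test_decoys_after_reals_give_zero_q(self):
        p = np.array([0.001, 0.002, 0.003, 0.8, 0.9])
        dec = np.array([False, False, False, True, True])
        q = decoy_fdr(p, dec, decoy_ratio=1.0)
        assert np.all(q[:3] == 0.0)

    def test_interleaved_ratio_one_fdr_near_one(self):
        p = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        dec = np.array([True, False, True, False, True, False])
        q = decoy_fdr(p, dec, decoy_ratio=1.0)
        assert q[1] == pytest.approx(1.0)

    def test_q_monotone_in_p_on_random_fixtures(self, rng):
        for _ in range(20):
            n = 40
            p = rng.random(n)
            dec = rng.random(n) < 0.3
            if dec.all() or not dec.any():
                continue
            q = decoy_fdr(p, dec, decoy_ratio=0.3)
            order = np.argsort(p)
            assert np.all(np.diff(q[order]) >= -1e-12)

    def test_zero_ratio_rejected(self):
        with pytest.raises(ValueError):
            decoy_fdr(np.array([0.1]), np.array([False]), decoy_ratio=0)
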