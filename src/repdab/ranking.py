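"""Ranking and filtering of candidate differentially abundant CDR3s.

Every CDR3 that belonged to a differentially abundant sub-repertoire in at
least one resample run is a candidate.  Candidates are scored by six
factors:

R1  random-forest importance (mean decrease in accuracy) of the candidate's
    per-sample abundance in classifying the sample groups;
R2  mean Fisher's exact p comparing its counts between sample pairs
    (all cross-group pairs when unpaired, matched pairs when paired);
R3  mean Fisher odds ratio from the same comparisons (Haldane 0.5
    correction on zero cells);
R4  mean condition/control ratio of its nucleotide-to-amino-acid variant
    count (convergent recombination);
R5  difference in per-group sample presence (condition minus control);
R6  number of resample runs in which it was detected.

Per direction each factor is converted to an average-tied rank (rank 1 =
best for that direction), min-max scaled to [0, 1], and summed into the
rank score C.  C gets a permutation p-value by independently shuffling each
factor's scaled values across candidates, and a decoy-based q-value: the
detection rate of decoy CDR3s spiked into the input estimates the FDR at
each p level, and q is the minimal FDR at or beyond that level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

from .io import ClonotypeKey, RepertoireSample

logger = logging.getLogger(__name__)

FACTOR_NAMES = ("R1", "R2", "R3", "R4", "R5", "R6")


def _group_cols(groups: dict[str, str], condition: str) -> tuple[list[str], list[str]]:
    cond = sorted(s for s, g in groups.items() if g == condition)
    ctrl = sorted(s for s, g in groups.items() if g != condition)
    return cond, ctrl


def _comparisons(
    cond: list[str],
    ctrl: list[str],
    paired: bool,
    pairs: list[tuple[str, str]] | None,
) -> list[tuple[str, str]]:
    """(condition_sample, control_sample) comparison tuples."""
    if paired:
        if pairs is None:
            raise ValueError("paired factors require explicit sample pairs")
        return [(b, a) for a, b in pairs]  # pairs are (control, condition)
    return [(a, b) for a in cond for b in ctrl]


def rf_importance_factor(
    candidates: list[ClonotypeKey],
    samples: dict[str, RepertoireSample],
    groups: dict[str, str],
    seed: int = 0,
    n_estimators: int = 200,
    n_repeats: int = 10,
) -> np.ndarray:
    """Mean-decrease-in-accuracy importance of each candidate's per-sample
    abundance in a random forest classifying the groups.

    Features are within-sample relative frequencies.  Importance is the
    classical per-tree, out-of-bag permutation measure: for every tree,
    the drop in its out-of-bag accuracy when feature j is permuted,
    averaged over trees.  Scoring per tree (a thin bagging loop over
    sklearn decision trees) rather than at forest level matters: with many
    mutually redundant candidates, permuting one feature never changes the
    ensemble vote, whereas the individual trees that split on it are
    visibly degraded.
    """
    sample_ids = sorted(samples)
    y = np.array([groups[s] for s in sample_ids])
    if len(set(y)) < 2:
        raise ValueError("need two classes for importance estimation")
    totals = {sid: samples[sid].total_abundance for sid in sample_ids}
    X = np.zeros((len(sample_ids), len(candidates)))
    for j, key in enumerate(candidates):
        for i, sid in enumerate(sample_ids):
            c = samples[sid].clonotypes.get(key)
            X[i, j] = 0.0 if c is None else c.count / totals[sid]
    rng = np.random.default_rng(seed)
    n, m = X.shape
    codes = np.unique(y, return_inverse=True)[1]
    deltas = np.zeros(m)
    weights = np.zeros(m)
    for t in range(n_estimators):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0 or len(set(codes[boot])) < 2:
            continue
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(2**31))
        )
        tree.fit(X[boot], codes[boot])
        used = np.zeros(m, dtype=bool)
        used[tree.tree_.feature[tree.tree_.feature >= 0]] = True
        base_acc = float((tree.predict(X[oob]) == codes[oob]).mean())
        if not used.any():
            continue
        used_idx = np.flatnonzero(used)
        # batch: one prediction call for all permuted copies of this tree
        blocks = []
        for j in used_idx:
            Xp = X[oob].copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            blocks.append(Xp)
        pred = tree.predict(np.vstack(blocks)).reshape(len(used_idx), oob.size)
        acc = (pred == codes[oob]).mean(axis=1)
        deltas[used_idx] += base_acc - acc
        weights += 1  # unused features count as zero decrease in this tree
    n_trees = weights.max()
    return deltas / n_trees if n_trees > 0 else deltas


def fisher_factors(
    candidates: list[ClonotypeKey],
    samples: dict[str, RepertoireSample],
    groups: dict[str, str],
    condition: str,
    paired: bool = False,
    pairs: list[tuple[str, str]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(mean Fisher p, mean Haldane-corrected odds ratio) per candidate.

    Each comparison tests the 2x2 table
    ``[count_cond, depth_cond - count_cond; count_ctrl, depth_ctrl - count_ctrl]``
    on raw (pre-normalization) integer counts.  A comparison where the
    candidate is absent from both samples is exactly neutral (its table is
    symmetric): it contributes p = 1, OR = 1 to the mean, so sparsely
    observed candidates are not rewarded for missing data.
    """
    cond, ctrl = _group_cols(groups, condition)
    comps = _comparisons(cond, ctrl, paired, pairs)
    totals = {sid: samples[sid].total_abundance for sid in samples}
    counts = {
        sid: {k: samples[sid].clonotypes[k].count for k in candidates if k in samples[sid].clonotypes}
        for sid in samples
    }
    mean_p = np.ones(len(candidates))
    mean_or = np.ones(len(candidates))
    for j, key in enumerate(candidates):
        ps, ors = [], []
        for sa, sb in comps:
            ca = int(counts[sa].get(key, 0))
            cb = int(counts[sb].get(key, 0))
            if ca == 0 and cb == 0:
                ps.append(1.0)
                ors.append(1.0)
                continue
            ta, tb = int(round(totals[sa])), int(round(totals[sb]))
            _, p = stats.fisher_exact([[ca, ta - ca], [cb, tb - cb]])
            ors.append(((ca + 0.5) * (tb - cb + 0.5)) / ((cb + 0.5) * (ta - ca + 0.5)))
            ps.append(p)
        if ps:
            mean_p[j] = float(np.mean(ps))
            mean_or[j] = float(np.mean(ors))
    return mean_p, mean_or


def nt_aa_variant_counts(
    samples: dict[str, RepertoireSample],
) -> dict[str, dict[tuple[str, str, str], int]]:
    """Per sample: (aa_seq, v_gene, j_gene) -> number of distinct nt variants."""
    out: dict[str, dict[tuple[str, str, str], int]] = {}
    for sid, s in samples.items():
        d: dict[tuple[str, str, str], int] = {}
        for c in s.clonotypes.values():
            k = (c.aa_seq, c.v_gene, c.j_gene)
            d[k] = d.get(k, 0) + 1
        out[sid] = d
    return out


def nt_aa_factor(
    candidates: list[ClonotypeKey],
    samples: dict[str, RepertoireSample],
    groups: dict[str, str],
    condition: str,
    paired: bool = False,
    pairs: list[tuple[str, str]] | None = None,
) -> np.ndarray:
    """Mean condition/control nt-to-aa variant-count ratio per candidate.

    When the control sample lacks the amino-acid CDR3 entirely (variant
    count 0) a +1 pseudocount is applied to both sides to keep the ratio
    finite; otherwise the plain ratio is used.  A comparison with the
    candidate absent from both samples is neutral (ratio 1).
    """
    cond, ctrl = _group_cols(groups, condition)
    comps = _comparisons(cond, ctrl, paired, pairs)
    variants = nt_aa_variant_counts(samples)
    aa_of = {}
    for key in candidates:
        for s in samples.values():
            c = s.clonotypes.get(key)
            if c is not None:
                aa_of[key] = (c.aa_seq, c.v_gene, c.j_gene)
                break
    out = np.ones(len(candidates))
    for j, key in enumerate(candidates):
        aa_key = aa_of.get(key)
        if aa_key is None:
            continue
        ratios = []
        for sa, sb in comps:
            va = variants[sa].get(aa_key, 0)
            vb = variants[sb].get(aa_key, 0)
            ratios.append(va / vb if vb > 0 else (va + 1.0) / 1.0)
        if ratios:
            out[j] = float(np.mean(ratios))
    return out


def publicness_factor(
    candidates: list[ClonotypeKey],
    samples: dict[str, RepertoireSample],
    groups: dict[str, str],
    condition: str,
) -> np.ndarray:
    """Condition-minus-control difference in the number of samples carrying
    the candidate."""
    cond, ctrl = _group_cols(groups, condition)
    out = np.zeros(len(candidates))
    for j, key in enumerate(candidates):
        n_cond = sum(1 for sid in cond if key in samples[sid].clonotypes)
        n_ctrl = sum(1 for sid in ctrl if key in samples[sid].clonotypes)
        out[j] = n_cond - n_ctrl
    return out


def detection_factor(
    candidates: list[ClonotypeKey],
    detection_counts: dict[ClonotypeKey, int],
) -> np.ndarray:
    """Number of resample runs in which each candidate was detected."""
    return np.array([detection_counts.get(k, 0) for k in candidates], dtype=float)


#: factor -> True if larger raw values are better when assessing enrichment
_ENRICH_HIGHER_BETTER = {"R1": True, "R2": False, "R3": True, "R4": True, "R5": True, "R6": True}
#: orientation flips for de-enrichment (R1, R2, R6 keep theirs)
_DEENRICH_HIGHER_BETTER = {"R1": True, "R2": False, "R3": False, "R4": False, "R5": False, "R6": True}


def rank_and_score(raw: pd.DataFrame, direction: str) -> pd.DataFrame:
    """Scale the six raw factors into [0, 1] ranks (0 = best) and sum them.

    ``raw`` must have columns R1..R6.  Ranks use the average-tie
    convention; a constant factor contributes 0 for every candidate.
    Returns a copy with scaled columns ``R1_scaled``..``R6_scaled`` and
    ``C``.
    """
    orient = _ENRICH_HIGHER_BETTER if direction == "enriched" else _DEENRICH_HIGHER_BETTER
    out = raw.copy()
    scaled_cols = []
    for name in FACTOR_NAMES:
        x = raw[name].to_numpy(float)
        ranks = stats.rankdata(-x if orient[name] else x)  # 1 = best
        rng_ = ranks.max() - ranks.min()
        scaled = np.zeros_like(ranks) if rng_ == 0 else (ranks - ranks.min()) / rng_
        out[f"{name}_scaled"] = scaled
        scaled_cols.append(f"{name}_scaled")
    out["C"] = out[scaled_cols].sum(axis=1)
    return out


def permutation_pvalue(
    scaled: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Permutation p-value for each candidate's rank score C.

    Each permutation shuffles every factor's scaled values independently
    across candidates and recomputes one rank sum per candidate; p_i is the
    fraction of all permuted sums (pooled over permutations and
    candidates) that are <= C_i.  No add-one smoothing, so a clear winner
    can reach p = 0.
    """
    cols = [f"{n}_scaled" for n in FACTOR_NAMES]
    X = scaled[cols].to_numpy(float)
    m = X.shape[0]
    if m < 2:
        raise ValueError("need at least two candidates for a permutation p-value")
    C = X.sum(axis=1)
    rng = np.random.default_rng(seed)
    sums = np.empty((n_perm, m))
    for t in range(n_perm):
        total = np.zeros(m)
        for j in range(X.shape[1]):
            total += X[rng.permutation(m), j]
        sums[t] = total
    pooled = np.sort(sums.ravel())
    return np.searchsorted(pooled, C, side="right") / pooled.size


def decoy_fdr(
    p_values: np.ndarray,
    is_decoy: np.ndarray,
    decoy_ratio: float,
) -> np.ndarray:
    """Decoy-based q-values (minimal FDR at each p level).

    At threshold t, ``FDR(t) = (#decoys with p <= t / decoy_ratio) /
    (#real with p <= t)`` clipped to [0, 1]; ``q(t)`` is the minimum FDR
    over thresholds >= t.  ``decoy_ratio`` is the injected decoy:real
    ratio, which rescales decoy detections to the size of the real pool.
    """
    if decoy_ratio <= 0:
        raise ValueError("decoy_ratio must be positive")
    p = np.asarray(p_values, float)
    dec = np.asarray(is_decoy, bool)
    order = np.argsort(p, kind="stable")
    thresholds = np.unique(p)
    fdrs = []
    for t in thresholds:
        below = p <= t
        n_real = int((below & ~dec).sum())
        n_dec = int((below & dec).sum())
        if n_real == 0:
            fdrs.append(np.nan)  # undefined, skipped in the running minimum
        else:
            fdrs.append(min(1.0, (n_dec / decoy_ratio) / n_real))
    # minimal FDR at or beyond each threshold (scan from the largest down)
    q_at = np.empty(len(thresholds))
    running = np.inf
    for i in range(len(thresholds) - 1, -1, -1):
        if not np.isnan(fdrs[i]):
            running = min(running, fdrs[i])
        q_at[i] = running if np.isfinite(running) else 1.0
    idx = np.searchsorted(thresholds, p)
    return q_at[idx]


@dataclass
class RankingResult:
    """Scored candidates of one direction."""

    direction: str
    table: pd.DataFrame  # raw + scaled factors, C, p, q, is_decoy

    def final_calls(self, p_cutoff: float = 0.05, q_cutoff: float = 0.05) -> pd.DataFrame:
        t = self.table
        mask = (t["p"] < p_cutoff) & ~t["is_decoy"]
        if t["q"].notna().any():
            mask &= t["q"] < q_cutoff
        return t.loc[mask]


def score_candidates(
    candidates: list[ClonotypeKey],
    direction: str,
    samples_raw: dict[str, RepertoireSample],
    groups: dict[str, str],
    condition: str,
    detection_counts: dict[ClonotypeKey, int],
    decoy_keys: set[ClonotypeKey],
    decoy_ratio: float | None,
    paired: bool = False,
    pairs: list[tuple[str, str]] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> RankingResult:
    """Compute all six factors, the rank score C, its permutation p-value
    and (when decoys were injected) the decoy-based q-value."""
    candidates = sorted(candidates)
    r1 = rf_importance_factor(candidates, samples_raw, groups, seed=seed)
    r2, r3 = fisher_factors(candidates, samples_raw, groups, condition, paired, pairs)
    r4 = nt_aa_factor(candidates, samples_raw, groups, condition, paired, pairs)
    r5 = publicness_factor(candidates, samples_raw, groups, condition)
    r6 = detection_factor(candidates, detection_counts)
    raw = pd.DataFrame(
        {"R1": r1, "R2": r2, "R3": r3, "R4": r4, "R5": r5, "R6": r6},
        index=pd.MultiIndex.from_tuples(candidates, names=["nt_seq", "v_gene", "j_gene"]),
    )
    scored = rank_and_score(raw, direction)
    scored["p"] = permutation_pvalue(scored, n_perm=n_perm, seed=seed)
    scored["is_decoy"] = [k in decoy_keys for k in candidates]
    if decoy_ratio and decoy_ratio > 0:
        scored["q"] = decoy_fdr(
            scored["p"].to_numpy(), scored["is_decoy"].to_numpy(), decoy_ratio
        )
    else:
        scored["q"] = np.nan
        logger.warning("no decoys injected; q-values undefined, final calls use p only")
    scored["detection_count"] = r6.astype(int)
    scored["direction"] = direction
    return RankingResult(direction=direction, table=scored)
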