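"""Sub-repertoire abundance estimation and differential-abundance testing.

Samples are depth-normalized first; a sub-repertoire's abundance in a
sample is then the sum of its member CDR3 counts (``sum``), that sum as a
fraction of the sample total (``relative``), or the mean member clone size
over the mean sample clone size (``relative_clone_size``).  Sub-repertoires
present in at least ``min_per_group`` samples of each group are tested with
a two-sample t-test (paired or unpaired) or a re-implemented two-class rank
product with sample-label permutation p-values.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import ClusterAssignment
from .io import RepertoireSample
from .matching import SubRepertoire

logger = logging.getLogger(__name__)

ABUNDANCE_MODES = ("sum", "relative", "relative_clone_size")

#: pseudocount added to abundances before forming fold-change ratios
RANKPROD_EPS = 0.5


def abundance_matrix(
    samples: dict[str, RepertoireSample],
    subreps: list[SubRepertoire],
    assignments: dict[str, ClusterAssignment],
    mode: str = "sum",
) -> pd.DataFrame:
    """Sub-repertoire x sample abundance matrix (missing entries are 0)."""
    if mode not in ABUNDANCE_MODES:
        raise ValueError(f"unknown abundance mode {mode!r}")
    sample_ids = sorted(samples)
    totals = {sid: samples[sid].total_abundance for sid in sample_ids}
    mean_clone = {
        sid: totals[sid] / len(samples[sid]) if len(samples[sid]) else np.nan
        for sid in sample_ids
    }
    M = np.zeros((len(subreps), len(sample_ids)))
    for i, sr in enumerate(subreps):
        per_sample = sr.clonotypes(assignments)
        for j, sid in enumerate(sample_ids):
            keys = per_sample.get(sid, [])
            if not keys:
                continue
            counts = [samples[sid].clonotypes[k].count for k in keys if k in samples[sid].clonotypes]
            if not counts:
                continue
            total = float(np.sum(counts))
            if mode == "sum":
                M[i, j] = total
            elif mode == "relative":
                M[i, j] = total / totals[sid]
            else:  # relative_clone_size
                M[i, j] = (total / len(counts)) / mean_clone[sid]
    df = pd.DataFrame(M, index=[sr.id for sr in subreps], columns=sample_ids)
    df.attrs["mode"] = mode
    return df


def filter_presence(
    matrix: pd.DataFrame, groups: dict[str, str], min_per_group: int = 3
) -> pd.DataFrame:
    """Keep rows with non-zero abundance in >= ``min_per_group`` samples of
    *each* group."""
    labels = pd.Series({c: groups[c] for c in matrix.columns})
    keep = pd.Series(True, index=matrix.index)
    for g in labels.unique():
        cols = labels.index[labels == g]
        keep &= (matrix[cols] > 0).sum(axis=1) >= min_per_group
    out = matrix.loc[keep]
    out.attrs.update(matrix.attrs)
    return out


@dataclass
class DAResult:
    subrep_id: int
    statistic: float
    p_value: float
    direction: str  # "enriched" | "de-enriched" (condition vs control)
    test: str
    passed: bool
    flagged: bool = False  # e.g. zero-variance row under the t-test


def _rank_product(
    cond: np.ndarray, ctrl: np.ndarray, pairs: list[tuple[int, int]]
) -> tuple[np.ndarray, np.ndarray]:
    """(RP_up, RP_down): geometric-mean fold-change ranks over comparisons.

    For each comparison (condition column a, control column b) rows are
    ranked by the ratio ``(cond_a + eps) / (ctrl_b + eps)``; rank 1 is the
    most up-regulated (for RP_up) or most down-regulated (for RP_down).
    """
    n_rows = cond.shape[0]
    log_up = np.zeros(n_rows)
    log_down = np.zeros(n_rows)
    for a, b in pairs:
        ratio = (cond[:, a] + RANKPROD_EPS) / (ctrl[:, b] + RANKPROD_EPS)
        r_up = stats.rankdata(-ratio)  # rank 1 = largest ratio
        r_down = stats.rankdata(ratio)
        log_up += np.log(r_up)
        log_down += np.log(r_down)
    m = len(pairs)
    return np.exp(log_up / m), np.exp(log_down / m)


def _label_permutations(n_cond: int, n_ctrl: int, n_perm: int | None, rng: np.random.Generator):
    """Yield boolean masks (length n_cond+n_ctrl, True = 'condition').

    Exhaustive when the number of distinct assignments is small or
    ``n_perm`` is None; otherwise ``n_perm`` uniform random assignments.
    """
    n = n_cond + n_ctrl
    n_distinct = math.comb(n, n_cond)
    if n_perm is None or n_distinct <= max(n_perm or 0, 1):
        for combo in itertools.combinations(range(n), n_cond):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            yield mask
    else:
        for _ in range(n_perm):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=n_cond, replace=False)] = True
            yield mask


def rank_product_test(
    X_cond: np.ndarray,
    X_ctrl: np.ndarray,
    n_perm: int | None = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-class unpaired rank-product test.

    Fold-change ranks are taken over all condition x control column pairs.
    Significance comes from permuting sample labels: each permutation
    recomputes both one-sided rank products for every row, and the pooled
    permuted values give ``p_up``/``p_down`` as the fraction of permuted
    rank products <= the observed one.  With few samples the permutation
    space is enumerated exhaustively.
    """
    rng = np.random.default_rng(seed)
    n_cond, n_ctrl = X_cond.shape[1], X_ctrl.shape[1]
    pairs = [(a, b) for a in range(n_cond) for b in range(n_ctrl)]
    rp_up, rp_down = _rank_product(X_cond, X_ctrl, pairs)

    pooled = np.hstack([X_cond, X_ctrl])
    perm_up, perm_down = [], []
    for mask in _label_permutations(n_cond, n_ctrl, n_perm, rng):
        pc, pt = pooled[:, mask], pooled[:, ~mask]
        ppairs = [(a, b) for a in range(pc.shape[1]) for b in range(pt.shape[1])]
        u, d = _rank_product(pc, pt, ppairs)
        perm_up.append(u)
        perm_down.append(d)
    perm_up = np.sort(np.concatenate(perm_up))
    perm_down = np.sort(np.concatenate(perm_down))
    # pooled across rows: P(permuted RP <= observed RP_i)
    p_up = np.searchsorted(perm_up, rp_up, side="right") / perm_up.size
    p_down = np.searchsorted(perm_down, rp_down, side="right") / perm_down.size
    return pd.DataFrame(
        {"rp_up": rp_up, "rp_down": rp_down, "p_up": p_up, "p_down": p_down}
    )


def da_test(
    matrix: pd.DataFrame,
    groups: dict[str, str],
    condition: str,
    test: str = "t",
    paired: bool = False,
    pairs: list[tuple[str, str]] | None = None,
    p_cutoff: float = 0.1,
    n_perm: int | None = 200,
    seed: int = 0,
) -> list[DAResult]:
    """Test each sub-repertoire row for a group difference.

    ``condition`` names the condition/treatment group; the other group is
    the control.  Direction is the sign of the condition-minus-control mean
    difference (t-test) or the smaller one-sided rank-product p (rankprod).
    """
    labels = pd.Series({c: groups[c] for c in matrix.columns})
    cond_cols = list(labels.index[labels == condition])
    ctrl_cols = list(labels.index[labels != condition])
    if len(cond_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need at least two samples per group")
    if paired:
        if pairs is None:
            raise ValueError("paired test requires explicit sample pairs")
        ctrl_cols = [p[0] for p in pairs]
        cond_cols = [p[1] for p in pairs]

    Xc = matrix[cond_cols].to_numpy(float)
    Xt = matrix[ctrl_cols].to_numpy(float)
    results: list[DAResult] = []
    if test == "t":
        for i, rid in enumerate(matrix.index):
            flagged = False
            diff = Xc[i].mean() - Xt[i].mean()
            if np.ptp(Xc[i]) == 0 and np.ptp(Xt[i]) == 0 and (not paired or np.ptp(Xc[i] - Xt[i]) == 0):
                stat, p, flagged = 0.0, 1.0, True
            else:
                if paired:
                    stat, p = stats.ttest_rel(Xc[i], Xt[i])
                else:
                    stat, p = stats.ttest_ind(Xc[i], Xt[i])
                if np.isnan(p):
                    stat, p, flagged = 0.0, 1.0, True
            direction = "enriched" if diff > 0 else "de-enriched"
            results.append(
                DAResult(int(rid), float(stat), float(p), direction, "t", bool(p < p_cutoff), flagged)
            )
    elif test == "rankprod":
        rp = rank_product_test(Xc, Xt, n_perm=n_perm, seed=seed)
        for i, rid in enumerate(matrix.index):
            up, down = rp.loc[i, "p_up"], rp.loc[i, "p_down"]
            if up <= down:
                direction, p, stat = "enriched", up, rp.loc[i, "rp_up"]
            else:
                direction, p, stat = "de-enriched", down, rp.loc[i, "rp_down"]
            results.append(
                DAResult(int(rid), float(stat), float(p), direction, "rankprod", bool(p < p_cutoff))
            )
    else:
        raise ValueError(f"unknown test {test!r}")
    return results
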