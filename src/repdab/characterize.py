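"""Post-hoc characterization of a called CDR3 list.

Four analyses probe whether a set of called CDR3s carries signal beyond
chance: V-gene usage bias against matched random background draws,
per-position amino-acid enrichment with information content in bits, a
randomization test for overlap with a known condition-associated CDR3 set,
and a chi-square comparison of gene usage between two matched clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import Clonotype

logger = logging.getLogger(__name__)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


def _frame(clonotypes: list[Clonotype] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(clonotypes, pd.DataFrame):
        return clonotypes
    return pd.DataFrame(
        {
            "aa_seq": [c.aa_seq for c in clonotypes],
            "v_gene": [c.v_gene for c in clonotypes],
            "cdr3_length": [len(c.aa_seq) for c in clonotypes],
        }
    )


@dataclass
class UsageBiasResult:
    table: pd.DataFrame  # stratum, observed_freq, null_mean, p
    n_rand: int

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table.loc[self.table["p"] < alpha]


def trbv_bias(
    called: list[Clonotype] | pd.DataFrame,
    background: list[Clonotype] | pd.DataFrame,
    n_rand: int = 100,
    seed: int = 0,
    by_length: bool = False,
) -> UsageBiasResult:
    """Test V genes (optionally V x CDR3-length strata) for over-use in the
    called list relative to ``n_rand`` equally sized random background
    draws.  Empirical p uses the add-one convention
    ``(1 + #draws >= observed) / (n_rand + 1)`` so its floor is
    ``1/(n_rand+1)``.
    """
    called_df = _frame(called)
    bg = _frame(background)
    rng = np.random.default_rng(seed)
    strata_cols = ["v_gene", "cdr3_length"] if by_length else ["v_gene"]

    def freq_table(df: pd.DataFrame) -> pd.Series:
        return df.groupby(strata_cols).size() / len(df)

    observed = freq_table(called_df)
    missing = [s for s in observed.index if s not in set(map(tuple, bg[strata_cols].itertuples(index=False))) and by_length]
    for s in missing:
        logger.warning("stratum %s absent from background; skipped", s)
    draws = np.zeros((n_rand, len(observed)))
    n = len(called_df)
    for t in range(n_rand):
        idx = rng.choice(len(bg), size=n, replace=len(bg) < n)
        draws[t] = freq_table(bg.iloc[idx]).reindex(observed.index, fill_value=0.0).to_numpy()
    exceed = (draws >= observed.to_numpy()).sum(axis=0)
    table = pd.DataFrame(
        {
            "observed_freq": observed.to_numpy(),
            "null_mean": draws.mean(axis=0),
            "p": (1 + exceed) / (n_rand + 1),
        },
        index=observed.index,
    ).reset_index()
    return UsageBiasResult(table=table, n_rand=n_rand)


@dataclass
class PositionEnrichment:
    """Per position: significantly over-used residues and bits of
    information in their (renormalized) frequency distribution."""

    table: pd.DataFrame  # position, residues, bits

    @property
    def bits(self) -> np.ndarray:
        return self.table["bits"].to_numpy()


def positional_aa_enrichment(
    subset: list[str],
    background: list[str],
    n_rand: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    min_subset: int = 5,
) -> PositionEnrichment:
    """Position-wise amino-acid enrichment of a fixed-length CDR3 subset.

    Per position, a residue is significantly over-used when its frequency
    exceeds that of ``n_rand`` random equal-size background draws at
    ``alpha`` (add-one empirical p).  Information content per position is
    ``log2(20) - H`` where H is the Shannon entropy of the significant
    residues' renormalized frequencies; positions with no significant
    residue carry 0 bits.
    """
    if len(subset) < min_subset:
        raise ValueError(f"subset smaller than {min_subset}; skipped")
    L = len(subset[0])
    if any(len(s) != L for s in subset):
        raise ValueError("all subset sequences must share one length")
    background = [s for s in background if len(s) == L]
    if not background:
        raise ValueError("no background sequences of matching length")
    rng = np.random.default_rng(seed)
    sub = np.array([list(s) for s in subset])
    bg = np.array([list(s) for s in background])
    n = len(subset)
    rows = []
    max_bits = np.log2(20.0)
    for pos in range(L):
        col = sub[:, pos]
        obs = pd.Series(col).value_counts(normalize=True)
        exceed = {aa: 0 for aa in obs.index}
        for _ in range(n_rand):
            idx = rng.choice(len(bg), size=n, replace=len(bg) < n)
            draw = pd.Series(bg[idx, pos]).value_counts(normalize=True)
            for aa in exceed:
                if draw.get(aa, 0.0) >= obs[aa]:
                    exceed[aa] += 1
        sig = [aa for aa in obs.index if (1 + exceed[aa]) / (n_rand + 1) < alpha]
        if sig:
            f = obs[sig].to_numpy()
            f = f / f.sum()
            bits = float(max_bits - stats.entropy(f, base=2))
        else:
            bits = 0.0
        rows.append({"position": pos, "residues": "".join(sorted(sig)), "bits": bits})
    return PositionEnrichment(table=pd.DataFrame(rows))


def known_overlap_test(
    called: set[str],
    known: set[str],
    universe: set[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Randomization test for overlap between a called set and a known
    condition-associated set.

    Draws ``n_perm`` uniform random sets of ``|called|`` from the universe;
    p is the fraction of draws whose overlap with ``known`` is >= the
    observed overlap.  Also reports the straightforward expectation
    ``|called| * |known| / |universe|``.
    """
    if not universe:
        raise ValueError("universe is empty")
    if not known <= universe or not called <= universe:
        raise ValueError("called and known sets must be subsets of the universe")
    rng = np.random.default_rng(seed)
    uni = sorted(universe)
    known_mask = np.array([u in known for u in uni])
    observed = len(called & known)
    n = len(called)
    overlaps = np.array(
        [known_mask[rng.choice(len(uni), size=n, replace=False)].sum() for _ in range(n_perm)]
    )
    return {
        "observed_overlap": float(observed),
        "expected_overlap": len(called) * len(known) / len(universe),
        "p": float((overlaps >= observed).mean()),
    }


def gene_usage_chi2(
    cluster_a: list[Clonotype],
    cluster_b: list[Clonotype],
    feature: str = "V",
) -> float:
    """Chi-square p for independence of gene usage between two clusters.

    ``feature`` selects the categories: V, J, VJ or VDJ combinations.
    Categories absent from both clusters are dropped; with a single shared
    category there is no variation and p = 1.
    """
    if not cluster_a or not cluster_b:
        raise ValueError("both clusters must be non-empty")
    if feature not in {"V", "J", "VJ", "VDJ"}:
        raise ValueError(f"unknown feature {feature!r}")

    def cat(c: Clonotype) -> str:
        parts = {"V": [c.v_gene], "J": [c.j_gene], "VJ": [c.v_gene, c.j_gene],
                 "VDJ": [c.v_gene, c.d_gene, c.j_gene]}[feature]
        return "|".join(parts)

    a = pd.Series([cat(c) for c in cluster_a]).value_counts()
    b = pd.Series([cat(c) for c in cluster_b]).value_counts()
    cats = sorted(set(a.index) | set(b.index))
    if len(cats) < 2:
        return 1.0
    table = np.array([[a.get(c, 0) for c in cats], [b.get(c, 0) for c in cats]])
    _, p, _, _ = stats.chi2_contingency(table)
    return float(p)


def plot_position_enrichment(result: PositionEnrichment, ax=None):
    """Logo-style bar chart: per-position bits with residue letters stacked
    proportionally to their renormalized frequencies."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(0.6 * len(result.table) + 1, 3))
    for _, row in result.table.iterrows():
        if not row["residues"]:
            continue
        share = row["bits"] / len(row["residues"])
        y = 0.0
        for aa in row["residues"]:
            ax.bar(row["position"], share, bottom=y, width=0.8, color="lightsteelblue", edgecolor="white")
            ax.text(row["position"], y + share / 2, aa, ha="center", va="center", fontsize=9)
            y += share
    ax.set_xlabel("CDR3 position")
    ax.set_ylabel("information (bits)")
    return ax
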