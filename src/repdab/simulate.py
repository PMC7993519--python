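"""Synthetic TCR repertoire generation with known ground truth.

The generator emulates the structural features the pipeline exploits,
without modelling full V(D)J recombination biophysics:

* toy germline segments (8 V, 4 J, 2 D-like labels) built once from
  non-stop codons, with real-style names (``TRBV01-01`` ...);
* CDR3s assembled codon-wise as V + N1 + motif/D + N2 + J so every
  sequence is in-frame and productive; non-templated inserts are random
  non-stop codons;
* *shared clusters*: groups of CDR3s carrying a common 5-codon motif (and
  a common V/J pair) planted in the junctional region, drawn from a pool
  shared across samples so clusters match across individuals;
* clone sizes from a rounded log-normal (default) or a discrete power law;
* convergent recombination: a configurable fraction of clonotypes is
  emitted as two synonymous nucleotide variants of the same amino-acid
  CDR3;
* condition-associated *spikes*: in affected condition samples the counts
  of chosen clusters are multiplied by a fold change.

Every draw flows from one seed, so a configuration reproduces its files
exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import (
    Clonotype,
    ClonotypeKey,
    RepertoireSample,
    SampleMetadata,
    write_immunoseq,
)

logger = logging.getLogger(__name__)

_STOPS = {"TAA", "TAG", "TGA"}
NONSTOP_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)

#: synonymous alternatives for each codon (same amino acid, different nt)
_SYNONYM: dict[str, list[str]] = {}
for _c in NONSTOP_CODONS:
    _aa = str(Seq(_c).translate())
    _SYNONYM.setdefault(_aa, []).append(_c)
CODON_ALTS = {
    c: [o for o in _SYNONYM[str(Seq(c).translate())] if o != c] for c in NONSTOP_CODONS
}


def _random_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(NONSTOP_CODONS, size=n))


@dataclass
class ToyGermline:
    v_segments: dict[str, str]
    j_segments: dict[str, str]
    d_names: tuple[str, ...] = ("TRBD01-01", "TRBD02-01")

    @classmethod
    def default(cls, n_v: int = 8, n_j: int = 4, seed: int = 20240) -> "ToyGermline":
        rng = np.random.default_rng(seed)
        v = {
            f"TRBV{i + 1:02d}-01": "TGC" + _random_codons(rng, 3)  # conserved Cys start
            for i in range(n_v)
        }
        j = {f"TRBJ{i // 2 + 1:02d}-{i % 2 + 1:02d}": _random_codons(rng, 4) for i in range(n_j)}
        return cls(v_segments=v, j_segments=j)


@dataclass
class SimConfig:
    """Study-design parameters of a simulated two-group repertoire dataset."""

    n_subjects: int = 8  # samples (unpaired) or subjects x2 samples (paired)
    paired: bool = False
    n_clonotypes: int = 2000  # clonotypes per sample, background + clusters
    n_shared_clusters: int = 12
    cluster_size: int = 60  # pool size per shared cluster
    cluster_member_prob: float = 0.9  # P(a pool member appears in a sample)
    motif_codons: int = 5  # planted junctional motif length (codons)
    n_insert_codons: tuple[int, int] = (1, 3)  # N1/N2 length range (codons)
    clone_size_law: str = "lognormal"  # "lognormal" | "powerlaw"
    powerlaw_exponent: float = 2.5
    lognormal_mu: float = 0.5
    lognormal_sigma: float = 1.0
    max_clone_size: int = 10_000
    n_spiked_clusters: int = 2
    fold_change: float = 4.0
    fraction_affected: float = 1.0  # fraction of condition samples spiked
    convergence_rate: float = 0.1  # P(clonotype emitted as 2 synonymous nt variants)
    # antigen-driven convergent recombination: spiked clonotypes in affected
    # condition samples recombine convergently more often than background
    spiked_convergence_rate: float = 0.5
    seed: int = 0
    germline: ToyGermline = field(default_factory=ToyGermline.default)

    def __post_init__(self) -> None:
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")
        if not 0 <= self.fraction_affected <= 1:
            raise ValueError("fraction_affected must be in [0, 1]")
        if self.n_shared_clusters > 4 ** (3 * self.motif_codons) // 64:
            raise ValueError("motif space too small for the requested cluster count")


@dataclass
class SimResult:
    samples: dict[str, RepertoireSample]
    metadata: SampleMetadata
    truth: pd.DataFrame
    spiked_keys: set[ClonotypeKey]
    config: SimConfig


def _draw_clone_size(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    if cfg.clone_size_law == "powerlaw":
        sizes = rng.zipf(cfg.powerlaw_exponent, size=n)
    elif cfg.clone_size_law == "lognormal":
        sizes = np.ceil(rng.lognormal(cfg.lognormal_mu, cfg.lognormal_sigma, size=n)).astype(int)
    else:
        raise ValueError(f"unknown clone_size_law {cfg.clone_size_law!r}")
    return np.clip(sizes, 1, cfg.max_clone_size)


@dataclass(frozen=True)
class _ClusterSpec:
    name: str
    v: str
    j: str
    d: str
    motif: str  # nt, 3*motif_codons long


def _make_cluster_specs(rng: np.random.Generator, cfg: SimConfig) -> list[_ClusterSpec]:
    v_names = sorted(cfg.germline.v_segments)
    j_names = sorted(cfg.germline.j_segments)
    seen: set[str] = set()
    specs = []
    for i in range(cfg.n_shared_clusters):
        while True:
            motif = _random_codons(rng, cfg.motif_codons)
            if motif not in seen:
                seen.add(motif)
                break
        specs.append(
            _ClusterSpec(
                name=f"cluster_{i:02d}",
                v=v_names[int(rng.integers(len(v_names)))],
                j=j_names[int(rng.integers(len(j_names)))],
                d=cfg.germline.d_names[int(rng.integers(len(cfg.germline.d_names)))],
                motif=motif,
            )
        )
    return specs


def _assemble(
    rng: np.random.Generator,
    cfg: SimConfig,
    v: str,
    j: str,
    motif: str,
    insert_range: tuple[int, int] | None = None,
) -> str:
    lo, hi = insert_range or cfg.n_insert_codons
    n1 = _random_codons(rng, int(rng.integers(lo, hi + 1)))
    n2 = _random_codons(rng, int(rng.integers(lo, hi + 1)))
    return cfg.germline.v_segments[v] + n1 + motif + n2 + cfg.germline.j_segments[j]


def _cluster_pools(
    rng: np.random.Generator, cfg: SimConfig, specs: list[_ClusterSpec]
) -> dict[str, list[tuple[str, str, str, str, str]]]:
    """Per cluster: pool of (nt, v, d, j, alt_nt) shared across samples.

    ``alt_nt`` is a fixed synonymous variant: convergent recombination
    produces the *same* recurrent nucleotide variants across individuals,
    so the alternative is a property of the pool clonotype, not redrawn per
    sample.
    """
    pools = {}
    seen_aa: set[tuple[str, str, str]] = set()
    for spec in specs:
        pool = []
        seen = set()
        while len(pool) < cfg.cluster_size:
            # antigen-selected clusters are junction-length restricted:
            # members differ only in short fixed-length inserts
            nt = _assemble(rng, cfg, spec.v, spec.j, spec.motif, insert_range=(1, 1))
            aa_key = (str(Seq(nt).translate()), spec.v, spec.j)
            # chance synonymy is rejected so that convergent variants arise
            # only through the explicit convergence mechanism
            if nt in seen or aa_key in seen_aa:
                continue
            seen.add(nt)
            seen_aa.add(aa_key)
            alt = _synonymous_variant(rng, nt) or nt
            pool.append((nt, spec.v, spec.d, spec.j, alt))
        pools[spec.name] = pool
    return pools


def generate_dataset(config: SimConfig, out_dir: str | Path | None = None) -> SimResult:
    """Generate a two-group dataset; optionally write immunoseq TSVs, a
    metadata CSV and the ground-truth table under ``out_dir``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    specs = _make_cluster_specs(rng, cfg)
    pools = _cluster_pools(rng, cfg, specs)
    spiked_clusters = {s.name for s in specs[: cfg.n_spiked_clusters]} if cfg.fold_change > 1 else set()

    if cfg.paired:
        plan = [
            (f"S{i + 1:02d}_{g}", f"subj{i + 1:02d}", g, f"pair{i + 1:02d}")
            for i in range(cfg.n_subjects)
            for g in ("control", "condition")
        ]
    else:
        half = cfg.n_subjects // 2
        plan = [
            (
                f"S{i + 1:02d}",
                f"subj{i + 1:02d}",
                "control" if i < half else "condition",
                "",
            )
            for i in range(cfg.n_subjects)
        ]
    cond_samples = [p[0] for p in plan if p[2] == "condition"]
    n_affected = math.ceil(cfg.fraction_affected * len(cond_samples))
    affected = set(rng.choice(cond_samples, size=n_affected, replace=False)) if n_affected else set()

    samples: dict[str, RepertoireSample] = {}
    truth_rows = []
    spiked_keys: set[ClonotypeKey] = set()
    v_names = sorted(cfg.germline.v_segments)
    j_names = sorted(cfg.germline.j_segments)

    for sample_id, subject_id, group, _pair in plan:
        sample = RepertoireSample(sample_id=sample_id, subject_id=subject_id, group=group)
        # nt, v, d, j, cluster, spiked, shared alt variant (None = draw privately)
        records: list[tuple[str, str, str, str, str, bool, str | None]] = []
        for spec in specs:
            spiked_here = spec.name in spiked_clusters and sample_id in affected
            for nt, v, d, j, alt in pools[spec.name]:
                if rng.random() < cfg.cluster_member_prob:
                    records.append((nt, v, d, j, spec.name, spiked_here, alt))
        n_background = max(0, cfg.n_clonotypes - len(records))
        seen_nt = {r[0] for r in records}
        seen_aa = {(str(Seq(r[0]).translate()), r[1], r[3]) for r in records}
        while n_background > 0:
            v = v_names[int(rng.integers(len(v_names)))]
            j = j_names[int(rng.integers(len(j_names)))]
            d = cfg.germline.d_names[int(rng.integers(2))]
            nt = _assemble(rng, cfg, v, j, _random_codons(rng, cfg.motif_codons))
            aa_key = (str(Seq(nt).translate()), v, j)
            if nt in seen_nt or aa_key in seen_aa:
                continue
            seen_nt.add(nt)
            seen_aa.add(aa_key)
            records.append((nt, v, d, j, "background", False, None))
            n_background -= 1

        sizes = _draw_clone_size(rng, cfg, len(records))
        for (nt, v, d, j, cluster, spiked, alt), size in zip(records, sizes):
            count = int(size)
            if spiked:
                count = int(round(count * cfg.fold_change))
            aa = str(Seq(nt).translate())
            variants = [(nt, count)]
            conv_rate = cfg.spiked_convergence_rate if spiked else cfg.convergence_rate
            if conv_rate > 0 and rng.random() < conv_rate and count >= 2:
                if alt is None:
                    alt = _synonymous_variant(rng, nt)
                if alt is not None and alt != nt:
                    c2 = count // 2
                    variants = [(nt, count - c2), (alt, c2)]
            for nt_var, c in variants:
                clone = Clonotype(nt_seq=nt_var, aa_seq=aa, count=c, v_gene=v, d_gene=d, j_gene=j)
                sample.add(clone)
                if spiked:
                    spiked_keys.add(clone.key)
                truth_rows.append(
                    {
                        "sample_id": sample_id,
                        "nt_seq": nt_var,
                        "aa_seq": aa,
                        "v_gene": v,
                        "d_gene": d,
                        "j_gene": j,
                        "cluster": cluster,
                        "spiked": spiked,
                        "count": c,
                    }
                )
        samples[sample_id] = sample

    meta = SampleMetadata(
        table=pd.DataFrame(
            plan, columns=["sample_id", "subject_id", "group", "pair_id"]
        ),
        paired=cfg.paired,
    )
    truth = pd.DataFrame(truth_rows)
    result = SimResult(samples=samples, metadata=meta, truth=truth, spiked_keys=spiked_keys, config=cfg)
    if out_dir is not None:
        write_dataset(result, out_dir)
    return result


def _synonymous_variant(rng: np.random.Generator, nt: str) -> str | None:
    """Swap one codon for a synonymous alternative; None if impossible."""
    positions = list(range(0, len(nt), 3))
    rng.shuffle(positions)
    for pos in positions:
        codon = nt[pos : pos + 3]
        alts = CODON_ALTS.get(codon, [])
        if alts:
            alt = alts[int(rng.integers(len(alts)))]
            return nt[:pos] + alt + nt[pos + 3 :]
    return None


def write_dataset(result: SimResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, sample in result.samples.items():
        write_immunoseq(sample, out / f"{sid}.tsv")
    result.metadata.table.to_csv(out / "metadata.csv", index=False)
    result.truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)


def null_reference(
    n_clonotypes: int = 2000,
    seed: int = 999_001,
    config: SimConfig | None = None,
    cluster_fraction: float = 1.0,
    cluster_size: int = 60,
) -> RepertoireSample:
    """A healthy-repertoire stand-in usable as a decoy reference pool.

    Like any repertoire, the reference carries motif-sharing public
    clusters (a ``cluster_fraction`` of its clonotypes, in clusters of
    ``cluster_size``) on top of diffuse background — but, being an
    independent healthy cohort, its junctional motifs are its *own*.
    Injected decoys therefore form their own clusters and sub-repertoires
    and traverse matching and differential testing exactly like real
    condition-irrelevant clonotypes, without free-riding inside truly
    condition-associated clusters; their detection rate is then a fair
    false-discovery estimate.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    ref_cfg = SimConfig(
        n_shared_clusters=max(1, round(n_clonotypes * cluster_fraction / cluster_size)),
        cluster_size=cluster_size,
        motif_codons=cfg.motif_codons,
        germline=cfg.germline,
        seed=seed,
    )
    specs = _make_cluster_specs(rng, ref_cfg)
    sample = RepertoireSample(sample_id="decoy_reference")
    v_names = sorted(cfg.germline.v_segments)
    j_names = sorted(cfg.germline.j_segments)
    seen: set[str] = set()

    records: list[tuple[str, str, str, str]] = []
    n_clustered = round(cluster_fraction * n_clonotypes)
    i = 0
    while len(records) < n_clustered:
        spec = specs[i % len(specs)]
        i += 1
        nt = _assemble(rng, cfg, spec.v, spec.j, spec.motif, insert_range=(1, 1))
        if nt in seen:
            continue
        seen.add(nt)
        records.append((nt, spec.v, spec.d, spec.j))
    while len(records) < n_clonotypes:
        v = v_names[int(rng.integers(len(v_names)))]
        j = j_names[int(rng.integers(len(j_names)))]
        nt = _assemble(rng, cfg, v, j, _random_codons(rng, cfg.motif_codons))
        if nt in seen:
            continue
        seen.add(nt)
        records.append((nt, v, cfg.germline.d_names[int(rng.integers(2))], j))
    sizes = _draw_clone_size(rng, cfg, len(records))
    for (nt, v, d, j), size in zip(records[:n_clonotypes], sizes):
        sample.add(
            Clonotype(
                nt_seq=nt,
                aa_seq=str(Seq(nt).translate()),
                count=int(size),
                v_gene=v,
                d_gene=d,
                j_gene=j,
            )
        )
    return sample


def inject_decoys(
    samples: dict[str, RepertoireSample],
    decoy_source: RepertoireSample,
    ratio: float,
    seed: int = 0,
) -> tuple[dict[str, RepertoireSample], set[ClonotypeKey]]:
    """Add on average ``ratio * n_clonotypes`` decoy clonotypes per sample.

    Decoys must be exchangeable with condition-irrelevant real clonotypes
    for their detection rate to estimate the false discovery rate, so the
    injection copies the *dataset's own* sharing and abundance profile:

    * a common decoy set is drawn from the healthy reference pool, sized so
      each sample receives ``ratio * n`` decoys in expectation;
    * each drawn decoy inherits the presence profile of a randomly chosen
      real clonotype: it appears in that many samples, chosen uniformly,
      so the decoy population reproduces the data's full public/private
      sharing spectrum rather than its mean;
    * its count in a sample is resampled from that sample's own clone-size
      distribution (decoys are as abundant as the data);
    * decoys carry convergent nucleotide variants at the data's own rate:
      with the empirical probability that a real amino-acid clonotype has
      two nucleotide variants in a sample, the decoy is emitted as its
      fixed synonymous pair with the count split between them.

    Pool entries whose key occurs in a sample are excluded there with a
    warning.  Returns the augmented samples and the set of injected decoy
    keys.
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    rng = np.random.default_rng(seed)
    out: dict[str, RepertoireSample] = {}
    if ratio == 0 or not samples:
        return dict(samples), set()
    sample_ids = sorted(samples)
    n_samples = len(sample_ids)
    presence: dict[ClonotypeKey, int] = {}
    for s in samples.values():
        for k in s.clonotypes:
            presence[k] = presence.get(k, 0) + 1
    if not presence:
        return dict(samples), set()
    presence_counts = np.array(sorted(presence.values()))
    sharing = float(presence_counts.mean()) / n_samples
    mean_n = float(np.mean([len(s) for s in samples.values()]))
    pool = sorted(decoy_source.clonotypes)
    n_draw = min(math.ceil(ratio * mean_n / sharing), len(pool))
    if n_draw < math.ceil(ratio * mean_n / sharing):
        logger.warning("decoy reference smaller than the requested draw; using all %d", n_draw)
    chosen = [pool[i] for i in sorted(rng.choice(len(pool), size=n_draw, replace=False))]
    # decoy -> set of receiving samples (bootstrap of real presence counts)
    destinations: dict[ClonotypeKey, set[str]] = {}
    alt_of: dict[ClonotypeKey, str | None] = {}
    for key in chosen:
        m = int(presence_counts[int(rng.integers(presence_counts.size))])
        dest = rng.choice(n_samples, size=m, replace=False)
        destinations[key] = {sample_ids[i] for i in dest}
        alt_of[key] = _synonymous_variant(rng, decoy_source.clonotypes[key].nt_seq)
    # empirical rate of convergent (multi-nt) amino-acid clonotypes
    n_groups, n_convergent = 0, 0
    for s in samples.values():
        groups_: dict[tuple[str, str, str], int] = {}
        for c in s.clonotypes.values():
            gk = (c.aa_seq, c.v_gene, c.j_gene)
            groups_[gk] = groups_.get(gk, 0) + 1
        n_groups += len(groups_)
        n_convergent += sum(1 for v in groups_.values() if v > 1)
    convergent_rate = n_convergent / n_groups if n_groups else 0.0

    injected: set[ClonotypeKey] = set()
    for sid in sample_ids:
        sample = samples[sid]
        if len(sample) == 0:
            out[sid] = sample
            continue
        counts = np.array([c.count for c in sample.clonotypes.values()])
        new = RepertoireSample(
            sample_id=sample.sample_id,
            clonotypes=dict(sample.clonotypes),
            subject_id=sample.subject_id,
            group=sample.group,
            is_cdna=sample.is_cdna,
            depth_normalized=sample.depth_normalized,
        )
        n_overlap = 0
        for key in chosen:
            if sid not in destinations[key]:
                continue
            if key in sample.clonotypes:
                n_overlap += 1
                continue
            src = decoy_source.clonotypes[key]
            count = float(counts[int(rng.integers(counts.size))])
            alt = alt_of[key]
            variants = [(src.nt_seq, count)]
            if alt is not None and count >= 2 and rng.random() < convergent_rate:
                half = count // 2 if float(count).is_integer() else count / 2
                variants = [(src.nt_seq, count - half), (alt, half)]
            for nt_var, c_var in variants:
                var_key = (nt_var, src.v_gene, src.j_gene)
                if nt_var != src.nt_seq and var_key in sample.clonotypes:
                    continue
                new.add(
                    Clonotype(
                        nt_seq=nt_var,
                        aa_seq=src.aa_seq,
                        count=c_var,
                        v_gene=src.v_gene,
                        d_gene=src.d_gene,
                        j_gene=src.j_gene,
                    )
                )
                injected.add(var_key)
        if n_overlap:
            logger.warning("%s: %d decoy pool entries overlap real clonotypes; dropped", sid, n_overlap)
        out[sid] = new
    return out, injected
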