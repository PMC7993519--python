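"""End-to-end orchestration: repeated resample runs of clustering, matching
and differential-abundance testing, followed by one candidate-ranking pass.

Repertoires are far too diverse to cluster whole, so the pipeline runs
``n_resamples`` independent rounds, each on a fresh random subsample of
unique CDR3s per sample.  Candidates detected in a round are pooled across
rounds (their detection count is ranking factor R6) and ranked once per
direction.  All randomness derives from one master seed, so a run is
reproducible end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import abundance as ab
from . import ranking as rk
from .cluster import cluster_within_sample
from .io import (
    ClonotypeKey,
    RepertoireSample,
    SampleMetadata,
    filter_singletons,
    normalize_depth,
    subsample_unique,
)
from .kmers import KmerSpace, encode_sample
from .matching import match_clusters, merge_same_sample
from .simulate import inject_decoys

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    kmer_space: str = "nt4"  # "nt4" | "aa3"
    n_resamples: int = 100
    subsample_size: int = 5000
    filter_singletons: bool = True
    matching_method: str = "km"  # "km" | "hc"
    abundance_mode: str = "sum"
    da_test: str = "t"  # "t" | "rankprod"
    da_p_cutoff: float = 0.1
    min_per_group: int = 3
    paired: bool = False
    condition_group: str = "condition"
    n_perm: int = 1000
    final_p_cutoff: float = 0.05
    final_q_cutoff: float = 0.05
    decoy_ratio: float = 0.1
    min_cluster_size: int = 5
    deep_split: int = 3
    rankprod_n_perm: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kmer_space not in {"nt4", "aa3"}:
            raise ValueError("kmer_space must be 'nt4' or 'aa3'")
        for name in ("n_resamples", "subsample_size", "min_per_group", "n_perm"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("da_p_cutoff", "final_p_cutoff", "final_q_cutoff"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")

    def space(self) -> KmerSpace:
        return KmerSpace.nt(4) if self.kmer_space == "nt4" else KmerSpace.aa(3)


@dataclass
class RunRecord:
    run_index: int
    seed: int
    cluster_counts: dict[str, int]
    chosen_k: int | None
    da_subreps: list[tuple[int, str, float]]  # (id, direction, p)
    candidates: dict[str, set[ClonotypeKey]]  # direction -> keys


@dataclass
class RunLog:
    records: list[RunRecord] = field(default_factory=list)
    n_failed: int = 0

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class PipelineResult:
    final_calls: pd.DataFrame
    rankings: dict[str, rk.RankingResult]
    run_log: RunLog
    decoy_keys: set[ClonotypeKey]
    config: PipelineConfig


def _run_seed(master: int, run_index: int) -> int:
    return int(np.random.SeedSequence([master, run_index]).generate_state(1)[0] % (2**31))


def run_once(
    samples: dict[str, RepertoireSample],
    metadata: SampleMetadata,
    config: PipelineConfig,
    run_index: int,
) -> RunRecord:
    """One resample round: subsample, encode, cluster, match, test."""
    seed = _run_seed(config.seed, run_index)
    space = config.space()
    sample_ids = sorted(samples)
    subs = [
        subsample_unique(samples[sid], config.subsample_size, seed=_run_seed(seed, i))
        for i, sid in enumerate(sample_ids)
    ]
    subs = normalize_depth(subs)
    sub_map = {s.sample_id: s for s in subs}
    assignments = []
    for s in subs:
        matrix = encode_sample(s, space)
        assignments.append(
            cluster_within_sample(
                matrix,
                min_cluster_size=config.min_cluster_size,
                deep_split=config.deep_split,
            )
        )
    subreps, ksel = match_clusters(
        assignments, method=config.matching_method, seed=seed
    )
    subreps, amap = merge_same_sample(subreps, assignments)
    matrix = ab.abundance_matrix(sub_map, subreps, amap, mode=config.abundance_mode)
    groups = metadata.groups
    filtered = ab.filter_presence(matrix, groups, min_per_group=config.min_per_group)
    pairs = metadata.pairs() if config.paired else None
    results = ab.da_test(
        filtered,
        groups,
        condition=config.condition_group,
        test=config.da_test,
        paired=config.paired,
        pairs=pairs,
        p_cutoff=config.da_p_cutoff,
        n_perm=config.rankprod_n_perm,
        seed=seed,
    )
    srmap = {sr.id: sr for sr in subreps}
    candidates: dict[str, set[ClonotypeKey]] = {"enriched": set(), "de-enriched": set()}
    da_rows = []
    for r in results:
        if not r.passed:
            continue
        da_rows.append((r.subrep_id, r.direction, r.p_value))
        for keys in srmap[r.subrep_id].clonotypes(amap).values():
            candidates[r.direction].update(keys)
    return RunRecord(
        run_index=run_index,
        seed=seed,
        cluster_counts={a.sample_id: a.n_clusters for a in assignments},
        chosen_k=ksel.k if ksel is not None else None,
        da_subreps=da_rows,
        candidates=candidates,
    )


def aggregate_candidates(run_log: RunLog) -> dict[str, dict[ClonotypeKey, int]]:
    """Union of candidates per direction with per-key detection counts."""
    if len(run_log) == 0:
        raise ValueError("run log is empty")
    out: dict[str, dict[ClonotypeKey, int]] = {"enriched": {}, "de-enriched": {}}
    for rec in run_log.records:
        for direction, keys in rec.candidates.items():
            d = out[direction]
            for k in keys:
                d[k] = d.get(k, 0) + 1
    return out


def run_pipeline(
    samples: dict[str, RepertoireSample],
    metadata: SampleMetadata,
    config: PipelineConfig,
    decoy_reference: RepertoireSample | None = None,
) -> PipelineResult:
    """Run the full method and return the final called CDR3 table.

    ``decoy_reference`` is a healthy/background repertoire pool; its
    clonotypes are spiked into every sample before analysis so that the
    decoy detection rate can calibrate the FDR of the final calls.  Without
    it the q-value is undefined and final calls rest on the permutation p
    alone.
    """
    groups = metadata.groups
    for g in set(groups.values()):
        n = sum(1 for v in groups.values() if v == g)
        if n < config.min_per_group:
            raise ValueError(f"group {g!r} has {n} samples, fewer than min_per_group")
    if config.condition_group not in set(groups.values()):
        raise ValueError(f"condition group {config.condition_group!r} not in metadata")

    work = dict(samples)
    if config.filter_singletons:
        work = {sid: filter_singletons(s) for sid, s in work.items()}
    decoy_keys: set[ClonotypeKey] = set()
    if decoy_reference is not None and config.decoy_ratio > 0:
        # decoys pass the same pre-filter as real clonotypes
        source = filter_singletons(decoy_reference) if config.filter_singletons else decoy_reference
        work, decoy_keys = inject_decoys(
            work, source, config.decoy_ratio, seed=_run_seed(config.seed, 987_654)
        )

    run_log = RunLog()
    for r in range(config.n_resamples):
        try:
            run_log.records.append(run_once(work, metadata, config, r))
        except Exception:  # noqa: BLE001 - a failed round is logged and skipped
            logger.exception("resample run %d failed", r)
            run_log.n_failed += 1
        if run_log.n_failed > config.n_resamples / 2:
            raise RuntimeError("more than half of the resample runs failed; aborting")

    detections = aggregate_candidates(run_log)
    pairs = metadata.pairs() if config.paired else None
    rankings: dict[str, rk.RankingResult] = {}
    tables = []
    for direction, det in detections.items():
        if len(det) < 2:
            if det:
                logger.warning("direction %s has <2 candidates; skipped", direction)
            continue
        ranking = rk.score_candidates(
            list(det),
            direction,
            samples_raw=work,
            groups=groups,
            condition=config.condition_group,
            detection_counts=det,
            decoy_keys=decoy_keys,
            decoy_ratio=config.decoy_ratio if decoy_keys else None,
            paired=config.paired,
            pairs=pairs,
            n_perm=config.n_perm,
            seed=_run_seed(config.seed, 123_456),
        )
        rankings[direction] = ranking
        calls = ranking.final_calls(config.final_p_cutoff, config.final_q_cutoff)
        tables.append(_annotate(calls, work))

    final = (
        pd.concat(tables).sort_values(["direction", "p", "C"])
        if tables
        else _empty_calls()
    )
    return PipelineResult(
        final_calls=final,
        rankings=rankings,
        run_log=run_log,
        decoy_keys=decoy_keys,
        config=config,
    )


def _annotate(calls: pd.DataFrame, samples: dict[str, RepertoireSample]) -> pd.DataFrame:
    out = calls.copy()
    nts, vs, js, aas = [], [], [], []
    for key in out.index:
        nt, v, j = key
        nts.append(nt)
        vs.append(v)
        js.append(j)
        aa = ""
        for s in samples.values():
            c = s.clonotypes.get(key)
            if c is not None:
                aa = c.aa_seq
                break
        aas.append(aa)
    out.insert(0, "nt_seq", nts)
    out.insert(1, "aa_seq", aas)
    out.insert(2, "v_gene", vs)
    out.insert(3, "j_gene", js)
    return out


def _empty_calls() -> pd.DataFrame:
    cols = ["nt_seq", "aa_seq", "v_gene", "j_gene", "C", "p", "q", "direction", "detection_count"]
    return pd.DataFrame(columns=cols)
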