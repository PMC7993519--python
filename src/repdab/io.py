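"""Reading, writing and pre-filtering of clonotype tables.

A *sample* is one repertoire file: a tab-delimited table with one row per
CDR3 clonotype (nucleotide sequence, amino-acid sequence, template count and
V/D/J gene calls).  Two dialects are supported: immunoseq-style exports and
MiXCR clone tables.  Records are keyed by ``(nt_seq, v_gene, j_gene)`` so
identical CDR3s arising from distinct rearrangements are kept apart;
duplicate rows under that key are summed on read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DNA_ALPHABET = set("ACGT")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

#: canonical field -> default immunoseq column name
IMMUNOSEQ_COLUMNS = {
    "nt_seq": "nucleotide",
    "aa_seq": "aminoAcid",
    "count": "count (templates/reads)",
    "v_gene": "vGeneName",
    "d_gene": "dGeneName",
    "j_gene": "jGeneName",
}

MIXCR_COLUMNS = {
    "nt_seq": "nSeqCDR3",
    "aa_seq": "aaSeqCDR3",
    "count": "cloneCount",
    "v_gene": "bestVHit",
    "d_gene": "bestDHit",
    "j_gene": "bestJHit",
}

REQUIRED_FIELDS = ("nt_seq", "aa_seq", "count", "v_gene", "j_gene")


class FormatError(ValueError):
    """Input table does not conform to the expected dialect."""


class EmptySampleError(ValueError):
    """Input table contains no clonotype rows."""


_GENE_RE = re.compile(
    r"^(?:TCR|TR)([ABGD])([VDJ])0*(\d+)(?:[-.]0*(\d+))?", re.IGNORECASE
)


def normalize_gene(name: object) -> str:
    """Normalize a V/D/J gene call to ``TR<chain><segment><family>[-<gene>]``.

    Family and gene numbers are zero-padded to two digits and allele
    suffixes (``*01``) are stripped, so immunoseq names (``TCRBV09-01*01``)
    and MiXCR names (``TRBV9-1*00``) become comparable (``TRBV09-01``).
    Missing or unresolved calls map to ``"NA"``.
    """
    if name is None or (isinstance(name, float) and np.isnan(name)):
        return "NA"
    s = str(name).strip()
    if not s or s.lower() in {"unresolved", "unknown", "na", "nan", "none"}:
        return "NA"
    m = _GENE_RE.match(s)
    if m is None:
        return s.split("*")[0]
    chain, segment, family, gene = m.groups()
    out = f"TR{chain.upper()}{segment.upper()}{int(family):02d}"
    if gene is not None:
        out += f"-{int(gene):02d}"
    return out


@dataclass(frozen=True, slots=True)
class Clonotype:
    """One CDR3 record; ``count`` is an integer template count on input and
    may become fractional after depth normalization."""

    nt_seq: str
    aa_seq: str
    count: float
    v_gene: str
    d_gene: str = "NA"
    j_gene: str = "NA"

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.nt_seq, self.v_gene, self.j_gene)

    @property
    def cdr3_length(self) -> int:
        return len(self.nt_seq)


ClonotypeKey = tuple[str, str, str]


@dataclass
class RepertoireSample:
    """A named collection of clonotypes keyed by ``(nt_seq, v_gene, j_gene)``."""

    sample_id: str
    clonotypes: dict[ClonotypeKey, Clonotype] = field(default_factory=dict)
    subject_id: str = ""
    group: str = ""
    is_cdna: bool = False
    depth_normalized: bool = False

    @property
    def total_abundance(self) -> float:
        return sum(c.count for c in self.clonotypes.values())

    @property
    def n_unique(self) -> int:
        return len(self.clonotypes)

    def add(self, clonotype: Clonotype) -> None:
        """Insert a clonotype, summing counts on key collision."""
        key = clonotype.key
        prev = self.clonotypes.get(key)
        if prev is None:
            self.clonotypes[key] = clonotype
        else:
            self.clonotypes[key] = replace(prev, count=prev.count + clonotype.count)

    def __len__(self) -> int:
        return len(self.clonotypes)


@dataclass
class SampleMetadata:
    """Per-sample design information (subject, group, optional pairing)."""

    table: pd.DataFrame
    paired: bool = False

    def __post_init__(self) -> None:
        required = {"sample_id", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"metadata missing column(s): {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise FormatError("duplicate sample_id in metadata")
        if self.table["group"].nunique() != 2:
            raise FormatError("exactly two groups are required")

    @property
    def groups(self) -> dict[str, str]:
        return dict(zip(self.table["sample_id"], self.table["group"]))

    def group_samples(self, group: str) -> list[str]:
        t = self.table
        return list(t.loc[t["group"] == group, "sample_id"])

    def pairs(self) -> list[tuple[str, str]]:
        """(control_sample, condition_sample) tuples from ``pair_id``."""
        if "pair_id" not in self.table.columns:
            raise FormatError("paired design requires a pair_id column")
        out = []
        for _, sub in self.table.groupby("pair_id"):
            if len(sub) != 2 or sub["group"].nunique() != 2:
                raise FormatError(
                    f"pair {sub['pair_id'].iloc[0]!r} must hold one sample per group"
                )
            sub = sub.sort_values("group")
            out.append((sub["sample_id"].iloc[0], sub["sample_id"].iloc[1]))
        return out


def read_metadata(path: str | Path) -> SampleMetadata:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table = pd.read_csv(path, sep=sep, dtype=str)
    paired = "pair_id" in table.columns and table["pair_id"].notna().all()
    return SampleMetadata(table=table, paired=paired)


def _validate_record(nt: str, aa: str) -> str | None:
    """Return a rejection reason, or None if the record is analysable."""
    if not nt or set(nt) - DNA_ALPHABET:
        return "non-ACGT nucleotide sequence"
    if not aa or "*" in aa or set(aa) - AA_ALPHABET:
        return "non-productive or invalid amino-acid sequence"
    if len(nt) % 3 != 0 or len(aa) != len(nt) // 3:
        return "out-of-frame record"
    return None


def _read_table(
    path: str | Path,
    columns: Mapping[str, str],
    sample_id: str | None,
    is_cdna: bool,
) -> RepertoireSample:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptySampleError(f"{path} is empty") from None
    for fld in REQUIRED_FIELDS:
        if columns[fld] not in df.columns:
            raise FormatError(f"{path}: missing required column {columns[fld]!r} ({fld})")
    if len(df) == 0:
        raise EmptySampleError(f"{path} contains no clonotype rows")

    sample = RepertoireSample(sample_id=sample_id or path.stem, is_cdna=is_cdna)
    n_dropped = 0
    d_col = columns.get("d_gene")
    for row in df.itertuples(index=False):
        rec = dict(zip(df.columns, row))
        nt = str(rec[columns["nt_seq"]]).strip().upper()
        aa = str(rec[columns["aa_seq"]]).strip().upper()
        reason = _validate_record(nt, aa)
        if reason is not None:
            n_dropped += 1
            continue
        try:
            count = int(float(rec[columns["count"]]))
        except (TypeError, ValueError):
            n_dropped += 1
            continue
        if count < 1:
            n_dropped += 1
            continue
        sample.add(
            Clonotype(
                nt_seq=nt,
                aa_seq=aa,
                count=count,
                v_gene=normalize_gene(rec[columns["v_gene"]]),
                d_gene=normalize_gene(rec.get(d_col)) if d_col in df.columns else "NA",
                j_gene=normalize_gene(rec[columns["j_gene"]]),
            )
        )
    if n_dropped:
        logger.info("%s: dropped %d invalid/out-of-frame rows", path, n_dropped)
    if len(sample) == 0:
        raise EmptySampleError(f"{path}: no analysable clonotypes after validation")
    return sample


def read_immunoseq(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sample_id: str | None = None,
) -> RepertoireSample:
    """Read an immunoseq-style tab-delimited clonotype table.

    ``dialect`` maps canonical field names (``nt_seq``, ``aa_seq``,
    ``count``, ``v_gene``, ``d_gene``, ``j_gene``) to the file's actual
    column headers; unmapped fields use the immunoseq defaults.
    """
    columns = dict(IMMUNOSEQ_COLUMNS)
    if dialect:
        columns.update(dialect)
    return _read_table(path, columns, sample_id, is_cdna=False)


def read_mixcr(path: str | Path, sample_id: str | None = None) -> RepertoireSample:
    """Read a MiXCR clone table.  The sample is flagged as cDNA-derived so
    downstream reports speak of differential expression rather than clonal
    expansion."""
    return _read_table(path, MIXCR_COLUMNS, sample_id, is_cdna=True)


def write_immunoseq(sample: RepertoireSample, path: str | Path) -> None:
    """Write a sample back out in the default immunoseq dialect."""
    rows = [
        {
            IMMUNOSEQ_COLUMNS["nt_seq"]: c.nt_seq,
            IMMUNOSEQ_COLUMNS["aa_seq"]: c.aa_seq,
            IMMUNOSEQ_COLUMNS["count"]: c.count,
            IMMUNOSEQ_COLUMNS["v_gene"]: c.v_gene,
            IMMUNOSEQ_COLUMNS["d_gene"]: c.d_gene,
            IMMUNOSEQ_COLUMNS["j_gene"]: c.j_gene,
        }
        for c in sample.clonotypes.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def filter_singletons(sample: RepertoireSample) -> RepertoireSample:
    """Drop clonotypes observed only once (count 1)."""
    kept = {k: c for k, c in sample.clonotypes.items() if c.count >= 2}
    if not kept:
        logger.warning("%s: all clonotypes are singletons; sample is empty", sample.sample_id)
    return replace_clonotypes(sample, kept)


def subsample_unique(
    sample: RepertoireSample, n: int, seed: int
) -> RepertoireSample:
    """Draw ``min(n, n_unique)`` clonotypes uniformly *without* abundance
    weighting; drawn clonotypes keep their original counts."""
    if n < 1:
        raise ValueError("n must be >= 1")
    keys = sorted(sample.clonotypes)
    if n >= len(keys):
        return replace_clonotypes(sample, dict(sample.clonotypes))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(keys), size=n, replace=False)
    kept = {keys[i]: sample.clonotypes[keys[i]] for i in sorted(chosen)}
    return replace_clonotypes(sample, kept)


def normalize_depth(samples: Iterable[RepertoireSample]) -> list[RepertoireSample]:
    """Rescale each sample's counts so all totals equal the minimum original
    total.  Counts become fractional; within-sample proportions are kept."""
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("need at least two samples to normalize")
    totals = [s.total_abundance for s in samples]
    if any(t <= 0 for t in totals):
        raise ValueError("cannot depth-normalize an empty sample")
    target = min(totals)
    out = []
    for s, total in zip(samples, totals):
        factor = target / total
        kept = {
            k: replace(c, count=c.count * factor) for k, c in s.clonotypes.items()
        }
        ns = replace_clonotypes(s, kept)
        ns.depth_normalized = True
        out.append(ns)
    return out


def replace_clonotypes(
    sample: RepertoireSample, clonotypes: dict[ClonotypeKey, Clonotype]
) -> RepertoireSample:
    return RepertoireSample(
        sample_id=sample.sample_id,
        clonotypes=clonotypes,
        subject_id=sample.subject_id,
        group=sample.group,
        is_cdna=sample.is_cdna,
        depth_normalized=sample.depth_normalized,
    )
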