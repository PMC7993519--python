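"""Contiguous k-mer composition encoding of CDR3 sequences.

Each CDR3 is represented by a dense vector of counts over every possible
k-mer of the chosen alphabet, columns in lexicographic order.  The defaults
mirror common practice: nucleotide 4-mers (256 features) or amino-acid
3-mers (8000 features).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .io import ClonotypeKey, RepertoireSample

logger = logging.getLogger(__name__)

NT_ALPHABET = "ACGT"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class KmerSpace:
    """A fixed alphabet and word length; defines a bijection between every
    possible k-mer and a column index."""

    alphabet: str
    k: int
    index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        kmers = ["".join(p) for p in itertools.product(sorted(self.alphabet), repeat=self.k)]
        object.__setattr__(self, "index", {km: i for i, km in enumerate(kmers)})

    @property
    def dim(self) -> int:
        return len(self.alphabet) ** self.k

    @property
    def kmer_names(self) -> list[str]:
        return sorted(self.index, key=self.index.get)

    @classmethod
    def nt(cls, k: int = 4) -> "KmerSpace":
        return cls(NT_ALPHABET, k)

    @classmethod
    def aa(cls, k: int = 3) -> "KmerSpace":
        return cls(AA_ALPHABET, k)

    @property
    def is_nucleotide(self) -> bool:
        return set(self.alphabet) == set(NT_ALPHABET)


def kmer_vector(seq: str, space: KmerSpace, normalize: bool = False) -> np.ndarray:
    """Count every overlapping window of length ``k`` in ``seq``.

    The result sums to ``len(seq) - k + 1``; with ``normalize=True`` it is
    divided by that window count.
    """
    k = space.k
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}: {seq!r}")
    vec = np.zeros(space.dim)
    index = space.index
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        j = index.get(window)
        if j is None:
            bad = next(p for p, ch in enumerate(seq) if ch not in space.alphabet)
            raise ValueError(
                f"invalid character {seq[bad]!r} at position {bad} for alphabet {space.alphabet!r}"
            )
        vec[j] += 1
    if normalize:
        vec /= len(seq) - k + 1
    return vec


@dataclass
class KmerMatrix:
    """Rows = clonotype keys (sorted, deterministic), columns = k-mers."""

    keys: list[ClonotypeKey]
    X: np.ndarray
    space: KmerSpace
    sample_id: str = ""

    def __len__(self) -> int:
        return len(self.keys)

    def to_tsv(self, path) -> None:
        """Debug dump: rows keyed by (nt_seq, v_gene, j_gene)."""
        import pandas as pd

        pd.DataFrame(
            self.X,
            index=pd.MultiIndex.from_tuples(self.keys, names=["nt_seq", "v_gene", "j_gene"]),
            columns=self.space.kmer_names,
        ).to_csv(path, sep="\t")


def encode_sample(
    sample: RepertoireSample, space: KmerSpace, normalize: bool = False
) -> KmerMatrix:
    """Encode every clonotype of a sample; nucleotide spaces read ``nt_seq``,
    amino-acid spaces read ``aa_seq``.  Sequences shorter than k are dropped
    with a warning."""
    if len(sample) == 0:
        raise ValueError(f"sample {sample.sample_id!r} is empty")
    keys = sorted(sample.clonotypes)
    rows, kept = [], []
    for key in keys:
        c = sample.clonotypes[key]
        seq = c.nt_seq if space.is_nucleotide else c.aa_seq
        if len(seq) < space.k:
            logger.warning("%s: sequence shorter than k, dropped: %r", sample.sample_id, seq)
            continue
        rows.append(kmer_vector(seq, space, normalize=normalize))
        kept.append(key)
    if not rows:
        raise ValueError(f"sample {sample.sample_id!r} has no encodable sequences")
    return KmerMatrix(keys=kept, X=np.vstack(rows), space=space, sample_id=sample.sample_id)
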