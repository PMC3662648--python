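"""Sequence-read containers and FASTA/FASTQ helpers.

Reads are held as a plain sequence string plus a numpy vector of phred-scaled
base qualities, the unit consumed by both the quality trimmer and the mapper.
FASTQ is phred+33 throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33
MAX_PHRED = 41
BASES = "ACGT"

_BASE_TO_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_TO_IDX[ord(_b)] = _i
    _BASE_TO_IDX[ord(_b.lower())] = _i
_IDX_TO_BASE = np.frombuffer(BASES.encode(), dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    """Encode an ACGT string as uint8 indices (A=0, C=1, G=2, T=3)."""
    return _BASE_TO_IDX[np.frombuffer(seq.encode(), dtype=np.uint8)].copy()


def decode_seq(arr: np.ndarray) -> str:
    return bytes(_IDX_TO_BASE[arr]).decode()


def phred_to_error_prob(qual: np.ndarray) -> np.ndarray:
    return np.power(10.0, -np.asarray(qual, dtype=float) / 10.0)


def error_prob_to_phred(p: float) -> int:
    return int(round(-10.0 * math.log10(max(p, 1e-10))))


@dataclass
class QualityRead:
    """A read with per-base phred qualities; the unit of trimming and mapping."""

    id: str
    seq: str
    qual: np.ndarray  # phred scores, uint8, same length as seq

    def __post_init__(self) -> None:
        self.qual = np.asarray(self.qual, dtype=np.uint8)
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def error_probs(self) -> np.ndarray:
        return phred_to_error_prob(self.qual)

    def slice(self, start: int, end: int) -> "QualityRead":
        return QualityRead(self.id, self.seq[start:end], self.qual[start:end])


def read_fastq(path: str | Path) -> list[QualityRead]:
    reads = []
    with open(path) as fh:
        for name, seq, qual in FastqGeneralIterator(fh):
            q = np.frombuffer(qual.encode(), dtype=np.uint8) - PHRED_OFFSET
            reads.append(QualityRead(name.split()[0], seq, q.astype(np.uint8)))
    return reads


def write_fastq(reads: Iterable[QualityRead], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            qual = bytes(r.qual + PHRED_OFFSET).decode()
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")
            n += 1
    return n


def iter_fastq(path: str | Path) -> Iterator[QualityRead]:
    with open(path) as fh:
        for name, seq, qual in FastqGeneralIterator(fh):
            q = np.frombuffer(qual.encode(), dtype=np.uint8) - PHRED_OFFSET
            yield QualityRead(name.split()[0], seq, q.astype(np.uint8))


def read_fasta(path: str | Path) -> dict[str, str]:
    """Reference contigs as an ordered {name: sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> int:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    return SeqIO.write(records, str(path), "fasta")
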