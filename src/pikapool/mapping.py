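"""Ungapped seed-and-extend read mapping and per-pool pileups.

A read is placed by exact k-mer seeding followed by ungapped extension along
the seed diagonal; the best placement is accepted only when the aligned
region's identity and the aligned fraction of the read both meet the
mapping policy (defaults: similarity 0.90, length fraction 0.50).  Reads
with more than one best-scoring placement are flagged ambiguous and kept out
of pileups, which prevents paralog-driven false variant calls.  Alignment is
substitutions-only: the simulator emits no indels and the downstream caller
handles SNPs only.

Coordinates are 0-based half-open internally; emitted tables are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .reads import MAX_PHRED, PHRED_OFFSET, QualityRead, encode_seq
from .simulate import POOLS


@dataclass
class MappingPolicy:
    """Acceptance rules: identity over the aligned region and aligned fraction."""

    min_similarity: float = 0.90
    min_length_fraction: float = 0.50
    seed_length: int = 16

    def __post_init__(self) -> None:
        for name in ("min_similarity", "min_length_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.seed_length < 4:
            raise ValueError("seed_length must be >= 4")


@dataclass
class Placement:
    """One accepted read placement on a reference contig."""

    read_id: str
    pool: str
    contig: str
    start: int  # 0-based offset of the aligned region on the contig
    read_offset: int  # first aligned base of the read
    span: int  # aligned length
    identity: float  # matches / span
    fraction: float  # span / read length
    ambiguous: bool = False

    @property
    def end(self) -> int:
        return self.start + self.span


class ReferenceIndex:
    """Encoded contigs plus an exact k-mer seed index."""

    def __init__(self, references: dict[str, str], seed_length: int = 16):
        if not references:
            raise ValueError("empty reference set")
        self.names = list(references)
        self.seed_length = seed_length
        self.encoded = {name: encode_seq(seq) for name, seq in references.items()}
        self.lengths = {name: len(seq) for name, seq in references.items()}
        self._index: dict[bytes, list[tuple[str, int]]] = {}
        for name, seq in references.items():
            raw = seq.upper().encode()
            for i in range(len(raw) - seed_length + 1):
                self._index.setdefault(raw[i : i + seed_length], []).append((name, i))

    def seed_hits(self, kmer: bytes) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


def map_read(
    read: QualityRead,
    index: ReferenceIndex,
    policy: MappingPolicy,
    pool: str = "high",
) -> Placement | None:
    """Best ungapped placement of a read, or ``None`` when unmapped.

    Candidate diagonals come from exact k-mer seeds taken at ``seed_length``
    strides (plus one terminal seed).  Ties on the match count are broken by
    lowest (contig id, position); multi-best reads are returned flagged
    ``ambiguous`` so pileup construction can exclude them.
    """
    k = index.seed_length
    rlen = len(read)
    if rlen < k:
        return None
    raw = read.seq.upper().encode()
    offsets = list(range(0, rlen - k + 1, k))
    if offsets[-1] != rlen - k:
        offsets.append(rlen - k)
    candidates: set[tuple[str, int]] = set()
    for off in offsets:
        for contig, pos in index.seed_hits(raw[off : off + k]):
            candidates.add((contig, pos - off))
    if not candidates:
        return None
    read_arr = encode_seq(read.seq)
    best: tuple[int, str, int] | None = None  # (-matches, contig, diag) minimised
    best_matches = -1
    n_best = 0
    best_layout: tuple[int, int, int] | None = None  # (ref_start, read_start, span)
    for contig, diag in sorted(candidates):
        clen = index.lengths[contig]
        ref_start = max(diag, 0)
        ref_end = min(diag + rlen, clen)
        span = ref_end - ref_start
        if span <= 0:
            continue
        read_start = ref_start - diag
        matches = int(
            np.count_nonzero(
                index.encoded[contig][ref_start:ref_end]
                == read_arr[read_start : read_start + span]
            )
        )
        if matches > best_matches:
            best_matches = matches
            n_best = 1
            best = (contig, ref_start)
            best_layout = (ref_start, read_start, span)
        elif matches == best_matches:
            n_best += 1  # first (lowest contig, position) already kept
    if best is None or best_matches <= 0:
        return None
    contig, ref_start = best
    ref_start, read_start, span = best_layout  # type: ignore[misc]
    identity = best_matches / span
    fraction = span / rlen
    if identity < policy.min_similarity or fraction < policy.min_length_fraction:
        return None
    return Placement(
        read_id=read.id,
        pool=pool,
        contig=contig,
        start=ref_start,
        read_offset=read_start,
        span=span,
        identity=identity,
        fraction=fraction,
        ambiguous=n_best > 1,
    )


def map_read_set(
    reads: list[QualityRead],
    index: ReferenceIndex,
    policy: MappingPolicy,
    pool: str,
) -> tuple[list[Placement], dict]:
    placements = []
    n_unmapped = 0
    n_ambiguous = 0
    for read in reads:
        p = map_read(read, index, policy, pool=pool)
        if p is None:
            n_unmapped += 1
        else:
            if p.ambiguous:
                n_ambiguous += 1
            placements.append(p)
    return placements, {
        "pool": pool,
        "n_reads": len(reads),
        "n_mapped": len(placements),
        "n_unmapped": n_unmapped,
        "n_ambiguous": n_ambiguous,
    }


def ingest_alignments(
    path: str | Path,
    references: dict[str, str],
    policy: MappingPolicy,
    pool_of=None,
) -> tuple[list[Placement], dict]:
    """Placements from an existing SAM file under the same acceptance rules.

    Identity over the aligned region comes from the NM tag when present,
    otherwise from per-base comparison against the reference.  Unmapped
    records are skipped and tallied; records naming unknown contigs raise.
    """
    if pool_of is None:
        pool_of = lambda qname: qname.split(":", 1)[0]
    encoded = {name: encode_seq(seq) for name, seq in references.items()}
    placements: list[Placement] = []
    stats = {"n_records": 0, "n_skipped_unmapped": 0, "n_rejected": 0, "n_accepted": 0}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            stats["n_records"] += 1
            if rec.is_unmapped:
                stats["n_skipped_unmapped"] += 1
                continue
            contig = rec.reference_name
            if contig not in references:
                raise ValueError(f"alignment references unknown contig {contig!r}")
            span = rec.query_alignment_length
            rlen = rec.query_length or len(rec.query_sequence or "")
            if span == 0 or rlen == 0:
                stats["n_rejected"] += 1
                continue
            if rec.has_tag("NM"):
                matches = span - int(rec.get_tag("NM"))
            elif rec.query_sequence is not None:
                seg = encode_seq(
                    rec.query_sequence[rec.query_alignment_start : rec.query_alignment_end]
                )
                ref_seg = encoded[contig][rec.reference_start : rec.reference_start + span]
                if len(seg) != len(ref_seg):
                    raise ValueError(
                        f"record {rec.query_name}: gapped alignment without NM tag"
                    )
                matches = int(np.count_nonzero(seg == ref_seg))
            else:
                raise ValueError(f"record {rec.query_name}: no identity information")
            identity = matches / span
            fraction = span / rlen
            if identity < policy.min_similarity or fraction < policy.min_length_fraction:
                stats["n_rejected"] += 1
                continue
            stats["n_accepted"] += 1
            placements.append(
                Placement(
                    read_id=rec.query_name,
                    pool=pool_of(rec.query_name),
                    contig=contig,
                    start=rec.reference_start,
                    read_offset=rec.query_alignment_start,
                    span=span,
                    identity=identity,
                    fraction=fraction,
                    ambiguous=False,
                )
            )
    return placements, stats


def write_placements_sam(
    placements: list[Placement],
    reads_by_id: dict[str, QualityRead],
    references: dict[str, str],
    path: str | Path,
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in references.items()],
    }
    tid = {name: i for i, name in enumerate(references)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for p in placements:
            read = reads_by_id[p.read_id]
            a = pysam.AlignedSegment()
            a.query_name = p.read_id
            a.query_sequence = read.seq
            a.query_qualities = pysam.qualitystring_to_array(
                bytes(read.qual + PHRED_OFFSET).decode()
            )
            a.reference_id = tid[p.contig]
            a.reference_start = p.start
            a.mapping_quality = 0 if p.ambiguous else 60
            cigar = []
            if p.read_offset:
                cigar.append((4, p.read_offset))  # soft clip
            cigar.append((0, p.span))
            tail = len(read) - p.read_offset - p.span
            if tail:
                cigar.append((4, tail))
            a.cigartuples = cigar
            a.flag = 0
            mism = p.span - int(round(p.identity * p.span))
            a.set_tag("NM", mism)
            out.write(a)


@dataclass
class PoolPileupColumn:
    """Per-pool base and quality counts at one reference position."""

    contig: str
    position: int  # 0-based
    base_counts: dict[str, dict[str, int]]  # pool -> base -> count
    base_quals: dict[str, dict[str, list[int]]]  # pool -> base -> phred list

    @property
    def depth(self) -> dict[str, int]:
        return {pool: sum(c.values()) for pool, c in self.base_counts.items()}


class PoolPileup:
    """Per-contig, per-pool counts of (position, base, quality).

    Backed by dense uint32 arrays of shape (n_pools, length, 4 bases,
    MAX_PHRED + 1) allocated lazily per contig, which keeps threshold-based
    calling a vectorised reduction.
    """

    def __init__(self, references: dict[str, str], pools: tuple[str, ...] = POOLS):
        self.references = references
        self.pools = pools
        self.pool_index = {p: i for i, p in enumerate(pools)}
        self.lengths = {name: len(seq) for name, seq in references.items()}
        self._arrays: dict[str, np.ndarray] = {}

    def _array(self, contig: str) -> np.ndarray:
        if contig not in self._arrays:
            self._arrays[contig] = np.zeros(
                (len(self.pools), self.lengths[contig], 4, MAX_PHRED + 1), dtype=np.uint32
            )
        return self._arrays[contig]

    @property
    def covered_contigs(self) -> list[str]:
        return list(self._arrays)

    def add_placement(self, placement: Placement, read: QualityRead) -> None:
        if placement.end > self.lengths[placement.contig]:
            raise ValueError(
                f"placement of {placement.read_id} exceeds contig "
                f"{placement.contig} bounds"
            )
        arr = self._array(placement.contig)
        pi = self.pool_index[placement.pool]
        ro = placement.read_offset
        bases = encode_seq(read.seq)[ro : ro + placement.span]
        quals = np.minimum(read.qual[ro : ro + placement.span], MAX_PHRED)
        positions = np.arange(placement.start, placement.end)
        np.add.at(arr, (pi, positions, bases, quals), 1)

    def counts(self, contig: str) -> np.ndarray:
        """(n_pools, length, 4, MAX_PHRED+1) count array for one contig."""
        return self._array(contig)

    def qpass_counts(self, contig: str, min_quality: int) -> np.ndarray:
        """(n_pools, length, 4) counts restricted to quality >= min_quality."""
        return self._array(contig)[..., min_quality:].sum(axis=-1)

    def depth(self, contig: str, min_quality: int = 0) -> np.ndarray:
        """(n_pools, length) read depth, optionally quality-restricted."""
        return self.qpass_counts(contig, min_quality).sum(axis=-1)

    def column(self, contig: str, position: int) -> PoolPileupColumn:
        arr = self._array(contig)[:, position]  # (pools, 4, Q+1)
        base_counts: dict[str, dict[str, int]] = {}
        base_quals: dict[str, dict[str, list[int]]] = {}
        for pool, pi in self.pool_index.items():
            base_counts[pool] = {}
            base_quals[pool] = {}
            for bi, base in enumerate("ACGT"):
                hist = arr[pi, bi]
                total = int(hist.sum())
                if total:
                    base_counts[pool][base] = total
                    base_quals[pool][base] = [
                        q for q in range(MAX_PHRED + 1) for _ in range(int(hist[q]))
                    ]
        return PoolPileupColumn(contig, position, base_counts, base_quals)

    def to_tsv(self, path: str | Path, min_depth: int = 1) -> None:
        with open(path, "w") as fh:
            fh.write("contig\tposition\tpool\tA\tC\tG\tT\n")
            for contig in self.covered_contigs:
                base_counts = self._array(contig).sum(axis=-1)  # pools, L, 4
                depth = base_counts.sum(axis=-1)
                for pos in np.flatnonzero(depth.sum(axis=0) >= min_depth):
                    for pool, pi in self.pool_index.items():
                        c = base_counts[pi, pos]
                        fh.write(
                            f"{contig}\t{pos + 1}\t{pool}\t{c[0]}\t{c[1]}\t{c[2]}\t{c[3]}\n"
                        )


def build_pileups(
    placements: list[Placement],
    reads_by_id: dict[str, QualityRead],
    references: dict[str, str],
    pools: tuple[str, ...] = POOLS,
) -> PoolPileup:
    """Accumulate accepted, unambiguous placements into per-pool pileups."""
    pileup = PoolPileup(references, pools=pools)
    for p in placements:
        if p.ambiguous:
            continue
        if p.read_id not in reads_by_id:
            raise KeyError(f"placement references unknown read {p.read_id!r}")
        pileup.add_placement(p, reads_by_id[p.read_id])
    return pileup
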