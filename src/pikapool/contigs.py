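"""Contig-level filters: high-coverage dataset, elevation-unique contigs,
and redundancy classes among the reference contigs."""

from __future__ import annotations

import operator
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mapping import Placement, PoolPileup
from .reads import encode_seq
from .simulate import POOLS
from .trim import max_scoring_segment

SUMMARY_COLUMNS = [
    "contig", "length",
    "mean_cov_high", "mean_cov_low", "n_reads_high", "n_reads_low",
]


def summarize_contigs(
    pileup: PoolPileup, placements: list[Placement]
) -> pd.DataFrame:
    """Per-contig length, per-pool mean coverage and mapped-read counts.

    Coverage counts every base of every accepted unambiguous placement
    (no quality filter), divided by contig length.
    """
    read_counts: dict[tuple[str, str], int] = {}
    for p in placements:
        if p.ambiguous:
            continue
        key = (p.contig, p.pool)
        read_counts[key] = read_counts.get(key, 0) + 1
    rows = []
    for contig, length in pileup.lengths.items():
        if contig in pileup.covered_contigs:
            depth = pileup.depth(contig)  # (2, L), all qualities
            cov = depth.sum(axis=1) / length
        else:
            cov = np.zeros(2)
        rows.append(
            {
                "contig": contig,
                "length": length,
                "mean_cov_high": float(cov[0]),
                "mean_cov_low": float(cov[1]),
                "n_reads_high": read_counts.get((contig, "high"), 0),
                "n_reads_low": read_counts.get((contig, "low"), 0),
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def filter_high_coverage(
    summaries: pd.DataFrame,
    min_length: int = 200,
    min_cov: float = 5.0,
    cov_op=operator.ge,
) -> list[str]:
    """Contigs of at least ``min_length`` whose mean coverage meets
    ``min_cov`` in BOTH pools (comparison operator configurable)."""
    keep = (
        (summaries["length"] >= min_length)
        & cov_op(summaries["mean_cov_high"], min_cov)
        & cov_op(summaries["mean_cov_low"], min_cov)
    )
    return summaries.loc[keep, "contig"].tolist()


def find_elevation_unique(
    summaries: pd.DataFrame,
    min_length: int = 200,
    min_cov: float = 5.0,
) -> dict[str, list[str]]:
    """Contigs covered by reads from only a single pool.

    Assignment to pool P requires mean coverage >= ``min_cov`` in P, zero
    mapped reads from the other pool, and length >= ``min_length``.
    """
    out: dict[str, list[str]] = {}
    for pool, other in (("high", "low"), ("low", "high")):
        keep = (
            (summaries["length"] >= min_length)
            & (summaries[f"mean_cov_{pool}"] >= min_cov)
            & (summaries[f"n_reads_{other}"] == 0)
        )
        out[pool] = summaries.loc[keep, "contig"].tolist()
    return out


@dataclass
class RedundancyClass:
    contig: str
    label: str  # unique | one_partner | multi_partner
    partners: list[str]


def cluster_redundant_contigs(
    contigs: dict[str, str],
    min_similarity: float = 0.90,
    min_length_fraction: float = 0.50,
    seed_length: int = 16,
) -> list[RedundancyClass]:
    """Pairwise-overlap redundancy classes among contigs.

    Two contigs are partners when an ungapped local alignment (best-scoring
    segment on a shared-k-mer diagonal, scored match = 1 - s, mismatch = -s
    for similarity threshold s, so a positive-sum segment has identity > s)
    spans at least ``min_length_fraction`` of the shorter contig.  Contigs
    partition into unique / one_partner / multi_partner by partner count.
    """
    if not contigs:
        raise ValueError("at least one contig required")
    names = list(contigs)
    encoded = {n: encode_seq(s) for n, s in contigs.items()}
    index: dict[bytes, list[tuple[str, int]]] = {}
    for name, seq in contigs.items():
        raw = seq.upper().encode()
        for i in range(0, max(len(raw) - seed_length + 1, 0)):
            index.setdefault(raw[i : i + seed_length], []).append((name, i))

    partners: dict[str, set[str]] = {n: set() for n in names}
    checked: set[tuple[str, str, int]] = set()
    for name, seq in contigs.items():
        raw = seq.upper().encode()
        arr = encoded[name]
        for off in range(0, max(len(raw) - seed_length + 1, 1), seed_length):
            for other, pos in index.get(raw[off : off + seed_length], []):
                if other == name:
                    continue
                a, b = sorted((name, other))
                # b[j] aligns a[j + diag]; the seed sits at `off` in `name`
                # and at `pos` in `other`
                diag = off - pos if a == name else pos - off
                key = (a, b, diag)
                if key in checked or other in partners[name]:
                    continue
                checked.add(key)
                arr_a, arr_b = encoded[a], encoded[b]
                # align b onto a at offset diag
                a_start = max(diag, 0)
                a_end = min(diag + len(arr_b), len(arr_a))
                if a_end <= a_start:
                    continue
                b_start = a_start - diag
                matches = (
                    arr_a[a_start:a_end] == arr_b[b_start : b_start + (a_end - a_start)]
                )
                scores = np.where(matches, 1.0 - min_similarity, -min_similarity)
                s, e, total = max_scoring_segment(scores)
                span = e - s
                shorter = min(len(arr_a), len(arr_b))
                if total > 0 and span >= min_length_fraction * shorter:
                    partners[a].add(b)
                    partners[b].add(a)
    out = []
    for name in names:
        n = len(partners[name])
        label = "unique" if n == 0 else ("one_partner" if n == 1 else "multi_partner")
        out.append(RedundancyClass(name, label, sorted(partners[name])))
    return out


def redundancy_class_counts(classes: list[RedundancyClass]) -> dict[str, int]:
    counts = {"unique": 0, "one_partner": 0, "multi_partner": 0}
    for c in classes:
        counts[c.label] += 1
    counts["total"] = len(classes)
    return counts


def write_summary_tsv(summaries: pd.DataFrame, path: str | Path) -> None:
    summaries.to_csv(path, sep="\t", index=False, float_format="%.4g")
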