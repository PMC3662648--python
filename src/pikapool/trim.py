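"""Read quality trimming (modified-Mott) and read-set summaries.

The trimmer reproduces a standard 454 preprocessing recipe: strip literal
adapter sequences from the read ends, remove a fixed number of terminal
nucleotides, keep the contiguous segment that maximises the Mott score
``sum(quality_limit - p_i)`` over per-base error probabilities ``p_i``, and
finally discard reads shorter than a minimum length.

The quality limit is an error-probability threshold: a base with error
probability below the limit contributes positively to the retained segment,
a base above it negatively.  With the default limit 0.05 a Q13+ base counts
as "good".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .reads import QualityRead


@dataclass
class TrimPolicy:
    """Trimming rules: error-probability limit, terminal clip, length floor."""

    quality_limit: float = 0.05
    terminal_trim: int = 5
    min_length: int = 100
    adapters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.quality_limit < 1.0:
            raise ValueError("quality_limit must be in (0, 1)")
        if self.terminal_trim < 0:
            raise ValueError("terminal_trim must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


def max_scoring_segment(scores: np.ndarray) -> tuple[int, int, float]:
    """Best-sum contiguous segment of ``scores``.

    Returns ``(start, end, total)`` for the half-open segment maximising the
    sum; among equal-sum segments the longest is preferred, then the leftmost.
    Returns ``(0, 0, 0.0)`` when no segment has positive sum.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n == 0:
        return 0, 0, 0.0
    pref = np.concatenate(([0.0], np.cumsum(scores)))
    minacc = np.minimum.accumulate(pref)
    # first index attaining the running minimum (smallest i -> longest segment)
    is_new_min = np.empty(n + 1, dtype=bool)
    is_new_min[0] = True
    is_new_min[1:] = pref[1:] < minacc[:-1]
    first_min_idx = np.maximum.accumulate(np.where(is_new_min, np.arange(n + 1), 0))
    ends = np.arange(1, n + 1)
    starts = first_min_idx[:-1]
    sums = pref[1:] - minacc[:-1]
    best = sums.max()
    if best <= 0:
        return 0, 0, 0.0
    cand = np.flatnonzero(sums == best)
    lengths = ends[cand] - starts[cand]
    # longest segment, then leftmost start
    order = np.lexsort((starts[cand], -lengths))
    j = cand[order[0]]
    return int(starts[j]), int(ends[j]), float(best)


def _strip_adapters(read: QualityRead, adapters: tuple[str, ...]) -> QualityRead:
    """Exact literal adapter removal at the read ends only."""
    start, end = 0, len(read)
    changed = True
    while changed:
        changed = False
        for ad in adapters:
            if not ad:
                continue
            if read.seq.startswith(ad, start, end):
                start += len(ad)
                changed = True
            if end - start >= len(ad) and read.seq.endswith(ad, start, end):
                end -= len(ad)
                changed = True
    if start == 0 and end == len(read):
        return read
    return read.slice(start, end)


def trim_read(read: QualityRead, policy: TrimPolicy) -> QualityRead | None:
    """Trim one read; ``None`` signals the read is discarded.

    Order of operations: adapters -> terminal trim -> Mott quality segment ->
    minimum-length filter.  The output is always a contiguous substring of
    the input.
    """
    r = _strip_adapters(read, policy.adapters)
    t = policy.terminal_trim
    if t > 0:
        if len(r) <= 2 * t:
            return None
        r = r.slice(t, len(r) - t)
    scores = policy.quality_limit - r.error_probs
    start, end, total = max_scoring_segment(scores)
    if total <= 0:
        return None
    r = r.slice(start, end)
    if len(r) < policy.min_length:
        return None
    return r


def trim_read_set(
    reads: list[QualityRead], policy: TrimPolicy
) -> tuple[list[QualityRead], dict]:
    kept = []
    n_discarded = 0
    for read in reads:
        out = trim_read(read, policy)
        if out is None:
            n_discarded += 1
        else:
            kept.append(out)
    return kept, {"n_input": len(reads), "n_kept": len(kept), "n_discarded": n_discarded}


@dataclass
class ReadSetSummary:
    """Totals for one read set, shaped like a per-library summary row."""

    n_reads: int
    n_bases: int
    mean_read_length: float  # NaN when the set is empty

    @property
    def mean_defined(self) -> bool:
        return not math.isnan(self.mean_read_length)


def summarize_read_set(reads: list[QualityRead]) -> ReadSetSummary:
    n_reads = len(reads)
    n_bases = sum(len(r) for r in reads)
    mean = n_bases / n_reads if n_reads else float("nan")
    return ReadSetSummary(n_reads=n_reads, n_bases=n_bases, mean_read_length=mean)
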