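"""Validation-panel population statistics and small-pool ascertainment.

Implements the per-locus, per-group statistics a genotyping validation panel
is scored with - observed/expected heterozygosity, the conditional exact
Hardy-Weinberg test, a permutation test of linkage disequilibrium, Holm's
step-down multiple-testing correction - plus the closed-form probability
that a population-polymorphic site looks fixed in a small pool sample.

Genotypes are coded as alt-allele dosage 0/1/2 with NaN for missing;
expected heterozygosity is plain 2pq without a small-sample correction, so
a fully heterozygous group prints He = 0.50 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd


def locus_heterozygosity(genotypes: np.ndarray | list) -> tuple[float, float]:
    """(Ho, He) for one locus in one group of 0/1/2-coded genotypes.

    Ho is the heterozygote fraction among genotyped individuals; He = 2pq
    with p the sample allele frequency.  Missing genotypes (NaN) are
    excluded from both denominators.
    """
    g = np.asarray(genotypes, dtype=float)
    g = g[~np.isnan(g)]
    if g.size == 0:
        raise ValueError("all genotypes missing")
    n = g.size
    ho = float(np.count_nonzero(g == 1) / n)
    p = float(g.sum() / (2 * n))  # alt-allele frequency
    he = 2.0 * p * (1.0 - p)
    return ho, he


def _het_weights(n: int, n_a: int) -> dict[int, int]:
    """Integer enumeration weights over heterozygote counts conditional on
    the allele count ``n_a`` (number of A alleles among 2n)."""
    n_b = 2 * n - n_a
    weights = {}
    h_max = min(n_a, n_b)
    for h in range(n_a % 2, h_max + 1, 2):
        n_aa = (n_a - h) // 2
        n_bb = (n_b - h) // 2
        # multinomial(n; n_aa, h, n_bb) * 2^h
        w = comb(n, n_aa) * comb(n - n_aa, h) * (2 ** h)
        weights[h] = w
    return weights


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg p-value conditional on allele counts.

    Enumerates all heterozygote counts compatible with the observed allele
    counts; the two-sided p-value sums the conditional probabilities of
    every configuration no more probable than the observed one (probability
    ordering).  Monomorphic samples return 1.
    """
    for c in (n_aa, n_ab, n_bb):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_aa + n_ab
    if n_a == 0 or n_a == 2 * n:
        return 1.0
    weights = _het_weights(n, n_a)
    total = sum(weights.values())
    w_obs = weights[n_ab]
    p = sum(w for w in weights.values() if w <= w_obs) / total
    return min(1.0, float(p))


@dataclass
class LdResult:
    testable: bool
    statistic: float = float("nan")
    p_value: float = float("nan")
    n_permutations: int = 0


def _g_statistic(g1: np.ndarray, g2: np.ndarray) -> float:
    """Log-likelihood G on the 3x3 genotype-pair contingency table."""
    counts = np.bincount(g1 * 3 + g2, minlength=9).reshape(3, 3).astype(float)
    total = counts.sum()
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    expected = row * col / total
    mask = counts > 0
    return float(2.0 * (counts[mask] * np.log(counts[mask] / expected[mask])).sum())


def ld_permutation_test(
    genotypes_1: np.ndarray | list,
    genotypes_2: np.ndarray | list,
    n_permutations: int = 999,
    seed: int = 0,
) -> LdResult:
    """Permutation test of genotypic association between two loci.

    The statistic is the log-likelihood G on the genotype-pair contingency
    table; the null is built by permuting one locus's genotypes across
    individuals.  p = (exceedances + 1) / (n_permutations + 1).  Pairs with
    a monomorphic locus (after removing incomplete pairs) are untestable.
    """
    g1 = np.asarray(genotypes_1, dtype=float)
    g2 = np.asarray(genotypes_2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("genotype vectors must have equal length")
    keep = ~(np.isnan(g1) | np.isnan(g2))
    g1 = g1[keep].astype(np.int64)
    g2 = g2[keep].astype(np.int64)
    if g1.size < 2 or len(np.unique(g1)) < 2 or len(np.unique(g2)) < 2:
        return LdResult(testable=False)
    obs = _g_statistic(g1, g2)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        if _g_statistic(g1, rng.permutation(g2)) >= obs:
            exceed += 1
    return LdResult(
        testable=True,
        statistic=obs,
        p_value=(exceed + 1) / (n_permutations + 1),
        n_permutations=n_permutations,
    )


def holm_correction(p_values, alpha: float = 0.05) -> np.ndarray:
    """Holm's step-down (sequential Bonferroni) reject decisions.

    Sorted p-values are rejected while p_(i) <= alpha / (m - i + 1); the
    first failure stops the sequence.  Returns a boolean array aligned with
    the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    reject = np.zeros(m, dtype=bool)
    order = np.argsort(p, kind="stable")
    for i, idx in enumerate(order):
        if p[idx] <= alpha / (m - i):
            reject[idx] = True
        else:
            break
    return reject


def apparent_fixation_probability(q: float, n: int) -> float:
    """Probability a pool of n diploids samples only one allele.

    Closed form (1-q)^(2n) + q^(2n): the chance that all 2n chromosomes in
    the pool carry the same allele although the population is polymorphic at
    frequency q - the small-pool ascertainment bias behind inflated
    fixed-site counts.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    return (1.0 - q) ** (2 * n) + q ** (2 * n)


def simulate_apparent_fixation(
    q: float,
    n: int,
    n_sites: int = 10_000,
    seed: int = 0,
    depth: int | None = None,
    min_coverage: int = 8,
    min_variant_freq: float = 0.10,
    min_reads_per_allele: int = 2,
) -> float:
    """Monte-Carlo apparent-fixation rate for a pool of n diploids.

    With ``depth`` None this samples chromosomes only and converges to the
    closed form.  With a read depth it additionally passes each site through
    the pooled-calling thresholds: a site "appears fixed" when the read
    sample fails to reveal both alleles at callable levels.  Convergence to
    the closed form as depth grows requires 1/(2n) >= ``min_variant_freq``.
    """
    rng = np.random.default_rng(seed)
    alt = rng.binomial(2 * n, q, size=n_sites)
    if depth is None:
        return float(np.mean((alt == 0) | (alt == 2 * n)))
    alt_reads = rng.binomial(depth, alt / (2 * n))
    ref_reads = depth - alt_reads
    callable_site = (
        (depth >= min_coverage)
        & (alt_reads >= min_reads_per_allele)
        & (ref_reads >= min_reads_per_allele)
        & (alt_reads / depth >= min_variant_freq)
        & (ref_reads / depth >= min_variant_freq)
    )
    return float(np.mean(~callable_site))


# ---------------------------------------------------------------------------
# panel-level reporting

def read_genotype_panel(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_genotype_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, sep="\t", index=False)


def panel_statistics(
    panel: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-locus, per-group Ho/He and exact HWE p, with Holm correction
    applied across all testable HWE p-values (one family, as a panel-wide
    type-I error control)."""
    rows = []
    for (locus, site, elev), grp in panel.groupby(["locus", "site", "elevation"]):
        g = grp["genotype"].to_numpy(dtype=float)
        ho, he = locus_heterozygosity(g)
        g_ok = g[~np.isnan(g)].astype(int)
        counts = np.bincount(g_ok, minlength=3)
        p_hwe = hwe_exact_test(int(counts[0]), int(counts[1]), int(counts[2]))
        rows.append(
            {
                "locus": locus,
                "site": site,
                "elevation": elev,
                "n": int(g_ok.size),
                "Ho": round(ho, 4),
                "He": round(he, 4),
                "monomorphic": bool(counts[1] == 0 and (counts[0] == 0 or counts[2] == 0)),
                "hwe_p": p_hwe,
            }
        )
    stats = pd.DataFrame(rows)
    testable = ~stats["monomorphic"]
    reject = np.zeros(len(stats), dtype=bool)
    if testable.any():
        reject[testable.to_numpy()] = holm_correction(
            stats.loc[testable, "hwe_p"].to_numpy(), alpha=alpha
        )
    stats["hwe_reject_holm"] = reject
    return stats
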