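"""Synthetic two-pool transcriptome data with known ground truth.

Emulates the study design the pipeline targets: two population pools of
three diploid individuals each (a "high" and a "low" elevation pool), whose
RNA is sequenced as pooled single-end reads.  Every generator takes an
explicit seed and is bit-reproducible.  A :class:`TruthTable` records the
population allele frequencies, the realized chromosome counts in each
2n = 6 pool sample, and every individual genotype, so downstream stages can
be scored against ground truth.

Reads are single-end with uniform start positions and lengths clipped at
transcript ends.  Only substitution errors are modelled (no homopolymer
indels) because the downstream caller handles substitutions only; correct
bases get a fixed high quality and error bases a low-to-mid quality drawn
uniformly, so the caller's quality filter is exercised in both directions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .reads import BASES, MAX_PHRED, QualityRead, decode_seq, encode_seq

POOLS = ("high", "low")

FreqSampler = Callable[[np.random.Generator], tuple[float, float]]


@dataclass
class RegimeMix:
    """Per-site allele-frequency sampler over the three cross-pool regimes.

    ``both_polymorphic``: alt frequency drawn Uniform(0,1) independently in
    each pool; ``one_fixed``: one pool fixed (alt frequency 0 or 1), the
    other Uniform(0,1); ``fixed_different``: the pools are fixed for
    alternate alleles.  Weights must sum to 1.
    """

    both_polymorphic: float = 0.70
    one_fixed: float = 0.25
    fixed_different: float = 0.05

    def __post_init__(self) -> None:
        w = (self.both_polymorphic, self.one_fixed, self.fixed_different)
        if any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("regime weights must be non-negative and sum to 1")

    def __call__(self, rng: np.random.Generator) -> tuple[float, float]:
        u = rng.random()
        if u < self.both_polymorphic:
            return float(rng.random()), float(rng.random())
        if u < self.both_polymorphic + self.one_fixed:
            fixed_val = float(rng.integers(2))
            other = float(rng.random())
            if rng.integers(2):
                return fixed_val, other
            return other, fixed_val
        if rng.integers(2):
            return 1.0, 0.0
        return 0.0, 1.0


@dataclass
class PopulationModel:
    """Two pools of diploid individuals and the variable-site model."""

    n_individuals_per_pool: int = 3
    variable_site_density: float = 0.003  # sites per base
    allele_freq_spec: FreqSampler = field(default_factory=RegimeMix)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals_per_pool < 1:
            raise ValueError("n_individuals_per_pool must be >= 1")
        if self.variable_site_density <= 0:
            raise ValueError("variable_site_density must be > 0")

    def to_json(self) -> str:
        spec = self.allele_freq_spec
        d = {
            "n_individuals_per_pool": self.n_individuals_per_pool,
            "variable_site_density": self.variable_site_density,
            "seed": self.seed,
        }
        if isinstance(spec, RegimeMix):
            d["regime_mix"] = {
                "both_polymorphic": spec.both_polymorphic,
                "one_fixed": spec.one_fixed,
                "fixed_different": spec.fixed_different,
            }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PopulationModel":
        d = json.loads(text)
        mix = d.pop("regime_mix", None)
        spec = RegimeMix(**mix) if mix else RegimeMix()
        return cls(allele_freq_spec=spec, **d)


@dataclass
class QualityProfile:
    """Phred quality assigned to correct vs erroneous simulated bases."""

    correct_q: int = 30
    error_q_low: int = 10
    error_q_high: int = 30  # inclusive

    def __post_init__(self) -> None:
        for q in (self.correct_q, self.error_q_low, self.error_q_high):
            if not 0 <= q <= MAX_PHRED:
                raise ValueError(f"phred quality {q} outside 0..{MAX_PHRED}")
        if self.error_q_low > self.error_q_high:
            raise ValueError("error_q_low must be <= error_q_high")


@dataclass
class SequencingModel:
    """Pooled single-end sequencing: depth, read lengths, substitution errors."""

    mean_depth_per_pool: float = 30.0
    mean_read_length: float = 260.0
    sd_read_length: float = 60.0
    substitution_error_rate: float = 0.002
    quality_profile: QualityProfile = field(default_factory=QualityProfile)
    min_read_length: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth_per_pool <= 0:
            raise ValueError("mean_depth_per_pool must be > 0")
        if not 0.0 <= self.substitution_error_rate < 1.0:
            raise ValueError("substitution_error_rate must be in [0, 1)")
        if self.mean_read_length < self.min_read_length:
            raise ValueError("mean_read_length below min_read_length")

    def to_json(self) -> str:
        qp = self.quality_profile
        return json.dumps(
            {
                "mean_depth_per_pool": self.mean_depth_per_pool,
                "mean_read_length": self.mean_read_length,
                "sd_read_length": self.sd_read_length,
                "substitution_error_rate": self.substitution_error_rate,
                "min_read_length": self.min_read_length,
                "seed": self.seed,
                "quality_profile": {
                    "correct_q": qp.correct_q,
                    "error_q_low": qp.error_q_low,
                    "error_q_high": qp.error_q_high,
                },
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SequencingModel":
        d = json.loads(text)
        qp = d.pop("quality_profile", None)
        profile = QualityProfile(**qp) if qp else QualityProfile()
        return cls(quality_profile=profile, **d)


@dataclass
class TruthTable:
    """Ground truth for one simulated dataset.

    ``sites`` has one row per variable site with 0-based positions, true
    per-pool alt-allele frequencies, realized alt chromosome counts out of
    2n per pool, and the per-individual genotypes (0/1/2 alt-allele dosage).
    ``haplotype_variants`` maps (pool, individual, copy) -> contig ->
    array of (position, alt base index) substitutions carried by that
    chromosome.
    """

    reference: dict[str, str]
    sites: pd.DataFrame
    haplotype_variants: dict[tuple[str, int, int], dict[str, np.ndarray]]
    n_individuals_per_pool: int

    @property
    def n_chromosomes(self) -> int:
        return 2 * self.n_individuals_per_pool

    def haplotype_seq(self, pool: str, individual: int, copy: int, contig: str) -> np.ndarray:
        """Encoded haplotype sequence for one chromosome of one individual."""
        arr = encode_seq(self.reference[contig])
        variants = self.haplotype_variants[(pool, individual, copy)].get(contig)
        if variants is not None and variants.size:
            arr[variants[:, 0]] = variants[:, 1]
        return arr

    def to_tsv(self, path: str | Path) -> None:
        out = self.sites.copy()
        out["position"] = out["position"] + 1  # 1-based in emitted tables
        out.to_csv(path, sep="\t", index=False)

    @staticmethod
    def realized_freq(alt_count: int, n_individuals: int) -> float:
        return alt_count / (2 * n_individuals)


def generate_reference(
    n_transcripts: int,
    mean_length: float,
    sd_length: float = 0.0,
    seed: int = 0,
    min_length: int = 100,
    name_prefix: str = "tx",
) -> dict[str, str]:
    """Random transcript-like reference contigs over {A,C,G,T}.

    Lengths are drawn from a normal distribution (degenerate when
    ``sd_length`` is 0) and floored at ``min_length``.
    """
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    if mean_length < 1:
        raise ValueError("mean_length must be >= 1")
    rng = np.random.default_rng(seed)
    width = len(str(n_transcripts))
    ref: dict[str, str] = {}
    for i in range(n_transcripts):
        if sd_length > 0:
            length = int(round(rng.normal(mean_length, sd_length)))
        else:
            length = int(round(mean_length))
        length = max(min_length, length)
        seq = rng.integers(0, 4, size=length).astype(np.uint8)
        ref[f"{name_prefix}{i + 1:0{width}d}"] = decode_seq(seq)
    return ref


def simulate_pool_genotypes(model: PopulationModel, reference: dict[str, str]) -> TruthTable:
    """Place variable sites on the reference and draw diploid genotypes.

    Each site gets ``n_individuals_per_pool`` diploid genotypes per pool,
    drawn Binomial(2, f) from the pool's true alt frequency; the truth table
    records the realized chromosome counts the pooled reads will sample.
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    rng = np.random.default_rng(model.seed)
    n = model.n_individuals_per_pool
    hap_keys = [(pool, ind, copy) for pool in POOLS for ind in range(n) for copy in range(2)]
    hap_vars: dict[tuple[str, int, int], dict[str, list[list[int]]]] = {
        k: {} for k in hap_keys
    }
    rows = []
    for contig, seq in reference.items():
        length = len(seq)
        positions = np.flatnonzero(rng.random(length) < model.variable_site_density)
        ref_arr = encode_seq(seq)
        for pos in positions:
            ref_base = int(ref_arr[pos])
            alt_base = int((ref_base + 1 + rng.integers(3)) % 4)
            f_high, f_low = model.allele_freq_spec(rng)
            if not (0.0 <= f_high <= 1.0 and 0.0 <= f_low <= 1.0):
                raise ValueError("allele frequencies must be in [0, 1]")
            row = {
                "contig": contig,
                "position": int(pos),
                "ref_allele": BASES[ref_base],
                "alt_allele": BASES[alt_base],
                "f_high_true": f_high,
                "f_low_true": f_low,
            }
            for pool, f in zip(POOLS, (f_high, f_low)):
                genotypes = rng.binomial(2, f, size=n)
                row[f"alt_count_{pool}"] = int(genotypes.sum())
                for ind, g in enumerate(genotypes):
                    row[f"gt_{pool}_{ind}"] = int(g)
                    if g == 2:
                        copies = (0, 1)
                    elif g == 1:
                        copies = (int(rng.integers(2)),)
                    else:
                        copies = ()
                    for copy in copies:
                        hap_vars[(pool, ind, copy)].setdefault(contig, []).append(
                            [int(pos), alt_base]
                        )
            rows.append(row)
    columns = [
        "contig", "position", "ref_allele", "alt_allele",
        "f_high_true", "f_low_true", "alt_count_high", "alt_count_low",
    ] + [f"gt_{pool}_{i}" for pool in POOLS for i in range(n)]
    sites = pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(columns=columns)
    packed = {
        k: {c: np.array(v, dtype=np.int64) for c, v in d.items()}
        for k, d in hap_vars.items()
    }
    return TruthTable(
        reference=dict(reference),
        sites=sites,
        haplotype_variants=packed,
        n_individuals_per_pool=n,
    )


def _simulate_pool(
    truth: TruthTable,
    seqmodel: SequencingModel,
    pool: str,
    rng: np.random.Generator,
) -> list[QualityRead]:
    contigs = list(truth.reference)
    lengths = np.array([len(truth.reference[c]) for c in contigs], dtype=float)
    total_len = lengths.sum()
    if total_len == 0:
        raise ValueError("zero-length reference")
    weights = lengths / total_len
    target_bases = seqmodel.mean_depth_per_pool * total_len
    n = truth.n_individuals_per_pool
    qp = seqmodel.quality_profile
    # encoded haplotypes, built lazily per (individual, copy, contig)
    hap_cache: dict[tuple[int, int, str], np.ndarray] = {}

    reads: list[QualityRead] = []
    emitted = 0
    serial = 0
    while emitted < target_bases:
        ci = int(rng.choice(len(contigs), p=weights))
        contig = contigs[ci]
        clen = int(lengths[ci])
        ind = int(rng.integers(n))
        copy = int(rng.integers(2))
        start = int(rng.integers(clen))
        rlen = int(round(rng.normal(seqmodel.mean_read_length, seqmodel.sd_read_length)))
        rlen = max(seqmodel.min_read_length, rlen)
        rlen = min(rlen, clen - start)  # clip at the transcript end
        if rlen < seqmodel.min_read_length:
            continue
        key = (ind, copy, contig)
        if key not in hap_cache:
            hap_cache[key] = truth.haplotype_seq(pool, ind, copy, contig)
        seq = hap_cache[key][start : start + rlen].copy()
        qual = np.full(rlen, qp.correct_q, dtype=np.uint8)
        if seqmodel.substitution_error_rate > 0:
            err_mask = rng.random(rlen) < seqmodel.substitution_error_rate
            n_err = int(err_mask.sum())
            if n_err:
                idx = np.flatnonzero(err_mask)
                seq[idx] = (seq[idx] + 1 + rng.integers(3, size=n_err)) % 4
                qual[idx] = rng.integers(qp.error_q_low, qp.error_q_high + 1, size=n_err)
        serial += 1
        name = f"{pool}:{contig}:{start + 1}:i{ind}c{copy}:{serial}"
        reads.append(QualityRead(name, decode_seq(seq), qual))
        emitted += rlen
    return reads


def simulate_pooled_reads(
    truth: TruthTable, seqmodel: SequencingModel
) -> dict[str, list[QualityRead]]:
    """Pooled single-end reads per pool; names carry pool/origin tags.

    Read names are ``pool:contig:start1:iIcC:serial`` (1-based start,
    individual I, chromosome copy C) so mapping results can be checked
    against the true origin.  Total emitted bases per pool hit
    ``mean_depth_per_pool * reference length`` to within one read.
    """
    if truth.sites is None or not truth.reference:
        raise ValueError("truth table with a non-empty reference required")
    seeds = np.random.SeedSequence(seqmodel.seed).spawn(2)
    return {
        pool: _simulate_pool(truth, seqmodel, pool, np.random.default_rng(s))
        for pool, s in zip(POOLS, seeds)
    }


def parse_read_origin(read_id: str) -> dict:
    """Invert the simulated read-name tag (pool, contig, 0-based start...)."""
    pool, contig, start1, indcopy, serial = read_id.split(":")
    ind, copy = indcopy[1:].split("c")
    return {
        "pool": pool,
        "contig": contig,
        "start": int(start1) - 1,
        "individual": int(ind),
        "copy": int(copy),
        "serial": int(serial),
    }


def simulate_genotype_panel(
    p: float | np.ndarray,
    n: int,
    inbreeding_f: float = 0.0,
    seed: int = 0,
    n_loci: int = 1,
    site: str = "BC",
    elevation: str = "high",
    locus_ids: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Biallelic genotypes for one group of individuals at one or more loci.

    Genotype probabilities follow the inbreeding model
    (p^2 + f p q, 2 p q (1 - f), q^2 + f p q) with ``p`` the frequency of the
    reference allele; genotypes are coded as alt-allele dosage 0/1/2.
    Returns a long-format frame (locus, individual, site, elevation, genotype).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= inbreeding_f <= 1.0:
        raise ValueError("inbreeding_f must be in [0, 1]")
    p_arr = np.broadcast_to(np.asarray(p, dtype=float), (n_loci,))
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("allele frequency p must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    if locus_ids is None:
        locus_ids = [f"locus{i + 1:02d}" for i in range(n_loci)]
    rows = []
    f = inbreeding_f
    for locus, pl in zip(locus_ids, p_arr):
        q = 1.0 - pl
        probs = np.array([pl * pl + f * pl * q, 2 * pl * q * (1 - f), q * q + f * pl * q])
        probs = probs / probs.sum()
        gts = rng.choice(3, size=n, p=probs)  # 0 = AA (ref hom), 1 = het, 2 = alt hom
        for ind, g in enumerate(gts):
            rows.append(
                {
                    "locus": locus,
                    "individual": f"{site}_{elevation}_{ind + 1:02d}",
                    "site": site,
                    "elevation": elevation,
                    "genotype": int(g),
                }
            )
    return pd.DataFrame(rows)


def simulate_validation_panel(
    seed: int = 0,
    n_loci: int = 17,
    divergence_floor: float = 0.5,
    group_sizes: dict[tuple[str, str], int] | None = None,
) -> pd.DataFrame:
    """A validation-style genotype panel: ~17 loci typed in four site groups.

    Mimics a panel ascertained for high cross-pool divergence: the two
    discovery-population groups get alt frequencies at least
    ``divergence_floor`` apart, while the independent population's
    frequencies are drawn around the discovery mean with extra fixation,
    emulating ascertainment-driven loss of polymorphism off-site.
    """
    if group_sizes is None:
        group_sizes = {
            ("BC", "high"): 10,
            ("BC", "low"): 11,
            ("Oregon", "high"): 11,
            ("Oregon", "low"): 10,
        }
    rng = np.random.default_rng(seed)
    locus_ids = [f"Ocp{i + 1:03d}" for i in range(n_loci)]
    frames = []
    for locus in locus_ids:
        lo = float(rng.uniform(0.0, 1.0 - divergence_floor))
        hi = float(rng.uniform(lo + divergence_floor, 1.0))
        if rng.integers(2):
            alt_bc = {"high": hi, "low": lo}
        else:
            alt_bc = {"high": lo, "low": hi}
        centre = (hi + lo) / 2.0
        alt_or = {}
        for elev in ("high", "low"):
            if rng.random() < 0.5:  # ascertainment: independent site often fixed
                alt_or[elev] = float(round(centre))
            else:
                alt_or[elev] = float(np.clip(rng.normal(centre, 0.2), 0.0, 1.0))
        for (site, elev), size in group_sizes.items():
            alt = alt_bc[elev] if site == "BC" else alt_or[elev]
            frames.append(
                simulate_genotype_panel(
                    p=1.0 - alt,
                    n=size,
                    n_loci=1,
                    site=site,
                    elevation=elev,
                    locus_ids=[locus],
                    rng=rng,
                )
            )
    return pd.concat(frames, ignore_index=True)
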