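"""The default synthetic benchmark and its parameter-recovery scoring.

One function simulates the study conditions (two pools of three diploids,
pooled single-end reads at 30x per pool over ~200 kb of transcript
reference, Q30 correct / Q10-30 error bases), runs the full discovery
pipeline, and scores the calls against the simulator's truth table:

* detection rate - a qualifying site is one whose realized 2n = 6
  chromosome sample is polymorphic with minor frequency >= 0.1 in at least
  one pool and whose pileup column has quality-passing depth >= the calling
  minimum in both pools; the site-level rate counts a qualifying site as
  detected when any qualifying pool calls it, and the stricter per
  (site, pool) rate requires each qualifying pool to call it;
* false-call rate - fraction of truth-invariant reference positions with
  adequate quality-passing depth in a pool that are nevertheless called
  polymorphic there.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import snps as snp_ops
from .mapping import MappingPolicy, ReferenceIndex, build_pileups, map_read_set
from .simulate import (
    POOLS,
    PopulationModel,
    SequencingModel,
    TruthTable,
    generate_reference,
    simulate_pool_genotypes,
    simulate_pooled_reads,
)
from .snps import CallingPolicy
from .trim import TrimPolicy, trim_read_set


@dataclass
class BenchmarkResult:
    truth: TruthTable
    merged: pd.DataFrame
    calls: dict[str, pd.DataFrame]
    metrics: dict


def run_default_benchmark(
    seed: int = 0,
    n_transcripts: int = 200,
    mean_length: float = 1000.0,
    sd_length: float = 150.0,
    mean_depth: float = 30.0,
    error_rate: float = 0.002,
    site_density: float = 0.003,
    trim_policy: TrimPolicy | None = None,
    mapping_policy: MappingPolicy | None = None,
    calling_policy: CallingPolicy | None = None,
) -> BenchmarkResult:
    """Simulate the default benchmark, run the pipeline, score recovery."""
    t0 = time.perf_counter()
    ss = np.random.SeedSequence(seed).spawn(3)
    trim_policy = trim_policy or TrimPolicy()
    mapping_policy = mapping_policy or MappingPolicy()
    calling_policy = calling_policy or CallingPolicy()

    reference = generate_reference(
        n_transcripts, mean_length, sd_length, seed=int(ss[0].generate_state(1)[0] % 2**31)
    )
    model = PopulationModel(
        variable_site_density=site_density,
        seed=int(ss[1].generate_state(1)[0] % 2**31),
    )
    truth = simulate_pool_genotypes(model, reference)
    seqmodel = SequencingModel(
        mean_depth_per_pool=mean_depth,
        substitution_error_rate=error_rate,
        seed=int(ss[2].generate_state(1)[0] % 2**31),
    )
    reads = simulate_pooled_reads(truth, seqmodel)

    trimmed = {}
    for pool in POOLS:
        trimmed[pool], _ = trim_read_set(reads[pool], trim_policy)

    index = ReferenceIndex(reference, seed_length=mapping_policy.seed_length)
    placements = []
    for pool in POOLS:
        p, _ = map_read_set(trimmed[pool], index, mapping_policy, pool)
        placements.extend(p)
    reads_by_id = {r.id: r for pool in POOLS for r in trimmed[pool]}
    pileup = build_pileups(placements, reads_by_id, reference)

    calls = {pool: snp_ops.call_group_snps(pileup, pool, calling_policy) for pool in POOLS}
    merged = snp_ops.merge_and_classify(calls["high"], calls["low"], pileup, calling_policy)

    # --- recovery scoring against the truth table -------------------------
    called_at = {
        pool: {(r.contig, r.position) for r in calls[pool].itertuples()} for pool in POOLS
    }
    truth_sites = {
        (r.contig, r.position) for r in truth.sites.itertuples()
    }
    two_n = truth.n_chromosomes
    qdepth = {}  # contig -> (2, L) quality-passing depth
    for contig in pileup.covered_contigs:
        qdepth[contig] = pileup.qpass_counts(contig, calling_policy.min_base_quality).sum(
            axis=-1
        )

    n_qualifying = 0
    n_detected = 0
    n_qualifying_sites = 0
    n_detected_sites = 0
    for r in truth.sites.itertuples():
        if r.contig not in qdepth:
            continue
        d = qdepth[r.contig][:, r.position]
        if (d < calling_policy.min_coverage).any():
            continue
        site_qualifies = False
        site_detected = False
        for pi, pool in enumerate(POOLS):
            alt = getattr(r, f"alt_count_{pool}")
            minor = min(alt, two_n - alt) / two_n
            if minor < 0.1 or alt in (0, two_n):
                continue
            n_qualifying += 1
            site_qualifies = True
            if (r.contig, r.position) in called_at[pool]:
                n_detected += 1
                site_detected = True
        if site_qualifies:
            n_qualifying_sites += 1
            if site_detected:
                n_detected_sites += 1

    n_invariant_assessed = 0
    n_false = 0
    for contig in pileup.covered_contigs:
        d = qdepth[contig]
        for pi, pool in enumerate(POOLS):
            assessed = np.flatnonzero(d[pi] >= calling_policy.min_coverage)
            for pos in assessed:
                if (contig, int(pos)) in truth_sites:
                    continue
                n_invariant_assessed += 1
                if (contig, int(pos)) in called_at[pool]:
                    n_false += 1

    cats = snp_ops.category_counts(merged)
    _, tstv = snp_ops.transition_transversion(merged)
    det = merged[(merged["status"] == "determined") & (merged["subst_class"] != "multiallelic")]
    elapsed = time.perf_counter() - t0
    metrics = {
        "n_truth_sites": int(len(truth.sites)),
        "n_qualifying_site_pools": n_qualifying,
        "n_detected_site_pools": n_detected,
        "detection_rate_site_pool": n_detected / n_qualifying if n_qualifying else float("nan"),
        "n_qualifying_sites": n_qualifying_sites,
        "n_detected_sites": n_detected_sites,
        "detection_rate": n_detected_sites / n_qualifying_sites
        if n_qualifying_sites
        else float("nan"),
        "n_invariant_assessed": n_invariant_assessed,
        "n_false_calls": n_false,
        "false_call_rate": n_false / n_invariant_assessed if n_invariant_assessed else 0.0,
        "categories": cats,
        "tstv_ratio": tstv,
        "mean_divergence": float(det["divergence"].mean()) if len(det) else float("nan"),
        "elapsed_seconds": elapsed,
    }
    return BenchmarkResult(truth=truth, merged=merged, calls=calls, metrics=metrics)
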