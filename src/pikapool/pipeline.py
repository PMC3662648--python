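"""End-to-end pipeline: trim -> map -> pileup -> contig filters -> call ->
merge/classify -> divergence & Ts/Tv -> candidate panel, with a summary
report whose every number is recomputable from the emitted per-stage TSVs."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import contigs as contig_ops
from . import snps as snp_ops
from .mapping import MappingPolicy, ReferenceIndex, build_pileups, map_read_set
from .reads import QualityRead, read_fasta, read_fastq
from .simulate import POOLS
from .snps import CallingPolicy
from .trim import TrimPolicy, summarize_read_set, trim_read_set

log = logging.getLogger("pikapool")


class PipelineInputError(ValueError):
    """Missing or malformed pipeline input (CLI exit code 2)."""


class PipelineInvariantError(RuntimeError):
    """Internal accounting violation (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    reads_high: str = ""
    reads_low: str = ""
    reference: str = ""
    outdir: str = "pikapool_out"
    trim: TrimPolicy = field(default_factory=TrimPolicy)
    mapping: MappingPolicy = field(default_factory=MappingPolicy)
    calling: CallingPolicy = field(default_factory=CallingPolicy)
    contig_min_length: int = 200
    contig_min_cov: float = 5.0
    panel_divergence: float = 0.50
    amplicon_length: int = 200
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=list)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        for key, typ in (("trim", TrimPolicy), ("mapping", MappingPolicy), ("calling", CallingPolicy)):
            if key in d and isinstance(d[key], dict):
                sub = d[key]
                if key == "trim" and "adapters" in sub:
                    sub["adapters"] = tuple(sub["adapters"])
                d[key] = typ(**sub)
        return cls(**d)


def run_pipeline(
    config: PipelineConfig,
    reads: dict[str, list[QualityRead]] | None = None,
    reference: dict[str, str] | None = None,
) -> dict:
    """Run all stages and write per-stage artifacts under ``config.outdir``.

    Inputs may be given as paths in the config or passed in memory (the
    analysis drivers do the latter).  Returns the summary report dict, also
    written as ``report.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if reference is None:
        if not config.reference:
            raise PipelineInputError("no reference FASTA given")
        if not Path(config.reference).exists():
            raise PipelineInputError(f"reference not found: {config.reference}")
        reference = read_fasta(config.reference)
    if not reference:
        raise PipelineInputError("reference FASTA contains no sequences")
    if reads is None:
        reads = {}
        for pool, path in (("high", config.reads_high), ("low", config.reads_low)):
            if not path:
                raise PipelineInputError(f"no {pool}-pool FASTQ given")
            if not Path(path).exists():
                raise PipelineInputError(f"{pool}-pool FASTQ not found: {path}")
            reads[pool] = read_fastq(path)
    for pool in POOLS:
        if not reads.get(pool):
            raise PipelineInputError(f"{pool}-pool read set is empty")

    (outdir / "config.json").write_text(config.to_json())

    # trim
    report: dict = {"stages": {}}
    trimmed: dict[str, list[QualityRead]] = {}
    read_rows = []
    for pool in POOLS:
        log.info("[trim] %s pool: %d reads in", pool, len(reads[pool]))
        kept, stats = trim_read_set(reads[pool], config.trim)
        trimmed[pool] = kept
        before = summarize_read_set(reads[pool])
        after = summarize_read_set(kept)
        read_rows.append(
            {
                "pool": pool,
                "n_reads_raw": before.n_reads,
                "n_bases_raw": before.n_bases,
                "mean_read_length_raw": round(before.mean_read_length, 2),
                "n_reads_trimmed": after.n_reads,
                "n_bases_trimmed": after.n_bases,
                "mean_read_length_trimmed": round(after.mean_read_length, 2)
                if after.n_reads
                else float("nan"),
                "n_discarded": stats["n_discarded"],
            }
        )
    read_summary = pd.DataFrame(read_rows)
    read_summary.to_csv(outdir / "read_summary.tsv", sep="\t", index=False)
    report["stages"]["trim"] = read_rows

    # map
    index = ReferenceIndex(reference, seed_length=config.mapping.seed_length)
    placements = []
    map_stats = []
    for pool in POOLS:
        log.info("[map] %s pool: mapping %d trimmed reads", pool, len(trimmed[pool]))
        p, stats = map_read_set(trimmed[pool], index, config.mapping, pool)
        placements.extend(p)
        map_stats.append(stats)
    report["stages"]["map"] = map_stats

    reads_by_id = {r.id: r for pool in POOLS for r in trimmed[pool]}
    pileup = build_pileups(placements, reads_by_id, reference)

    # contig filters
    summaries = contig_ops.summarize_contigs(pileup, placements)
    contig_ops.write_summary_tsv(summaries, outdir / "contig_summary.tsv")
    high_cov = contig_ops.filter_high_coverage(
        summaries, config.contig_min_length, config.contig_min_cov
    )
    unique = contig_ops.find_elevation_unique(
        summaries, config.contig_min_length, config.contig_min_cov
    )
    pd.DataFrame({"contig": high_cov}).to_csv(
        outdir / "high_coverage_contigs.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [(pool, c) for pool in POOLS for c in unique[pool]],
        columns=["pool", "contig"],
    ).to_csv(outdir / "elevation_unique_contigs.tsv", sep="\t", index=False)
    report["stages"]["contigs"] = {
        "n_contigs": len(summaries),
        "n_high_coverage": len(high_cov),
        "n_high_unique": len(unique["high"]),
        "n_low_unique": len(unique["low"]),
        "mean_length": round(float(summaries["length"].mean()), 2),
        "mean_cov_high": round(float(summaries["mean_cov_high"].mean()), 2),
        "mean_cov_low": round(float(summaries["mean_cov_low"].mean()), 2),
    }

    # call + merge
    calls = {
        pool: snp_ops.call_group_snps(pileup, pool, config.calling) for pool in POOLS
    }
    for pool in POOLS:
        out = calls[pool].copy()
        if len(out):
            out["position"] = out["position"] + 1
        out.to_csv(outdir / f"calls_{pool}.tsv", sep="\t", index=False)
    merged = snp_ops.merge_and_classify(calls["high"], calls["low"], pileup, config.calling)
    snp_ops.write_snp_tsv(merged, outdir / "snps.tsv")

    cats = snp_ops.category_counts(merged)
    if cats["a"] + cats["b"] + cats["c"] + cats["undetermined"] != cats["total"]:
        raise PipelineInvariantError("category counts do not partition the SNP table")
    _, tstv = snp_ops.transition_transversion(merged)
    det = merged[(merged["status"] == "determined") & (merged["subst_class"] != "multiallelic")]
    report["stages"]["snps"] = {
        "n_calls_high": int(len(calls["high"])),
        "n_calls_low": int(len(calls["low"])),
        "categories": cats,
        "tstv_ratio": round(tstv, 4) if tstv == tstv else None,
        "mean_divergence": round(float(det["divergence"].mean()), 4) if len(det) else None,
    }

    # candidate panel
    contig_lengths = {name: len(seq) for name, seq in reference.items()}
    panel = snp_ops.select_candidate_panel(
        merged,
        contig_lengths,
        divergence_threshold=config.panel_divergence,
        amplicon_length=config.amplicon_length,
    )
    snp_ops.write_snp_tsv(panel, outdir / "panel_candidates.tsv")
    report["stages"]["panel"] = {"n_candidates": int(len(panel))}

    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    log.info("[report] written to %s", outdir / "report.json")
    return report
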