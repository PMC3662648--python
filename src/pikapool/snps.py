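"""Per-pool SNP calling, cross-pool classification, and divergence scoring.

The caller applies the four pooled-sequencing thresholds (minimum coverage,
minimum variant frequency, minimum reads per allele, minimum base quality)
to each pileup column, separately per pool.  The two call tables are then
merged so each site is classified as

* ``a`` - polymorphic in both pools,
* ``b`` - polymorphic in one pool, fixed in the other (the fixed pool must
  itself have adequate depth and a single quality-passing allele, otherwise
  the site is ``undetermined`` rather than silently treated as fixed),
* ``c`` - fixed for alternate alleles in the two pools.

The divergence index D of a biallelic site is the absolute difference
between pools in the frequency of the major allele (major = most frequent
allele in the combined pools, ties broken lexicographically); D is 1 exactly
for category-c sites.  Frequencies use quality-passing reads only, matching
the calling denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mapping import PoolPileup
from .simulate import POOLS

_BASES = np.array(list("ACGT"))
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


@dataclass
class CallingPolicy:
    """Pooled SNP-calling thresholds."""

    min_coverage: int = 8
    min_variant_freq: float = 0.10
    min_reads_per_allele: int = 2
    min_base_quality: int = 20

    def __post_init__(self) -> None:
        if self.min_coverage < 1 or self.min_reads_per_allele < 1:
            raise ValueError("count thresholds must be positive")
        if not 0.0 < self.min_variant_freq < 1.0:
            raise ValueError("min_variant_freq must be in (0, 1)")
        if self.min_base_quality < 0:
            raise ValueError("min_base_quality must be >= 0")


def call_group_snps(
    pileup: PoolPileup, pool: str, policy: CallingPolicy
) -> pd.DataFrame:
    """Threshold-based SNP calls for one pool.

    A column yields a call iff its quality-passing depth reaches
    ``min_coverage`` and at least two alleles each have
    ``min_reads_per_allele`` quality-passing reads and frequency (over
    quality-passing depth) at least ``min_variant_freq``.  Reported allele
    frequencies are renormalised over the passing alleles.
    """
    pi = pileup.pool_index[pool]
    rows = []
    for contig in pileup.covered_contigs:
        qpass = pileup.qpass_counts(contig, policy.min_base_quality)[pi]  # (L, 4)
        depth = qpass.sum(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = qpass / depth[:, None]
        passing = (
            (qpass >= policy.min_reads_per_allele)
            & (freq >= policy.min_variant_freq)
            & (depth[:, None] >= policy.min_coverage)
        )
        called = np.flatnonzero(passing.sum(axis=-1) >= 2)
        for pos in called:
            allele_idx = np.flatnonzero(passing[pos])
            counts = qpass[pos, allele_idx]
            total = counts.sum()
            rows.append(
                {
                    "contig": contig,
                    "position": int(pos),
                    "depth": int(depth[pos]),
                    "alleles": ",".join(_BASES[allele_idx]),
                    "counts": ",".join(str(int(c)) for c in counts),
                    "freqs": ",".join(f"{c / total:.6g}" for c in counts),
                }
            )
    return pd.DataFrame(
        rows, columns=["contig", "position", "depth", "alleles", "counts", "freqs"]
    )


MERGED_COLUMNS = [
    "contig", "position", "status", "category", "alleles", "major_allele",
    "f_high_major", "f_low_major", "divergence", "subst_class",
    "depth_high", "depth_low",
]


def merge_and_classify(
    calls_high: pd.DataFrame,
    calls_low: pd.DataFrame,
    pileup: PoolPileup,
    policy: CallingPolicy,
) -> pd.DataFrame:
    """Merged cross-pool SNP table with category, divergence and Ts/Tv class.

    Sites called in exactly one pool are category ``b`` only when the other
    pool has quality-passing depth >= ``min_coverage`` and a single
    quality-passing allele; otherwise their status is ``undetermined`` (low
    coverage could hide variation).  Columns called in neither pool but
    monomorphic for different alleles at adequate depth in both pools are
    category ``c``.  Category counts plus undetermined always partition the
    merged table.
    """
    called = {
        "high": {(r.contig, r.position) for r in calls_high.itertuples()},
        "low": {(r.contig, r.position) for r in calls_low.itertuples()},
    }
    call_alleles: dict[tuple[str, int], dict[str, str]] = {}
    for pool, table in (("high", calls_high), ("low", calls_low)):
        for r in table.itertuples():
            call_alleles.setdefault((r.contig, r.position), {})[pool] = r.alleles

    rows = []
    for contig in pileup.covered_contigs:
        qpass = pileup.qpass_counts(contig, policy.min_base_quality)  # (2, L, 4)
        depth = qpass.sum(axis=-1)  # (2, L)
        n_alleles = (qpass > 0).sum(axis=-1)  # (2, L)
        consensus = qpass.argmax(axis=-1)  # (2, L)

        pos_called_any = sorted(
            {p for pool in POOLS for (c, p) in called[pool] if c == contig}
        )
        # candidate fixed-different columns: monomorphic at depth in both pools
        cmask = (
            (depth >= policy.min_coverage).all(axis=0)
            & (n_alleles == 1).all(axis=0)
            & (consensus[0] != consensus[1])
        )
        pos_c = [
            int(p) for p in np.flatnonzero(cmask) if (contig, int(p)) not in called["high"]
            and (contig, int(p)) not in called["low"]
        ]

        for pos in sorted(set(pos_called_any) | set(pos_c)):
            in_high = (contig, pos) in called["high"]
            in_low = (contig, pos) in called["low"]
            site_alleles: set[str] = set()
            for pool_alleles in call_alleles.get((contig, pos), {}).values():
                site_alleles.update(pool_alleles.split(","))
            status = "determined"
            if in_high and in_low:
                category = "a"
            elif in_high or in_low:
                other = 1 if in_high else 0
                if depth[other, pos] >= policy.min_coverage and n_alleles[other, pos] == 1:
                    category = "b"
                    site_alleles.add(str(_BASES[consensus[other, pos]]))
                else:
                    category = ""
                    status = "undetermined"
                    if depth[other, pos] > 0:
                        site_alleles.add(str(_BASES[consensus[other, pos]]))
            else:
                category = "c"
                site_alleles.update(
                    str(_BASES[consensus[k, pos]]) for k in range(2)
                )
            alleles = sorted(site_alleles)
            combined = qpass[0, pos] + qpass[1, pos]
            allele_idx = [("ACGT").index(a) for a in alleles]
            # major allele over combined pools, lexicographic tie-break
            major = alleles[int(np.argmax([combined[i] for i in allele_idx]))]
            mi = "ACGT".index(major)
            fh = qpass[0, pos, mi] / depth[0, pos] if depth[0, pos] else np.nan
            fl = qpass[1, pos, mi] / depth[1, pos] if depth[1, pos] else np.nan
            if len(alleles) == 2:
                subst = (
                    "transition" if frozenset(alleles) in _TRANSITIONS else "transversion"
                )
                d = abs(fh - fl) if status == "determined" else np.nan
            else:
                subst = "multiallelic"
                d = np.nan
            rows.append(
                {
                    "contig": contig,
                    "position": pos,
                    "status": status,
                    "category": category,
                    "alleles": ",".join(alleles),
                    "major_allele": major,
                    "f_high_major": float(fh),
                    "f_low_major": float(fl),
                    "divergence": float(d) if d == d else np.nan,
                    "subst_class": subst,
                    "depth_high": int(depth[0, pos]),
                    "depth_low": int(depth[1, pos]),
                }
            )
    return pd.DataFrame(rows, columns=MERGED_COLUMNS)


def divergence_index(record) -> float:
    """D = |f_high(major) - f_low(major)| for a determined biallelic site."""
    status = record["status"] if isinstance(record, (dict, pd.Series)) else record.status
    if status != "determined":
        raise ValueError("divergence index is defined for determined sites only")
    if isinstance(record, (dict, pd.Series)):
        alleles, fh, fl = record["alleles"], record["f_high_major"], record["f_low_major"]
    else:
        alleles, fh, fl = record.alleles, record.f_high_major, record.f_low_major
    if len(alleles.split(",")) != 2:
        raise ValueError("divergence index is defined for biallelic sites only")
    return abs(fh - fl)


def transition_transversion(records: pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-site Ts/Tv class and the aggregate transition/transversion ratio.

    Multiallelic sites are excluded; the ratio is NaN (flagged undefined)
    when there are no transversions.
    """
    classes = records["subst_class"]
    n_ts = int((classes == "transition").sum())
    n_tv = int((classes == "transversion").sum())
    ratio = n_ts / n_tv if n_tv else float("nan")
    return classes, ratio


def category_counts(records: pd.DataFrame) -> dict[str, int]:
    det = records[records["status"] == "determined"]
    return {
        "a": int((det["category"] == "a").sum()),
        "b": int((det["category"] == "b").sum()),
        "c": int((det["category"] == "c").sum()),
        "undetermined": int((records["status"] == "undetermined").sum()),
        "total": int(len(records)),
    }


def select_candidate_panel(
    records: pd.DataFrame,
    contig_lengths: dict[str, int],
    divergence_threshold: float = 0.50,
    amplicon_length: int = 200,
) -> pd.DataFrame:
    """High-divergence SNPs whose amplicon window holds no other SNP.

    A determined biallelic record qualifies when D >= the threshold and an
    ``amplicon_length`` window centred on the SNP fits inside the contig and
    contains no other merged SNP (of any status) - the single-SNP amplicon
    requirement of melt-based genotyping assays.
    """
    half = amplicon_length // 2
    positions_by_contig: dict[str, np.ndarray] = {
        contig: grp["position"].to_numpy()
        for contig, grp in records.groupby("contig")
    }
    selected = []
    for rec in records.itertuples():
        if rec.status != "determined" or rec.subst_class == "multiallelic":
            continue
        if not rec.divergence >= divergence_threshold:
            continue
        start = rec.position - half
        end = start + amplicon_length
        if start < 0 or end > contig_lengths[rec.contig]:
            continue
        others = positions_by_contig[rec.contig]
        in_window = (others >= start) & (others < end)
        if in_window.sum() != 1:  # the SNP itself is the only one allowed
            continue
        d = rec._asdict()
        d.pop("Index", None)
        d["window_start"] = start
        d["window_end"] = end
        selected.append(d)
    return pd.DataFrame(selected, columns=MERGED_COLUMNS + ["window_start", "window_end"])


def write_snp_tsv(records: pd.DataFrame, path: str | Path) -> None:
    out = records.copy()
    out["position"] = out["position"] + 1  # 1-based in emitted tables
    for col in ("window_start", "window_end"):
        if col in out.columns:
            out[col] = out[col] + 1
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_snp_tsv(path: str | Path) -> pd.DataFrame:
    records = pd.read_csv(
        path, sep="\t", dtype={"category": "string"}, keep_default_na=True
    )
    records["position"] = records["position"] - 1
    records["category"] = records["category"].fillna("")
    return records


def write_vcf(
    records: pd.DataFrame,
    references: dict[str, str],
    path: str | Path,
) -> None:
    """Minimal VCF export of merged biallelic records (per-pool major-allele
    frequencies as INFO fields)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pikapool\n")
        for name, seq in references.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##INFO=<ID=CAT,Number=1,Type=String,Description="Cross-pool category">\n')
        fh.write('##INFO=<ID=D,Number=1,Type=Float,Description="Divergence index">\n')
        fh.write('##INFO=<ID=FH,Number=1,Type=Float,Description="Major-allele freq, high pool">\n')
        fh.write('##INFO=<ID=FL,Number=1,Type=Float,Description="Major-allele freq, low pool">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in records.itertuples():
            alleles = rec.alleles.split(",")
            if len(alleles) != 2:
                continue
            ref_base = references[rec.contig][rec.position]
            alts = [a for a in alleles if a != ref_base] or [alleles[-1]]
            cat = rec.category or "undetermined"
            d = f"{rec.divergence:.4f}" if rec.divergence == rec.divergence else "."
            fh.write(
                f"{rec.contig}\t{rec.position + 1}\t.\t{ref_base}\t{','.join(alts)}\t.\t"
                f"PASS\tCAT={cat};D={d};FH={rec.f_high_major:.4f};FL={rec.f_low_major:.4f}\n"
            )
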