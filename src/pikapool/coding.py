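"""Synonymous/non-synonymous classification of substitutions between
aligned haplotypes of a coding region.

Built for mitochondrially encoded genes (e.g. the NADH dehydrogenase
subunit 5 comparison between elevation-associated haplotypes), so the
vertebrate mitochondrial code is the default: ATA -> Met, TGA -> Trp,
AGA/AGG -> Stop.  Codon translation goes through Biopython's codon tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

GENETIC_CODES = {
    "standard": 1,
    "vertebrate_mitochondrial": 2,
}

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


@dataclass
class CodingRegion:
    """A nucleotide sequence with reading frame and genetic code."""

    seq: str
    frame: int = 0
    code: str = "vertebrate_mitochondrial"

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("U", "T")
        if self.frame not in (0, 1, 2):
            raise ValueError("frame must be 0, 1 or 2")
        if self.code not in GENETIC_CODES:
            raise ValueError(f"unknown genetic code {self.code!r}")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence contains non-ACGTN symbols: {sorted(bad)}")

    @property
    def cds(self) -> str:
        return self.seq[self.frame :]

    def codons(self) -> list[str]:
        cds = self.cds
        if len(cds) % 3:
            raise ValueError(
                f"effective length {len(cds)} is not a multiple of 3 in frame {self.frame}"
            )
        return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def translate_codon(codon: str, code: str = "vertebrate_mitochondrial") -> str:
    """One-letter amino acid for a codon ('*' = stop, 'X' = ambiguous)."""
    table = CodonTable.unambiguous_dna_by_id[GENETIC_CODES[code]]
    if "N" in codon:
        return "X"
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


def translate_cds(region: CodingRegion) -> str:
    """Translate a coding region under its declared code.

    Codons containing N translate to X; an internal stop raises a warning
    (possible frame or assembly error) but is still reported as '*'.
    """
    aa = "".join(translate_codon(c, region.code) for c in region.codons())
    if "*" in aa[:-1]:
        warnings.warn(
            f"internal stop codon at codon {aa.index('*') + 1}; check the reading frame",
            stacklevel=2,
        )
    return aa


@dataclass
class SubstitutionRecord:
    """One mismatching nucleotide between two aligned haplotypes."""

    nt_position: int  # 0-based position in the input sequences
    codon_index: int  # 0-based codon number
    codon_a: str
    codon_b: str
    aa_a: str
    aa_b: str
    substitution_class: str  # synonymous | nonsynonymous
    tstv_class: str  # transition | transversion
    stop_gain: bool = False


def classify_codon_substitutions(
    hap_a: CodingRegion, hap_b: CodingRegion
) -> list[SubstitutionRecord]:
    """Per-site substitution records between two aligned haplotypes.

    Codons with multiple differences are evaluated as a whole-codon
    amino-acid comparison, each differing site inheriting the codon's
    class.  Stop-gain substitutions are flagged and counted as
    non-synonymous.
    """
    if len(hap_a.seq) != len(hap_b.seq):
        raise ValueError("haplotypes must be aligned to equal length")
    if hap_a.frame != hap_b.frame or hap_a.code != hap_b.code:
        raise ValueError("haplotypes must share frame and genetic code")
    codons_a = hap_a.codons()
    codons_b = hap_b.codons()
    records = []
    for ci, (ca, cb) in enumerate(zip(codons_a, codons_b)):
        if ca == cb:
            continue
        aa_a = translate_codon(ca, hap_a.code)
        aa_b = translate_codon(cb, hap_b.code)
        sub_class = "synonymous" if aa_a == aa_b else "nonsynonymous"
        stop_gain = ("*" in (aa_a, aa_b)) and aa_a != aa_b
        for k in range(3):
            if ca[k] == cb[k]:
                continue
            pair = frozenset((ca[k], cb[k]))
            tstv = "transition" if pair in _TRANSITIONS else "transversion"
            records.append(
                SubstitutionRecord(
                    nt_position=hap_a.frame + 3 * ci + k,
                    codon_index=ci,
                    codon_a=ca,
                    codon_b=cb,
                    aa_a=aa_a,
                    aa_b=aa_b,
                    substitution_class=sub_class,
                    tstv_class=tstv,
                    stop_gain=stop_gain,
                )
            )
    return records


def substitution_totals(records: list[SubstitutionRecord]) -> tuple[int, int]:
    """(n_sites, n_nonsynonymous) over a record list."""
    n_sites = len(records)
    n_nonsyn = sum(1 for r in records if r.substitution_class == "nonsynonymous")
    return n_sites, n_nonsyn


def records_to_frame(records: list[SubstitutionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "position": r.nt_position + 1,  # 1-based in emitted tables
                "codon_index": r.codon_index + 1,
                "codon_a": r.codon_a,
                "codon_b": r.codon_b,
                "aa_a": r.aa_a,
                "aa_b": r.aa_b,
                "class": r.substitution_class,
                "tstv": r.tstv_class,
                "stop_gain": r.stop_gain,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "position", "codon_index", "codon_a", "codon_b",
            "aa_a", "aa_b", "class", "tstv", "stop_gain",
        ],
    )


def write_substitution_tsv(records: list[SubstitutionRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)
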