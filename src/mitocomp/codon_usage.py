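"""Codon counts, amino-acid frequencies, and RSCU under the vertebrate
mitochondrial genetic code (NCBI table 2: ATA=Met, TGA=Trp, AGA/AGG=stop).

RSCU (relative synonymous codon usage) for codon j in a synonymous family
i of size n_i is the observed count scaled by the family mean:

    RSCU_ij = X_ij * n_i / sum_j X_ij

so a family used uniformly has RSCU 1 for every member.  Stop codons form
their own family: they enter the amino-acid frequency denominator but are
excluded from RSCU by default.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from Bio.Data import CodonTable

__all__ = ["CodonUsageTable", "VERTEBRATE_MITO", "codon_to_aa", "synonymous_families",
           "count_codons", "rscu", "amino_acid_frequencies"]

VERTEBRATE_MITO = CodonTable.unambiguous_dna_by_id[2]

ALL_CODONS = ["".join(p) for p in itertools.product("TCAG", repeat=3)]


def codon_to_aa(codon: str) -> str:
    """Amino acid (one-letter) for a codon; '*' for stops."""
    codon = codon.upper().replace("U", "T")
    if codon in VERTEBRATE_MITO.stop_codons:
        return "*"
    return VERTEBRATE_MITO.forward_table[codon]


def synonymous_families() -> dict[str, list[str]]:
    """Amino acid -> codon family (Leu is the 6-codon union; '*' = stops)."""
    fams: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        fams.setdefault(codon_to_aa(codon), []).append(codon)
    return fams


_FAMILIES = synonymous_families()


@dataclass
class CodonUsageTable:
    """Per-codon counts with optional RSCU; one table per sequence set."""

    counts: dict[str, int]
    n_codons: int
    n_skipped: int = 0  # codons containing N
    rscu: dict[str, float | None] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "codon": c,
                "aa": codon_to_aa(c),
                "count": self.counts.get(c, 0),
                "rscu": self.rscu.get(c),
            }
            for c in ALL_CODONS
        ]
        return pd.DataFrame(rows)


def count_codons(pcg_seqs: Iterable[str]) -> CodonUsageTable:
    """In-frame codon counts over coding-strand sequences.

    Each sequence is read from base 1; a trailing partial codon (the
    incomplete-stop case) is dropped; codons containing N are skipped and
    tallied in ``n_skipped``.
    """
    counts = {c: 0 for c in ALL_CODONS}
    n_skipped = 0
    for seq in pcg_seqs:
        s = seq.upper().replace("U", "T")
        if len(s) < 3:
            raise ValueError("coding sequence shorter than one codon")
        bad = set(s) - set("ACGTN")
        if bad:
            raise ValueError(f"unexpected characters in coding sequence: {sorted(bad)}")
        for i in range(0, len(s) - len(s) % 3, 3):
            codon = s[i : i + 3]
            if "N" in codon:
                n_skipped += 1
            else:
                counts[codon] += 1
    return CodonUsageTable(counts=counts, n_codons=sum(counts.values()), n_skipped=n_skipped)


def rscu(table: CodonUsageTable, include_stops: bool = False) -> CodonUsageTable:
    """Fill RSCU values in place and return the table.

    Families with zero total leave RSCU as None (undefined, not 0);
    unobserved codons inside an observed family get RSCU 0.
    """
    values: dict[str, float | None] = {}
    for aa, codons in _FAMILIES.items():
        if aa == "*" and not include_stops:
            for c in codons:
                values[c] = None
            continue
        total = sum(table.counts.get(c, 0) for c in codons)
        if total == 0:
            for c in codons:
                values[c] = None
            continue
        n_i = len(codons)
        for c in codons:
            values[c] = table.counts.get(c, 0) * n_i / total
    table.rscu = values
    return table


def amino_acid_frequencies(table: CodonUsageTable, include_stops: bool = True) -> pd.Series:
    """Per-amino-acid percentage of total codons.

    Stops ('*') are included in the denominator by default, consistent
    with reporting stop usage alongside residue frequencies.
    """
    totals: dict[str, int] = {}
    for aa, codons in _FAMILIES.items():
        if aa == "*" and not include_stops:
            continue
        totals[aa] = sum(table.counts.get(c, 0) for c in codons)
    denom = sum(totals.values())
    if denom == 0:
        warnings.warn("no codons counted; frequencies undefined", UserWarning)
        return pd.Series(dtype=float)
    return pd.Series({aa: 100.0 * n / denom for aa, n in totals.items()}).sort_values(
        ascending=False
    )
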