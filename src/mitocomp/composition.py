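"""Base composition, AT/GC strand skews, and start/stop codon classification.

Skews quantify strand compositional asymmetry:

    AT skew = (A - T) / (A + T)        GC skew = (G - C) / (G + C)

computed on full-precision counts; display rounding (half-up, 1 decimal
for percentages, 3 for skews) never propagates into downstream numbers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .model import MitogenomeRecord, extract_gene_sequence

__all__ = [
    "BaseComposition",
    "SkewPair",
    "CodonClassification",
    "CompositionError",
    "round_half_up",
    "base_composition",
    "skews",
    "classify_codons",
    "region_stats_table",
]

# legal complete stops under the vertebrate mitochondrial code
MITO_STOPS = ("TAA", "TAG", "AGA", "AGG")


class CompositionError(ValueError):
    pass


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero, as printed tables do."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BaseComposition:
    """Percentages of unambiguous bases; counts retained for full precision."""

    a: int
    t: int
    g: int
    c: int
    n_count: int = 0

    @property
    def total(self) -> int:
        return self.a + self.t + self.g + self.c

    @property
    def a_pct(self) -> float:
        return 100.0 * self.a / self.total

    @property
    def t_pct(self) -> float:
        return 100.0 * self.t / self.total

    @property
    def g_pct(self) -> float:
        return 100.0 * self.g / self.total

    @property
    def c_pct(self) -> float:
        return 100.0 * self.c / self.total

    @property
    def at_pct(self) -> float:
        return self.a_pct + self.t_pct

    @property
    def gc_pct(self) -> float:
        return self.g_pct + self.c_pct

    def rounded(self) -> dict[str, float]:
        """Display values: 1-decimal half-up percentages."""
        return {
            "a_pct": round_half_up(self.a_pct, 1),
            "t_pct": round_half_up(self.t_pct, 1),
            "g_pct": round_half_up(self.g_pct, 1),
            "c_pct": round_half_up(self.c_pct, 1),
            "at_pct": round_half_up(self.at_pct, 1),
            "gc_pct": round_half_up(self.gc_pct, 1),
        }

    @classmethod
    def from_percentages(cls, a: float, t: float, g: float, c: float,
                         scale: int = 10_000) -> "BaseComposition":
        """Build a composition from printed percentages (e.g. a published
        table row) by scaling to integer pseudo-counts."""
        return cls(
            a=round(a * scale), t=round(t * scale), g=round(g * scale), c=round(c * scale)
        )


@dataclass(frozen=True)
class SkewPair:
    at_skew: float | None
    gc_skew: float | None

    def rounded(self) -> dict[str, float | None]:
        return {
            "at_skew": None if self.at_skew is None else round_half_up(self.at_skew, 3),
            "gc_skew": None if self.gc_skew is None else round_half_up(self.gc_skew, 3),
        }


def base_composition(seq: str) -> BaseComposition:
    """Count A/T/G/C (case-insensitive); N excluded from the denominator."""
    if not seq:
        raise CompositionError("empty sequence has no composition")
    s = seq.upper()
    bad = set(s) - set("ACGTN")
    if bad:
        raise CompositionError(f"unexpected characters in sequence: {sorted(bad)}")
    comp = BaseComposition(
        a=s.count("A"), t=s.count("T"), g=s.count("G"), c=s.count("C"),
        n_count=s.count("N"),
    )
    if comp.total == 0:
        raise CompositionError("all-N sequence has undefined composition")
    if comp.n_count > 0.1 * len(s):
        warnings.warn(f"sequence is {100 * comp.n_count / len(s):.0f}% N", UserWarning)
    return comp


def skews(comp: BaseComposition) -> SkewPair:
    """AT and GC skew from full-precision counts; undefined skews are None."""
    at = comp.a + comp.t
    gc = comp.g + comp.c
    return SkewPair(
        at_skew=(comp.a - comp.t) / at if at > 0 else None,
        gc_skew=(comp.g - comp.c) / gc if gc > 0 else None,
    )


@dataclass(frozen=True)
class CodonClassification:
    start_codon: str
    stop_kind: str  # complete | TA_incomplete | T_incomplete
    stop_text: str  # e.g. "TAA", "TA-", "T--"


def classify_codons(gene_seq: str) -> CodonClassification:
    """Start codon and (possibly incomplete) stop of an annotated ORF.

    Genes whose length is not a codon multiple end in a truncated stop
    completed by mRNA polyadenylation: length mod 3 == 1 leaves a bare T
    ("T--"), mod 3 == 2 leaves TA ("TA-").
    """
    s = gene_seq.upper()
    if len(s) < 6:
        raise CompositionError("gene sequence shorter than two codons")
    start = s[:3]
    rem = len(s) % 3
    if rem == 0:
        stop = s[-3:]
        if stop not in MITO_STOPS:
            warnings.warn(f"terminal codon {stop} is not a mitochondrial stop", UserWarning)
        return CodonClassification(start, "complete", stop)
    if rem == 2:
        tail = s[-2:]
        if tail != "TA":
            warnings.warn(f"incomplete stop {tail!r} is not 'TA'", UserWarning)
        return CodonClassification(start, "TA_incomplete", f"{tail}-")
    tail = s[-1]
    if tail != "T":
        warnings.warn(f"incomplete stop {tail!r} is not 'T'", UserWarning)
    return CodonClassification(start, "T_incomplete", f"{tail}--")


def region_stats_table(record: MitogenomeRecord, rounding: str = "paper") -> pd.DataFrame:
    """Per-feature statistics table in genome order, plus a whole-genome row.

    Per-feature composition and skews are computed on the coding-strand
    sequence; the genome row uses the H strand.  Without a sequence only
    the coordinate-derived columns (size, intergenic) are filled.

    ``rounding``: "paper" rounds for display (1 dp percentages, 3 dp
    skews); "full" keeps full precision.
    """
    if rounding not in ("paper", "full"):
        raise ValueError("rounding must be 'paper' or 'full'")
    has_seq = record.sequence is not None
    rows = []
    feats = record.features
    for i, f in enumerate(feats):
        row: dict = {
            "locus": f.name,
            "strand": f.strand,
            "start": f.start,
            "end": f.end,
            "size_bp": f.size,
            "category": f.category,
            "anticodon": f.anticodon,
        }
        if i + 1 < len(feats):
            row["intergenic"] = feats[i + 1].start - f.end - 1
        else:
            row["intergenic"] = math.nan
        if has_seq:
            seq = extract_gene_sequence(record, f)
            _fill_seq_columns(row, seq, rounding)
            if f.category == "PCG":
                cls = classify_codons(seq)
                row["start_codon"] = cls.start_codon
                row["stop_codon"] = cls.stop_text
        rows.append(row)
    if has_seq:
        genome_row = {
            "locus": record.id or "genome",
            "strand": "H",
            "start": 1,
            "end": record.length,
            "size_bp": record.length,
            "category": "genome",
            "anticodon": None,
            "intergenic": math.nan,
        }
        _fill_seq_columns(genome_row, record.sequence, rounding)
        rows.append(genome_row)
    return pd.DataFrame(rows)


def _fill_seq_columns(row: dict, seq: str, rounding: str) -> None:
    comp = base_composition(seq)
    sk = skews(comp)
    if rounding == "paper":
        row.update(comp.rounded())
        row.update(sk.rounded())
    else:
        row.update(
            a_pct=comp.a_pct, t_pct=comp.t_pct, g_pct=comp.g_pct, c_pct=comp.c_pct,
            at_pct=comp.at_pct, gc_pct=comp.gc_pct,
            at_skew=sk.at_skew, gc_skew=sk.gc_skew,
        )
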