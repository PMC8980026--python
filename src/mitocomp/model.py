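"""Annotated circular mitogenome model.

A vertebrate mitogenome (~16-17 kb) carries 13 protein-coding genes, 22
tRNAs, 2 rRNAs and one control region (D-loop).  Features are stored with
1-based inclusive coordinates on the heavy (H) strand, matching GenBank
convention; light-strand (L) features keep H-strand coordinates and are
reverse-complemented only on sequence extraction.  Origin-spanning
features are not modelled (``circular`` is a reserved flag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

__all__ = [
    "GeneFeature",
    "MitogenomeRecord",
    "SpacerOverlap",
    "ValidationError",
    "AnnotationWarning",
    "reverse_complement",
    "read_annotation_table",
    "write_annotation_table",
    "read_genbank",
    "read_fasta",
    "write_fasta",
    "extract_gene_sequence",
    "spacers_and_overlaps",
]

CATEGORIES = ("PCG", "tRNA", "rRNA", "control_region")

# size sanity windows per feature class (bp); violations warn, never raise
_SIZE_RANGES = {"tRNA": (60, 100), "rRNA": (900, 1800)}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMacgtnryswkm", "TGCANYRSWMKtgcanyrswmk")


class ValidationError(ValueError):
    """Raised for coordinate or consistency violations in annotations."""


class AnnotationWarning(UserWarning):
    """Non-fatal oddities found while reading or validating annotations."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated locus with 1-based inclusive coordinates."""

    name: str
    strand: str
    start: int
    end: int
    category: str = "PCG"
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("H", "L"):
            raise ValidationError(f"{self.name}: strand must be 'H' or 'L', got {self.strand!r}")
        if self.start < 1:
            raise ValidationError(f"{self.name}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(
                f"{self.name}: end ({self.end}) < start ({self.start}); "
                "wrap-around features are not supported"
            )
        if self.category not in CATEGORIES:
            raise ValidationError(f"{self.name}: unknown category {self.category!r}")
        lo_hi = _SIZE_RANGES.get(self.category)
        if lo_hi and not (lo_hi[0] <= self.size <= lo_hi[1]):
            warnings.warn(
                f"{self.name}: {self.category} size {self.size} bp outside "
                f"expected range {lo_hi[0]}-{lo_hi[1]} bp",
                AnnotationWarning,
                stacklevel=2,
            )

    @property
    def size(self) -> int:
        """Feature length in bp (end - start + 1)."""
        return self.end - self.start + 1


@dataclass
class MitogenomeRecord:
    """A (possibly sequence-less) annotated mitogenome."""

    id: str
    length: int
    features: list[GeneFeature] = field(default_factory=list)
    sequence: str | None = None
    circular: bool = True

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.length:
                raise ValidationError(
                    f"{self.id}: sequence length {len(self.sequence)} != "
                    f"declared length {self.length}"
                )
        for f in self.features:
            if f.end > self.length:
                raise ValidationError(
                    f"{self.id}: feature {f.name} extends past genome length {self.length}"
                )
        if any(
            a.start > b.start for a, b in zip(self.features, self.features[1:])
        ):
            warnings.warn(
                f"{self.id}: features not sorted by start; sorting", AnnotationWarning,
                stacklevel=2,
            )
            self.features.sort(key=lambda f: (f.start, f.end))

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def features_by_category(self, category: str) -> list[GeneFeature]:
        return [f for f in self.features if f.category == category]


@dataclass(frozen=True)
class SpacerOverlap:
    """Adjacency relation between two consecutive features in genome order."""

    upstream: str
    downstream: str
    kind: str  # spacer | overlap | adjacent
    length: int

    def __post_init__(self) -> None:
        if (self.length == 0) != (self.kind == "adjacent"):
            raise ValidationError(
                f"{self.upstream}/{self.downstream}: length {self.length} "
                f"inconsistent with kind {self.kind!r}"
            )


def infer_category(name: str) -> str:
    low = name.lower()
    if low.startswith("trna") or low.startswith("trn"):
        return "tRNA"
    if "rrna" in low or low in ("12s", "16s"):
        return "rRNA"
    if "loop" in low or "control" in low or low in ("cr", "d-loop", "dloop"):
        return "control_region"
    return "PCG"


def read_annotation_table(path: str | Path, id: str | None = None) -> MitogenomeRecord:
    """Read a tab-separated annotation table into a validated record.

    Requires columns ``locus``, ``strand``, ``start``, ``end``; honours
    optional ``category``, ``anticodon`` and cross-checks an optional
    ``size`` column against end - start + 1 (mismatch warns, the
    coordinates win).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:  # noqa: BLE001 - surface as parse error
        raise ValidationError(f"{path}: cannot parse annotation table: {exc}") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"locus", "strand", "start", "end"}
    if missing := required - set(df.columns):
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")

    features = []
    for i, row in df.iterrows():
        lineno = i + 2  # header is line 1
        try:
            start, end = int(row["start"]), int(row["end"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"{path}: line {lineno}: malformed coordinate "
                f"({row['start']!r}, {row['end']!r})"
            ) from exc
        name = str(row["locus"]).strip()
        category = _cell(row, "category") or infer_category(name)
        feat = GeneFeature(
            name=name,
            strand=str(row["strand"]).strip(),
            start=start,
            end=end,
            category=category,
            anticodon=_cell(row, "anticodon"),
        )
        declared = _cell(row, "size")
        if declared is not None and int(declared) != feat.size:
            warnings.warn(
                f"{path}: line {lineno}: declared size {declared} != "
                f"computed {feat.size} for {name}; keeping coordinates",
                AnnotationWarning,
                stacklevel=2,
            )
        features.append(feat)

    features.sort(key=lambda f: (f.start, f.end))
    length = max((f.end for f in features), default=0)
    return MitogenomeRecord(id=id or path.stem, length=length, features=features)


def _cell(row: pd.Series, key: str) -> str | None:
    if key not in row or pd.isna(row[key]):
        return None
    val = str(row[key]).strip()
    return val if val not in ("", ".") else None


def write_annotation_table(record: MitogenomeRecord, path: str | Path) -> None:
    rows = [
        {
            "locus": f.name,
            "strand": f.strand,
            "start": f.start,
            "end": f.end,
            "category": f.category,
            "anticodon": f.anticodon or ".",
        }
        for f in record.features
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genbank(path: str | Path) -> MitogenomeRecord:
    """Read an annotated mitogenome from a GenBank flat file."""
    from Bio import SeqIO

    rec = SeqIO.read(str(path), "genbank")
    wanted = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA", "D-loop": "control_region"}
    features = []
    for f in rec.features:
        if f.type not in wanted:
            continue
        quals = f.qualifiers
        name = (quals.get("gene") or quals.get("product") or [f.type])[0]
        anticodon = None
        if f.type == "tRNA" and "anticodon" in quals:
            anticodon = quals["anticodon"][0]
        features.append(
            GeneFeature(
                name=name,
                strand="L" if f.location.strand == -1 else "H",
                start=int(f.location.start) + 1,  # Biopython is 0-based half-open
                end=int(f.location.end),
                category=wanted[f.type],
                anticodon=anticodon,
            )
        )
    if not features:
        warnings.warn(f"{path}: GenBank record has no usable features", AnnotationWarning)
    features.sort(key=lambda f: (f.start, f.end))
    sequence = str(rec.seq).upper() if len(rec.seq) else None
    length = len(rec.seq) if sequence else max((f.end for f in features), default=0)
    return MitogenomeRecord(id=rec.id, length=length, features=features, sequence=sequence)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def attach_sequence(record: MitogenomeRecord, sequence: str) -> MitogenomeRecord:
    """Return a copy of *record* carrying *sequence* (validated)."""
    return MitogenomeRecord(
        id=record.id,
        length=len(sequence),
        features=list(record.features),
        sequence=sequence,
        circular=record.circular,
    )


def extract_gene_sequence(record: MitogenomeRecord, feature: GeneFeature | str) -> str:
    """Coding-strand sequence of a feature.

    H-strand features are sliced directly; L-strand features are returned
    as the reverse complement of the H-strand slice.
    """
    if isinstance(feature, str):
        feature = record.feature(feature)
    if record.sequence is None:
        raise ValidationError(f"{record.id}: record carries no sequence")
    if feature.end > record.length:
        raise ValidationError(f"{feature.name}: out of bounds for length {record.length}")
    sub = record.sequence[feature.start - 1 : feature.end]
    return reverse_complement(sub) if feature.strand == "L" else sub


def spacers_and_overlaps(
    record: MitogenomeRecord, across_origin: bool = False
) -> list[SpacerOverlap]:
    """Classify every consecutive feature pair as spacer/overlap/adjacent.

    Adjacency follows genome (H-strand) order and ignores strand: the
    printed annotation tables report a single intergenic column.  With
    ``across_origin`` the last-to-first pair of the circle is included.
    """
    feats = sorted(record.features, key=lambda f: (f.start, f.end))
    if feats != record.features:
        warnings.warn(f"{record.id}: features re-sorted for adjacency", AnnotationWarning)
    if len(feats) < 2:
        raise ValidationError("need at least two features")
    pairs = list(zip(feats, feats[1:]))
    out = []
    for up, down in pairs:
        gap = down.start - up.end - 1
        if gap > 0:
            out.append(SpacerOverlap(up.name, down.name, "spacer", gap))
        elif gap < 0:
            out.append(SpacerOverlap(up.name, down.name, "overlap", -gap))
        else:
            out.append(SpacerOverlap(up.name, down.name, "adjacent", 0))
    if across_origin and record.circular:
        up, down = feats[-1], feats[0]
        gap = (record.length - up.end) + (down.start - 1)
        kind = "spacer" if gap > 0 else "adjacent"
        out.append(SpacerOverlap(up.name, down.name, kind, max(gap, 0)))
    return out
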