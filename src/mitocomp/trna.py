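"""Cloverleaf tRNA structure analysis: stem/loop partition from dot-bracket
notation, base-pair classification (Watson-Crick / G-U wobble / named
mismatch), per-site pairing frequencies on a canonical 25-site map,
per-stem wobble tallies, heavy- vs light-strand comparison, and the mTERF
tridecamer check on tRNA-Leu(TAA).

The four helices of a cloverleaf are assigned in 5'->3' order as the
amino-acid acceptor (AA) stem (the enclosing helix), DHU arm, anticodon
(AC) arm and T-psi-U arm; 3-helix structures (the tRNA-Ser(GCT) case,
which lacks a DHU stem) are accepted with ``dhu_present=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "CloverleafStructure",
    "PairClass",
    "StructureError",
    "partition_cloverleaf",
    "classify_pair",
    "canonical_site_map",
    "site_frequencies",
    "wobble_table",
    "strand_comparison",
    "mterf_site_check",
    "MTERF_TRIDECAMER",
]

MTERF_TRIDECAMER = "TGGCAGAGCCCGG"

STEM_NAMES = ("AA", "DHU", "AC", "TPsiU")

# canonical outermost pair per stem and number of canonical sites, anchored
# on the published 100%-bonded positions (1-87, 2-86, 8-80; 12-32; 40-48;
# 64-74); inner sites are filled by uniform inward interpolation.
_CANONICAL_ANCHORS = {"AA": (1, 87, 8), "DHU": (12, 32, 5), "AC": (38, 50, 6),
                      "TPsiU": (61, 77, 6)}


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class PairClass:
    category: str  # watson_crick | wobble_GU | mismatch
    mismatch_label: str | None = None


def classify_pair(b1: str, b2: str) -> PairClass:
    """Classify a base pair; T and U are equivalent; symmetric in arguments."""
    x, y = b1.upper().replace("U", "T"), b2.upper().replace("U", "T")
    if x not in "ACGT" or y not in "ACGT":
        raise ValueError(f"not nucleotide bases: {b1!r}, {b2!r}")
    pair = frozenset((x, y))
    if pair in (frozenset("AT"), frozenset("GC")):
        return PairClass("watson_crick")
    if pair == frozenset("GT"):
        return PairClass("wobble_GU")
    label = "-".join(sorted((x, y)))
    return PairClass("mismatch", mismatch_label=label)


@dataclass
class CloverleafStructure:
    """A tRNA sequence partitioned into cloverleaf stems and loops.

    ``stems`` maps stem name to an ordered (outermost-first) list of
    0-based (i, j) paired index pairs; ``loops`` maps loop name to a
    range of 0-based indices.
    """

    name: str
    sequence: str
    stems: dict[str, list[tuple[int, int]]]
    loops: dict[str, range]
    strand: str = "H"
    anticodon: str | None = None
    dhu_present: bool = True

    @property
    def n_pairs(self) -> int:
        return sum(len(v) for v in self.stems.values())

    def pair_bases(self, stem: str) -> list[tuple[str, str]]:
        return [(self.sequence[i], self.sequence[j]) for i, j in self.stems[stem]]


def _pair_table(dot_bracket: str) -> list[tuple[int, int]]:
    if set(dot_bracket) - set(".()"):
        raise StructureError(
            "only '.', '(' and ')' are supported (no pseudoknot notation)"
        )
    stack: list[int] = []
    pairs = []
    for i, ch in enumerate(dot_bracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {i}")
            pairs.append((stack.pop(), i))
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return sorted(pairs)


def _helices(pairs: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group pairs into maximal stacked runs (i+1, j-1)."""
    helices: list[list[tuple[int, int]]] = []
    for p in pairs:
        if helices and helices[-1][-1] == (p[0] - 1, p[1] + 1):
            helices[-1].append(p)
        else:
            helices.append([p])
    return helices


def _merge_bulges(helices: list[list[tuple[int, int]]]) -> list[list[tuple[int, int]]]:
    """Merge a helix with its unique nested child so a small internal bulge
    does not split one biological stem into two."""
    merged = True
    while merged:
        merged = False
        for h in helices:
            children = [
                c for c in helices
                if c is not h and h[-1][0] < c[0][0] and c[0][1] < h[-1][1]
                and not any(  # direct child: no intermediate helix encloses it
                    m is not h and m is not c
                    and m[-1][0] < c[0][0] and c[0][1] < m[-1][1]
                    and h[-1][0] < m[0][0] and m[0][1] < h[-1][1]
                    for m in helices
                )
            ]
            if len(children) == 1:
                h.extend(children[0])
                helices.remove(children[0])
                merged = True
                break
    return helices


def partition_cloverleaf(
    sequence: str,
    dot_bracket: str,
    name: str = "tRNA",
    strand: str = "H",
    anticodon_pos: int | None = None,
) -> CloverleafStructure:
    """Partition a tRNA into cloverleaf stems and loops.

    The enclosing helix is the AA stem; the 3 (or 2) inner helices are,
    5'->3', the DHU, AC and T-psi-U arms.  With 3 helices total the
    structure is DHU-less (``dhu_present=False``) and the first inner
    helix is the AC arm, cross-checked against ``anticodon_pos`` (0-based
    index expected near the middle of the AC loop) when given.
    """
    if len(sequence) != len(dot_bracket):
        raise StructureError("sequence and dot-bracket lengths differ")
    pairs = _pair_table(dot_bracket)
    if not pairs:
        raise StructureError("no base pairs: not a cloverleaf")
    helices = _merge_bulges(_helices(pairs))
    # enclosing helix: contains all the others
    span = (min(p[0] for p in pairs), max(p[1] for p in pairs))
    outer = [h for h in helices if h[0][0] == span[0] and h[0][1] == span[1]]
    inner = [h for h in helices if h not in outer]
    if not outer or len(helices) not in (3, 4):
        raise StructureError(
            f"{len(helices)} helices found; a cloverleaf has 4 (or 3 without a DHU arm)"
        )
    aa = sorted(outer[0])
    inner.sort(key=lambda h: h[0][0])
    dhu_present = len(inner) == 3
    if dhu_present:
        dhu, ac, tpu = inner
    else:
        dhu, (ac, tpu) = [], inner
    stems = {"AA": aa, "DHU": sorted(dhu), "AC": sorted(ac), "TPsiU": sorted(tpu)}

    loops: dict[str, range] = {}
    if dhu_present:
        loops["DHU_loop"] = range(stems["DHU"][-1][0] + 1, stems["DHU"][-1][1])
    else:
        # DHU-less tRNAs keep a small unpaired loop where the arm would be
        loops["DHU_loop"] = range(stems["AA"][-1][0] + 1, stems["AC"][0][0])
    loops["AC_loop"] = range(stems["AC"][-1][0] + 1, stems["AC"][-1][1])
    loops["TPsiU_loop"] = range(stems["TPsiU"][-1][0] + 1, stems["TPsiU"][-1][1])
    loops["V_loop"] = range(stems["AC"][0][1] + 1, stems["TPsiU"][0][0])
    if anticodon_pos is not None and anticodon_pos not in loops["AC_loop"]:
        raise StructureError(
            f"anticodon position {anticodon_pos} not inside the anticodon loop "
            f"{loops['AC_loop']}"
        )
    return CloverleafStructure(
        name=name, sequence=sequence.upper(), stems=stems, loops=loops,
        strand=strand, dhu_present=dhu_present,
    )


def canonical_site_map() -> dict[str, list[str]]:
    """Stem -> ordered canonical pair labels (outermost first), 25 in all."""
    out = {}
    for stem, (a5, a3, n) in _CANONICAL_ANCHORS.items():
        out[stem] = [f"{a5 + k}-{a3 - k}" for k in range(n)]
    return out


def site_frequencies(
    structs: Iterable[CloverleafStructure],
    site_map: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Per-canonical-site pairing class percentages across structures.

    Each structure's k-th (outermost-first) pair in a stem occupies the
    k-th canonical site of that stem; structures with shorter stems simply
    lack the innermost sites and drop out of those denominators.  Returns
    one row per site with % Watson-Crick, % wobble, % mismatch, % bonded
    (WC + wobble) and the count of contributing structures.
    """
    site_map = site_map or canonical_site_map()
    tallies: dict[str, dict[str, int]] = {
        s: {"watson_crick": 0, "wobble_GU": 0, "mismatch": 0}
        for labels in site_map.values() for s in labels
    }
    for st in structs:
        for stem, labels in site_map.items():
            for k, (b1, b2) in enumerate(st.pair_bases(stem)):
                if k >= len(labels):
                    break  # pairs beyond the canonical map are not tracked
                tallies[labels[k]][classify_pair(b1, b2).category] += 1
    rows = []
    for stem, labels in site_map.items():
        for label in labels:
            t = tallies[label]
            n = sum(t.values())
            row = {"stem": stem, "site": label, "n": n}
            if n:
                row["pct_watson_crick"] = 100.0 * t["watson_crick"] / n
                row["pct_wobble"] = 100.0 * t["wobble_GU"] / n
                row["pct_mismatch"] = 100.0 * t["mismatch"] / n
                row["pct_bonded"] = row["pct_watson_crick"] + row["pct_wobble"]
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class WobbleSummary:
    """Per-tRNA, per-stem wobble pair counts with strand-group averages."""

    table: pd.DataFrame  # one row per tRNA
    strand_means: pd.Series  # mean wobble % per strand group
    grand_average: float | None


def wobble_table(structs: Sequence[CloverleafStructure]) -> WobbleSummary:
    """Tally G-U wobble pairs per tRNA per stem.

    Structures sharing a name are pooled (the multi-species case); the
    wobble percentage denominator is the number of pairs actually present.
    """
    by_name: dict[str, list[CloverleafStructure]] = {}
    for st in structs:
        by_name.setdefault(st.name, []).append(st)
    rows = []
    for name, group in by_name.items():
        strands = {st.strand for st in group}
        if len(strands) > 1:
            raise ValueError(f"{name}: inconsistent strand labels {strands}")
        row: dict = {"trna": name, "strand": group[0].strand}
        total_pairs = total_wobble = 0
        for stem in STEM_NAMES:
            wob = sum(
                1
                for st in group
                for b1, b2 in st.pair_bases(stem)
                if classify_pair(b1, b2).category == "wobble_GU"
            )
            npairs = sum(len(st.stems[stem]) for st in group)
            row[f"wobble_{stem}"] = wob
            total_pairs += npairs
            total_wobble += wob
        row["total_wobble"] = total_wobble
        row["total_pairs"] = total_pairs
        row["pct_wobble"] = 100.0 * total_wobble / total_pairs if total_pairs else None
        rows.append(row)
    df = pd.DataFrame(rows)
    strand_means = df.groupby("strand")["pct_wobble"].mean()
    grand = float(df["pct_wobble"].mean()) if len(df) else None
    return WobbleSummary(table=df, strand_means=strand_means, grand_average=grand)


def strand_comparison(summary: WobbleSummary) -> tuple[float, float]:
    """Two-sided Mann-Whitney U on per-tRNA wobble percentages, H vs L.

    Returns (U statistic, p-value); exact p for small tie-free samples,
    normal approximation with tie correction otherwise (scipy's policy).
    """
    df = summary.table
    h = df.loc[df["strand"] == "H", "pct_wobble"].dropna()
    l = df.loc[df["strand"] == "L", "pct_wobble"].dropna()
    if len(h) < 3 or len(l) < 3:
        raise ValueError("need at least 3 tRNAs per strand group")
    res = stats.mannwhitneyu(h, l, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class MterfHit:
    offset: int  # 0-based start of the match
    n_mismatches: int
    mismatch_positions: tuple[int, ...]  # 0-based within the motif


def mterf_site_check(
    trna_leu_seq: str, motif: str = MTERF_TRIDECAMER, max_mismatches: int = 0
) -> MterfHit | None:
    """Locate the mTERF-binding tridecamer in a tRNA-Leu(TAA) gene region.

    Sliding Hamming search; returns the best (fewest-mismatch, leftmost)
    window within ``max_mismatches``, or None.
    """
    seq, m = trna_leu_seq.upper(), motif.upper()
    best: MterfHit | None = None
    for off in range(len(seq) - len(m) + 1):
        mism = tuple(k for k in range(len(m)) if seq[off + k] != m[k])
        if len(mism) <= max_mismatches and (best is None or len(mism) < best.n_mismatches):
            best = MterfHit(offset=off, n_mismatches=len(mism), mismatch_positions=mism)
            if not mism:
                break
    return best
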