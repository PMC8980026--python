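"""Synthetic mitogenomes, tRNA structure sets, and control regions with
recorded ground truth.

The defaults emulate the study system: a 16,542 bp circular teleost
mitogenome laid out on the canonical 38-feature gene order (13 PCGs,
22 tRNAs, 2 rRNAs, D-loop; ND6 and 8 tRNAs light-strand encoded), with
whole-genome base probabilities A 0.275 / C 0.302 / T 0.254 / G 0.169,
tRNA sets of 14 heavy- and 8 light-strand genes with per-stem G-U wobble
probabilities 0.03 (H) vs 0.13 (L), and an 840 bp control region with the
six conserved sequence blocks planted in canonical order.

Every generated artefact comes with a ground-truth report; downstream
analyses must reproduce it exactly (counts, positions) or within binomial
sampling error (compositions).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np

from .control_region import MotifLibrary, default_motif_library, scan_motif
from .model import (
    GeneFeature,
    MitogenomeRecord,
    read_annotation_table,
    reverse_complement,
)

__all__ = [
    "GeneratorSpec",
    "TrnaGene",
    "drusselli_layout",
    "DEFAULT_BASE_PROBS",
    "generate_mitogenome",
    "generate_trna_set",
    "generate_control_region",
]

DEFAULT_BASE_PROBS = {"A": 0.275, "C": 0.302, "T": 0.254, "G": 0.169}

_STOPS = ("TAA", "TAG", "AGA", "AGG")

# Published stem-length windows (bp): AA 6-8, DHU 3-5, AC 5-6, TPsiU 4-6
DEFAULT_STEM_RANGES = {"AA": (6, 8), "DHU": (3, 5), "AC": (5, 6), "TPsiU": (4, 6)}
DEFAULT_LOOP_LENS = {"DHU": 8, "AC": 7, "V": 4, "TPsiU": 7}

_H_TRNAS = ["tRNA-Phe", "tRNA-Val", "tRNA-Leu(TAA)", "tRNA-Ile", "tRNA-Met",
            "tRNA-Trp", "tRNA-Asp", "tRNA-Lys", "tRNA-Gly", "tRNA-Arg",
            "tRNA-His", "tRNA-Ser(GCT)", "tRNA-Leu(TAG)", "tRNA-Thr"]
_L_TRNAS = ["tRNA-Gln", "tRNA-Ala", "tRNA-Asn", "tRNA-Cys", "tRNA-Tyr",
            "tRNA-Ser(TGA)", "tRNA-Glu", "tRNA-Pro"]


def drusselli_layout() -> MitogenomeRecord:
    """The canonical 38-feature annotation layout shipped with the package
    (coordinates, strands, anticodons and start/stop patterns of the
    Indian scad worked example)."""
    ref = importlib.resources.files("mitocomp.data") / "drusselli_annotation.tsv"
    with importlib.resources.as_file(ref) as path:
        rec = read_annotation_table(path, id="D_russelli_layout")
    return MitogenomeRecord(id=rec.id, length=16542, features=rec.features)


def drusselli_codon_patterns() -> dict[str, tuple[str, str]]:
    """PCG name -> (start codon, stop display text) from the shipped table."""
    import pandas as pd

    ref = importlib.resources.files("mitocomp.data") / "drusselli_annotation.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    out = {}
    for _, row in df.iterrows():
        if row["category"] == "PCG":
            out[row["locus"]] = (row["start_codon"], row["stop_codon"])
    return out


@dataclass
class GeneratorSpec:
    """Everything that determines a synthetic mitogenome; the seed fully
    determines the output."""

    seed: int = 0
    layout: MitogenomeRecord | None = None  # defaults to the shipped 38-feature layout
    base_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_PROBS))
    codon_patterns: dict[str, tuple[str, str]] | None = None  # PCG -> (start, stop text)

    def __post_init__(self) -> None:
        total = sum(self.base_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"base probabilities sum to {total}, not 1")


def _sample_bases(rng: np.random.Generator, n: int, probs: dict[str, float]) -> str:
    bases = list(probs)
    return "".join(rng.choice(bases, size=n, p=[probs[b] for b in bases]))


def _sense_codon_sampler(probs: dict[str, float]):
    import itertools

    codons = ["".join(p) for p in itertools.product("ACGT", repeat=3)
              if "".join(p) not in _STOPS]
    w = np.array([np.prod([probs[b] for b in c]) for c in codons])
    w /= w.sum()
    return codons, w


def _pcg_coding_sequence(rng, size: int, start: str, stop_text: str,
                         probs: dict[str, float]) -> str:
    stop = stop_text.rstrip("-")
    body_len = size - 3 - len(stop)
    if body_len < 0 or body_len % 3:
        raise ValueError(
            f"gene size {size} incompatible with stop {stop_text!r} "
            "(size mod 3 must match the truncated-stop length)"
        )
    codons, w = _sense_codon_sampler(probs)
    body = "".join(rng.choice(codons, size=body_len // 3, p=w))
    if stop in ("TA", "T"):
        pass  # truncated stop written verbatim
    return start + body + stop


def generate_mitogenome(spec: GeneratorSpec) -> tuple[MitogenomeRecord, dict]:
    """Synthetic mitogenome on the spec's layout, with ground truth.

    PCGs are written in frame with the declared start codon and
    (possibly incomplete) stop; L-strand features are written as reverse
    complements on the heavy strand.  Features are written in genome
    order, so in overlap regions the downstream feature's bases win; the
    truth report flags start/stop codons whose bases were overwritten.
    """
    rng = np.random.default_rng(spec.seed)
    layout = spec.layout or drusselli_layout()
    patterns = spec.codon_patterns or drusselli_codon_patterns()
    n = layout.length
    seq = np.array(list(_sample_bases(rng, n, spec.base_probs)))
    writer = np.full(n, -1, dtype=int)

    planted: dict[str, dict] = {}
    for idx, feat in enumerate(layout.features):
        if feat.category == "PCG":
            start, stop_text = patterns.get(feat.name, ("ATG", "TAA"))
            coding = _pcg_coding_sequence(rng, feat.size, start, stop_text,
                                          spec.base_probs)
            planted[feat.name] = {"start_codon": start, "stop_codon": stop_text}
        else:
            coding = _sample_bases(rng, feat.size, spec.base_probs)
        placed = reverse_complement(coding) if feat.strand == "L" else coding
        sl = slice(feat.start - 1, feat.end)
        seq[sl] = list(placed)
        writer[sl] = idx

    # flag codons whose bases survived the genome-order overwrites
    for idx, feat in enumerate(layout.features):
        if feat.category != "PCG":
            continue
        if feat.strand == "H":
            head = slice(feat.start - 1, feat.start + 2)
            tail = slice(feat.end - 3, feat.end)
        else:  # coding start sits at the H-strand 3' end
            head = slice(feat.end - 3, feat.end)
            tail = slice(feat.start - 1, feat.start + 2)
        planted[feat.name]["start_intact"] = bool((writer[head] == idx).all())
        planted[feat.name]["stop_intact"] = bool((writer[tail] == idx).all())

    record = MitogenomeRecord(
        id=f"synthetic_mitogenome_seed{spec.seed}",
        length=n,
        features=list(layout.features),
        sequence="".join(seq),
    )
    truth = {
        "seed": spec.seed,
        "base_probs": dict(spec.base_probs),
        "pcg_total_bp": sum(f.size for f in layout.features if f.category == "PCG"),
        "trna_total_bp": sum(f.size for f in layout.features if f.category == "tRNA"),
        "rrna_total_bp": sum(f.size for f in layout.features if f.category == "rRNA"),
        "genes": planted,
    }
    return record, truth


@dataclass(frozen=True)
class TrnaGene:
    name: str
    strand: str
    sequence: str
    dot_bracket: str
    anticodon_pos: int  # 0-based index of the anticodon's first base


_WC_PAIRS = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]
_GU_PAIRS = [("G", "T"), ("T", "G")]


def _build_cloverleaf(rng, stem_lens: dict[str, int], loop_lens: dict[str, int],
                      wobble_p: float, dhu_present: bool) -> tuple[str, str, dict, int]:
    pairs: dict[str, list[tuple[str, str]]] = {}
    wobble_counts: dict[str, int] = {}
    for stem in ("AA", "DHU", "AC", "TPsiU"):
        k = stem_lens[stem] if (dhu_present or stem != "DHU") else 0
        chosen, wob = [], 0
        for _ in range(k):
            if rng.random() < wobble_p:
                chosen.append(_GU_PAIRS[rng.integers(2)])
                wob += 1
            else:
                chosen.append(_WC_PAIRS[rng.integers(4)])
        pairs[stem] = chosen
        wobble_counts[stem] = wob

    def loop(n_):
        return "".join(rng.choice(list("ACGT"), size=n_))

    def arm(stem, loop_seq):
        five = "".join(p[0] for p in pairs[stem])
        three = "".join(p[1] for p in reversed(pairs[stem]))
        seq_ = five + loop_seq + three
        db_ = "(" * len(pairs[stem]) + "." * len(loop_seq) + ")" * len(pairs[stem])
        return seq_, db_

    d_seq, d_db = (arm("DHU", loop(loop_lens["DHU"])) if dhu_present
                   else (loop(loop_lens["DHU"] // 2), "." * (loop_lens["DHU"] // 2)))
    ac_loop = loop(loop_lens["AC"])
    ac_seq, ac_db = arm("AC", ac_loop)
    t_seq, t_db = arm("TPsiU", loop(loop_lens["TPsiU"]))
    v_seq = loop(loop_lens["V"])
    inner_seq = d_seq + ac_seq + v_seq + t_seq
    inner_db = d_db + ac_db + "." * len(v_seq) + t_db
    aa5 = "".join(p[0] for p in pairs["AA"])
    aa3 = "".join(p[1] for p in reversed(pairs["AA"]))
    seq = aa5 + inner_seq + aa3
    db = "(" * len(aa5) + inner_db + ")" * len(aa3)
    # anticodon: middle triplet of the 7-nt (or configured) AC loop
    ac_loop_start = len(aa5) + len(d_seq) + len(pairs["AC"])
    anticodon_pos = ac_loop_start + (loop_lens["AC"] - 3) // 2
    return seq, db, wobble_counts, anticodon_pos


def generate_trna_set(
    seed: int = 0,
    n_h: int = 14,
    n_l: int = 8,
    wobble_p_h: float = 0.03,
    wobble_p_l: float = 0.13,
    n_species: int = 1,
    stem_ranges: dict[str, tuple[int, int]] | None = None,
    loop_lens: dict[str, int] | None = None,
    dhu_less: tuple[str, ...] = ("tRNA-Ser(GCT)",),
) -> tuple[list[TrnaGene], dict]:
    """Dot-bracket cloverleaf set with planted per-stem wobble pairs.

    Stem lengths are drawn uniformly from the published windows; every
    stem pair is G-U wobble with the strand group's probability, else a
    random Watson-Crick pair.  With ``n_species > 1`` each tRNA gets one
    structure per species (the family-panel case, where per-tRNA wobble
    tallies pool a few hundred pairs each); the truth records the exact
    planted wobble count per structure per stem, summed per tRNA.
    """
    if not (0 <= wobble_p_h <= 1 and 0 <= wobble_p_l <= 1):
        raise ValueError("wobble probabilities must be in [0, 1]")
    stem_ranges = stem_ranges or DEFAULT_STEM_RANGES
    loop_lens = loop_lens or DEFAULT_LOOP_LENS
    for stem, (lo, hi) in stem_ranges.items():
        if lo < 1 or hi < lo:
            raise ValueError(f"impossible stem-length range for {stem}: {(lo, hi)}")
    rng = np.random.default_rng(seed)
    names = [(_H_TRNAS[i % len(_H_TRNAS)] + ("" if i < len(_H_TRNAS) else f"_{i}"), "H")
             for i in range(n_h)]
    names += [(_L_TRNAS[i % len(_L_TRNAS)] + ("" if i < len(_L_TRNAS) else f"_{i}"), "L")
              for i in range(n_l)]
    genes, truth = [], {}
    for name, strand in names:
        p = wobble_p_h if strand == "H" else wobble_p_l
        dhu = name not in dhu_less
        per_stem = {s: 0 for s in DEFAULT_STEM_RANGES}
        total_pairs = 0
        for _ in range(n_species):
            stem_lens = {s: int(rng.integers(lo, hi + 1))
                         for s, (lo, hi) in stem_ranges.items()}
            seq, db, wob, ac_pos = _build_cloverleaf(rng, stem_lens, loop_lens, p, dhu)
            genes.append(TrnaGene(name, strand, seq, db, ac_pos))
            for s, k in wob.items():
                per_stem[s] += k
            total_pairs += sum(stem_lens[s] for s in stem_lens if dhu or s != "DHU")
        truth[name] = {
            "strand": strand,
            "dhu_present": dhu,
            "wobble_per_stem": per_stem,
            "total_wobble": sum(per_stem.values()),
            "total_pairs": total_pairs,
        }
    return genes, {"seed": seed, "wobble_p_h": wobble_p_h, "wobble_p_l": wobble_p_l,
                   "n_species": n_species, "trnas": truth}


def _mutate_motif(rng, motif: str, n_sub: int, n_ins: int, n_del: int
                  ) -> tuple[str, dict]:
    """Apply exactly the requested edit counts to a motif copy.

    Edit positions are kept >= 3 apart (and off the motif ends) where the
    motif length allows, so the minimum-edit alignment of the mutated copy
    against the reference decomposes into exactly the planted counts
    instead of collapsing clustered edits into cheaper shifted alignments.
    """
    bases = "ACGT"
    seq = list(motif)
    n_edits = n_sub + n_ins + n_del
    if n_edits == 0:
        return motif, {"sub": [], "del": [], "ins": []}
    spacing = 3
    while spacing > 1 and 1 + (n_edits - 1) * spacing > len(seq) - 2:
        spacing -= 1
    chosen: list[int] = []
    candidates = list(rng.permutation(range(1, len(seq) - 1)))
    for p in candidates:
        if all(abs(p - q) >= spacing for q in chosen):
            chosen.append(int(p))
            if len(chosen) == n_edits:
                break
    if len(chosen) < n_edits:  # tiny motif fallback: any distinct positions
        extra = [int(p) for p in candidates if p not in chosen]
        chosen += extra[: n_edits - len(chosen)]
    rng.shuffle(chosen)
    sub_pos = sorted(chosen[:n_sub])
    del_pos = sorted(chosen[n_sub : n_sub + n_del])
    ins_pos = sorted(chosen[n_sub + n_del : n_edits])
    for p in sub_pos:
        seq[p] = rng.choice([b for b in bases if b != seq[p]])
    shift = 0  # apply right-to-left so recorded positions refer to the reference
    for p in sorted(del_pos, reverse=True):
        del seq[p]
    for p in sorted(ins_pos, reverse=True):
        if p >= len(seq):
            p = len(seq) - 1
        ins_base = rng.choice([b for b in bases if b != seq[p] and b != seq[p - 1]])
        seq.insert(p, str(ins_base))
    return "".join(seq), {"sub": sub_pos, "del": del_pos, "ins": ins_pos}


_SCRUB_PATTERNS = ("TACAT", "ATGTA", "TTTTT")


def _scrub_filler(rng, filler: str) -> str:
    """Remove accidental palindromic motifs, long T-runs, and exact small
    tandem repeats from filler sequence so the planted truth stays exact."""
    from .control_region import find_palindromes, find_tandem_repeats

    s = list(filler)
    for _ in range(100):
        text = "".join(s)
        dirty = False
        for pat in _SCRUB_PATTERNS:
            i = text.find(pat)
            if i >= 0:
                s[i + len(pat) // 2] = rng.choice(
                    [b for b in "ACGT" if b != s[i + len(pat) // 2]])
                dirty = True
        if not dirty:
            for rep in find_tandem_repeats(text, min_copies=3):
                j = rep["start"] - 1 + len(rep["unit"])
                s[j] = rng.choice([b for b in "ACGT" if b != s[j]])
                dirty = True
        if not dirty:
            return text
    return "".join(s)


def generate_control_region(
    seed: int = 0,
    length: int = 840,
    motif_edits: dict[str, tuple[int, int, int]] | None = None,
    n_palindrome_copies: int = 3,
    t_run_len: int = 8,
    lib: MotifLibrary | None = None,
) -> tuple[str, dict]:
    """Synthetic control region with motifs planted in canonical order.

    ``motif_edits`` maps motif name to (substitutions, insertions,
    deletions) applied to the planted copy — default all zero.  TACAT /
    ATGTA palindrome copies are placed near the 5' end and a T-run of
    ``t_run_len`` (family range 5-12) between CSB-D and CSB-1.  Filler is
    random at the whole-genome base probabilities, scrubbed of accidental
    palindromes, T-runs and exact tandem repeats so the ground truth is
    exact.
    """
    if not 5 <= t_run_len <= 12:
        raise ValueError("t_run_len outside the family range 5-12")
    rng = np.random.default_rng(seed)
    lib = lib or default_motif_library()
    motif_edits = motif_edits or {}
    plant_order = list(CSB_PLANT_ORDER)
    for name in motif_edits:
        if name not in lib:
            raise ValueError(f"unknown motif {name!r}")

    segments: list[tuple[str, str | None]] = []  # (sequence, planted motif name)

    def filler(n_):
        return (_scrub_filler(rng, _sample_bases(rng, n_, DEFAULT_BASE_PROBS)), None)

    # 5' block with palindrome copies
    pal_truth = []
    five_prime = []
    for i in range(n_palindrome_copies):
        five_prime.append(filler(18))
        motif = ("TACAT", "ATGTA")[i % 2]
        five_prime.append((motif, f"palindrome:{motif}"))
    five_prime.append(filler(12))
    segments.extend(five_prime)

    edits_truth = {}
    for name in plant_order:
        n_sub, n_ins, n_del = motif_edits.get(name, (0, 0, 0))
        # redraw edit placements until the planted counts are also the
        # minimal-alignment decomposition, so the recorded truth is exact
        from .control_region import divergence_mask

        for _ in range(50):
            mutated, positions = _mutate_motif(rng, lib[name].sequence,
                                               n_sub, n_ins, n_del)
            m = divergence_mask(lib[name].sequence, mutated)
            if (m.n_substitutions, m.n_insertions, m.n_deletions) == (n_sub, n_ins, n_del):
                break
        edits_truth[name] = {"n_sub": n_sub, "n_ins": n_ins, "n_del": n_del,
                             "edit_positions": positions}
        segments.append((mutated, name))
        if name == "CSB-D":
            segments.append(filler(10))
            segments.append(("T" * t_run_len, "t_run"))
            segments.append(filler(10))
        elif name != plant_order[-1]:
            segments.append(filler(14))

    core_len = sum(len(s) for s, _ in segments)
    tail_pad = length - core_len
    if tail_pad < 0:
        raise ValueError(f"planted layout ({core_len} bp) exceeds region length {length}")
    segments.append(filler(tail_pad))

    region_parts, truth_hits, pos = [], {}, 0
    t_run_truth = None
    for seqpart, label in segments:
        if label and label.startswith("palindrome:"):
            pal_truth.append((label.split(":")[1], pos + 1))
        elif label == "t_run":
            t_run_truth = (pos + 1, len(seqpart))
        elif label:
            truth_hits[label] = {"start": pos + 1, "end": pos + len(seqpart),
                                 **edits_truth[label]}
        region_parts.append(seqpart)
        pos += len(seqpart)
    region = "".join(region_parts)
    protected = [(h["start"], h["end"]) for h in truth_hits.values()]
    protected += [(p, p + 4) for _, p in pal_truth]
    protected.append((t_run_truth[0], t_run_truth[0] + t_run_truth[1] - 1))
    boundaries = {name: (truth_hits[name]["start"], truth_hits[name]["end"],
                         lib[name].sequence[0], lib[name].sequence[-1])
                  for name in truth_hits}
    region = _global_fix(rng, region, protected, set(pal_truth), t_run_truth,
                         boundaries)
    truth = {
        "seed": seed,
        "length": length,
        "motifs": truth_hits,
        "palindromes": pal_truth,
        "t_run": t_run_truth,
        "tandem_repeats": [],
        "motif_spans": [(h["start"], h["end"]) for h in truth_hits.values()],
    }
    return region, truth


def _global_fix(rng, region: str, protected: list[tuple[int, int]],
                planted_pals: set[tuple[str, int]],
                planted_t_run: tuple[int, int],
                boundaries: dict[str, tuple[int, int, str, str]] | None = None,
                ) -> str:
    """Break accidental palindromes, T-runs and tandem repeats (including
    ones spanning segment junctions) by mutating filler bases, never
    touching the protected (planted) spans.  Filler bases flanking a
    planted motif are kept different from the motif reference's terminal
    bases, so a motif-scan alignment cannot extend past the planted span
    and absorb an indel more cheaply."""
    from .control_region import find_palindromes, find_tandem_repeats, t_homopolymer_runs

    def inside(p1: int) -> bool:
        return any(a <= p1 <= b for a, b in protected)

    s = list(region)
    for name, (a, b, first, last) in (boundaries or {}).items():
        if a >= 2 and s[a - 2] == first and not inside(a - 1):
            s[a - 2] = rng.choice([x for x in "ACG" if x != first])
        if b < len(s) and s[b] == last and not inside(b + 1):
            s[b] = rng.choice([x for x in "ACG" if x != last])
    for _ in range(500):
        text = "".join(s)
        span = None  # 1-based inclusive span of the first violation found
        for m, p in find_palindromes(text):
            if (m, p) not in planted_pals and not all(inside(q) for q in range(p, p + 5)):
                span = (p, p + 4)
                break
        if span is None:
            for start, ln in t_homopolymer_runs(text):
                if (start, ln) != planted_t_run:
                    span = (start, start + ln - 1)
                    break
        if span is None:
            for rep in find_tandem_repeats(text):
                a = rep["start"]
                b = a + len(rep["unit"]) * rep["copies"] - 1
                if not all(inside(q) for q in range(a, b + 1)):
                    span = (a, b)
                    break
        if span is None:
            return text
        editable = [q for q in range(span[0], span[1] + 1) if not inside(q)]
        if not editable:
            break  # fully protected; leave as-is
        q = int(editable[len(editable) // 2])
        s[q - 1] = rng.choice([b for b in "ACGT" if b != s[q - 1]])
    return "".join(s)


CSB_PLANT_ORDER = ("CSB-F", "CSB-E", "CSB-D", "CSB-1", "CSB-2", "CSB-3",
                   "terminal-3prime")
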