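"""Pairwise p-distances and Nei-Gojobori Ka/Ks for aligned mitochondrial genes.

The p-distance is the proportion of differing sites among pairwise-comparable
(non-gap, non-N) columns, optionally restricted to codon positions 1+2 or 3.

Ka/Ks follows the Nei & Gojobori (1986) unweighted-pathway method under the
vertebrate mitochondrial code: per-codon synonymous site fractions, observed
differences averaged with equal weight over all minimal mutational pathways
(pathways through stop codons discarded when an alternative exists), and the
Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .codon_usage import VERTEBRATE_MITO, codon_to_aa

__all__ = [
    "AlignedGeneSet",
    "PDistanceResult",
    "KaKsResult",
    "FrameError",
    "p_distance",
    "kaks_pair",
    "gene_average_kaks",
    "synonymous_site_fraction",
]

_STOPS = frozenset(VERTEBRATE_MITO.stop_codons)
_BASES = "ACGT"


class FrameError(ValueError):
    """Alignment is not a clean reading frame (internal stops etc.)."""


@dataclass
class AlignedGeneSet:
    """Equal-length aligned coding sequences for one gene, keyed by taxon."""

    gene: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene}: aligned rows differ in length")
        self.sequences = {t: s.upper() for t, s in self.sequences.items()}

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()), ""))


@dataclass
class PDistanceResult:
    partition: str  # all | pos12 | pos3
    mean_p: float | None
    matrix: pd.DataFrame
    n_missing_pairs: int = 0


@dataclass
class KaKsResult:
    ka: float | None
    ks: float | None
    ratio: float | None
    pn: float | None = None  # uncorrected proportions
    ps: float | None = None
    sites_n: float | None = None
    sites_s: float | None = None
    undefined_reason: str | None = None
    per_pair: pd.DataFrame | None = None
    n_undefined_pairs: int = 0


_PARTITION_POS = {"all": (0, 1, 2), "pos12": (0, 1), "pos3": (2,)}


def p_distance(aln: AlignedGeneSet, partition: str = "all") -> PDistanceResult:
    """Mean pairwise p-distance over a codon-position partition.

    Columns with a gap or N in either member of a pair are deleted
    pairwise; the mean is over all unordered pairs with >= 1 comparable
    site (pairs with none are reported missing).
    """
    if partition not in _PARTITION_POS:
        raise ValueError(f"unknown partition {partition!r}")
    taxa = aln.taxa
    if len(taxa) < 2:
        raise ValueError("need at least two taxa")
    keep = _PARTITION_POS[partition]
    good = np.frombuffer(b"ACGT", dtype="S1")
    arr = {t: np.frombuffer(aln.sequences[t].encode(), dtype="S1") for t in taxa}
    col_ok = {t: np.isin(arr[t], good) for t in taxa}
    pos_mask = np.isin(np.arange(aln.length) % 3, keep)
    mat = pd.DataFrame(np.zeros((len(taxa), len(taxa))), index=taxa, columns=taxa)
    values, n_missing = [], 0
    for t1, t2 in itertools.combinations(taxa, 2):
        usable = pos_mask & col_ok[t1] & col_ok[t2]
        n = int(usable.sum())
        if n == 0:
            mat.loc[t1, t2] = mat.loc[t2, t1] = np.nan
            n_missing += 1
            continue
        p = float((arr[t1][usable] != arr[t2][usable]).sum()) / n
        mat.loc[t1, t2] = mat.loc[t2, t1] = p
        values.append(p)
    return PDistanceResult(
        partition=partition,
        mean_p=float(np.mean(values)) if values else None,
        matrix=mat,
        n_missing_pairs=n_missing,
    )


@lru_cache(maxsize=None)
def synonymous_site_fraction(codon: str) -> float:
    """Number of synonymous sites in a codon (0..3).

    Each position contributes the fraction of its three possible point
    mutations that preserve the encoded amino acid; mutations creating a
    stop codon count as nonsynonymous.
    """
    aa = codon_to_aa(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant not in _STOPS and codon_to_aa(mutant) == aa:
                syn += 1
        s += syn / 3.0
    return s


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons,
    averaged with equal weight over all minimal mutational pathways."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_pos):
        cur, sd, nd, via_stop = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS or cur in _STOPS:
                via_stop = True
                nd += 1  # counted nonsynonymous if this pathway must be used
            elif codon_to_aa(cur) == codon_to_aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        pathways.append((sd, nd, via_stop))
    clean = [p for p in pathways if not p[2]]
    use = clean if clean else pathways
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def kaks_pair(seq1: str, seq2: str) -> KaKsResult:
    """Nei-Gojobori Ka/Ks for one aligned coding pair.

    Codons containing a gap or N in either sequence are removed pairwise;
    a terminal stop codon (in either) is trimmed; an internal stop raises
    ``FrameError``.  The ratio is None when Ks is 0 or a correction is
    undefined (p >= 3/4).
    """
    s1, s2 = seq1.upper(), seq2.upper()
    if len(s1) != len(s2):
        raise ValueError("aligned sequences differ in length")
    if len(s1) % 3:
        raise ValueError("aligned length not divisible by 3")
    codons = []
    for i in range(0, len(s1), 3):
        c1, c2 = s1[i : i + 3], s2[i : i + 3]
        if set(c1 + c2) - set("ACGT"):
            continue  # gap or ambiguity: pairwise codon removal
        codons.append((c1, c2))
    while codons and (codons[-1][0] in _STOPS or codons[-1][1] in _STOPS):
        codons.pop()
    for c1, c2 in codons:
        if c1 in _STOPS or c2 in _STOPS:
            raise FrameError("internal stop codon in aligned pair")
    if not codons:
        return KaKsResult(None, None, None, undefined_reason="no comparable codons")

    S = sum((synonymous_site_fraction(c1) + synonymous_site_fraction(c2)) / 2.0
            for c1, c2 in codons)
    N = 3.0 * len(codons) - S
    Sd = Nd = 0.0
    for c1, c2 in codons:
        sd, nd = _pathway_counts(c1, c2)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else None
    pn = Nd / N if N > 0 else None
    ks = _jukes_cantor(ps) if ps is not None else None
    ka = _jukes_cantor(pn) if pn is not None else None
    reason = None
    if ps is not None and ps >= 0.75:
        reason = "pS >= 3/4; Jukes-Cantor correction undefined"
    elif pn is not None and pn >= 0.75:
        reason = "pN >= 3/4; Jukes-Cantor correction undefined"
    ratio = None
    if ka is not None and ks is not None:
        if ks > 0:
            ratio = ka / ks
        else:
            reason = reason or "Ks = 0; ratio undefined"
    return KaKsResult(ka=ka, ks=ks, ratio=ratio, pn=pn, ps=ps,
                      sites_n=N, sites_s=S, undefined_reason=reason)


def gene_average_kaks(aln: AlignedGeneSet) -> KaKsResult:
    """Average pairwise Ka, Ks and Ka/Ks over all taxon pairs of a gene.

    The ratio average runs over pairs whose ratio is defined; undefined
    pairs are excluded and counted in ``n_undefined_pairs``.
    """
    taxa = aln.taxa
    if len(taxa) < 2:
        raise ValueError("need at least two taxa")
    rows = []
    for t1, t2 in itertools.combinations(taxa, 2):
        r = kaks_pair(aln.sequences[t1], aln.sequences[t2])
        rows.append({"taxon1": t1, "taxon2": t2, "ka": r.ka, "ks": r.ks,
                     "ratio": r.ratio, "reason": r.undefined_reason})
    df = pd.DataFrame(rows)
    ratios = df["ratio"].dropna()
    kas, kss = df["ka"].dropna(), df["ks"].dropna()
    return KaKsResult(
        ka=float(kas.mean()) if len(kas) else None,
        ks=float(kss.mean()) if len(kss) else None,
        ratio=float(ratios.mean()) if len(ratios) else None,
        per_pair=df,
        n_undefined_pairs=int(df["ratio"].isna().sum()),
        undefined_reason=None if len(ratios) else "all pairs undefined",
    )
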