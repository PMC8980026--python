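"""Evolutionary-rate tests, including a from-scratch brute-force
Nei-Gojobori enumerator used as the independent oracle for kaks_pair."""

import itertools
import math
import statistics

import numpy as np
import pytest

from mitocomp.codon_usage import ALL_CODONS, codon_to_aa
from mitocomp.rates import (
    AlignedGeneSet,
    FrameError,
    gene_average_kaks,
    kaks_pair,
    p_distance,
)

STOPS = {"TAA", "TAG", "AGA", "AGG"}
SENSE = [c for c in ALL_CODONS if c not in STOPS]


# --- independent oracle ------------------------------------------------------

def _oracle_syn_sites(codon):
    syn = 0
    for pos, base in enumerate(codon):
        for b in "ACGT":
            if b == base:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut not in STOPS and codon_to_aa(mut) == codon_to_aa(codon):
                syn += 1
    return syn / 3.0


def _oracle_pathways(c1, c2):
    """Enumerate every order of single-base steps recursively."""
    results = []

    def walk(cur, remaining, sd, nd, via_stop):
        if not remaining:
            results.append((sd, nd, via_stop))
            return
        for pos in remaining:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                walk(nxt, [p for p in remaining if p != pos], sd, nd + 1, True)
            elif codon_to_aa(cur) == codon_to_aa(nxt):
                walk(nxt, [p for p in remaining if p != pos], sd + 1, nd, via_stop)
            else:
                walk(nxt, [p for p in remaining if p != pos], sd, nd + 1, via_stop)

    walk(c1, [i for i in range(3) if c1[i] != c2[i]], 0, 0, False)
    clean = [r for r in results if not r[2]]
    use = clean or results
    return (sum(r[0] for r in use) / len(use), sum(r[1] for r in use) / len(use))


def oracle_kaks(s1, s2):
    codons = [(s1[i : i + 3], s2[i : i + 3]) for i in range(0, len(s1), 3)]
    S = sum((_oracle_syn_sites(a) + _oracle_syn_sites(b)) / 2 for a, b in codons)
    N = 3 * len(codons) - S
    sd = nd = 0.0
    for a, b in codons:
        s_, n_ = _oracle_pathways(a, b)
        sd += s_
        nd += n_
    ps, pn = sd / S, nd / N

    def jc(p):
        return None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return jc(pn), jc(ps), S, N


def _random_pair(rng, n_codons, n_mut):
    s = list("".join(rng.choice(SENSE, size=n_codons)))
    q = s[:]
    applied = 0
    while applied < n_mut:
        p = int(rng.integers(len(q)))
        b = rng.choice([x for x in "ACGT" if x != q[p]])
        old = q[p]
        q[p] = b
        ci = p // 3 * 3
        if "".join(q[ci : ci + 3]) in STOPS:
            q[p] = old
            continue
        applied += 1
    return "".join(s), "".join(q)


class TestKaKsAgainstOracle:
    def test_single_synonymous_third_position_change(self):
        s1 = "ATGGCCAAACTTGGGTTTCCCGAAGAT"
        s2 = "ATGGCCAAACTTGGGTTTCCAGAAGAT"  # Pro CCC -> CCA
        r = kaks_pair(s1, s2)
        ka, ks, S, N = oracle_kaks(s1, s2)
        assert r.ka == 0.0
        assert r.ks == pytest.approx(ks, abs=1e-12)
        assert r.sites_s == pytest.approx(S, abs=1e-12)
        assert r.sites_n == pytest.approx(N, abs=1e-12)
        assert r.ks > 0

    def test_random_short_pairs_match_oracle_exactly(self):
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(150):
            n_codons = int(rng.integers(3, 11))
            s1, s2 = _random_pair(rng, n_codons, int(rng.integers(0, 5)))
            r = kaks_pair(s1, s2)
            ka, ks, S, N = oracle_kaks(s1, s2)
            assert r.sites_s == pytest.approx(S, abs=1e-12)
            if ks is None or ka is None:
                assert r.undefined_reason is not None
                continue
            assert r.ka == pytest.approx(ka, abs=1e-12)
            assert r.ks == pytest.approx(ks, abs=1e-12)
            checked += 1
        assert checked > 50

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            s1, s2 = _random_pair(rng, 8, 3)
            a, b = kaks_pair(s1, s2), kaks_pair(s2, s1)
            assert a.ka == pytest.approx(b.ka, abs=1e-12)
            assert a.ks == pytest.approx(b.ks, abs=1e-12)

    def test_identical_sequences_zero(self):
        s = "ATGGCCAAA"
        r = kaks_pair(s, s)
        assert r.ka == 0.0 and r.ks == 0.0 and r.ratio is None

    def test_codon_shuffle_invariance(self):
        rng = np.random.default_rng(5)
        s1, s2 = _random_pair(rng, 10, 4)
        perm = rng.permutation(10)
        p1 = "".join(s1[3 * i : 3 * i + 3] for i in perm)
        p2 = "".join(s2[3 * i : 3 * i + 3] for i in perm)
        assert kaks_pair(s1, s2).ks == pytest.approx(kaks_pair(p1, p2).ks, abs=1e-12)
        assert kaks_pair(s1, s2).ka == pytest.approx(kaks_pair(p1, p2).ka, abs=1e-12)


def _mutate_only(rng, seq, synonymous, n_mut, codon_pool=None):
    """One synonymous (or nonsynonymous) single-base change in each of
    n_mut distinct codons: keeps Ka (resp. Ks) exactly zero, since two
    changes in one codon can force mixed minimal pathways."""
    q = list(seq)
    pool = list(codon_pool if codon_pool is not None else range(len(seq) // 3))
    order = rng.permutation(len(pool))
    applied = 0
    for idx in order:
        if applied >= n_mut:
            break
        ci = pool[idx] * 3
        old = "".join(q[ci : ci + 3])
        options = [(p, b) for p in range(3) for b in "ACGT" if b != old[p]]
        for j in rng.permutation(len(options)):
            p, b = options[j]
            new = old[:p] + b + old[p + 1 :]
            if new in STOPS:
                continue
            if (codon_to_aa(new) == codon_to_aa(old)) == synonymous:
                q[ci : ci + 3] = list(new)
                applied += 1
                break
    return "".join(q)


class TestSelectionRegimes:
    def test_pure_synonymous_drift_gives_ka_zero(self):
        rng = np.random.default_rng(21)
        s = "".join(rng.choice(SENSE, size=60))
        q = _mutate_only(rng, s, synonymous=True, n_mut=12)
        r = kaks_pair(s, q)
        assert r.ka == 0.0 and r.ks > 0

    def test_pure_nonsynonymous_gives_ks_zero(self):
        rng = np.random.default_rng(22)
        s = "".join(rng.choice(SENSE, size=60))
        q = _mutate_only(rng, s, synonymous=False, n_mut=12)
        r = kaks_pair(s, q)
        assert r.ks == 0.0 and r.ka > 0

    def test_neutral_pressure_gives_ratio_near_one(self):
        # random accepted point mutations are the neutral expectation of the
        # counting method: Ka/Ks -> 1; tolerance = 3 s.e. of the 10-replicate
        # mean (per-replicate sd ~0.25 measured on this design)
        rng = np.random.default_rng(23)
        ratios = []
        for _ in range(10):
            s, q = _random_pair(rng, 500, 80)
            ratios.append(kaks_pair(s, q).ratio)
        assert statistics.mean(ratios) == pytest.approx(1.0, abs=0.25)


class TestKaKsEdgeCases:
    def test_internal_stop_raises(self):
        with pytest.raises(FrameError):
            kaks_pair("ATGTAAGCC", "ATGTAAGCC")

    def test_terminal_stop_trimmed(self):
        r = kaks_pair("ATGGCCTAA", "ATGGCCTAA")
        assert r.ka == 0.0 and r.ks == 0.0

    def test_gap_codons_removed_pairwise(self):
        r = kaks_pair("ATG---GCC", "ATGAAAGCC")
        assert r.ka == 0.0 and r.ks == 0.0


class TestPDistance:
    def test_identical_rows_zero_every_partition(self):
        aln = AlignedGeneSet("g", {"a": "ATGGCC", "b": "ATGGCC"})
        for part in ("all", "pos12", "pos3"):
            assert p_distance(aln, part).mean_p == 0.0

    def test_third_position_partition(self):
        aln = AlignedGeneSet("g", {"a": "ACGACG", "b": "ACTACG"})
        assert p_distance(aln, "all").mean_p == pytest.approx(1 / 6)
        assert p_distance(aln, "pos12").mean_p == 0.0
        assert p_distance(aln, "pos3").mean_p == pytest.approx(1 / 2)

    def test_gap_columns_deleted_pairwise(self):
        aln = AlignedGeneSet("g", {"a": "AC-", "b": "ACG"})
        assert p_distance(aln, "all").mean_p == 0.0

    def test_matrix_symmetric_zero_diagonal(self):
        aln = AlignedGeneSet("g", {"a": "ACGACG", "b": "ACTACT", "c": "ACGACT"})
        m = p_distance(aln, "all").matrix
        assert (m.values == m.values.T).all()
        assert (m.values.diagonal() == 0).all()

    def test_partition_ordering_when_pos3_carries_all_changes(self):
        rng = np.random.default_rng(9)
        s = "".join(rng.choice(SENSE, size=50))
        q = _mutate_only(rng, s, synonymous=True, n_mut=10)
        aln = AlignedGeneSet("g", {"a": s, "b": q})
        p12 = p_distance(aln, "pos12").mean_p
        p3 = p_distance(aln, "pos3").mean_p
        pall = p_distance(aln, "all").mean_p
        assert p12 <= pall <= p3


class TestGeneAverage:
    def test_identical_taxa_reported_missing(self):
        aln = AlignedGeneSet("g", {"a": "ATGGCC", "b": "ATGGCC"})
        r = gene_average_kaks(aln)
        assert r.ratio is None and r.n_undefined_pairs == 1

    def test_synonymous_family_ratio_zero(self):
        # disjoint codon pools per taxon keep every pairwise comparison
        # one-change-per-codon, hence strictly synonymous
        rng = np.random.default_rng(31)
        anc = "".join(rng.choice(SENSE, size=90))
        taxa = {f"t{i}": _mutate_only(rng, anc, synonymous=True, n_mut=8,
                                      codon_pool=range(i * 30, (i + 1) * 30))
                for i in range(3)}
        r = gene_average_kaks(AlignedGeneSet("g", taxa))
        assert r.ratio == pytest.approx(0.0, abs=1e-12)
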