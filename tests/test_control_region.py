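import warnings

import edlib
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitocomp.control_region import (
    CSB_ORDER,
    Motif,
    MotifLibrary,
    annotate_control_region,
    apply_mask,
    default_motif_library,
    divergence_mask,
    find_palindromes,
    find_tandem_repeats,
    palindrome_check,
    scan_motif,
    t_homopolymer_runs,
)
from mitocomp.synthetic import generate_control_region

LIB = default_motif_library()
dna = st.text(alphabet="ACGT", min_size=1, max_size=120)


def _annotate(region, lib=None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return annotate_control_region(region, lib)


class TestScanMotif:
    def test_verbatim_hit_zero_edits(self):
        region = "AAGG" + LIB["CSB-D"].sequence + "TTCC"
        h = scan_motif(region, LIB["CSB-D"])
        assert (h.start, h.end) == (5, 4 + len(LIB["CSB-D"].sequence))
        assert h.n_edits == 0 and set(h.mask.text) == {"*"}

    def test_planted_substitutions_within_budget(self):
        region, truth = generate_control_region(seed=20, motif_edits={"CSB-D": (2, 0, 0)})
        h = scan_motif(region, LIB["CSB-D"], max_sub=3)
        t = truth["motifs"]["CSB-D"]
        assert (h.start, h.end, h.n_substitutions) == (t["start"], t["end"], 2)
        assert sum(c not in "*-" and c.isupper() for c in h.mask.text) == 2

    def test_absent_motif_no_hit(self):
        rng = np.random.default_rng(21)
        region = "".join(rng.choice(list("ACGT"), size=300))
        motif = Motif("x", "TTTTACCCGGGAATTTT", max_sub=1, max_indel=0)
        assert motif.sequence not in region
        assert scan_motif(region, motif) is None

    def test_empty_motif_rejected(self):
        with pytest.raises(ValueError):
            Motif("x", "")

    @given(dna, st.text(alphabet="ACGT", min_size=3, max_size=10))
    @settings(max_examples=150, deadline=None)
    def test_zero_budget_equals_substring_search(self, region, motif):
        h = scan_motif(region, motif, max_sub=0, max_indel=0)
        pos = region.find(motif)  # naive-search oracle
        if pos < 0:
            assert h is None
        else:
            assert (h.start, h.end) == (pos + 1, pos + len(motif))

    def test_edit_distance_matches_edlib_oracle(self):
        rng = np.random.default_rng(22)
        for _ in range(40):
            region = "".join(rng.choice(list("ACGT"), size=250))
            motif = "".join(rng.choice(list("ACGT"), size=18))
            h = scan_motif(region, motif, max_sub=18, max_indel=18)
            d = edlib.align(motif, region, mode="HW")["editDistance"]
            assert h is not None and h.n_edits == d


class TestDivergenceMask:
    def test_identical_all_asterisks(self):
        assert divergence_mask("ACGT", "ACGT").text == "****"

    def test_terminal_sequence_single_substitution(self):
        # the study species differs from the 3'-terminal reference by one
        # C at position 7
        ref = "TATTATAATATTTCACAT"
        query = ref[:6] + "C" + ref[7:]
        assert divergence_mask(ref, query).text == "******C***********"

    def test_single_insertion_lowercase(self):
        m = divergence_mask("ACGTACGT", "ACGTTACGT")
        assert m.n_insertions == 1 and sum(c.islower() for c in m.text) == 1

    def test_single_deletion_dash(self):
        m = divergence_mask("ACGTACGT", "ACGACGT")
        assert m.n_deletions == 1 and m.text.count("-") == 1

    @given(dna, st.data())
    @settings(max_examples=100, deadline=None)
    def test_mask_reconstructs_query(self, ref, data):
        # inverse consistency on arbitrary query derived by random edits
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        q = list(ref)
        for _ in range(rng.integers(0, 4)):
            op = rng.integers(3)
            if op == 0 and q:
                p = rng.integers(len(q))
                q[p] = "ACGT"[rng.integers(4)]
            elif op == 1 and q:
                del q[rng.integers(len(q))]
            else:
                q.insert(rng.integers(len(q) + 1), "ACGT"[rng.integers(4)])
        if not q:
            return
        query = "".join(q)
        m = divergence_mask(ref, query)
        assert apply_mask(ref, m) == query
        assert m.reference_length == len(ref)


class TestPalindromes:
    def test_tacat_atgta_are_mutual_reverse_complements(self):
        assert palindrome_check("TACAT", "ATGTA")
        assert palindrome_check("ATGTA", "TACAT")

    def test_aaaa_tttt(self):
        assert palindrome_check("AAAA", "TTTT")

    def test_aaaa_not_self(self):
        assert not palindrome_check("AAAA", "AAAA")

    def test_overlapping_occurrences_found(self):
        hits = find_palindromes("ATACATACAT")
        assert ("TACAT", 2) in hits and ("TACAT", 6) in hits


class TestHomopolymerAndRepeats:
    def test_t_run_reported(self):
        assert t_homopolymer_runs("CCTTTTTTTAA") == [(3, 7)]

    def test_short_runs_ignored(self):
        assert t_homopolymer_runs("CCTTTTAA") == []

    def test_tandem_repeat_positive_control(self):
        reps = find_tandem_repeats("GG" + "ATC" * 4 + "GG")
        assert any(r["unit"] == "ATC" and r["copies"] == 4 for r in reps)

    def test_homopolymer_not_reported_as_tandem_repeat(self):
        assert find_tandem_repeats("AACCCCCCCCAA") == []


class TestAnnotateControlRegion:
    def test_all_motifs_recovered_in_order(self):
        region, truth = generate_control_region(seed=23)
        ann = _annotate(region)
        assert ann.order_satisfied
        for name in CSB_ORDER + ("terminal-3prime",):
            h, t = ann.hits[name], truth["motifs"][name]
            assert (h.start, h.end, h.n_edits) == (t["start"], t["end"], 0)

    def test_planted_palindromes_recovered(self):
        region, truth = generate_control_region(seed=24)
        ann = _annotate(region)
        found = set(ann.palindromes)
        assert set(truth["palindromes"]) <= found
        # any extra occurrence is inside a planted motif (CSB-F itself
        # begins with ATGTA), never in filler
        spans = truth["motif_spans"]
        for m, p in found - set(truth["palindromes"]):
            assert any(a <= p and p + 4 <= b for a, b in spans)

    def test_flagged_t_run_between_csb_d_and_csb_1(self):
        region, truth = generate_control_region(seed=25, t_run_len=12)
        ann = _annotate(region)
        assert ann.flagged_t_run == truth["t_run"] == (truth["t_run"][0], 12)
        d, c1 = ann.hits["CSB-D"], ann.hits["CSB-1"]
        assert d.end < ann.flagged_t_run[0] < c1.start

    def test_no_tandem_repeats_in_generated_region(self):
        # mirrors the family-wide observation of repeat-free control regions
        for seed in range(3):
            region, _ = generate_control_region(seed=seed)
            assert _annotate(region).tandem_repeats == []

    def test_short_region_rejected(self):
        with pytest.raises(ValueError):
            annotate_control_region("ACGT" * 10)

    def test_order_violation_warns_but_reports_hits(self):
        lib = MotifLibrary()
        lib.add(Motif("CSB-F", LIB["CSB-F"].sequence, 2, 0))
        lib.add(Motif("CSB-E", LIB["CSB-E"].sequence, 2, 0))
        rng = np.random.default_rng(26)
        filler = "".join(rng.choice(list("ACG"), size=100))
        region = filler + lib["CSB-E"].sequence + filler + lib["CSB-F"].sequence + filler
        with pytest.warns(UserWarning, match="order"):
            ann = annotate_control_region(region, lib)
        assert not ann.order_satisfied
        assert ann.hits["CSB-F"] is not None and ann.hits["CSB-E"] is not None


class TestPlantedEditRecovery:
    @pytest.mark.parametrize("name,edits", [
        ("CSB-E", (4, 0, 0)),
        ("CSB-F", (3, 0, 0)),
        ("CSB-D", (5, 0, 0)),
        ("terminal-3prime", (1, 0, 0)),
    ])
    @pytest.mark.parametrize("seed", range(5))
    def test_substitution_plantings_recovered_exactly(self, name, edits, seed):
        region, truth = generate_control_region(seed=seed, motif_edits={name: edits})
        h = _annotate(region).hits[name]
        t = truth["motifs"][name]
        assert (h.start, h.end) == (t["start"], t["end"])
        assert (h.n_substitutions, h.n_insertions, h.n_deletions) == edits

    def test_nine_substitutions_on_central_block_reference(self):
        # the family's maximum divergence load (9 substitutions) is
        # identifiable on the 62-nt concatenated central-block reference
        central = (LIB["CSB-F"].sequence + LIB["CSB-E"].sequence
                   + LIB["CSB-D"].sequence)
        lib = MotifLibrary()
        for m in LIB.values():
            lib.add(m)
        lib.add(Motif("CSB-E", central, 9, 2))
        for seed in range(5):
            region, truth = generate_control_region(
                seed=seed, motif_edits={"CSB-E": (9, 0, 0)}, lib=lib)
            h = _annotate(region, lib).hits["CSB-E"]
            t = truth["motifs"]["CSB-E"]
            assert (h.start, h.end, h.n_substitutions) == (t["start"], t["end"], 9)

    @pytest.mark.parametrize("name,edits", [
        ("CSB-D", (2, 1, 1)),
        ("CSB-1", (3, 1, 0)),
        ("CSB-2", (2, 0, 1)),
    ])
    @pytest.mark.parametrize("seed", range(5))
    def test_indel_plantings_recovered_at_most_planted_cost(self, name, edits, seed):
        # minimum-distance tie-breaking may re-express an end-adjacent
        # indel as substitutions; span and total cost are still recovered
        region, truth = generate_control_region(seed=seed, motif_edits={name: edits})
        h = _annotate(region).hits[name]
        t = truth["motifs"][name]
        assert h is not None
        assert h.n_edits <= sum(edits)
        assert abs(h.start - t["start"]) <= 2 and abs(h.end - t["end"]) <= 2
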