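"""Binding-site search, amplicon enumeration and copy-number classes."""

import pytest

from palmsat.epcr import (
    Amplicon,
    BindingSite,
    EpcrParams,
    amplify,
    classify_copy_number,
    enumerate_amplicons,
    find_binding_sites,
)
from palmsat.primer_design import PrimerPair, design_primers
from palmsat.repeat_finder import find_ssrs_in_seq, reverse_complement

from conftest import random_dna
from oracles import sliding_hamming_sites

PRIMER = "gcattgcacgtgcatcgtca"


def _as_tuples(sites):
    return {(s.strand, s.start, s.end, s.mismatches) for s in sites}


class TestBindingSites:
    def test_verbatim_primer_found_once_plus_strand(self, rng):
        seq = random_dna(rng, 500) + PRIMER + random_dna(rng, 500)
        sites = find_binding_sites("s", seq, PRIMER)
        plus = [s for s in sites if s.strand == "+"]
        assert [(s.start, s.mismatches) for s in plus] == [(500, 0)]

    def test_reverse_complement_occurrence_found_on_minus_strand(self, rng):
        seq = random_dna(rng, 300) + reverse_complement(PRIMER) + random_dna(rng, 300)
        sites = find_binding_sites("s", seq, PRIMER)
        assert _as_tuples(sites) == {("-", 300, 320, 0)}

    def test_two_substitutions_rejected_at_one_mismatch(self, rng):
        mutated = "tt" + PRIMER[2:]  # two substitutions at the 5' end
        assert mutated != PRIMER and len(mutated) == len(PRIMER)
        seq = random_dna(rng, 400) + mutated + random_dna(rng, 400)
        assert find_binding_sites("s", seq, PRIMER) == []

    def test_one_substitution_accepted_and_counted(self, rng):
        mutated = "t" + PRIMER[1:]
        seq = random_dna(rng, 400) + mutated + random_dna(rng, 400)
        sites = find_binding_sites("s", seq, PRIMER)
        assert _as_tuples(sites) == {("+", 400, 420, 1)}

    def test_n_in_template_never_matches(self):
        seq = "c" * 50 + PRIMER[:10] + "n" + PRIMER[11:] + "c" * 50
        sites = find_binding_sites("s", seq, PRIMER)
        assert _as_tuples(sites) == {("+", 50, 70, 1)}
        assert find_binding_sites(
            "s", seq, PRIMER, EpcrParams(max_mismatch_per_primer=0)
        ) == []

    def test_three_prime_protect_blocks_terminal_mismatch(self, rng):
        mutated = PRIMER[:-1] + ("a" if PRIMER[-1] != "a" else "c")
        seq = random_dna(rng, 200) + mutated + random_dna(rng, 200)
        lenient = find_binding_sites("s", seq, PRIMER)
        assert _as_tuples(lenient) == {("+", 200, 220, 1)}
        protected = find_binding_sites(
            "s", seq, PRIMER, EpcrParams(three_prime_protect=3)
        )
        assert protected == []

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError):
            find_binding_sites("s", "acgt" * 100, "acgtacg")

    def test_oracle_equivalence_on_random_cases(self, rng):
        for _ in range(25):
            seq = random_dna(rng, int(rng.integers(200, 1200)),
                             "acgtn" if rng.random() < 0.3 else "acgt")
            primer = random_dna(rng, int(rng.integers(10, 22)))
            for mm in (0, 1, 2):
                got = _as_tuples(
                    find_binding_sites("s", seq, primer,
                                       EpcrParams(max_mismatch_per_primer=mm))
                )
                assert got == sliding_hamming_sites(seq, primer, mm)

    def test_site_sets_monotone_in_mismatch_budget(self, rng):
        seq = random_dna(rng, 3000)
        primer = random_dna(rng, 16)
        previous = set()
        for mm in (0, 1, 2, 3):
            sites = {(s.strand, s.start, s.end) for s in find_binding_sites(
                "s", seq, primer, EpcrParams(max_mismatch_per_primer=mm))}
            assert previous <= sites
            previous = sites


class TestAmplicons:
    def _pair_sites(self, fwd_at, rev_end, seq_id="s", m=20):
        f = BindingSite(seq_id, "+", fwd_at, fwd_at + m, 0)
        r = BindingSite(seq_id, "-", rev_end - m, rev_end, 0)
        return [f], [r]

    def test_convergent_pair_at_expected_size(self):
        sf, sr = self._pair_sites(100, 250)
        amps = enumerate_amplicons(sf, sr, expected_size=150)
        assert len(amps) == 1 and amps[0].size == 150

    def test_size_window_is_a_strict_inequality(self):
        sf, sr = self._pair_sites(100, 350)  # size 250, expected 150
        assert enumerate_amplicons(sf, sr, 150, EpcrParams(size_deviation=100)) == []
        amps = enumerate_amplicons(sf, sr, 150, EpcrParams(size_deviation=101))
        assert len(amps) == 1

    def test_overlapping_sites_rejected(self):
        f = [BindingSite("s", "+", 100, 120, 0)]
        r = [BindingSite("s", "-", 110, 130, 0)]
        assert enumerate_amplicons(f, r, 30) == []

    def test_mirrored_orientation_counts(self):
        # reverse primer binds plus strand upstream of the forward's minus site
        f = [BindingSite("s", "-", 300, 320, 0)]
        r = [BindingSite("s", "+", 100, 120, 0)]
        amps = enumerate_amplicons(f, r, 220)
        assert len(amps) == 1 and amps[0].start == 100 and amps[0].end == 320

    def test_cross_record_pairings_excluded(self):
        f = [BindingSite("s1", "+", 100, 120, 0)]
        r = [BindingSite("s2", "-", 200, 220, 0)]
        assert enumerate_amplicons(f, r, 120) == []

    def test_three_planted_copies_give_three_products(self, rng):
        fwd, rev = PRIMER, "tgacgtgcttacgcagtgca"
        cassette = fwd + random_dna(rng, 110) + reverse_complement(rev)
        seq = random_dna(rng, 200)
        for _ in range(3):
            seq += cassette + random_dna(rng, 200)
        pair = _pair(fwd, rev, expected=150)
        amps = amplify({"s": seq}, pair)
        assert len(amps) == 3
        assert classify_copy_number(len(amps)) == "3"


class TestStrandSymmetry:
    def test_reverse_complemented_genome_mirrors_amplicons(self, rng):
        seq = random_dna(rng, 1500)
        fwd, rev = PRIMER, "tgacgtgcttacgcagtgca"
        cassette = fwd + random_dna(rng, 80) + reverse_complement(rev)
        seq = seq[:700] + cassette + seq[700 + len(cassette):]
        pair = _pair(fwd, rev, expected=len(cassette))
        amps = amplify({"s": seq}, pair)
        mirrored = amplify({"s": reverse_complement(seq)}, pair)
        n = len(seq)
        assert {(a.start, a.end) for a in mirrored} == {
            (n - a.end, n - a.start) for a in amps
        }


class TestSelfRecovery:
    def test_designed_pairs_recover_their_own_locus(self, rng):
        seq = random_dna(rng, 3000)
        seq = seq[:1000] + "ag" * 7 + seq[1014:]
        strict = EpcrParams(max_mismatch_per_primer=0)
        n_checked = 0
        for locus in find_ssrs_in_seq("s", seq):
            result = design_primers(seq, locus)
            if not isinstance(result, PrimerPair):
                continue
            n_checked += 1
            amps = amplify({"s": seq}, result, strict)
            assert any(a.size == result.expected_product_size for a in amps)
        assert n_checked > 0


class TestCopyNumber:
    @pytest.mark.parametrize("n,label", [(1, "1"), (2, "2"), (3, "3"), (4, ">3"),
                                         (57, ">3")])
    def test_classes(self, n, label):
        assert classify_copy_number(n) == label

    def test_zero_products_have_no_class(self):
        assert classify_copy_number(0) is None

    def test_negative_count_is_a_logic_error(self):
        with pytest.raises(ValueError):
            classify_copy_number(-1)


def _pair(fwd: str, rev: str, expected: int) -> PrimerPair:
    from palmsat.repeat_finder import SSRLocus

    locus = SSRLocus("s", 0, 8, "ag", 4, "ag/ct")
    return PrimerPair(
        marker_id="m1",
        forward_seq=fwd,
        reverse_seq=rev,
        forward_tm=60.0,
        reverse_tm=60.0,
        forward_gc=50.0,
        reverse_gc=50.0,
        forward_start=0,
        reverse_end=expected,
        source_locus=locus,
    )
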