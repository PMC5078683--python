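"""SSR detection: thresholds, primitivity, maximality, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palmsat.repeat_finder import (
    DEFAULT_MIN_REPEATS,
    SSRLocus,
    canonicalize_motif,
    density,
    find_ssrs,
    find_ssrs_in_seq,
    is_primitive,
    percentage,
    summarize,
)

from conftest import random_dna
from oracles import brute_force_ssrs, brute_primitive

FLANK_L = "gctgatcgtg"
FLANK_R = "ccgatcagtc"


def _as_tuples(loci):
    return {(l.seq_id, l.start, l.end, l.unit, l.repeat_count) for l in loci}


class TestThresholds:
    def test_mono_run_at_minimum_is_reported(self):
        loci = find_ssrs_in_seq("s", FLANK_L + "a" * 12 + FLANK_R)
        assert len(loci) == 1
        (l,) = loci
        assert (l.unit, l.repeat_count, l.start, l.end) == ("a", 12, 10, 22)

    def test_mono_run_below_minimum_is_silent(self):
        assert find_ssrs_in_seq("s", FLANK_L + "a" * 11 + FLANK_R) == []

    def test_dinucleotide_reported_at_smallest_unit_only(self):
        loci = find_ssrs_in_seq("s", "cccccc" + "at" * 4 + "cccccc")
        assert _as_tuples(loci) == {("s", 6, 14, "at", 4)}

    def test_threshold_keys_validated(self):
        with pytest.raises(ValueError):
            find_ssrs_in_seq("s", "acgt", thresholds={1: 12, 2: 4})

    def test_non_iupac_character_error_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            find_ssrs_in_seq("s", "acgXacgt")


class TestScanningSemantics:
    def test_case_insensitive_and_n_splits_runs(self):
        flank = "gctgatcgtc"  # must not extend the repeat phase
        loci = find_ssrs_in_seq("s", flank + "AGAGagag" + "N" + "agagAGAG" + flank)
        # each half is only 4 units long after the N split
        assert {(l.start, l.end, l.unit) for l in loci} == {
            (10, 18, "ag"),
            (19, 27, "ag"),
        }

    def test_run_at_contig_boundary_is_reported(self):
        loci = find_ssrs_in_seq("s", "tg" * 5 + FLANK_R)
        assert _as_tuples(loci) == {("s", 0, 10, "tg", 5)}

    def test_abutting_different_unit_runs_both_reported(self):
        loci = find_ssrs_in_seq("s", FLANK_L + "a" * 12 + "t" * 12 + FLANK_R)
        assert {(l.unit, l.start) for l in loci} == {("a", 10), ("t", 22)}

    def test_partial_trailing_unit_excluded_from_span(self):
        # 4 full 'agc' units plus a dangling 'ag'
        loci = find_ssrs_in_seq("s", "tt" + "agc" * 4 + "ag" + "tttgca")
        assert _as_tuples(loci) == {("s", 2, 14, "agc", 4)}


class TestPrimitivity:
    def test_exhaustive_units_up_to_hexamers_match_brute_force(self):
        from itertools import product

        for length in range(1, 7):
            for unit in map("".join, product("acgt", repeat=length)):
                assert is_primitive(unit) == brute_primitive(unit), unit

    def test_empty_unit_rejected(self):
        with pytest.raises(ValueError):
            is_primitive("")

    @given(st.text(alphabet="acgt", min_size=1, max_size=3), st.integers(2, 3))
    @settings(derandomize=True)
    def test_concatenated_units_never_primitive(self, unit, reps):
        assert not is_primitive(unit * reps)


class TestMotifClass:
    @pytest.mark.parametrize(
        "unit,label",
        [
            ("tc", "tc/ga"),
            ("at", "at"),
            ("cg", "cg"),
            ("ca", "ca/tg"),
            ("gt", "gt/ac"),
            ("tct", "tct/aga"),
        ],
    )
    def test_class_labels(self, unit, label):
        assert canonicalize_motif(unit) == label

    def test_rotational_phases_stay_distinct(self):
        assert canonicalize_motif("ca") != canonicalize_motif("ac")

    def test_non_primitive_unit_is_a_logic_error(self):
        with pytest.raises(ValueError):
            canonicalize_motif("atat")


class TestOracleEquivalence:
    def test_random_sequences_match_brute_force(self, rng):
        for _ in range(30):
            n = int(rng.integers(500, 3000))
            seq = random_dna(rng, n, "acgtn" if rng.random() < 0.3 else "acgt")
            got = _as_tuples(find_ssrs_in_seq("s", seq))
            want = brute_force_ssrs("s", seq, DEFAULT_MIN_REPEATS)
            assert got == want

    def test_maximality_of_every_reported_locus(self, rng):
        for _ in range(10):
            seq = random_dna(rng, 2000)
            for l in find_ssrs_in_seq("s", seq):
                k = l.unit_length
                if l.start >= k:
                    assert seq[l.start - k : l.start] != l.unit
                if l.end + k <= len(seq):
                    assert seq[l.end : l.end + k] != l.unit

    def test_no_locus_contained_in_same_unit_family_locus(self, rng):
        for _ in range(10):
            seq = random_dna(rng, 3000)
            loci = find_ssrs_in_seq("s", seq)
            for a in loci:
                for b in loci:
                    if a is b:
                        continue
                    nested = b.start <= a.start and a.end <= b.end
                    same_family = set(a.unit) == set(b.unit) and (
                        a.unit in b.unit * 2 or b.unit in a.unit * 2
                    )
                    assert not (nested and same_family)


class TestSummary:
    def test_counts_and_lengths_are_conserved(self, rng):
        seq = random_dna(rng, 20000)
        loci = find_ssrs_in_seq("s", seq)
        summary = summarize(loci, len(seq))
        t = summary.table
        total_row = t[t.level == "total"].iloc[0]
        tiers = t[t.level == "tier"]
        classes = t[t.level == "class"]
        assert total_row["count"] == len(loci)
        assert tiers["count"].sum() == len(loci)
        assert classes["count"].sum() == len(loci)
        assert total_row.total_length_bp == sum(l.total_length for l in loci)
        assert tiers.total_length_bp.sum() == total_row.total_length_bp
        assert classes.percent_of_total.sum() == pytest.approx(100.0)
        # unrounded identity: mean * unit_length * count == summed length
        for row in classes.itertuples():
            ulen = len(row.motif.split("/")[0])
            assert row.mean_repeats * ulen * row.count == pytest.approx(
                row.total_length_bp
            )

    def test_single_locus_summary(self):
        locus = SSRLocus("s", 0, 10, "ag", 5, "ag/ct")
        summary = summarize([locus], 1000)
        row = summary.table[summary.table.level == "class"].iloc[0]
        assert row["count"] == 1
        assert row.total_length_bp == 10
        assert row.mean_repeats == 5.0

    def test_empty_locus_list_gives_zero_table(self):
        summary = summarize([], 5000)
        assert summary.n_loci == 0
        assert summary.density_per_mb == 0.0
        assert summary.kb_per_locus is None

    def test_summary_matches_planted_spectrum(self, rng):
        from palmsat.simulate import PlantedSSR, SyntheticGenomeSpec, generate_genome

        planted = [("at", 6), ("at", 8), ("tct", 5), ("ca", 7)]
        spec = SyntheticGenomeSpec(
            length=4000,
            planted_ssrs=tuple(PlantedSSR(u, c) for u, c in planted),
            seed=7,
        )
        genome, truth = generate_genome(spec)
        loci = find_ssrs(genome)
        oracle = brute_force_ssrs("seq0", genome["seq0"], DEFAULT_MIN_REPEATS)
        assert _as_tuples(loci) == oracle
        mined = {(l.start, l.end, l.unit, l.repeat_count) for l in loci}
        for row in truth.itertuples():
            assert (row.start, row.end, row.unit, row.repeat_count) in mined


class TestDensity:
    def test_single_locus_per_mb(self):
        per_mb, spacing = density(1, 1_000_000)
        assert per_mb == 1.0
        assert spacing == 1000.0

    def test_zero_loci(self):
        per_mb, spacing = density(0, 1_000_000)
        assert per_mb == 0.0
        assert spacing is None

    def test_non_positive_length_rejected(self):
        with pytest.raises(ValueError):
            density(5, 0)

    def test_percentage_of_empty_total(self):
        assert percentage(0, 0) == 0.0
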