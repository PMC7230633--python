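"""Homopolymer statistics, RLE collisions, and flank-repeat similarity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strnano.diagnostics import (
    feature_report, flank_repeat_identity, max_homopolymer_run,
    repeat_homopolymer_length, rle_collision_scan, run_length_encode,
)
from strnano.panel import LocusDefinition, RepeatBlock

from ._oracles import edit_distance_dp, max_run_oracle, rle_oracle
from .conftest import random_dna

dna = st.text(alphabet="ACGT", max_size=80)


def str_locus(motif, labels, flank5="", flank3="", **kw):
    return LocusDefinition(
        name="X1", primer_fwd="ACGTAC", primer_rev="ACGTAC",
        flank5=flank5, flank3=flank3,
        repeat_blocks=(RepeatBlock(motif),), allele_labels=labels, **kw,
    )


class TestHomopolymerRun:
    @pytest.mark.parametrize("seq,expected", [
        ("AAAAGAAAAG", 4),   # two tandem CD4 units
        ("AGAAAGAA", 3),     # two tandem D18S51 units: the run spans the junction
        ("ACGT", 1),
        ("", 0),
    ])
    def test_examples(self, seq, expected):
        assert max_homopolymer_run(seq) == expected

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            max_homopolymer_run("ACGN")

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(dna, dna)
    def test_concatenation_never_shrinks_the_max_run(self, x, y):
        assert max_homopolymer_run(x + y) >= max(
            max_homopolymer_run(x), max_homopolymer_run(y)
        )

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(dna)
    def test_agrees_with_oracle(self, x):
        assert max_homopolymer_run(x) == max_run_oracle(x)

    @pytest.mark.parametrize("motif,expected", [
        ("AAAAG", 4),  # CD4
        ("AGAA", 3),   # D18S51
        ("ACGT", 1),
    ])
    def test_repeat_homopolymer_from_two_copy_tandem(self, motif, expected):
        loc = str_locus(motif, ("1", "2"))
        assert repeat_homopolymer_length(loc) == expected

    def test_sequence_locus_not_applicable(self, panel):
        amel = next(l for l in panel if l.is_sequence_locus)
        assert repeat_homopolymer_length(amel) is None


class TestRunLengthEncode:
    @pytest.mark.parametrize("seq,expected", [("AATG", "ATG"), ("AAAAG", "AG"), ("", "")])
    def test_examples(self, seq, expected):
        assert run_length_encode(seq) == expected

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(dna)
    def test_idempotent_shorter_and_no_adjacent_repeats(self, x):
        enc = run_length_encode(x)
        assert run_length_encode(enc) == enc
        assert len(enc) <= len(x)
        assert all(a != b for a, b in zip(enc, enc[1:]))
        assert enc == rle_oracle(x)


class TestRleCollisions:
    def test_th01_fixture_collides_at_nine_point_three(self, panel):
        scan = rle_collision_scan(panel)
        assert {frozenset(p) for p in scan["TH01"]} == {frozenset({"9.3", "10"})}

    def test_pure_locus_without_partials_has_no_collisions(self):
        loc = str_locus("AGAA", tuple(str(i) for i in range(5, 12)))
        assert rle_collision_scan([loc]) == {"X1": []}

    def test_fixture_panel_only_th01_collides(self, panel):
        scan = rle_collision_scan(panel)
        assert [k for k, v in scan.items() if v] == ["TH01"]

    def test_partial_of_run_duplicated_base_always_collides(self):
        """Generalized TH01: when the n.y partial is the motif minus one base
        of a duplicated run, RLE merges n.y with the adjacent full allele."""
        for motif, side in (("AATG", "suffix"), ("GAA", "prefix"), ("CCTA", "suffix")):
            y = len(motif) - 1
            loc = str_locus(
                motif, ("3", "4", f"3.{y}"), partial_side=side, partial_after=2
            )
            scan = rle_collision_scan([loc])["X1"]
            assert (("4", f"3.{y}") in scan) or ((f"3.{y}", "4") in scan)


class TestFlankRepeatIdentity:
    def test_perfect_tandem_flank_scores_one(self):
        loc = str_locus("AGAA", ("1", "2"), flank5="AGAA" * 5)
        assert flank_repeat_identity(loc) == pytest.approx(1.0)

    def test_rotation_invariance_for_perfect_arrays(self):
        motif = "AGAA"
        for shift in range(4):
            rot = motif[shift:] + motif[:shift]
            loc = str_locus(motif, ("1", "2"), flank5=(rot * 6)[:20])
            assert flank_repeat_identity(loc) == pytest.approx(1.0)

    def _baseline(self, motif, length, n=100):
        rng = np.random.default_rng(20200401)
        loc_scores = []
        for _ in range(n):
            loc = str_locus(motif, ("1", "2"), flank5=random_dna(rng, length))
            loc_scores.append(flank_repeat_identity(loc))
        return float(np.mean(loc_scores))

    def test_d18s51_flank_beats_random_baseline(self, panel):
        d18 = next(l for l in panel if l.name == "D18S51")
        obs = flank_repeat_identity(d18)
        assert obs > self._baseline("AGAA", len(d18.flank5))

    def test_d21s11_adjacent_sequence_beats_random_baseline(self, panel):
        d21 = next(l for l in panel if l.name == "D21S11")
        flank = d21.flank5  # the published repeat-adjacent sequence
        loc = str_locus("TCTA", ("1", "2"), flank5=flank)
        obs = flank_repeat_identity(loc)
        assert obs > self._baseline("TCTA", len(flank))

    def test_identity_agrees_with_dp_oracle(self):
        flank = "AAAGAGAGAGGAAAGAAAGAGAAAAAGAAAAGAAATAGTA"
        motif = "AGAA"
        best = max(
            1 - edit_distance_dp(flank, ((motif[i:] + motif[:i]) * 10)[: len(flank)]) / len(flank)
            for i in range(4)
        )
        loc = str_locus(motif, ("1", "2"), flank5=flank)
        assert flank_repeat_identity(loc) == pytest.approx(best)


class TestFeatureReport:
    def test_fixture_rows(self, panel):
        rep = feature_report(panel).set_index("locus")
        assert rep.loc["CD4", "repeat_homopolymer_len"] == 4
        assert rep.loc["D18S51", "repeat_homopolymer_len"] == 3
        assert rep.loc["TPOX", "allele_range_width"] == 5
        amel = rep.loc["AMEL"]
        assert amel["allele_range_width"] == 2
        assert amel.isna()["repeat_homopolymer_len"]
        assert rep.loc["TH01", "rle_collisions"] != ""
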