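"""Stutter ladder statistics, platform error process, and reproducibility."""

import numpy as np
import pytest

from strnano.panel import LocusDefinition, RepeatBlock, build_reference_db
from strnano.simulate import (
    ErrorModel, Genotype, MixtureSpec, Molecule, StutterModel,
    build_amplicon_pool, expected_deletions, get_preset, presets,
    sequence_reads, write_fastq,
)


@pytest.fixture(scope="module")
def one_locus_db():
    loc = LocusDefinition(
        name="L1", primer_fwd="ACGTACGTAC", primer_rev="TACGTACGTA",
        flank5="GGCC", flank3="TTAA",
        repeat_blocks=(RepeatBlock("GATA"),),
        allele_labels=tuple(str(i) for i in range(6, 15)),
    )
    return [loc], build_reference_db([loc])


class TestAmpliconPool:
    def test_no_stutter_all_parents(self, one_locus_db):
        _, db = one_locus_db
        mix = MixtureSpec.single(Genotype("S", {"L1": ("9",)}))
        pool = build_amplicon_pool(mix, db, StutterModel(), depth_per_locus=100, seed=0)
        assert len(pool) == 100
        assert all(m.label == "9" == m.parent_label for m in pool)

    def test_stutter_fraction_matches_binomial_expectation(self, one_locus_db):
        _, db = one_locus_db
        rho = 0.10
        depth = 10_000
        mix = MixtureSpec.single(Genotype("S", {"L1": ("9", "12")}))
        pool = build_amplicon_pool(
            mix, db, StutterModel(rho_minus=rho, rho_plus=0.02),
            depth_per_locus=depth, seed=7,
        )
        for parent, minus in (("9", "8"), ("12", "11")):
            from_parent = [m for m in pool if m.parent_label == parent]
            frac = sum(m.label == minus for m in from_parent) / len(from_parent)
            se = np.sqrt(rho * (1 - rho) / len(from_parent))
            assert abs(frac - rho) < 3 * se

    def test_balanced_mixture_gives_four_equal_alleles(self, one_locus_db):
        _, db = one_locus_db
        depth = 8000
        mix = MixtureSpec.balanced(
            Genotype("P1", {"L1": ("6", "8")}), Genotype("P2", {"L1": ("10", "13")})
        )
        pool = build_amplicon_pool(mix, db, StutterModel(), depth_per_locus=depth, seed=3)
        for lab in ("6", "8", "10", "13"):
            frac = sum(m.label == lab for m in pool) / depth
            se = np.sqrt(0.25 * 0.75 / depth)
            assert abs(frac - 0.25) < 4 * se

    def test_edge_allele_stutter_clamped_to_parent(self, one_locus_db):
        _, db = one_locus_db
        # allele 6 is the range floor: its n-1 product does not exist
        mix = MixtureSpec.single(Genotype("S", {"L1": ("6",)}))
        pool = build_amplicon_pool(
            mix, db, StutterModel(rho_minus=0.3), depth_per_locus=500, seed=1
        )
        assert {m.label for m in pool} <= {"6", "7"}
        assert len(pool) == 500

    def test_zero_bias_everywhere_rejected(self, one_locus_db):
        _, db = one_locus_db
        mix = MixtureSpec.single(Genotype("S", {"L1": ("9",)}))
        with pytest.raises(ValueError, match="bias"):
            build_amplicon_pool(mix, db, representation_bias={"L1": 0.0}, seed=0)

    def test_repeat_scaling_increases_stutter_for_long_alleles(self):
        s = StutterModel(rho_minus=0.1, rho_plus=0.02, repeat_scaling=0.1, pivot=10)
        assert s.rates_for(20)[0] > s.rates_for(10)[0] == 0.1


class TestSequenceReads:
    def test_zero_error_reads_equal_molecules(self, one_locus_db):
        _, db = one_locus_db
        mix = MixtureSpec.single(Genotype("S", {"L1": ("9",)}))
        pool = build_amplicon_pool(mix, db, depth_per_locus=50, seed=0)
        reads, truth = sequence_reads(pool, ErrorModel(), seed=0, rc_fraction=0.0)
        assert [r.sequence for r in reads] == [m.sequence for m in pool]
        assert list(truth["allele"].unique()) == ["9"]

    def test_same_seed_byte_identical_fastq(self, one_locus_db, tmp_path):
        _, db = one_locus_db
        mix = MixtureSpec.single(Genotype("S", {"L1": ("9", "11")}))
        blobs = []
        for run in range(2):
            pool = build_amplicon_pool(mix, db, StutterModel(0.1, 0.02), 200, seed=42)
            reads, _ = sequence_reads(pool, get_preset("long-noisy"), seed=99, rc_fraction=0.5)
            p = tmp_path / f"run{run}.fastq"
            write_fastq(reads, p)
            blobs.append(p.read_bytes())
        assert blobs[0] == blobs[1]

    def test_homopolymer_sequences_lose_more_bases(self, rng):
        """Mean observed deletions in a homopolymer-rich sequence exceed the
        homopolymer-free one and match the model's own closed form."""
        error = ErrorModel(p_del=0.01, homopolymer_factor=3, homopolymer_cap=8)
        hp = "ACGT" * 4 + "AAAAAA" + "ACGT" * 4  # one 6-run
        flat = ("ACGT" * 10)[: len(hp)]  # homopolymer-free, same length
        assert expected_deletions(hp, error) > expected_deletions(flat, error)
        n = 10_000
        dels = {}
        for name, seq in (("hp", hp), ("flat", flat)):
            reads, _ = sequence_reads(
                [Molecule("L", "1", "1", "S", seq)] * n, error, seed=rng, rc_fraction=0.0
            )
            dels[name] = sum(len(seq) - len(r.sequence) for r in reads) / n
        assert dels["hp"] > dels["flat"]
        assert dels["hp"] == pytest.approx(expected_deletions(hp, error), rel=0.15)

    def test_truth_table_is_the_side_channel(self, one_locus_db):
        _, db = one_locus_db
        mix = MixtureSpec.single(Genotype("S", {"L1": ("9",)}))
        pool = build_amplicon_pool(mix, db, depth_per_locus=5, seed=0)
        reads, truth = sequence_reads(pool, ErrorModel(), seed=0)
        for r in reads:
            assert "L1" not in r.read_id and "9" not in r.read_id.lstrip("read0")
        assert set(truth.columns) >= {"read_id", "locus", "allele", "parent_allele", "contributor"}


class TestPresetsAndValidation:
    def test_both_presets_exist_and_are_ordered(self):
        p = presets()
        assert {"short-accurate", "long-noisy"} <= set(p)
        assert p["long-noisy"].total_error > p["short-accurate"].total_error
        assert p["long-noisy"].homopolymer_factor > 1

    def test_unknown_preset_raises(self):
        with pytest.raises(KeyError, match="unknown"):
            get_preset("nanopore-r7")

    def test_error_model_config_round_trip(self, tmp_path):
        m = get_preset("long-noisy")
        p = tmp_path / "model.json"
        m.to_config(p)
        assert ErrorModel.from_config(p) == m

    @pytest.mark.parametrize("kw", [
        {"p_sub": 1.0}, {"p_del": -0.1},
        {"p_del": 0.3, "homopolymer_factor": 5, "homopolymer_cap": 8},
    ])
    def test_invalid_error_models_rejected(self, kw):
        with pytest.raises(ValueError):
            ErrorModel(**kw)

    def test_stutter_fractions_must_stay_below_one(self):
        with pytest.raises(ValueError):
            StutterModel(rho_minus=0.6, rho_plus=0.5)

    def test_mixture_weights_validated(self, genotypes):
        with pytest.raises(ValueError, match="sum to 1"):
            MixtureSpec(((genotypes["A"], 0.5), (genotypes["B"], 0.2)))
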