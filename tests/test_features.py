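import numpy as np
import pytest

from mirhairpin import (
    FEATURE_NAMES,
    FoldConfig,
    RnaSequence,
    SecondaryStructure,
    analyze_structure,
    extract_all,
    extract_features,
    fold_mfe,
)
from mirhairpin.exceptions import DataError
from mirhairpin.features import (
    TRIPLET_NAMES,
    HairpinFeaturizer,
    basepair_features,
    sequential_features,
    thermodynamic_features,
    triplet_features,
)

from conftest import random_rna
from oracles import triplet_count_by_windows


def structure_of(db: str, mfe: float = 0.0) -> SecondaryStructure:
    return SecondaryStructure.from_dotbracket(db, mfe=mfe)


class TestCanonicalSchema:
    def test_54_features_in_five_groups(self):
        assert len(FEATURE_NAMES) == 54
        assert len(TRIPLET_NAMES) == 32
        assert len(set(FEATURE_NAMES)) == 54

    def test_triplet_keys_are_nucleotide_times_pairing_pattern(self):
        assert len({name[0] for name in TRIPLET_NAMES}) == 4
        assert len({name[1:] for name in TRIPLET_NAMES}) == 8


class TestTriplets:
    def test_homogeneous_open_chain(self):
        values = triplet_features(RnaSequence("a", "AAAA"), structure_of("...."))
        by_name = dict(zip(TRIPLET_NAMES, values))
        assert by_name["A..."] == 1.0
        assert values.sum() == pytest.approx(1.0)

    def test_matches_sliding_window_oracle_on_random_folds(self, fold_config):
        rng = np.random.default_rng(21)
        for _ in range(30):
            seq = RnaSequence("r", random_rna(rng, int(rng.integers(9, 50))))
            structure = fold_mfe(seq, fold_config)
            values = triplet_features(seq, structure)
            expected = triplet_count_by_windows(seq.residues, structure.dotbracket)
            L = len(seq)
            for name, v in zip(TRIPLET_NAMES, values):
                assert v == pytest.approx(expected.get(name, 0) / (L - 2))
            assert values.sum() == pytest.approx(1.0)

    def test_both_bracket_directions_count_as_paired(self):
        seq = RnaSequence("h", "GGGAAACCC")
        values = dict(zip(TRIPLET_NAMES, triplet_features(seq, structure_of("(((...)))"))))
        assert values["C((("] == pytest.approx(1 / 7)  # the closing side's C


class TestSequential:
    @pytest.mark.parametrize(
        "seq,expected", [("GGCC", 100.0), ("AUAU", 0.0), ("GACU", 50.0)]
    )
    def test_gc_content(self, seq, expected):
        stats = analyze_structure(structure_of("." * len(seq)))
        assert sequential_features(RnaSequence("s", seq), stats)["%G+C"] == expected

    def test_lengths_copied_from_structure_stats(self):
        seq = RnaSequence("h", "GGGGAAACCCC")
        stats = analyze_structure(structure_of("((((...))))"))
        out = sequential_features(seq, stats)
        assert out["sequence length"] == 11.0
        assert out["hairpin length"] == 11.0
        assert out["loop length"] == 3.0


class TestThermodynamic:
    def test_direct_arithmetic(self):
        seq = RnaSequence("h", "GGGGAAACCCC")
        structure = structure_of("((((...))))", mfe=-5.5)
        stats = analyze_structure(structure)
        out = thermodynamic_features(seq, structure, stats, shuffles=5, seed=0)
        assert out["dP"] == pytest.approx(4 / 11)
        assert out["dG"] == pytest.approx(-0.5)
        assert out["MFEI_4"] == pytest.approx(-5.5 / 4)
        assert out["MFEI_2"] == pytest.approx(-0.5 / 1)  # one 4-pair stem
        assert out["MFEI_3"] == pytest.approx(-0.5 / 1)  # one terminal loop

    def test_homopolymer_shuffle_guard_returns_zero(self):
        seq = RnaSequence("a", "AAAAAAAAAA")
        structure = fold_mfe(seq)
        stats = analyze_structure(structure)
        flags: dict = {}
        out = thermodynamic_features(seq, structure, stats, shuffles=10, seed=0, flags=flags)
        assert out["zP"] == 0.0 and out["zG"] == 0.0
        assert flags["zP"] == "zero_shuffle_sd" and flags["zG"] == "zero_shuffle_sd"

    def test_zscores_reproducible_under_seed(self, fold_config):
        rng = np.random.default_rng(33)
        seq = RnaSequence("r", random_rna(rng, 60))
        structure = fold_mfe(seq, fold_config)
        stats = analyze_structure(structure)
        a = thermodynamic_features(seq, structure, stats, shuffles=100, seed=5)
        b = thermodynamic_features(seq, structure, stats, shuffles=100, seed=5)
        assert a == b


class TestBasePair:
    def test_all_gc_stem(self):
        seq = RnaSequence("h", "GGGAAACCC")
        structure = structure_of("(((...)))")
        out = basepair_features(seq, structure, analyze_structure(structure))
        assert out["|G-C|/L"] == pytest.approx(3 / 9)
        assert out["|A-U|/L"] == 0.0 and out["|G-U|/L"] == 0.0

    def test_avg_bp_stem_on_perfect_stem(self):
        seq = RnaSequence("h", "GGGGAAACCCC")
        structure = structure_of("((((...))))")
        out = basepair_features(seq, structure, analyze_structure(structure))
        assert out["Avg_BP_Stem"] == 4.0
        assert out["ConsecBP"] == 4.0

    def test_pair_type_counts_conserve_total_pairs(self, fold_config):
        rng = np.random.default_rng(8)
        for _ in range(30):
            seq = RnaSequence("r", random_rna(rng, int(rng.integers(10, 60))))
            structure = fold_mfe(seq, fold_config)
            out = basepair_features(seq, structure, analyze_structure(structure))
            total = (out["|A-U|/L"] + out["|G-C|/L"] + out["|G-U|/L"]) * len(seq)
            assert total == pytest.approx(structure.n_bp)

    def test_noncanonical_pair_from_external_structure_rejected(self):
        seq = RnaSequence("h", "AAAAAACCC")  # would pair A with C
        structure = structure_of("(((...)))")
        with pytest.raises(DataError, match="non-canonical"):
            basepair_features(seq, structure, analyze_structure(structure))


class TestExtractAll:
    def test_vector_is_54_deterministic_and_normalised(self):
        seq = RnaSequence("h", "GGGCGGUAGCAAAAGCUACCGCCC")
        a = extract_all(seq, shuffles=20, seed=3)
        b = extract_all(seq, shuffles=20, seed=3)
        assert a.values.shape == (54,)
        assert np.array_equal(a.values, b.values)
        assert a.values[:32].sum() == pytest.approx(1.0)

    def test_short_sequences_rejected(self):
        with pytest.raises(DataError):
            extract_all(RnaSequence("s", "AC"), shuffles=5)

    def test_no_nonfinite_values_on_random_batch(self, fold_config):
        rng = np.random.default_rng(9)
        seqs = [
            RnaSequence(f"r{k}", random_rna(rng, int(rng.integers(5, 50))))
            for k in range(200)
        ]
        table = extract_features(seqs, shuffles=5, seed=2)
        assert np.isfinite(table.to_numpy()).all()
        assert list(table.columns) == list(FEATURE_NAMES)

    def test_dP_bounded_and_au_gc_gu_sum_to_dP(self, fold_config):
        rng = np.random.default_rng(10)
        seqs = [RnaSequence(f"r{k}", random_rna(rng, 40)) for k in range(30)]
        table = extract_features(seqs, shuffles=5, seed=2)
        dP = table["dP"]
        assert ((dP >= 0) & (dP <= 0.5)).all()
        total = table["|A-U|/L"] + table["|G-C|/L"] + table["|G-U|/L"]
        assert np.allclose(total, dP)

    def test_avg_bp_stem_at_least_four_when_stems_exist(self):
        from mirhairpin import generate_synthetic_hairpins

        seqs = generate_synthetic_hairpins(20, seed=17)
        table = extract_features(seqs, shuffles=5, seed=2)
        with_stems = table[table["Avg_BP_Stem"] > 0]
        assert (with_stems["Avg_BP_Stem"] >= 4).all()


class TestFeaturizer:
    def test_batch_equals_record_by_record(self):
        from mirhairpin import generate_synthetic_hairpins

        seqs = generate_synthetic_hairpins(6, seed=19)
        featurizer = HairpinFeaturizer(shuffles=20, random_state=7)
        batch = featurizer.fit(seqs).transform(seqs)
        singles = np.vstack([featurizer.transform([s]) for s in seqs])
        assert np.array_equal(batch, singles)

    def test_sklearn_params_roundtrip(self):
        featurizer = HairpinFeaturizer(shuffles=10, random_state=3)
        params = featurizer.get_params()
        clone = HairpinFeaturizer(**params)
        assert clone.get_params() == params
        assert list(featurizer.fit([]).get_feature_names_out()) == list(FEATURE_NAMES)
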