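import math

import numpy as np
import pytest

from conftest import random_rna
from rnathermscan import (RnaSequence, SecondaryStructure, centroid_structure,
                          enumerate_structures, fold, fold_mfe,
                          partition_function, score_structure)
from rnathermscan.energy import GAS_CONSTANT, PAIR_TYPES, Temperature
from rnathermscan.errors import EngineError, SequenceError, StructureError
from rnathermscan.folding import PairProbMatrix


def count_structures(residues: str) -> int:
    """Independent counting recursion (no enumeration, no shared code path)."""
    canonical = {"AU", "UA", "CG", "GC", "GU", "UG"}
    n = len(residues)
    memo = {}

    def c(i, j):
        if j - i < 4:
            return 1
        if (i, j) not in memo:
            total = c(i + 1, j)
            for k in range(i + 4, j + 1):
                if residues[i] + residues[k] in canonical:
                    total += c(i + 1, k - 1) * c(k + 1, j)
            memo[(i, j)] = total
        return memo[(i, j)]

    return c(0, n - 1)


class TestScoreStructure:
    def test_open_chain_scores_zero(self, params):
        seq = RnaSequence("x", "ACGUACGUA")
        s = SecondaryStructure.open_chain(9)
        assert score_structure(seq, s, 37.0, params) == 0.0

    def test_hand_summed_stem_loop(self, params):
        # GGGAAACCC with pairs (1,9),(2,8),(3,7): two stacks + size-3 hairpin
        seq = RnaSequence("x", "GGGAAACCC")
        s = SecondaryStructure(length=9, pairs=frozenset({(1, 9), (2, 8), (3, 7)}))
        expected = (params.stack_dH[("GC", "GC")] - 310.15 * params.stack_dS[("GC", "GC")]) * 2 \
            + params.hairpin_dG37[3]
        assert score_structure(seq, s, 37.0, params) == pytest.approx(expected)

    def test_temperature_additivity(self, params):
        seq = RnaSequence("x", "GGGAAACCC")
        s = SecondaryStructure(length=9, pairs=frozenset({(1, 9), (2, 8), (3, 7)}))
        d_total = score_structure(seq, s, 45.0, params) - score_structure(seq, s, 30.0, params)
        ctx = ("GC", "GC")
        d_stack = (45.0 - 30.0) * -params.stack_dS[ctx]
        d_loop = (Temperature(45.0).kelvin - Temperature(30.0).kelvin) / 310.15 \
            * params.hairpin_dG37[3]
        assert d_total == pytest.approx(2 * d_stack + d_loop)

    def test_internal_loop_and_bulge_terms(self, params):
        # (1,12) directly encloses (3,10): internal loop of 1+1=2 unpaired
        seq = RnaSequence("x", "GAGGAAAACCUC")
        s = SecondaryStructure(length=12, pairs=frozenset({(1, 12), (3, 10)}))
        expected = params.loop_dG37[2] + params.hairpin_dG37[6]
        assert score_structure(seq, s, 37.0, params) == pytest.approx(expected)

    def test_invalid_structure_rejected(self, params):
        seq = RnaSequence("x", "AAAAAAAAA")
        s = SecondaryStructure(length=9, pairs=frozenset({(1, 9)}))  # A-A pair
        with pytest.raises(StructureError):
            score_structure(seq, s, 37.0, params)


class TestEnumerate:
    def test_no_canonical_pairs_gives_open_chain_only(self):
        assert len(enumerate_structures(RnaSequence("x", "AAAA"))) == 1

    def test_single_possible_pair(self):
        structs = enumerate_structures(RnaSequence("x", "GAAAC"))
        assert {s.pairs for s in structs} == {frozenset(), frozenset({(1, 5)})}

    @pytest.mark.parametrize("seq", ["GGAAACC", "GCGCAAAGCGC", "ACGUACGUACGU"])
    def test_count_matches_independent_recursion(self, seq):
        structs = enumerate_structures(RnaSequence("x", seq))
        assert len(structs) == count_structures(seq)
        assert len({s.pairs for s in structs}) == len(structs)  # duplicate-free

    def test_refuses_long_sequences(self):
        with pytest.raises(SequenceError):
            enumerate_structures(RnaSequence("x", "A" * 21))


class TestFoldMfe:
    def test_unpairable_sequence_stays_open(self, params):
        r = fold_mfe(RnaSequence("x", "AAAAAAAA"), 37.0, params)
        assert r.structure.pairs == frozenset()
        assert r.energy == 0.0

    @pytest.mark.parametrize("temp", [25.0, 37.0, 55.0])
    def test_equals_bruteforce_minimum(self, params, temp):
        rng = np.random.default_rng(int(temp))
        for _ in range(25):
            seq = random_rna(rng, int(rng.integers(8, 15)))
            structs = enumerate_structures(seq)
            best = min(score_structure(seq, s, temp, params) for s in structs)
            got = fold_mfe(seq, temp, params)
            assert got.energy == pytest.approx(best, abs=1e-9)
            # reported energy must equal the score of the returned structure
            assert score_structure(seq, got.structure, temp, params) == \
                pytest.approx(got.energy, abs=1e-9)

    def test_energy_never_positive(self, params):
        rng = np.random.default_rng(3)
        for _ in range(20):
            seq = random_rna(rng, 30)
            assert fold_mfe(seq, 37.0, params).energy <= 0.0

    def test_designed_hairpin_melts(self, params):
        from rnathermscan import ThermometerSpec, design_hairpin
        spec = ThermometerSpec(stem_length=10, loop_length=4,
                               tm_low=37.0, tm_high=42.0, seed=5)
        seq_str, tm, designed = design_hairpin(spec, params)
        seq = RnaSequence("hp", seq_str)
        cold = fold_mfe(seq, tm - 4.0, params)
        hot = fold_mfe(seq, tm + 4.0, params)
        assert cold.structure.pairs == designed.pairs
        assert cold.energy < 0
        assert hot.structure.pairs == frozenset()
        # energy of the designed structure changes sign across Tm
        assert score_structure(seq, designed, tm - 4.0, params) < 0
        assert score_structure(seq, designed, tm + 4.0, params) > 0

    def test_traceback_deterministic(self, params):
        rng = np.random.default_rng(11)
        seq = random_rna(rng, 60)
        a = fold_mfe(seq, 37.0, params)
        b = fold_mfe(seq, 37.0, params)
        assert a.structure == b.structure


class TestPartitionFunction:
    def test_unpairable_sequence(self, params):
        Z, probs = partition_function(RnaSequence("x", "AAAA"), 37.0, params)
        assert Z == pytest.approx(1.0)
        assert list(probs.items()) == []

    def test_matches_boltzmann_sum_over_enumeration(self, params):
        rng = np.random.default_rng(17)
        temp = 37.0
        rt = GAS_CONSTANT * Temperature(temp).kelvin
        for _ in range(15):
            seq = random_rna(rng, int(rng.integers(6, 13)))
            structs = enumerate_structures(seq)
            w = [math.exp(-score_structure(seq, s, temp, params) / rt)
                 for s in structs]
            z_ref = sum(w)
            Z, probs = partition_function(seq, temp, params)
            assert Z == pytest.approx(z_ref, rel=1e-9)
            for i in range(1, seq.length + 1):
                for j in range(i + 1, seq.length + 1):
                    p_ref = sum(wk for s, wk in zip(structs, w)
                                if (i, j) in s.pairs) / z_ref
                    assert probs.get(i, j) == pytest.approx(p_ref, rel=1e-9, abs=1e-12)

    def test_mfe_weight_bounded_by_z(self, params):
        rng = np.random.default_rng(23)
        for _ in range(10):
            seq = random_rna(rng, 25)
            e = fold_mfe(seq, 37.0, params).energy
            Z, _ = partition_function(seq, 37.0, params)
            w = math.exp(-e / (GAS_CONSTANT * 310.15))
            assert w <= Z * (1 + 1e-12)

    def test_two_state_hairpin_weight_is_temperature_invariant(self, params):
        # GAAAC has two structures (open chain and the lone G1-C5 pair whose
        # only energy term is the entropic hairpin loop), so E/RT — and with
        # it the pair probability — is the same at every temperature
        w = math.exp(-params.hairpin_dG37[3] / (GAS_CONSTANT * 310.15))
        expected = w / (1 + w)
        for t in (10.0, 37.0, 90.0):
            _, probs = partition_function(RnaSequence("x", "GAAAC"), t, params)
            assert probs.get(1, 5) == pytest.approx(expected, rel=1e-9)

    def test_probabilities_satisfy_row_sums(self, params):
        rng = np.random.default_rng(29)
        for _ in range(5):
            seq = random_rna(rng, 40)
            _, probs = partition_function(seq, 37.0, params)
            probs.validate()


class TestCentroid:
    def test_all_below_half_gives_open_chain(self):
        p = np.zeros((6, 6))
        p[0, 5] = 0.4
        s = centroid_structure(PairProbMatrix(n=6, _p=p))
        assert s.pairs == frozenset()

    def test_thresholding(self):
        p = np.zeros((9, 9))
        p[0, 8] = 0.9
        p[1, 7] = 0.7
        p[2, 6] = 0.49
        s = centroid_structure(PairProbMatrix(n=9, _p=p))
        assert s.pairs == frozenset({(1, 9), (2, 8)})

    def test_centroid_valid_on_random_ensembles(self, params):
        rng = np.random.default_rng(31)
        for _ in range(25):
            seq = random_rna(rng, int(rng.integers(6, 13)))
            _, probs = partition_function(seq, 37.0, params)
            s = centroid_structure(probs)  # constructor enforces invariants
            assert s.length == seq.length

    def test_monotone_melting_of_designed_hairpin(self, params):
        from rnathermscan import ThermometerSpec, design_hairpin
        spec = ThermometerSpec(stem_length=9, loop_length=4,
                               tm_low=37.0, tm_high=42.0, seed=2)
        seq_str, tm, designed = design_hairpin(spec, params)
        seq = RnaSequence("hp", seq_str)
        closing = min(designed.pairs)
        last = 1.1
        for t in np.linspace(tm - 12, tm + 12, 7):
            _, probs = partition_function(seq, float(t), params)
            p = probs.get(*closing)
            assert p <= last + 1e-9
            last = p


class TestFoldDispatch:
    def test_builtin_centroid_on_unpairable(self, params):
        r = fold(RnaSequence("x", "AAAA"), 37.0, mode="centroid")
        assert r.structure.pairs == frozenset()
        assert r.energy == 0.0

    def test_unknown_mode(self):
        with pytest.raises(EngineError):
            fold(RnaSequence("x", "ACGU"), 37.0, mode="suboptimal")

    def test_unknown_engine(self):
        with pytest.raises(EngineError):
            fold(RnaSequence("x", "GGGAAACCC"), 37.0, engine="no-such-engine")

    def test_vienna_adapter_contract(self):
        # external engine: only the structural contract is asserted — the
        # full Turner model will generally disagree with the reduced model
        pytest.importorskip("RNA")
        seq = RnaSequence("x", "GGGGAAAACCCC")
        for mode in ("mfe", "centroid"):
            r = fold(seq, 30.0, mode=mode, engine="vienna")
            assert r.structure.length == seq.length
            assert r.temperature.celsius == 30.0
            assert r.engine == "vienna"

    def test_registered_custom_engine_and_bad_output(self):
        from rnathermscan.engines import register_engine
        register_engine("const", lambda s, t, m: ("." * len(s), 0.0))
        r = fold(RnaSequence("x", "GGGAAACCC"), 37.0, engine="const")
        assert r.structure.pairs == frozenset()
        register_engine("broken", lambda s, t, m: ("((((", -1.0))
        with pytest.raises(EngineError):
            fold(RnaSequence("x", "GGGAAACCC"), 37.0, engine="broken")
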