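"""Thermodynamics engine: explicit-structure energies, exhaustive-enumeration
oracle agreement, partition functions, and the tube equilibrium solver."""

import math
import random

import numpy as np
import pytest

from swtkit.core_seq import reverse_complement
from swtkit.thermo import (
    EnergyModel,
    NumericalError,
    SecondaryStructure,
    StructureError,
    TubeSpec,
    duplex_dG,
    enumerate_structures,
    equilibrium_concentrations,
    fold_mfe,
    fold_mfe_dimer,
    is_unstructured,
    mfe_energy,
    partition_function,
    structure_energy,
)


@pytest.fixture(scope="module")
def m():
    return EnergyModel.default()


def random_rna(rng, n):
    return "".join(rng.choice("ACGU") for _ in range(n))


class TestEnergyModel:
    def test_rt_follows_temperature(self, m):
        assert m.RT == pytest.approx(0.0019872 * 310.15)
        cold = EnergyModel.default(temperature=300.0)
        assert cold.RT < m.RT

    def test_stack_table_symmetry(self, m):
        # stack(p1, p2) must equal stack(flip(p2), flip(p1)): the same duplex
        # motif read from the other strand
        flip = {0: 1, 1: 0, 2: 3, 3: 2, 4: 5, 5: 4}
        for p1 in range(6):
            for p2 in range(6):
                assert m.stack[p1, p2] == pytest.approx(
                    m.stack[flip[p2], flip[p1]])

    def test_hairpin_below_minimum_undefined(self, m):
        with pytest.raises(StructureError):
            m.hairpin_dG(2)


class TestSecondaryStructure:
    def test_dot_bracket_round_trip(self):
        s = SecondaryStructure.from_dot_bracket("((..))..&..()")
        assert s.nick == 8
        assert SecondaryStructure.from_dot_bracket(s.dot_bracket) == s

    def test_pseudoknot_rejected(self):
        with pytest.raises(StructureError, match="cross"):
            SecondaryStructure(strand_lengths=(8,),
                               pairs=frozenset({(0, 4), (2, 6)}))

    def test_duplicate_index_rejected(self):
        with pytest.raises(StructureError):
            SecondaryStructure(strand_lengths=(8,),
                               pairs=frozenset({(0, 4), (0, 6)}))


class TestStructureEnergy:
    def test_open_chain_is_reference_zero(self, m):
        s = SecondaryStructure(strand_lengths=(12,), pairs=frozenset())
        assert structure_energy("GGGGAAAACCCC", s, m) == 0.0

    def test_hairpin_hand_sum(self, m):
        # three stacked G-C/G-C stacks plus the 4-nt hairpin initiation
        s = SecondaryStructure.from_dot_bracket("((((....))))")
        e = structure_energy("GGGGAAAACCCC", s, m)
        expected = 3 * m.stack[3, 3] + m.hairpin_dG(4)
        assert e == pytest.approx(expected)

    def test_full_duplex_hand_sum(self, m):
        # GGGG.CCCC duplex: three G-C/G-C stacks + duplex initiation
        s = SecondaryStructure.from_dot_bracket("((((&))))")
        e = structure_energy(["GGGG", "CCCC"], s, m)
        assert e == pytest.approx(3 * m.stack[3, 3] + m.duplex_init)

    def test_undersized_hairpin_rejected(self, m):
        s = SecondaryStructure(strand_lengths=(6,), pairs=frozenset({(0, 3)}))
        with pytest.raises(StructureError):
            structure_energy("GAAAAC", s, m)

    def test_disconnected_dimer_rejected(self, m):
        s = SecondaryStructure.from_dot_bracket("(....)&....")
        with pytest.raises(StructureError, match="inter-strand"):
            structure_energy(["GAAAAC", "AAAA"], s, m)


class TestFoldMFE:
    def test_poly_a_open(self, m):
        struct, dG = fold_mfe("AAAAAAAA", m)
        assert dG == 0.0 and not struct.pairs

    def test_gc_hairpin(self, m):
        struct, dG = fold_mfe("GGGGAAAACCCC", m)
        assert struct.dot_bracket == "((((....))))"
        assert dG == pytest.approx(3 * m.stack[3, 3] + m.hairpin_dG(4))

    def test_traceback_energy_consistent(self, m):
        rng = random.Random(11)
        for _ in range(25):
            seq = random_rna(rng, rng.randint(10, 40))
            struct, dG = fold_mfe(seq, m)
            assert structure_energy(seq, struct, m) == pytest.approx(dG, abs=1e-6)


class TestEnumerationOracle:
    """The DP algorithms against brute-force enumeration (the independent
    oracle) on short random inputs."""

    def test_acgu_only_open_chain(self, m):
        structs = enumerate_structures("ACGU", m)
        assert len(structs) == 1 and structs[0][1] == 0.0

    def test_known_hairpin_member(self, m):
        dbs = {s.dot_bracket for s, _ in enumerate_structures("GGGAAACCC", m)}
        assert "(((...)))" in dbs

    def test_enumeration_count_matches_recursive_counter(self, m):
        # independent pair-based recursion counting valid structures
        seq = "GCGCAAAGCGC"

        def count(i, j):
            if j - i < 4:
                return 1
            total = count(i + 1, j)
            for k in range(i + 4, j + 1):
                if m.can_pair(seq[i], seq[k]):
                    total += count(i + 1, k - 1) * count(k + 1, j)
            return total

        assert len(enumerate_structures(seq, m)) == count(0, len(seq) - 1)

    def test_over_length_guarded(self, m):
        with pytest.raises(StructureError):
            enumerate_structures("A" * 21, m)

    def test_single_strand_pf_and_mfe_match_oracle(self, m):
        rng = random.Random(2024)
        for _ in range(30):
            seq = random_rna(rng, rng.randint(6, 15))
            structs = enumerate_structures(seq, m)
            q_ref = sum(math.exp(-e / m.RT) for _, e in structs)
            q_dp, _ = partition_function(seq, m)
            assert q_dp == pytest.approx(q_ref, rel=1e-9)
            assert fold_mfe(seq, m)[1] == pytest.approx(
                min(e for _, e in structs), abs=1e-9)

    def test_dimer_pf_and_mfe_match_oracle(self, m):
        rng = random.Random(99)
        for _ in range(30):
            a = random_rna(rng, rng.randint(3, 8))
            b = random_rna(rng, rng.randint(3, 8))
            structs = enumerate_structures([a, b], m)
            q_dp, dg = partition_function([a, b], m)
            if not structs:
                assert q_dp == 0.0 and dg == math.inf
                continue
            q_ref = sum(math.exp(-e / m.RT) for _, e in structs)
            assert q_dp == pytest.approx(q_ref, rel=1e-9)
            assert mfe_energy([a, b], m) == pytest.approx(
                min(e for _, e in structs), abs=1e-9)

    def test_dimer_traceback_structure_is_optimal(self, m):
        rng = random.Random(7)
        for _ in range(20):
            a = random_rna(rng, rng.randint(4, 8))
            b = random_rna(rng, rng.randint(4, 8))
            struct, e = fold_mfe_dimer(a, b, m)
            if struct is None:
                assert not enumerate_structures([a, b], m)
                continue
            assert structure_energy([a, b], struct, m) == pytest.approx(e, abs=1e-9)


class TestPartitionFunction:
    def test_poly_a_trivial(self, m):
        assert partition_function("AAAA", m) == (1.0, 0.0)

    def test_colder_ensemble_weighs_structure_more(self, m):
        seq = "GGGGAAAACCCC"
        q_warm, _ = partition_function(seq, m)
        q_cold, _ = partition_function(seq, EnergyModel.default(temperature=300.0))
        assert q_cold > q_warm

    def test_ensemble_below_mfe(self, m):
        rng = random.Random(5)
        for _ in range(10):
            seq = random_rna(rng, 20)
            _, dg_ens = partition_function(seq, m)
            assert dg_ens <= fold_mfe(seq, m)[1] + 1e-9

    def test_duplex_symmetry(self, m):
        rng = random.Random(6)
        a, b = random_rna(rng, 15), random_rna(rng, 12)
        assert duplex_dG(a, b, m) == pytest.approx(duplex_dG(b, a, m), rel=1e-9)


class TestScreeningBounds:
    def test_complementary_run_length(self, m):
        # GGGG vs CCCC: a 4-bp WC run; wobble included adds G.U options
        from swtkit.thermo import longest_complementary_run

        assert longest_complementary_run("GGGG", "CCCC", m) == 4
        assert longest_complementary_run("AAAA", "CCCC", m) == 0
        assert longest_complementary_run("GGGG", "UUUU", m) == 0
        assert longest_complementary_run(
            "GGGG", "UUUU", m, include_wobble=True) == 4

    def test_perfect_duplex_run(self, m):
        rng = random.Random(4)
        seq = random_rna(rng, 12)
        from swtkit.thermo import longest_complementary_run

        assert longest_complementary_run(seq, reverse_complement(seq), m) == 12

    def test_helix_bound_upper_bounds_dimer_ensemble(self, m):
        from swtkit.thermo import best_cross_helix_bound

        rng = random.Random(21)
        for _ in range(15):
            a = random_rna(rng, rng.randint(10, 25))
            b = random_rna(rng, rng.randint(10, 25))
            bound = best_cross_helix_bound(a, b, m)
            dg = duplex_dG(a, b, m)
            if math.isfinite(dg):
                assert dg <= bound + 1e-9


class TestIsUnstructured:
    def test_poly_a(self, m):
        rep = is_unstructured("AAAAAAAAAA", m)
        assert rep and rep.mfe_dot_bracket == "" and rep.mfe_dG == 0.0

    def test_hairpin_reported(self, m):
        rep = is_unstructured("GGGGAAAACCCC", m)
        assert not rep
        assert rep.mfe_dot_bracket == "((((....))))"
        assert rep.mfe_dG < 0


class TestEquilibrium:
    def test_lone_species_stays_free(self, m):
        res = equilibrium_concentrations(
            TubeSpec(species=(("a", "AAAAAAAA"),)), m)
        assert res.free_fraction["a"] == pytest.approx(1.0)
        assert res.residual < 1e-9

    def test_two_state_closed_form(self, m):
        rng = np.random.default_rng(1)
        a = "".join(rng.choice(list("ACGU"), 20))
        b = reverse_complement(a)
        res = equilibrium_concentrations(TubeSpec(species=(("A", a), ("B", b))), m)
        dg_a = partition_function(a, m)[1]
        dg_b = partition_function(b, m)[1]
        K = math.exp(-(duplex_dG(a, b, m) - dg_a - dg_b) / m.RT)
        c = 1e-8
        x = ((2 * c + 1 / K) - math.sqrt((2 * c + 1 / K) ** 2 - 4 * c * c)) / 2
        assert res.dimers[("A", "B")] == pytest.approx(x, rel=1e-6)

    def test_mass_conservation_random_tubes(self, m):
        rng = random.Random(42)
        for _ in range(6):
            species = tuple(
                (f"s{i}", random_rna(rng, rng.randint(8, 18))) for i in range(5))
            conc = tuple(rng.uniform(1e-9, 1e-7) for _ in species)
            res = equilibrium_concentrations(
                TubeSpec(species=species, concentrations=conc), m)
            assert res.residual < 1e-9

    def test_bound_fraction_monotone_in_concentration(self, m):
        rng = np.random.default_rng(3)
        a = "".join(rng.choice(list("ACGU"), 12))
        b = reverse_complement(a)
        fracs = []
        for c in (1e-9, 2e-9, 4e-9):
            res = equilibrium_concentrations(
                TubeSpec(species=(("A", a), ("B", b)),
                         concentrations=(c, c)), m)
            fracs.append(res.bound_fraction("A", "B"))
        assert fracs[0] <= fracs[1] <= fracs[2]

    def test_max_complex_size_one_keeps_monomers(self, m):
        rng = np.random.default_rng(4)
        a = "".join(rng.choice(list("ACGU"), 15))
        b = reverse_complement(a)
        res = equilibrium_concentrations(
            TubeSpec(species=(("A", a), ("B", b)), max_complex_size=1), m)
        assert res.free_fraction["A"] == pytest.approx(1.0)
        assert not res.dimers

    def test_invalid_tube_spec(self):
        with pytest.raises(ValueError):
            TubeSpec(species=(("a", "ACGU"),), max_complex_size=3)
        with pytest.raises(ValueError):
            TubeSpec(species=(("a", "ACGU"), ("a", "GGGG")))
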