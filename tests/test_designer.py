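"""Design loop: constraint sampling, candidate diagnostics, activation
scoring, crosstalk matrices and the multi-tube defect."""

import numpy as np
import pytest

from swtkit.core_seq import (
    ConstraintError,
    TriggerMode,
    derive_trigger,
    gc_fraction,
    reverse_complement,
)
from swtkit.designer import (
    CandidatePair,
    CrosstalkMatrix,
    DesignConstraints,
    activation_tube,
    check_candidate,
    crosstalk_matrix,
    make_candidate,
    multi_tube_defect,
    predicted_activation,
    sample_stem5,
    sample_toehold,
)
from swtkit.thermo import is_unstructured


class TestConstraints:
    def test_defaults_are_study_conditions(self):
        c = DesignConstraints()
        assert c.toehold_length == 40
        assert c.toehold_gc_window == (0.50, 0.60)
        assert c.stem_length == 10 and c.stem_nonGC_pairs == 1
        assert c.concentration == pytest.approx(1e-8)
        assert c.trigger_mode is TriggerMode.TOEHOLD_STEM

    def test_threshold_must_stay_below_floor(self):
        with pytest.raises(ConstraintError):
            DesignConstraints(crosstalk_threshold=0.95)


class TestSampling:
    def test_toehold_deterministic_per_seed(self, constraints, model):
        a = sample_toehold(np.random.default_rng(1), constraints, model)
        b = sample_toehold(np.random.default_rng(1), constraints, model)
        assert a == b

    def test_toehold_constraints_hold(self, constraints, model):
        rng = np.random.default_rng(0)
        for _ in range(5):
            th = sample_toehold(rng, constraints, model)
            assert len(th) == 40
            assert 0.50 <= gc_fraction(th) <= 0.60
            assert is_unstructured(th, model)

    def test_stem_composition(self, constraints):
        rng = np.random.default_rng(0)
        for _ in range(20):
            arm = sample_stem5(rng, constraints)
            assert len(arm) == 10
            assert sum(1 for ch in arm if ch in "AU") == 1


class TestCheckCandidate:
    def test_accepted_library_pairs_pass_everything(self, library):
        for pair in library.pairs:
            assert pair.all_passed, {
                k: v for k, v in pair.diagnostics.items() if not v.passed}

    def test_shuffled_trigger_fails_cognate_check(self, library, constraints, model):
        good = library.pairs[0]
        shuffled = good.trigger.sequence[25:] + good.trigger.sequence[:25]
        bad = CandidatePair(
            swt=good.swt,
            trigger=type(good.trigger)(
                name="shuffled", mode=good.trigger.mode,
                sequence=shuffled, cognate=good.swt.name))
        diag = check_candidate(bad, constraints, model)
        assert not diag["cognate_duplex_is_mfe"].passed

    def test_structured_toehold_fails(self, library, constraints, model):
        good = library.pairs[0]
        toehold = "GGGGAAAACCCC" + good.swt.toehold[12:]
        cand = make_candidate(
            "bad", toehold, good.swt.stem5, constraints, model)
        assert not cand.diagnostics["toehold_unstructured"].passed


class TestPredictedActivation:
    def test_cognate_pair_saturates(self, library, constraints, model):
        p = library.pairs[0]
        act = predicted_activation(p.swt, p.trigger, constraints, model)
        assert act >= constraints.cognate_min_activation

    def test_unrelated_trigger_stays_unbound(self, library, constraints, model):
        p = library.pairs[0]
        decoy = type(p.trigger)(
            name="polyA", mode=p.trigger.mode,
            sequence="A" * len(p.trigger.sequence), cognate=p.swt.name)
        assert predicted_activation(p.swt, decoy, constraints, model) <= 0.05

    def test_partial_triggers_activate_less(self, library, constraints, model):
        """Trigger-variant ordering: the free-monomer fraction resolves the
        ordering where the bound fraction saturates in double precision."""
        swt = library.pairs[0].swt
        free = {}
        act = {}
        for mode in (TriggerMode.TOEHOLD_ONLY, TriggerMode.STEM_ONLY,
                     TriggerMode.TOEHOLD_STEM):
            trig = derive_trigger(swt, mode)
            res = activation_tube(swt, trig, constraints, model)
            free[mode] = res.free_fraction["swt"]
            act[mode] = res.bound_fraction("swt", "trigger")
        assert act[TriggerMode.STEM_ONLY] < act[TriggerMode.TOEHOLD_STEM]
        assert act[TriggerMode.TOEHOLD_ONLY] <= act[TriggerMode.TOEHOLD_STEM]
        assert free[TriggerMode.TOEHOLD_ONLY] > free[TriggerMode.TOEHOLD_STEM]
        assert free[TriggerMode.STEM_ONLY] > free[TriggerMode.TOEHOLD_ONLY]


class TestCrosstalkMatrix:
    def test_library_matrix_invariants(self, library, constraints):
        mat = library.crosstalk
        n = len(library.pairs)
        assert mat.activation.shape == (n, n)
        assert np.all(mat.activation >= 0) and np.all(mat.activation <= 1)
        assert mat.diagonal_min >= constraints.cognate_min_activation
        assert mat.offdiagonal_max <= constraints.crosstalk_threshold
        # diagonal dominance at the configured ratio
        assert mat.diagonal_min / max(mat.offdiagonal_max, 1e-12) >= (
            constraints.cognate_min_activation / constraints.crosstalk_threshold)

    def test_duplicated_trigger_gives_identical_columns(
            self, library, constraints, model):
        swts = [p.swt for p in library.pairs[:2]]
        trig = library.pairs[0].trigger
        mat, _ = crosstalk_matrix(swts, [trig, trig], constraints, model)
        assert np.allclose(mat.activation[:, 0], mat.activation[:, 1])

    def test_single_cognate_pair(self, library, constraints, model):
        p = library.pairs[0]
        mat, reports = crosstalk_matrix([p.swt], [p.trigger], constraints, model)
        assert mat.activation.shape == (1, 1)
        assert mat.activation[0, 0] >= constraints.cognate_min_activation
        assert set(reports) == {"individual", "pooled", "pairs"}
        assert len(reports["individual"]) == 2

    def test_entry_bounds_enforced(self):
        with pytest.raises(ValueError):
            CrosstalkMatrix(("a",), ("b",), np.array([[1.5]]))


class TestMultiTubeDefect:
    def test_defect_nonnegative_and_finite(self, library, constraints, model):
        assert 0.0 <= library.defect < 10 * len(library.pairs) ** 2

    def test_defect_invariant_under_ordering(self, library, constraints, model):
        import dataclasses

        reversed_lib = dataclasses.replace(
            library,
            pairs=tuple(reversed(library.pairs)),
            tube_reports={},
        )
        # rebuild reports for the reordered library
        from swtkit.designer import crosstalk_matrix as cm

        mat, reports = cm(
            [p.swt for p in reversed_lib.pairs],
            [p.trigger for p in reversed_lib.pairs], constraints, model)
        reversed_lib = dataclasses.replace(
            reversed_lib, crosstalk=mat, tube_reports=reports)
        assert multi_tube_defect(reversed_lib, constraints, model) == pytest.approx(
            library.defect, rel=1e-6)

    def test_duplicate_trigger_raises_defect(self, library, constraints, model):
        """Reusing pair 0's trigger for pair 1's switch misallocates
        concentration in the pair and pooled tubes, so the defect must rise
        relative to the properly wired two-pair library."""
        import dataclasses

        from swtkit.designer import crosstalk_matrix as cm

        p0, p1 = library.pairs[0], library.pairs[1]
        clash = CandidatePair(
            swt=p1.swt,
            trigger=type(p0.trigger)(
                name="dup", mode=p0.trigger.mode,
                sequence=p0.trigger.sequence, cognate=p1.swt.name))

        def defect_of(pairs):
            mat, reports = cm(
                [p.swt for p in pairs], [p.trigger for p in pairs],
                constraints, model)
            lib = dataclasses.replace(
                library, pairs=tuple(pairs), crosstalk=mat, tube_reports=reports)
            return multi_tube_defect(lib, constraints, model)

        assert defect_of([p0, clash]) > defect_of([p0, p1])
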