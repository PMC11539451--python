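"""Fluorescence analysis: normalization, fold change, Welch's t, the
orthogonality matrix, and the seeded plate simulator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from swtkit.assay import (
    AssayError,
    SimSpec,
    UndefinedFoldChangeError,
    background_level,
    fold_change,
    normalize_fluorescence,
    orthogonality_table,
    simulate_plate,
    validate_plate,
    welch_t_test,
)


def plate_of(on, off, background, construct="c1"):
    rows = []
    for cond, vals in (("ON", on), ("OFF", off)):
        for i, v in enumerate(vals):
            rows.append(dict(well=f"{cond}{i}", construct=construct,
                             condition=cond, replicate=i + 1, rfu=float(v),
                             timepoint_min=120.0))
    for i, v in enumerate(background):
        rows.append(dict(well=f"B{i}", construct="no_template",
                         condition="BACKGROUND", replicate=i + 1, rfu=float(v),
                         timepoint_min=120.0))
    return pd.DataFrame(rows)


class TestNormalization:
    def test_subtraction(self):
        assert normalize_fluorescence(1500, 300) == 1200
        assert normalize_fluorescence(300, 300) == 0

    def test_negative_warns(self):
        with pytest.warns(UserWarning, match="below zero"):
            out = normalize_fluorescence(100, 300)
        assert out == -200

    def test_background_is_batch_mean(self):
        plate = plate_of([1500], [400], [290, 300, 310])
        assert background_level(plate) == pytest.approx(300.0)


class TestFoldChange:
    def test_hand_computed_example(self):
        plate = plate_of([1500, 1500, 1500], [400, 400, 400], [300])
        r = fold_change(plate[plate.condition == "ON"],
                        plate[plate.condition == "OFF"],
                        plate[plate.condition == "BACKGROUND"])
        assert r.fold_change == pytest.approx(12.0)
        assert r.normalized_on == pytest.approx(1200.0)
        assert r.normalized_off == pytest.approx(100.0)

    def test_on_equals_off_gives_unity(self):
        plate = plate_of([900, 900], [900, 900], [300])
        r = fold_change(plate[plate.condition == "ON"],
                        plate[plate.condition == "OFF"],
                        plate[plate.condition == "BACKGROUND"])
        assert r.fold_change == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(min_value=0.25, max_value=8.0))
    def test_invariant_under_common_rescaling(self, scale):
        base = plate_of([1500, 1550, 1450], [420, 400, 380], [300, 310, 290])
        scaled = base.assign(rfu=base["rfu"] * scale)

        def fc(plate):
            return fold_change(plate[plate.condition == "ON"],
                               plate[plate.condition == "OFF"],
                               plate[plate.condition == "BACKGROUND"]).fold_change

        assert fc(scaled) == pytest.approx(fc(base), rel=1e-9)

    def test_nonpositive_off_is_reported_not_clamped(self):
        plate = plate_of([1500], [250], [300])
        with pytest.raises(UndefinedFoldChangeError):
            fold_change(plate[plate.condition == "ON"],
                        plate[plate.condition == "OFF"],
                        plate[plate.condition == "BACKGROUND"])

    def test_mean_of_ratios_option(self):
        plate = plate_of([1300, 1500], [400, 500], [300])
        r = fold_change(plate[plate.condition == "ON"],
                        plate[plate.condition == "OFF"],
                        plate[plate.condition == "BACKGROUND"],
                        method="mean_of_ratios")
        assert r.fold_change == pytest.approx((1000 / 100 + 1200 / 200) / 2)


class TestWelch:
    def test_closed_form_oracle(self):
        # equal variances 1, n=3: t = -3/sqrt(2/3), Welch df = 4
        t, df, p = welch_t_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3 / np.sqrt(2 / 3))
        assert df == pytest.approx(4.0)
        assert 0 < p < 1

    def test_identical_groups(self):
        t, df, p = welch_t_test([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert t == 0.0 and p == 1.0

    def test_antisymmetry(self):
        t1, df1, p1 = welch_t_test([1, 2, 3], [4, 5, 7])
        t2, df2, p2 = welch_t_test([4, 5, 7], [1, 2, 3])
        assert t1 == pytest.approx(-t2)
        assert df1 == pytest.approx(df2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_group_rejected(self):
        with pytest.raises(AssayError):
            welch_t_test([1.0], [2.0, 3.0])

    def test_directionality_matches_permutation_test(self):
        """On clearly separated simulated groups, Welch's p < 0.05 agrees with
        a brute-force permutation test."""
        rng = np.random.default_rng(0)
        a = rng.normal(10.0, 1.0, size=6)
        b = rng.normal(16.0, 2.0, size=6)
        t, _, p = welch_t_test(a, b)
        perm = stats.permutation_test(
            (a, b), lambda x, y: np.mean(x) - np.mean(y),
            permutation_type="independent", n_resamples=2000,
            random_state=0).pvalue
        assert (p < 0.05) == (perm < 0.05) == True  # noqa: E712
        assert t < 0  # group a is lower


class TestSimulatePlate:
    def test_zero_cv_reproduces_means_exactly(self):
        spec = SimSpec(construct_means={"c": (1500.0, 400.0)},
                       background_mean=300.0, cv=0.0, replicates=3, seed=1)
        plate = simulate_plate(spec)
        assert set(plate[plate.condition == "ON"]["rfu"]) == {1500.0}
        assert set(plate[plate.condition == "BACKGROUND"]["rfu"]) == {300.0}

    def test_seeded_determinism(self):
        spec = SimSpec(construct_means={"c": (1500.0, 400.0)}, seed=9)
        assert simulate_plate(spec).equals(simulate_plate(spec))

    def test_fold_recovery_within_noise(self):
        spec = SimSpec(construct_means={"c": (1500.0, 400.0)},
                       background_mean=300.0, cv=0.05, replicates=3, seed=2)
        plate = simulate_plate(spec)
        r = fold_change(plate[plate.condition == "ON"],
                        plate[plate.condition == "OFF"],
                        plate[plate.condition == "BACKGROUND"])
        # programmed fold 12; ratio error propagation at cv=0.05, n=3 gives a
        # relative sd of roughly sqrt(2) * cv * (on/(on-bg)) / sqrt(3) ~ 7%
        assert r.fold_change == pytest.approx(12.0, rel=3 * 0.07)

    def test_invalid_spec(self):
        with pytest.raises(AssayError):
            SimSpec(construct_means={"c": (200.0, 100.0)}, background_mean=300.0)


class TestOrthogonalityTable:
    def test_programmed_matrix_recovered(self):
        # 2x2 plate: diagonal fold 50, off-diagonal 1
        bg = 300.0
        means = {}
        for s in ("S1", "S2"):
            for t in ("T1", "T2"):
                fold = 50.0 if s[1] == t[1] else 1.0
                means[f"{s}_{t}"] = (bg + 100.0 * fold, bg + 100.0)
        spec = SimSpec(construct_means=means, background_mean=bg, cv=0.03,
                       replicates=3, seed=5)
        plate = simulate_plate(spec)
        mapping = pd.DataFrame(
            [{"swt": s, "trigger": t, "construct": f"{s}_{t}"}
             for s in ("S1", "S2") for t in ("T1", "T2")])
        mat = orthogonality_table(plate, mapping)
        assert list(mat.index) == ["S1", "S2"]
        assert mat.loc["S1", "T1"] == pytest.approx(50.0, rel=0.25)
        assert mat.loc["S2", "T2"] == pytest.approx(50.0, rel=0.25)
        assert mat.loc["S1", "T2"] == pytest.approx(1.0, rel=0.25)
        assert mat.loc["S2", "T1"] == pytest.approx(1.0, rel=0.25)

    def test_missing_combination_stays_nan(self):
        spec = SimSpec(construct_means={"S1_T1": (1500.0, 400.0)},
                       background_mean=300.0, cv=0.0, replicates=3, seed=0)
        plate = simulate_plate(spec)
        mapping = pd.DataFrame(
            [{"swt": "S1", "trigger": "T1", "construct": "S1_T1"},
             {"swt": "S1", "trigger": "T2", "construct": "S1_T2"}])
        mat = orthogonality_table(plate, mapping)
        assert mat.loc["S1", "T1"] == pytest.approx(12.0)
        assert np.isnan(mat.loc["S1", "T2"])

    def test_plate_schema_enforced(self):
        with pytest.raises(AssayError):
            validate_plate(pd.DataFrame({"well": ["A1"], "rfu": [1.0]}))
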