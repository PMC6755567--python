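"""Shift referencing, error metrics, empirical scaling, cross-validation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shiftkit import (
    MethodSpec,
    MockRunner,
    ScalingModel,
    apply_scaling,
    error_metrics,
    fit_scaling,
    monte_carlo_cv,
    parse_engine_output,
    reference_from_shieldings,
    render_input_deck,
    shieldings_to_shifts,
)
from shiftkit.dft_interface import ShieldingResult
from shiftkit.errors import ScalingError
from shiftkit.molecule_io import MoleculeRecord
from shiftkit.shifts_scaling import (
    SHIELDING_BASED,
    SHIFT_BASED,
    load_model,
    save_model,
)
from shiftkit.synthetic_data import SyntheticTruth, gen_shift_dataset


def brute_force_metrics(exp, calc, model=None):
    """Independent elementwise evaluation of MAE/CMAE/RMSE/MAXAE."""
    n = len(exp)
    abs_errors = [abs(e - c) for e, c in zip(exp, calc)]
    mae = sum(abs_errors) / n
    rmse = math.sqrt(sum((e - c) ** 2 for e, c in zip(exp, calc)) / n)
    maxae = max(abs_errors)
    cmae = None
    if model is not None:
        cmae = (
            sum(
                abs(e - (c - model.intercept) / model.slope)
                for e, c in zip(exp, calc)
            )
            / n
        )
    return mae, cmae, rmse, maxae


def _record(elements):
    return MoleculeRecord(
        name="synthetic",
        atoms=[(el, float(i), 0.0, 0.0) for i, el in enumerate(elements)],
    )


class TestReference:
    def test_sigma_ref_is_mean_over_equivalent_nuclei(self):
        rec = _record(["H", "H"])
        result = ShieldingResult({1: 31.7, 2: 31.9})
        ref = reference_from_shieldings(rec, result, {"H": 0.0})
        assert ref.sigma_ref["H"] == pytest.approx(31.8)
        assert ref.delta_ref["H"] == 0.0

    def test_all_equal_shieldings(self):
        rec = _record(["H"] * 12)
        result = ShieldingResult({i: 31.8 for i in range(1, 13)})
        ref = reference_from_shieldings(rec, result, {"H": 0.0})
        assert ref.sigma_ref["H"] == pytest.approx(31.8)

    def test_requesting_absent_nucleus_raises(self):
        rec = _record(["H", "C"])
        result = ShieldingResult({1: 31.8, 2: 190.0})
        with pytest.raises(ScalingError, match="no shielded N"):
            reference_from_shieldings(rec, result, {"N": 0.0}, nuclei=["N"])


class TestShiftEquation:
    @pytest.mark.parametrize(
        "sigma_ref,sigma_i,delta_ref,expected",
        [
            (31.8, 31.8, 0.0, 0.0),  # reference shifts itself to zero
            (189.7, 128.5, 0.0, 61.2),
            (31.8, 24.5, 0.1, 7.4),
        ],
    )
    def test_direct_arithmetic(self, sigma_ref, sigma_i, delta_ref, expected):
        rec = _record(["C"])
        result = ShieldingResult({1: sigma_i})
        ref = reference_from_shieldings(
            _record(["C"]), ShieldingResult({1: sigma_ref}), {"C": delta_ref}
        )
        table = shieldings_to_shifts(rec, result, ref)
        assert table.shifts[1] == pytest.approx(expected)
        assert table.provenance == "unscaled"

    def test_linearity_in_sigma(self):
        rec = _record(["C"])
        ref = reference_from_shieldings(
            _record(["C"]), ShieldingResult({1: 190.0}), {"C": 0.0}
        )
        base = shieldings_to_shifts(rec, ShieldingResult({1: 150.0}), ref).shifts[1]
        raised = shieldings_to_shifts(rec, ShieldingResult({1: 153.5}), ref).shifts[1]
        assert raised == pytest.approx(base - 3.5)

    def test_invariance_under_global_sigma_offset(self):
        rec = _record(["C"])
        for offset in (0.0, 10.0, -77.3):
            ref = reference_from_shieldings(
                _record(["C"]), ShieldingResult({1: 190.0 + offset}), {"C": 0.0}
            )
            shifted = shieldings_to_shifts(
                rec, ShieldingResult({1: 150.0 + offset}), ref
            ).shifts[1]
            assert shifted == pytest.approx(40.0)

    def test_missing_reference_nucleus_raises(self):
        rec = _record(["N"])
        ref = reference_from_shieldings(
            _record(["C"]), ShieldingResult({1: 190.0}), {"C": 0.0}
        )
        with pytest.raises(ScalingError, match="N"):
            shieldings_to_shifts(rec, ShieldingResult({1: 250.0}), ref)


class TestErrorMetrics:
    def test_zero_error_case(self):
        rep = error_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.mae == rep.rmse == rep.maxae == 0.0
        assert rep.n == 3

    def test_hand_evaluated_example(self):
        rep = error_metrics([0.0, 0.0], [3.0, 4.0])
        assert rep.mae == pytest.approx(3.5)
        assert rep.rmse == pytest.approx(math.sqrt(12.5))
        assert rep.maxae == pytest.approx(4.0)

    def test_identity_model_makes_cmae_equal_mae(self):
        model = ScalingModel(slope=1.0, intercept=0.0)
        rep = error_metrics([1.0, 2.0], [1.5, 2.5], model=model)
        assert rep.cmae == pytest.approx(rep.mae)

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        model = ScalingModel(slope=1.03, intercept=-0.4)
        for n in range(1, 11):
            exp = list(rng.uniform(0, 200, n))
            calc = list(rng.uniform(0, 200, n))
            rep = error_metrics(exp, calc, model=model)
            mae, cmae, rmse, maxae = brute_force_metrics(exp, calc, model)
            assert rep.mae == pytest.approx(mae, abs=1e-12)
            assert rep.cmae == pytest.approx(cmae, abs=1e-12)
            assert rep.rmse == pytest.approx(rmse, abs=1e-12)
            assert rep.maxae == pytest.approx(maxae, abs=1e-12)

    def test_empty_or_mismatched_pairings_raise(self):
        with pytest.raises(ScalingError):
            error_metrics([], [])
        with pytest.raises(ScalingError):
            error_metrics([1.0], [1.0, 2.0])

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=-250, max_value=250),
                st.floats(min_value=-250, max_value=250),
            ),
            min_size=1,
            max_size=50,
        )
    )
    def test_metric_ordering_invariant(self, pairs):
        exp, calc = zip(*pairs)
        rep = error_metrics(exp, calc)
        assert rep.mae <= rep.rmse + 1e-12
        assert rep.rmse <= rep.maxae + 1e-12


class TestScalingFit:
    def test_identity_line(self):
        exp = [0.0, 1.0, 2.0]
        model = fit_scaling(exp, exp)
        assert model.slope == pytest.approx(1.0)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)
        assert model.r2 == pytest.approx(1.0)

    def test_exact_line_recovered_and_inverted(self):
        exp = [0.0, 1.0, 2.0]
        calc = [2 * e + 5 for e in exp]
        model = fit_scaling(calc, exp)
        assert model.slope == pytest.approx(2.0)
        assert model.intercept == pytest.approx(5.0)
        assert apply_scaling(calc, model) == pytest.approx(exp)
        assert error_metrics(exp, calc, model=model).cmae == pytest.approx(0.0)

    def test_shielding_mode_negative_slope(self):
        exp = [0.0, 10.0, 20.0, 30.0]
        sigma = [180.0 - e for e in exp]
        model = fit_scaling(sigma, exp, mode=SHIELDING_BASED)
        assert model.slope == pytest.approx(-1.0)
        assert model.intercept == pytest.approx(180.0)
        assert apply_scaling(sigma, model) == pytest.approx(exp)

    def test_apply_scaling_arithmetic(self):
        assert apply_scaling([61.2], ScalingModel(2.0, 5.0))[0] == pytest.approx(28.1)
        assert apply_scaling([160.0], ScalingModel(-1.0, 180.0))[0] == pytest.approx(20.0)

    def test_noiseless_round_trip_to_1e9(self):
        truth = SyntheticTruth(slope=1.03, intercept=-1.2, noise_sd=0.0,
                               shift_range=(0.0, 220.0), nucleus="C", seed=11)
        df = gen_shift_dataset(200, truth)
        model = fit_scaling(df["calc"], df["delta_exp"])
        assert model.slope == pytest.approx(truth.slope, abs=1e-9)
        assert model.intercept == pytest.approx(truth.intercept, abs=1e-9)
        scaled = apply_scaling(df["calc"], model)
        assert np.max(np.abs(np.asarray(scaled) - df["delta_exp"].values)) < 1e-9

    def test_fit_against_closed_form_ols_oracle(self):
        # hand-rolled normal equations on a small instance
        exp = np.array([1.0, 2.0, 4.0, 7.0])
        calc = np.array([1.9, 4.2, 8.3, 14.8])
        sxx = np.sum((exp - exp.mean()) ** 2)
        sxy = np.sum((exp - exp.mean()) * (calc - calc.mean()))
        slope = sxy / sxx
        intercept = calc.mean() - slope * exp.mean()
        model = fit_scaling(calc, exp)
        assert model.slope == pytest.approx(slope, abs=1e-12)
        assert model.intercept == pytest.approx(intercept, abs=1e-12)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ScalingError):
            fit_scaling([1.0], [1.0])
        with pytest.raises(ScalingError):
            fit_scaling([1.0, 2.0], [3.0, 3.0])
        with pytest.raises(ScalingError):
            ScalingModel(slope=0.0, intercept=1.0)

    def test_model_persistence_round_trip(self, tmp_path):
        model = ScalingModel(1.0213, -0.173, mode=SHIFT_BASED, n=42, r2=0.991)
        path = tmp_path / "h.model"
        save_model(model, path)
        back = load_model(path)
        assert back.slope == model.slope
        assert back.intercept == model.intercept
        assert back.mode == model.mode
        assert back.n == model.n


class TestMonteCarloCv:
    def test_noiseless_line_gives_constant_folds(self):
        truth = SyntheticTruth(slope=0.98, intercept=0.3, noise_sd=0.0, seed=3)
        df = gen_shift_dataset(100, truth)
        report = monte_carlo_cv(df["calc"], df["delta_exp"], repetitions=20, seed=9)
        assert np.allclose(report.slopes, truth.slope, atol=1e-9)
        assert np.allclose(report.intercepts, truth.intercept, atol=1e-9)
        assert report.test_mae_mean < 1e-9

    def test_same_seed_identical_report(self):
        truth = SyntheticTruth(noise_sd=0.3, seed=4)
        df = gen_shift_dataset(80, truth)
        a = monte_carlo_cv(df["calc"], df["delta_exp"], repetitions=15, seed=17)
        b = monte_carlo_cv(df["calc"], df["delta_exp"], repetitions=15, seed=17)
        assert a.slopes == b.slopes
        assert a.test_maes == b.test_maes

    def test_infeasible_split_raises(self):
        with pytest.raises(ScalingError):
            monte_carlo_cv([1.0, 2.0], [1.0, 2.0], split_fraction=0.5, repetitions=1)

    def test_training_folds_mirror_full_set_fit(self):
        # stability claim: train-fold parameters match the full-data fit
        truth = SyntheticTruth(slope=1.02, intercept=0.05, noise_sd=0.3, seed=6)
        df = gen_shift_dataset(400, truth)
        full = fit_scaling(df["calc"], df["delta_exp"])
        report = monte_carlo_cv(df["calc"], df["delta_exp"], repetitions=50, seed=6)
        assert report.slope_mean == pytest.approx(full.slope, abs=3 * report.slope_sd)
        assert report.intercept_mean == pytest.approx(
            full.intercept, abs=3 * report.intercept_sd
        )
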