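"""Grip-force decomposition: regressions, baselines, intended-peak model."""

import numpy as np
import pandas as pd
import pytest

from gripstretch import preprocess
from gripstretch.gripforce import (
    IntendedPeakRegressor,
    baseline_before_probe,
    baseline_between_probes,
    contact_features,
    decompose,
    delta_vs_zero_gain,
    first_last_ratio_analysis,
    fit_intended_peak_model,
    gf_lf_regression,
    peak_ratio,
    predict_intended_peak,
)
from gripstretch.preprocess import Probe, segment_field, segment_probes
from gripstretch.synth import apply_force_field, eq3_catch_features, probe_kinematics


def _probe_with_peaks(peak_grip, peak_load):
    return Probe(
        trial=0, field="standard", probe_number=1, start_idx=0, end_idx=10,
        contact_idx=2, contact_end=8, depth=0.025, duration=0.2,
        peak_grip=peak_grip, peak_load=peak_load,
    )


class TestPeakRatio:
    @pytest.mark.parametrize(
        "grip, load, expected", [(2.0, 4.0, 0.5), (3.0, 3.0, 1.0)]
    )
    def test_ratio(self, grip, load, expected):
        assert peak_ratio(_probe_with_peaks(grip, load)) == expected

    def test_zero_peak_load_rejected(self):
        with pytest.raises(ValueError):
            peak_ratio(_probe_with_peaks(1.0, 0.0))


class TestGFLFRegression:
    def _exact(self, slope, intercept):
        load = np.concatenate([[0.0], np.linspace(0.1, 3, 50), [0.0]])
        grip = slope * load + intercept
        probe = Probe(
            trial=0, field="standard", probe_number=1, start_idx=0,
            end_idx=len(load), contact_idx=1, contact_end=len(load) - 1,
            depth=0.03, duration=0.1,
        )
        return gf_lf_regression(probe, load, grip)

    def test_exact_affine_recovery(self):
        reg = self._exact(0.1, 0.5)
        assert reg.slope == pytest.approx(0.1)
        assert reg.intercept == pytest.approx(0.5)
        assert reg.r2 == pytest.approx(1.0)
        assert not reg.excluded

    def test_negative_slope_flagged_for_exclusion(self):
        assert self._exact(-0.05, 1.0).excluded

    def test_degenerate_inputs_rejected(self):
        probe = Probe(
            trial=0, field="standard", probe_number=1, start_idx=0,
            end_idx=10, contact_idx=0, contact_end=10, depth=0.03,
            duration=0.1,
        )
        with pytest.raises(ValueError, match="constant load"):
            gf_lf_regression(probe, np.ones(10), np.ones(10))
        probe.contact_end = 2
        with pytest.raises(ValueError, match="at least 3"):
            gf_lf_regression(probe, np.arange(10.0), np.ones(10))

    def test_recovers_generator_controller(
        self, noiseless_trajectory, noiseless_controller
    ):
        load = noiseless_trajectory["load_N"].to_numpy()
        grip = noiseless_trajectory["grip_N"].to_numpy()
        probes = segment_probes(noiseless_trajectory, fs=500.0)
        for number in (2, 7):
            probe = probes[number - 1]
            reg = gf_lf_regression(probe, load, grip)
            assert reg.slope == pytest.approx(
                noiseless_controller.slope(100.0, number)
            )
            assert reg.intercept == pytest.approx(
                noiseless_controller.baseline(100.0, number)
            )
            assert reg.r2 == pytest.approx(1.0)


class TestBaseline:
    def _gap_probes(self, n):
        a = Probe(
            trial=0, field="standard", probe_number=1, start_idx=0,
            end_idx=n, contact_idx=10, contact_end=20, depth=0.03,
            duration=0.02,
        )
        b = Probe(
            trial=0, field="standard", probe_number=2, start_idx=20,
            end_idx=n, contact_idx=n - 10, contact_end=n - 5, depth=0.03,
            duration=0.01,
        )
        return a, b

    def test_constant_gap_returns_constant(self):
        fs, n = 500.0, 500
        grip = np.full(n, 1.2)
        a, b = self._gap_probes(n)
        assert baseline_between_probes(grip, fs, a, b) == pytest.approx(1.2)

    def test_decay_then_plateau_returns_plateau(self):
        # grip decays fast (rate >> 0.1 N/s), then sits at B: the first
        # quiescent instant falls on the plateau and the window mean is B
        fs = 500.0
        decay = np.linspace(2.0, 0.8, 100)  # 6 N/s decay over 0.2 s
        plateau = np.full(400, 0.8)
        grip = np.concatenate([np.full(20, 2.0), decay, plateau])
        a, b = self._gap_probes(len(grip))
        a.contact_end = 120  # gap starts where the plateau starts
        value = baseline_between_probes(grip, fs, a, b)
        assert value == pytest.approx(0.8)

    def test_never_quiescent_returns_missing(self):
        fs = 500.0
        grip = np.cumsum(np.full(600, 0.01))  # 5 N/s everywhere
        a, b = self._gap_probes(len(grip))
        assert np.isnan(baseline_between_probes(grip, fs, a, b))

    def test_nonconsecutive_probes_rejected(self):
        a, b = self._gap_probes(500)
        b.probe_number = 5
        with pytest.raises(ValueError, match="consecutive"):
            baseline_between_probes(np.ones(500), 500.0, a, b)

    def test_recovers_generator_baseline(
        self, noiseless_trajectory, noiseless_controller
    ):
        grip = noiseless_trajectory["grip_N"].to_numpy()
        probes = segment_probes(noiseless_trajectory, fs=500.0)
        assert baseline_before_probe(grip, 500.0, probes[0]) == pytest.approx(
            noiseless_controller.baseline(100.0, 1)
        )
        assert baseline_before_probe(grip, 500.0, probes[4]) == pytest.approx(
            noiseless_controller.baseline(100.0, 5)
        )


class TestContactFeatures:
    def test_backward_difference(self):
        probe = _probe_with_peaks(1.0, 1.0)
        probe.contact_idx = 1
        grip = np.array([1.0, 1.1, 1.2])
        gfc, rate = contact_features(probe, grip, 1000.0)
        assert gfc == pytest.approx(1.1)
        assert rate == pytest.approx(100.0)

    def test_flat_grip_has_zero_rate(self):
        probe = _probe_with_peaks(1.0, 1.0)
        probe.contact_idx = 1
        assert contact_features(probe, np.ones(5), 500.0)[1] == 0.0

    def test_contact_at_first_sample_rejected(self):
        probe = _probe_with_peaks(1.0, 1.0)
        probe.contact_idx = 0
        with pytest.raises(ValueError):
            contact_features(probe, np.ones(5), 500.0)

    def test_matches_generator_eq3_consistency(
        self, noiseless_trajectory, noiseless_controller
    ):
        # the generator shapes the approach ramp so the contact features map
        # onto the realized peak through the intended-peak coefficients
        grip = noiseless_trajectory["grip_N"].to_numpy()
        probes = segment_probes(noiseless_trajectory, fs=500.0)
        a, b, c = noiseless_controller.eq3_coeffs
        for probe in probes:
            gfc, rate = contact_features(probe, grip, 500.0)
            assert a * gfc + b * rate + c == pytest.approx(probe.peak_grip)


class TestIntendedPeakModel:
    def test_exact_recovery_of_printed_coefficients(self, rng):
        feats = eq3_catch_features(15, coeffs=(1.14, 0.06, 0.1), rng=rng)
        model = fit_intended_peak_model(feats)
        assert model.a_ == pytest.approx(1.14, abs=1e-9)
        assert model.b_ == pytest.approx(0.06, abs=1e-9)
        assert model.c_ == pytest.approx(0.1, abs=1e-9)
        assert model.r2_ == pytest.approx(1.0)

    def test_collinear_design_rejected(self):
        X = np.column_stack([np.linspace(1, 2, 10), np.zeros(10)])
        with pytest.raises(ValueError, match="collinear"):
            IntendedPeakRegressor().fit(X, np.linspace(1, 2, 10))

    def test_noisy_estimate_within_three_standard_errors(self, rng):
        n, sd = 200, 0.05
        feats = eq3_catch_features(n, rng=rng, noise_sd=sd)
        X = feats[["gf_contact", "gf_rate_contact"]].to_numpy()
        design = np.column_stack([X, np.ones(n)])
        cov = sd**2 * np.linalg.inv(design.T @ design)
        se_a = np.sqrt(cov[0, 0])
        model = fit_intended_peak_model(feats)
        assert abs(model.a_ - 1.14) < 3 * se_a

    @pytest.mark.parametrize(
        "gfc, rate, expected",
        [(1.0, 5.0, 1.54), (0.0, 0.0, 0.1), (2.0, 0.0, 2 * 1.14 + 0.1)],
    )
    def test_prediction_closed_form(self, gfc, rate, expected):
        model = IntendedPeakRegressor.from_coefficients(1.14, 0.06, 0.1)
        assert predict_intended_peak(model, gfc, rate) == pytest.approx(expected)

    def test_sklearn_interface(self):
        model = IntendedPeakRegressor()
        assert model.get_params() == {}
        feats = eq3_catch_features(10, rng=np.random.default_rng(0))
        X = feats[["gf_contact", "gf_rate_contact"]].to_numpy()
        fitted = model.fit(X, feats["peak_grip"].to_numpy())
        assert fitted.score(X, feats["peak_grip"].to_numpy()) == pytest.approx(1.0)


class TestDecompose:
    def test_modulation_is_intended_minus_contact(self):
        model = IntendedPeakRegressor.from_coefficients(1.14, 0.06, 0.1)
        probe = _probe_with_peaks(2.0, 3.0)
        probe.contact_idx = 2
        grip = np.array([1.0, 1.0, 1.0, 1.5, 2.0, 1.5, 1.0, 1.0, 1.0, 1.0])
        d = decompose(probe, grip, 500.0, model, baseline=1.0, gain=33.0)
        assert d.modulation == pytest.approx(d.intended_peak - d.gf_contact)
        assert d.gf_contact == 1.0

    def test_noiseless_ordering(self, noiseless_trajectory, noiseless_controller):
        # baseline <= contact grip <= intended peak for nonnegative rates
        grip = noiseless_trajectory["grip_N"].to_numpy()
        probes = segment_probes(noiseless_trajectory, fs=500.0)
        model = IntendedPeakRegressor.from_coefficients(
            *noiseless_controller.eq3_coeffs
        )
        for probe in probes[1:]:
            base = baseline_before_probe(grip, 500.0, probe)
            d = decompose(probe, grip, 500.0, model, base, gain=100.0)
            assert base <= d.gf_contact + 1e-9
            assert d.gf_contact <= d.intended_peak


class TestDeltaVsZeroGain:
    def _table(self):
        rows = []
        for pid in range(2):
            for probe in (2, 7):
                for gain, val in ((0.0, 1.0), (100.0, 1.4)):
                    rows.append(
                        dict(
                            participant=pid, probe_number=probe, gain=gain,
                            value=val + 0.1 * pid,
                        )
                    )
        return pd.DataFrame(rows)

    def test_zero_gain_column_becomes_zero(self):
        out = delta_vs_zero_gain(self._table())
        assert (out.loc[out["gain"] == 0.0, "value"] == 0).all()
        assert np.allclose(out.loc[out["gain"] == 100.0, "value"], 0.4)

    def test_missing_zero_gain_cell_rejected(self):
        t = self._table()
        t = t[~((t["participant"] == 1) & (t["gain"] == 0.0))]
        with pytest.raises(ValueError, match="gain-0"):
            delta_vs_zero_gain(t)


class TestFirstLastRatio:
    def test_single_probe_trials_excluded_and_pairs_formed(self):
        table = pd.DataFrame(
            dict(
                trial=[0, 0, 0, 1, 2, 2],
                probe_number=[1, 2, 3, 1, 1, 2],
                peak_grip=[1.0, 1.2, 1.6, 1.0, 1.0, 1.5],
                peak_load=[2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
                gain=[100.0] * 6,
            )
        )
        out = first_last_ratio_analysis(table)
        assert set(out["trial"]) == {0, 2}  # trial 1 probed once: dropped
        row0 = out[out["trial"] == 0].iloc[0]
        assert row0["first_ratio"] == pytest.approx(0.5)
        assert row0["last_ratio"] == pytest.approx(0.8)

    def test_buildup_raises_last_ratio_at_high_gain(self, noiseless_controller):
        from gripstretch.schedule import TrialSpec
        from gripstretch.synth import generate_trial_trajectory

        rows = []
        for i, gain in enumerate((0.0, 100.0)):
            trial = TrialSpec(
                experiment="exp2", group="g2", session=1, phase="test",
                trial_index=i, comparison_stiffness=85.0, gain=gain,
            )
            traj = generate_trial_trajectory(
                trial, noiseless_controller, np.random.default_rng(3),
                fs=250.0, probes_per_field=6, fields=("standard",),
            )
            for p in segment_probes(traj, fs=250.0):
                rows.append(
                    dict(
                        trial=i, probe_number=p.probe_number,
                        peak_grip=p.peak_grip, peak_load=p.peak_load,
                        gain=gain,
                    )
                )
        out = first_last_ratio_analysis(pd.DataFrame(rows))
        zero = out[out["gain"] == 0.0].iloc[0]
        high = out[out["gain"] == 100.0].iloc[0]
        assert zero["last_ratio"] == pytest.approx(zero["first_ratio"], abs=1e-6)
        assert high["last_ratio"] > high["first_ratio"] + 0.05
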