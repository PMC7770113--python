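"""Sigmoid fits, threshold inversion, human-space scaling, confusions, ANOVA."""

import numpy as np
import pandas as pd
import pytest

from dinmodel import psychometrics as ps

SNR_GRID = np.arange(-50.0, 55.0, 5.0)  # 21 points


def _human(a=0.5, b=-20.0):
    return ps.SigmoidFit(0.10, 0.90, a=a, b=b, variant="human")


def _model(a=0.4, b=-18.0):
    return ps.SigmoidFit(0.09, 0.88, a=a, b=b, variant="model")


class TestSigmoidFit:
    def test_parameter_recovery_under_noise(self):
        """100 noisy realizations (sigma=0.02): slope recovered within 10%
        and inflection within 1 dB on average."""
        rng = np.random.default_rng(0)
        truth = _human()
        a_err, b_err = [], []
        for _ in range(100):
            y = np.clip(truth(SNR_GRID) + rng.normal(0, 0.02, len(SNR_GRID)),
                        0, 1)
            fit = ps.fit_sigmoid(ps.PsychometricCurve(SNR_GRID, y), "human")
            a_err.append(abs(fit.a - truth.a) / truth.a)
            b_err.append(abs(fit.b - truth.b))
        assert np.mean(a_err) < 0.10
        assert np.mean(b_err) < 1.0

    def test_noiseless_data_fit_exactly(self):
        fit = ps.fit_sigmoid(ps.PsychometricCurve(SNR_GRID, _human()(SNR_GRID)),
                             "human")
        assert fit.residual < 1e-10
        assert fit.a == pytest.approx(0.5, rel=1e-5)
        assert fit.b == pytest.approx(-20.0, abs=1e-4)

    def test_mirror_symmetry_negates_inflection_only(self):
        """Point-reflecting the data (x -> -x, accuracy about the sigmoid
        midpoint) leaves the fitted slope unchanged and negates the
        inflection — the sigmoid family's symmetry."""
        floor, span = ps.SIGMOID_VARIANTS["human"]
        y = _human(a=0.31, b=-17.0)(SNR_GRID)
        fit = ps.fit_sigmoid(ps.PsychometricCurve(SNR_GRID, y), "human")
        y_mirror = (2 * floor + span) - y[::-1]
        mirrored = ps.fit_sigmoid(
            ps.PsychometricCurve(np.sort(-SNR_GRID), y_mirror), "human")
        assert mirrored.a == pytest.approx(fit.a, rel=1e-6)
        assert mirrored.b == pytest.approx(-fit.b, abs=1e-6)

    def test_flat_data_rejected_with_diagnostic(self):
        flat = np.full(len(SNR_GRID), 0.1)
        with pytest.raises(ValueError, match="identifiable"):
            ps.fit_sigmoid(ps.PsychometricCurve(SNR_GRID, flat), "human")

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ps.fit_sigmoid(ps.PsychometricCurve(
                np.array([-10.0, 0.0, 10.0]), np.array([0.2, 0.5, 0.9])))


class TestThresholdInversion:
    def test_closed_form_against_root_finding(self):
        from scipy.optimize import brentq
        fit = _human(a=0.37, b=-12.0)
        x50 = ps.snr_at_accuracy(fit, 0.5)
        assert x50 == pytest.approx(fit.b - np.log(0.9 / 0.4 - 1.0) / fit.a,
                                    abs=1e-12)
        numeric = brentq(lambda x: fit(x) - 0.5, -100, 100)
        assert x50 == pytest.approx(numeric, abs=1e-9)

    def test_midpoint_target_returns_inflection(self):
        fit = _model(a=0.8, b=3.0)
        assert ps.snr_at_accuracy(fit, 0.09 + 0.44) == pytest.approx(3.0)

    def test_round_trip_for_random_targets(self):
        fit = _human(a=0.22, b=-25.0)
        rng = np.random.default_rng(1)
        for t in rng.uniform(0.101, 0.999, 100):
            assert fit(ps.snr_at_accuracy(fit, t)) == pytest.approx(t, abs=1e-9)

    def test_asymptote_targets_rejected(self):
        fit = _human()
        for bad in (0.05, 0.1, 1.0):
            with pytest.raises(ValueError):
                ps.snr_at_accuracy(fit, bad)


class TestHumanSpaceScaling:
    def test_model_fit_maps_onto_human_fit_exactly(self):
        mfit, hfit = _model(), _human()
        curve = ps.PsychometricCurve(SNR_GRID, mfit(SNR_GRID))
        scaled = ps.scale_to_human(curve, mfit, hfit)
        assert np.allclose(scaled.accuracy, np.clip(hfit(SNR_GRID), 0, 1),
                           atol=1e-12)

    def test_identical_fits_change_nothing(self):
        mfit = _model()
        rng = np.random.default_rng(2)
        acc = np.clip(mfit(SNR_GRID) + rng.normal(0, 0.03, len(SNR_GRID)), 0, 1)
        curve = ps.PsychometricCurve(SNR_GRID, acc)
        scaled = ps.scale_to_human(curve, mfit, mfit)
        assert np.allclose(scaled.accuracy, acc)

    def test_scaled_sigmoids_stay_monotone(self):
        """For 100 random rising fit pairs, scaling a model-fit curve yields
        a monotone (human-fit) curve; the remap never inverts the
        psychometric ordering of its own calibration family."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            mfit = _model(a=rng.uniform(0.05, 1.0), b=rng.uniform(-30, 10))
            hfit = _human(a=rng.uniform(0.05, 1.0), b=rng.uniform(-30, 10))
            curve = ps.PsychometricCurve(SNR_GRID, mfit(SNR_GRID))
            scaled = ps.scale_to_human(curve, mfit, hfit)
            assert np.all(np.diff(scaled.accuracy) >= -1e-12)
            assert np.all(scaled.accuracy >= 0) and np.all(scaled.accuracy <= 1)


class TestConfusions:
    def test_identity_rmse_zero(self):
        m = ps.ConfusionMatrix.from_predictions([1, 2, 3] * 10,
                                                [1, 2, 3] * 10)
        rmse, diag = ps.confusion_stats(m, m)
        assert rmse == 0.0
        assert diag[1] == 100.0

    def test_hand_computed_two_cell_difference(self):
        a = np.full((10, 10), 10.0)
        b = a.copy()
        b[0, 0] += 10.0
        b[0, 1] -= 10.0
        rmse, _ = ps.confusion_stats(a, b)
        assert rmse == pytest.approx(np.sqrt(200.0 / 100.0))

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a = ps.ConfusionMatrix.from_predictions(rng.integers(0, 10, 200),
                                                rng.integers(0, 10, 200))
        b = ps.ConfusionMatrix.from_predictions(rng.integers(0, 10, 200),
                                                rng.integers(0, 10, 200))
        assert ps.confusion_stats(a, b)[0] == ps.confusion_stats(b, a)[0]

    def test_unnormalized_rows_rejected(self):
        with pytest.raises(ValueError):
            ps.confusion_stats(np.full((10, 10), 5.0), np.full((10, 10), 10.0))


class TestPlots:
    def test_figures_render_and_save(self, tmp_path):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        rng = np.random.default_rng(6)
        curve = ps.PsychometricCurve(SNR_GRID, _human()(SNR_GRID),
                                     sem=np.full(len(SNR_GRID), 0.02), n=10)
        ax = ps.plot_psychometric({"NH": curve}, {"NH": _human()})
        ax.figure.savefig(tmp_path / "curve.png")
        cm = ps.ConfusionMatrix.from_predictions(rng.integers(0, 10, 300),
                                                 rng.integers(0, 10, 300),
                                                 snr_db=-20.0, source_id="demo")
        ax2 = ps.plot_confusion(cm)
        ax2.figure.savefig(tmp_path / "confusion.png")
        plt.close("all")
        assert (tmp_path / "curve.png").stat().st_size > 0
        assert (tmp_path / "confusion.png").stat().st_size > 0


def _threshold_table(effect_db=0.0, seed=0, n_folds=10):
    rng = np.random.default_rng(seed)
    rows = []
    for fold in range(n_folds):
        fold_offset = rng.normal(0, 0.3)
        for aud in ("NH", "flat", "sloping"):
            for anf in ("healthy", "degraded"):
                for mocr in (0, 20):
                    for paradigm in ("nh_control", "unconstrained",
                                     "constrained"):
                        value = fold_offset + rng.normal(0, 0.5)
                        if anf == "degraded":
                            value += effect_db
                        rows.append({"fold": fold, "audiometric": aud,
                                     "anf": anf, "mocr": mocr,
                                     "paradigm": paradigm,
                                     "threshold_db": value})
    return pd.DataFrame(rows)


class TestThresholdAnova:
    def test_injected_main_effect_detected(self):
        """A 5 dB ANF main effect with sigma=0.5 noise is significant at
        alpha=0.001 in every one of 50 simulations."""
        for seed in range(50):
            table = ps.threshold_anova(_threshold_table(5.0, seed))
            row = table[table["effect"] == "anf"].iloc[0]
            assert row["p"] < 0.001

    def test_null_f_statistics_near_one(self):
        """Pure-noise thresholds: mean F per effect over 200 simulations is
        near 1 (within [0.5, 2])."""
        fs = {}
        for seed in range(200):
            table = ps.threshold_anova(_threshold_table(0.0, 1000 + seed,
                                                        n_folds=4))
            for _, row in table.iterrows():
                fs.setdefault(row["effect"], []).append(row["F"])
        for effect, values in fs.items():
            assert 0.5 <= np.mean(values) <= 2.0, effect

    def test_permuting_labels_destroys_effect(self):
        table = _threshold_table(5.0, seed=7)
        rng = np.random.default_rng(8)
        table["anf"] = rng.permutation(table["anf"].to_numpy())
        # permutation leaves the design balanced only by chance; rebalance by
        # reassigning exactly half the rows per cell
        table["anf"] = np.tile(["healthy", "degraded"],
                               len(table) // 2)
        out = ps.threshold_anova(table)
        assert out[out["effect"] == "anf"]["p"].iloc[0] > 0.001

    def test_unbalanced_design_rejected(self):
        table = _threshold_table(0.0, 9).iloc[:-5]
        with pytest.raises(ValueError):
            ps.threshold_anova(table)
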