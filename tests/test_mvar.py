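"""MVAR lattice fitting, validation, spectral causality, sender summaries."""

import numpy as np
import pytest

from hyperflow.mvar import (
    MEASURES,
    MVARModel,
    band_mean_connectivity,
    causality_spectrum,
    fit_mvar,
    fit_mvar_sliding,
    sliding_window_positions,
    to_from_summary,
    top_senders,
    validate_model,
)
from hyperflow.synth import simulate_region_series


class TestFit:
    def test_sliding_grid_on_nc_epoch(self):
        win, step, starts = sliding_window_positions(768, 256.0, 0.5, 0.025)
        assert (win, step) == (128, 6)  # 25 ms rounds down to 6 samples
        assert len(starts) == (768 - 128) // 6 + 1 == 107

    def test_var2_coefficients_recovered(self):
        a1 = np.array([[0.5, 0.1], [0.0, 0.4]])
        a2 = np.array([[-0.2, 0.0], [0.15, -0.1]])
        x = simulate_region_series([a1, a2], 20000, 1.0, 7)
        model = fit_mvar(x, max_order=5)
        assert model.order == 2
        assert np.max(np.abs(model.coeffs - np.stack([a1, a2]))) < 0.05

    def test_constant_channel_rejected(self):
        x = np.zeros((2, 500))
        x[0] = np.random.default_rng(0).standard_normal(500)
        with pytest.raises(ValueError, match="singular|zero-variance"):
            fit_mvar(x, max_order=2)

    def test_epoch_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            fit_mvar_sliding(np.zeros((1, 2, 64)), 256.0, window=0.5)

    def test_aic_recovers_true_order(self):
        """AIC order selection on long multichannel samples.  The 2*p*d^2
        penalty makes spurious extra orders (chi-square_{d^2} improvements)
        rare once d > 1, the regime the region-group analysis runs in."""
        base = [
            np.array([[0.4, 0.1, 0.0], [0.0, 0.3, 0.1], [0.1, 0.0, 0.35]]),
            np.array([[-0.3, 0.0, 0.0], [0.05, -0.25, 0.0], [0.0, 0.05, -0.2]]),
            np.array([[0.2, 0.0, 0.05], [0.0, 0.15, 0.0], [0.0, 0.0, 0.2]]),
        ]
        hits = 0
        cases = []
        for true_p in (1, 2, 3):
            for seed in range(4):
                x = simulate_region_series(base[:true_p], 5000, 1.0, 10 * true_p + seed)
                m = fit_mvar(x, max_order=5)
                cases.append((true_p, m.order))
                hits += m.order == true_p
        assert hits >= 11, cases  # >= ~90% on long samples


class TestValidation:
    def test_stable_model_reported_stable(self):
        m = MVARModel(0.0, 1, np.array([[[0.7]]]), np.eye(1), 0.0, 256.0)
        assert m.spectral_radius() == pytest.approx(0.7)
        x = simulate_region_series([np.array([[0.7]])], 2000, 1.0, 0)
        rep = validate_model(m, x)
        assert rep.stable and rep.consistency > 80.0

    def test_unit_root_flagged_unstable(self):
        m = MVARModel(0.0, 1, np.array([[[1.0]]]), np.eye(1), 0.0, 256.0)
        rep = validate_model(m, np.cumsum(np.random.default_rng(0).standard_normal((1, 500)), axis=1))
        assert not rep.stable

    def test_whiteness_calibrated_on_true_model(self):
        """Residuals of the generating model are white: the portmanteau test
        rejects at roughly its nominal 5% level."""
        rejections = 0
        n_runs = 60
        for seed in range(n_runs):
            x = simulate_region_series([np.array([[0.5]])], 2000, 1.0, 300 + seed)
            m = fit_mvar(x, order=1)
            rep = validate_model(m, x, seed=seed)
            rejections += rep.whiteness_p < 0.05
        assert rejections <= 0.12 * n_runs


class TestCausalitySpectra:
    def test_independent_channels_no_cross_causality(self):
        model = MVARModel(
            0.0, 1, np.diag([0.5, -0.3, 0.2])[None], np.eye(3), 0.0, 256.0
        )
        for meas in MEASURES:
            _, vals = causality_spectrum(model, meas)
            off = vals[~np.eye(3, dtype=bool)]
            assert np.max(np.abs(off)) < 1e-6

    def test_pdc_column_normalization(self):
        rng = np.random.default_rng(3)
        a = 0.3 * rng.standard_normal((3, 3))
        a *= 0.9 / max(np.abs(np.linalg.eigvals(a)))
        model = MVARModel(0.0, 1, a[None], np.eye(3), 0.0, 256.0)
        freqs = np.arange(13.0, 51.0)
        phase = np.exp(-2j * np.pi * freqs[:, None, None] / 256.0)
        abar = np.eye(3)[None] - phase * a[None]
        pdc2 = np.abs(abar) ** 2 / (np.abs(abar) ** 2).sum(axis=1, keepdims=True)
        assert np.allclose(pdc2.sum(axis=1), 1.0)  # defining normalization
        # implementation reports the same squared entries off-diagonal
        _, vals = causality_spectrum(model, "nPDC", freqs)
        for i in range(3):
            for j in range(3):
                if i != j:
                    assert np.allclose(vals[j, i], pdc2[:, i, j])

    def test_unidirectional_coupling_ordered_all_measures(self):
        a = np.array([[0.6, 0.0], [0.5, 0.6]])  # channel 0 -> channel 1
        hits = {m: 0 for m in MEASURES}
        n_seeds = 10
        for seed in range(n_seeds):
            x = simulate_region_series([a], 2000, 1.0, seed)
            model = fit_mvar(x, max_order=5)
            for meas in MEASURES:
                _, vals = causality_spectrum(model, meas)
                bm = vals.mean(axis=-1)
                hits[meas] += bm[0, 1] > bm[1, 0]
        assert all(hits[m] == n_seeds for m in MEASURES), hits

    def test_band_mean_requires_stable_models(self):
        m = MVARModel(0.0, 1, np.array([[[1.2]]]), np.eye(1), 0.0, 256.0, stable=False)
        with pytest.raises(ValueError, match="stable"):
            band_mean_connectivity([m], "GGC")

    def test_values_nonnegative(self):
        x = simulate_region_series(
            [0.3 * np.random.default_rng(1).standard_normal((4, 4)) * 0.5], 3000, 1.0, 2
        )
        model = fit_mvar(x, max_order=3)
        for meas in MEASURES:
            _, vals = causality_spectrum(model, meas)
            assert np.all(vals >= 0.0)


class TestToFromSummary:
    def test_symmetric_matrix_zero_log_ratios(self, rng):
        c = rng.random((5, 5))
        c = (c + c.T) / 2
        summary = to_from_summary(c)
        assert np.allclose(summary.log_ratio, 0.0)

    def test_3x3_hand_computation(self):
        c = np.array([[0.0, 2.0, 4.0], [1.0, 0.0, 1.0], [2.0, 0.5, 0.0]])
        summary = to_from_summary(c)
        # region 0: partners 1, 2 -> (2/1 + 4/2) / 2 = 2
        assert summary.ratio[0] == pytest.approx((2.0 / 1.0 + 4.0 / 2.0) / 2)
        # region 1: (1/2 + 1/0.5) / 2 = 1.25
        assert summary.ratio[1] == pytest.approx((0.5 + 2.0) / 2)
        assert summary.log_ratio[2] == pytest.approx(
            (np.log(2.0 / 4.0) + np.log(0.5 / 1.0)) / 2
        )

    def test_pure_sender_flagged(self):
        c = np.array([[0.0, 1.0], [0.0, 0.0]])  # nothing flows into region 0
        with pytest.warns(UserWarning, match="floored"):
            summary = to_from_summary(c)
        assert (0, 1) in summary.flagged


class TestTopSenders:
    def test_all_equal_yields_empty(self):
        edges = top_senders(np.ones((5, 5)), retain_fraction=0.1)
        assert edges == []

    def test_exactly_top_fraction_retained(self, rng):
        d = 5  # 20 off-diagonal connections
        m = np.zeros((d, d))
        vals = rng.permutation(20).astype(float)
        k = 0
        for i in range(d):
            for j in range(d):
                if i != j:
                    m[i, j] = vals[k]
                    k += 1
        edges = top_senders(m, retain_fraction=0.10)
        got = sorted(e[2] for e in edges)
        assert got == [18.0, 19.0]  # the 2 largest of 20

    def test_boundary_tie_resolved_lexicographically(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[0, 2] = m[1, 0] = 1.0  # three-way tie at the maximum
        edges = top_senders(m, retain_fraction=1.0 / 6.0)
        assert edges == [(0, 1, 1.0)]
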