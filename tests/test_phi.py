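"""Binarization, TPM construction, integrated information, normalization."""

import numpy as np
import pytest

from hyperflow.config import CONDITIONS
from hyperflow.phi import (
    binarize_ramp,
    build_tpm,
    cross_coupling_tpm,
    factorized_tpm,
    global_mean,
    normalize_conditions,
    phi,
    phi_batch,
    stationary_distribution,
)

from oracles import phi_oracle


class TestBinarize:
    def test_rule_application(self):
        assert binarize_ramp(np.array([1.0, 2, 2, 1, 3])).tolist() == [1, 0, 0, 1]

    def test_strictly_decreasing_all_off(self):
        assert not binarize_ramp(np.arange(10.0)[::-1]).any()

    def test_factor_20_gives_12p8_hz_steps(self):
        x = np.arange(256.0 * 2)
        out = binarize_ramp(x, down_factor=20)
        assert len(out) == len(x[::20]) - 1
        assert 256.0 / 20 == pytest.approx(12.8)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            binarize_ramp(np.arange(5.0), down_factor=3)


class TestBuildTpm:
    def test_alternating_pair_is_deterministic(self):
        a = np.array([1.0, 2] * 6)
        b = np.array([2.0, 1] * 6)
        with pytest.warns(UserWarning, match="never visited"):
            model = build_tpm(a, b, 1)
        # states alternate 10 -> 01 -> 10 ...: visited rows are unit vectors
        assert model.tpm[1].tolist() == [0, 0, 1, 0]
        assert model.tpm[2].tolist() == [0, 1, 0, 0]
        assert model.unvisited[0] and model.unvisited[3]

    def test_hand_counted_toy(self):
        a = np.array([0.0, 1, 0, 1, 1, 0, 0, 1, 1, 1, 0, 1])
        b = np.array([1.0, 0, 0, 1, 0, 1, 1, 1, 0, 0, 1, 0])
        model = build_tpm(a, b, 1)
        # oracle: binarize by hand and count joint transitions directly
        ba = (np.diff(a) > 0).astype(int)
        bb = (np.diff(b) > 0).astype(int)
        joint = 2 * ba + bb
        counts = np.zeros((4, 4))
        for s, s2 in zip(joint[:-1], joint[1:]):
            counts[s, s2] += 1
        assert np.array_equal(model.counts, counts)
        visited = counts.sum(axis=1) > 0
        assert np.allclose(
            model.tpm[visited],
            counts[visited] / counts[visited].sum(axis=1, keepdims=True),
        )

    def test_shift_pooling_conserves_counts(self, rng):
        x = rng.standard_normal(200)
        y = rng.standard_normal(200)
        factor = 4
        model = build_tpm(x, y, factor)
        expected = 0
        for shift in range(factor):
            n_ds = len(x[shift:][::factor])
            expected += n_ds - 2  # transitions in the binarized series
        assert model.counts.sum() == expected

    def test_rows_stochastic(self, rng):
        model = build_tpm(rng.standard_normal(500), rng.standard_normal(500), 3)
        assert np.allclose(model.tpm.sum(axis=1), 1.0, atol=1e-12)

    def test_trial_pooling_adds_counts(self, rng):
        xs = [rng.standard_normal(100) for _ in range(3)]
        ys = [rng.standard_normal(100) for _ in range(3)]
        pooled = build_tpm(xs, ys, 2)
        singles = [build_tpm(x, y, 2) for x, y in zip(xs, ys)]
        assert np.array_equal(pooled.counts, sum(s.counts for s in singles))

    def test_shift_pooled_tpm_converges_to_single_shift(self):
        """As the series grows, the shift-pooled TPM approaches the
        single-shift TPM (both estimate the same process)."""
        rng = np.random.default_rng(0)

        def l1(n):
            x, y = rng.standard_normal(n), rng.standard_normal(n)
            pooled = build_tpm(x, y, 5).tpm
            single = build_tpm(x[::5], y[::5], 1).tpm
            return np.abs(pooled - single).sum()

        assert l1(40000) < l1(2000)


class TestPhi:
    def test_independent_product_is_zero(self, rng):
        f = rng.random((2, 2))
        f /= f.sum(axis=1, keepdims=True)
        g = rng.random((2, 2))
        g /= g.sum(axis=1, keepdims=True)
        prod = np.einsum("ax,by->abxy", f, g).reshape(4, 4)
        assert phi(prod).phi < 1e-12

    def test_fair_coins_zero(self):
        assert phi(np.full((4, 4), 0.25)).phi == 0.0

    def test_cross_copy_matches_bruteforce_oracle(self):
        det = cross_coupling_tpm(1.0)
        got = phi(det).phi
        assert got == pytest.approx(phi_oracle(det), abs=1e-12)
        assert got == pytest.approx(2.0)  # each node fully copies the other

    def test_random_tpms_match_oracle(self, rng):
        for _ in range(100):
            tpm = rng.random((4, 4))
            tpm /= tpm.sum(axis=1, keepdims=True)
            assert phi(tpm).phi == pytest.approx(phi_oracle(tpm), abs=1e-10)

    def test_batch_matches_scalar(self, rng):
        tpms = rng.random((50, 4, 4))
        tpms /= tpms.sum(axis=2, keepdims=True)
        scalar = np.array([phi(t).phi for t in tpms])
        assert np.max(np.abs(scalar - phi_batch(tpms))) < 1e-12

    def test_nonnegative_everywhere(self, rng):
        tpms = rng.random((200, 4, 4))
        tpms /= tpms.sum(axis=2, keepdims=True)
        assert np.all(phi_batch(tpms) >= 0.0)

    def test_monotone_in_cross_coupling(self):
        grid = np.linspace(0.0, 0.95, 12)
        vals = [phi(cross_coupling_tpm(c)).phi for c in grid]
        assert np.all(np.diff(vals) > 0)

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError, match="row-stochastic"):
            phi(np.ones((4, 4)))

    def test_stationary_distribution_is_invariant(self, rng):
        tpm = rng.random((4, 4))
        tpm /= tpm.sum(axis=1, keepdims=True)
        pi = stationary_distribution(tpm)
        assert np.allclose(pi @ tpm, pi, atol=1e-9)
        assert pi.sum() == pytest.approx(1.0)

    def test_factorized_tpm_is_stochastic(self, rng):
        tpm = rng.random((4, 4))
        tpm /= tpm.sum(axis=1, keepdims=True)
        q = factorized_tpm(tpm)
        assert np.allclose(q.sum(axis=1), 1.0)


class TestNormalization:
    def test_arithmetic_5_2_2(self):
        raw = {("c",): dict(zip(CONDITIONS, (5.0, 2.0, 2.0)))}
        out = normalize_conditions(raw)
        assert [out[("c",)][c] for c in CONDITIONS] == pytest.approx([2.0, -1.0, -1.0])

    def test_equal_values_all_zero(self):
        out = normalize_conditions({("c",): {c: 3.3 for c in CONDITIONS}})
        assert all(v == pytest.approx(0.0) for v in out[("c",)].values())

    def test_zero_sum_per_connection(self, rng):
        raw = {
            (i,): dict(zip(CONDITIONS, rng.random(3))) for i in range(20)
        }
        out = normalize_conditions(raw)
        for vals in out.values():
            assert sum(vals.values()) == pytest.approx(0.0, abs=1e-12)

    def test_missing_condition_excluded_with_warning(self):
        raw = {("a",): {c: 1.0 for c in CONDITIONS}, ("b",): {"TeamFlow": 1.0}}
        with pytest.warns(UserWarning, match="missing"):
            out = normalize_conditions(raw)
        assert ("b",) not in out and ("a",) in out


class TestGlobalMean:
    def test_single_connection_passthrough(self):
        norm = {("x",): dict(zip(CONDITIONS, (0.5, -0.25, -0.25)))}
        glob = global_mean(norm)
        assert glob["TeamFlow"] == pytest.approx(0.5)

    def test_toy_table_hand_mean(self):
        norm = {
            ("a",): dict(zip(CONDITIONS, (1.0, 0.0, -1.0))),
            ("b",): dict(zip(CONDITIONS, (3.0, -2.0, -1.0))),
        }
        glob = global_mean(norm)
        assert glob["TeamFlow"] == pytest.approx(2.0)
        assert glob["TeamOnly"] == pytest.approx(-1.0)
        assert sum(glob.values()) == pytest.approx(0.0)

    def test_empty_filter_rejected(self):
        norm = {("a",): {c: 0.0 for c in CONDITIONS}}
        with pytest.raises(ValueError, match="no connections"):
            global_mean(norm, connection_filter=lambda k: False)
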