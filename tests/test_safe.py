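"""Spatial extractor: closed-form attention vs numeric oracle, UCCF wiring."""

import numpy as np
import pytest
from scipy.optimize import minimize

from hastf.nn import Tensor
from hastf.safe import (
    SAFE,
    UCCF,
    SAParams,
    UCCFConfig,
    attention_refine,
    simam_energy,
    spatial_attention,
)

SIGMOID_HALF = 1.0 / (1.0 + np.exp(-0.5))  # ~0.62246


def energy_direct(w, b, t, others, lam):
    """The separability energy, written out verbatim for use as an oracle."""
    M1 = len(others)
    return (
        (1.0 - (w * t + b)) ** 2
        + np.mean((-1.0 - (w * others + b)) ** 2)
        + lam * w * w
    )


def analytic_minimizer(t, others, lam):
    # Stationary point of the energy with targets (+1 for t, -1 for the
    # rest); note the energy-minimizing slope is +2(t-u)/D for this
    # target assignment (the opposite sign corresponds to swapping the
    # two targets and leaves the minimum value unchanged).
    u = others.mean()
    var = others.var()
    w = 2.0 * (t - u) / ((t - u) ** 2 + 2 * var + 2 * lam)
    b = -0.5 * (t + u) * w
    return w, b


@pytest.mark.parametrize("lam", [1e-6, 1e-4, 1e-2])
def test_constant_slice_energy_is_exactly_two(lam):
    fm = np.full((3, 3), 2.7)
    assert simam_energy(fm, (1, 1), SAParams(lam=lam)) == pytest.approx(2.0, abs=1e-12)


@pytest.mark.parametrize("lam", [1e-6, 1e-4, 1e-2])
def test_closed_form_matches_numeric_minimization(lam):
    """Analytic e* equals the numerically minimized energy, over 100 maps."""
    rng = np.random.default_rng(100)
    worst = 0.0
    for _ in range(100):
        fm = rng.standard_normal((3, 3)) * rng.uniform(0.5, 3)
        r, c = rng.integers(0, 3, 2)
        t = fm[r, c]
        others = np.delete(fm.ravel(), r * 3 + c)
        e_analytic = simam_energy(fm, (r, c), SAParams(lam=lam))

        res = minimize(
            lambda p: energy_direct(p[0], p[1], t, others, lam),
            x0=[0.0, 0.0],
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 10000},
        )
        worst = max(worst, abs(e_analytic - res.fun) / abs(res.fun))

        w_a, b_a = analytic_minimizer(t, others, lam)
        assert energy_direct(w_a, b_a, t, others, lam) == pytest.approx(e_analytic, rel=1e-10)
        assert abs(w_a - res.x[0]) < 1e-5 and abs(b_a - res.x[1]) < 1e-5
    assert worst < 1e-6


def test_large_lambda_limit_gives_uniform_weights():
    rng = np.random.default_rng(4)
    fm = rng.standard_normal((5, 5))
    _, attn = spatial_attention(fm, SAParams(lam=1e9))
    np.testing.assert_allclose(attn.energies, 2.0, rtol=1e-6)
    np.testing.assert_allclose(attn.weights, SIGMOID_HALF, rtol=1e-6)


def test_constant_map_scales_by_sigmoid_half():
    fm = np.full((4, 9, 9), 3.0)
    refined, attn = spatial_attention(fm)
    np.testing.assert_allclose(refined, SIGMOID_HALF * fm, rtol=1e-12)
    np.testing.assert_allclose(attn.weights, SIGMOID_HALF)


def test_weights_in_unit_interval_and_sign_preserved():
    rng = np.random.default_rng(6)
    fm = rng.standard_normal((8, 9, 9)) * 5
    refined, attn = spatial_attention(fm)
    assert np.all(attn.weights > 0) and np.all(attn.weights < 1)
    assert np.all(np.sign(refined) == np.sign(fm))


def test_permutation_equivariance():
    rng = np.random.default_rng(7)
    fm = rng.standard_normal((6, 6))
    perm = rng.permutation(36)
    _, attn = spatial_attention(fm)
    _, attn_p = spatial_attention(fm.ravel()[perm].reshape(6, 6))
    np.testing.assert_allclose(attn_p.weights.ravel(), attn.weights.ravel()[perm], rtol=1e-12)


def test_outlier_position_gets_above_median_weight():
    rng = np.random.default_rng(8)
    for _ in range(100):
        fm = rng.standard_normal((5, 5))
        r, c = rng.integers(0, 5, 2)
        fm[r, c] = 10.0 * np.sign(rng.standard_normal() + 1e-9)
        _, attn = spatial_attention(fm)
        assert attn.weights[r, c] > np.median(attn.weights)


def test_leave_one_out_statistics_are_exact():
    rng = np.random.default_rng(9)
    fm = rng.standard_normal((4, 4))
    _, attn = spatial_attention(fm)
    r, c = 2, 1
    others = np.delete(fm.ravel(), r * 4 + c)
    assert attn.mean[r, c] == pytest.approx(others.mean(), abs=1e-12)
    assert attn.variance[r, c] == pytest.approx(others.var(), abs=1e-12)


def test_shared_statistics_mode():
    rng = np.random.default_rng(10)
    fm = rng.standard_normal((4, 4))
    _, attn = spatial_attention(fm, SAParams(statistics_mode="shared"))
    np.testing.assert_allclose(attn.mean, fm.mean(), rtol=1e-12)


def test_attention_has_zero_parameters():
    rng = np.random.default_rng(0)
    cfg = UCCFConfig(filters=(4, 8, 8, 4, 4))
    with_sa = SAFE(cfg, 16, np.random.default_rng(0), use_attention=True)
    without = SAFE(cfg, 16, np.random.default_rng(0), use_attention=False)
    assert with_sa.n_parameters() == without.n_parameters()


def test_differentiable_attention_matches_numpy_path():
    rng = np.random.default_rng(11)
    x = rng.standard_normal((3, 2, 9, 9))
    refined_np, _ = spatial_attention(x)
    refined_t = attention_refine(Tensor(x))
    np.testing.assert_allclose(refined_t.data, refined_np, rtol=1e-12)


class TestUCCF:
    CFG = UCCFConfig(filters=(4, 8, 8, 4, 4))

    def test_zero_weights_give_zero_output(self):
        net = UCCF(self.CFG, np.random.default_rng(0))
        for p in net.parameters():
            p.data[:] = 0.0
        out = net(Tensor(np.random.default_rng(1).standard_normal((2, 5, 9, 9))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_spatial_dims_preserved(self):
        net = UCCF(self.CFG, np.random.default_rng(0))
        out = net(Tensor(np.random.default_rng(1).standard_normal((3, 5, 9, 9))))
        assert out.shape == (3, self.CFG.filters[4], 9, 9)

    def test_skip_concatenation_channel_counts(self):
        assert self.CFG.layer4_in == self.CFG.filters[2] + self.CFG.filters[1]
        assert self.CFG.layer5_in == self.CFG.filters[3] + self.CFG.filters[0]
        net = UCCF(self.CFG, np.random.default_rng(0))
        assert net.conv4.weight.shape[1] == self.CFG.layer4_in
        assert net.conv5.weight.shape[1] == self.CFG.layer5_in

    def test_gradient_reaches_all_five_layers(self):
        net = UCCF(self.CFG, np.random.default_rng(2))
        x = Tensor(np.random.default_rng(3).standard_normal((2, 5, 9, 9)))
        (net(x) ** 2).sum().backward()
        for conv in (net.conv1, net.conv2, net.conv3, net.conv4, net.conv5):
            assert conv.weight.grad is not None
            assert np.any(conv.weight.grad != 0)

    def test_determinism_given_weights(self):
        x = np.random.default_rng(4).standard_normal((2, 5, 9, 9))
        net = UCCF(self.CFG, np.random.default_rng(5))
        np.testing.assert_array_equal(net(Tensor(x)).data, net(Tensor(x)).data)


class TestSAFEForward:
    def test_output_dim_is_projection_width(self):
        safe = SAFE(UCCFConfig(filters=(4, 8, 8, 4, 4)), 24, np.random.default_rng(0))
        out = safe(Tensor(np.random.default_rng(1).standard_normal((6, 5, 9, 9))))
        assert out.shape == (6, 24)

    def test_disabling_attention_changes_output(self):
        cfg = UCCFConfig(filters=(4, 8, 8, 4, 4))
        a = SAFE(cfg, 16, np.random.default_rng(0), use_attention=True)
        b = SAFE(cfg, 16, np.random.default_rng(0), use_attention=False)
        x = Tensor(np.random.default_rng(2).standard_normal((3, 5, 9, 9)))
        assert not np.allclose(a(x).data, b(x).data)

    def test_pooled_spatial_size(self):
        from hastf.nn import maxpool2d

        out = maxpool2d(Tensor(np.zeros((1, 4, 9, 9))), 2)
        assert out.shape[-2:] == (4, 4)
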