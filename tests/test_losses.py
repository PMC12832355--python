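"""Loss-kernel checks: closed forms, independent oracles, limits, baselines."""

import numpy as np
import pytest
from scipy.stats import multivariate_t

from dnatloss import losses
from dnatloss.autodiff import Tensor
from dnatloss.losses import (LossConfig, baseline_loss, cross_entropy,
                             fit_nu_mle, gaussian_nll, student_t_nll,
                             student_t_nll_per_image)
from dnatloss.synthetic import sample_t_residuals


def mvt_oracle_nll(delta, lam, nu) -> float:
    """Independent multivariate-t log-density via scipy."""
    d = len(delta)
    dist = multivariate_t(loc=np.zeros(d), shape=np.diag(np.exp(-lam)), df=nu)
    return -float(dist.logpdf(delta))


class TestStudentTNLL:
    def test_standard_cauchy_mode(self):
        # D=1, δ=0, λ=0, ν=1: NLL of a standard Cauchy at its mode is ln π
        val = student_t_nll(np.zeros(1), np.zeros(1), 1.0).item()
        assert val == pytest.approx(np.log(np.pi), rel=1e-12)

    def test_standard_cauchy_at_one(self):
        # Cauchy density at 1 is 1/(2π), so the NLL is ln 2π
        val = student_t_nll(np.ones(1), np.zeros(1), 1.0).item()
        assert val == pytest.approx(np.log(2 * np.pi), rel=1e-12)

    def test_matches_multivariate_t_oracle(self, rng):
        for _ in range(200):
            d = int(rng.integers(1, 17))
            delta = rng.uniform(-1, 1, d)
            lam = rng.uniform(-2, 2, d)
            nu = float(rng.uniform(0.3, 30))
            ours = student_t_nll(delta, lam, nu).item()
            assert ours == pytest.approx(mvt_oracle_nll(delta, lam, nu), rel=1e-6)

    def test_gaussian_limit(self, rng):
        for _ in range(50):
            d = int(rng.integers(1, 17))
            delta = rng.uniform(-1, 1, d)
            lam = rng.uniform(-2, 2, d)
            t_val = student_t_nll(delta, lam, 1e8).item()
            g_val = gaussian_nll(delta, lam).item()
            assert abs(t_val - g_val) < 1e-3

    def test_batched_equals_loop(self, rng):
        deltas = rng.uniform(-1, 1, (5, 4, 4))
        lam = rng.uniform(-1, 1, (4, 4))
        nus = rng.uniform(1, 6, 5)
        per = student_t_nll_per_image(deltas, lam, nus)
        loop = [student_t_nll(deltas[i], lam, nus[i]).item() for i in range(5)]
        np.testing.assert_allclose(per.data, loop, rtol=1e-12)

    def test_monotone_penalty_in_lambda(self):
        # raising λ_i always raises the squared-Mahalanobis penalty; once
        # that penalty dominates the −½λ log-determinant credit (λ ≥ 1 at
        # |δ| = 1) the loss itself rises too
        delta = np.array([[1.0, 0.0], [0.0, 0.0]])
        quads, vals = [], []
        for lam_val in (1.0, 2.0, 3.0):
            lam = np.zeros((2, 2))
            lam[0, 0] = lam_val
            quads.append(float((delta**2 * np.exp(lam)).sum()))
            vals.append(student_t_nll(delta, lam, 3.0).item())
        assert np.all(np.diff(quads) > 0)
        assert np.all(np.diff(vals) > 0)

    def test_heavy_tail_downweights_large_residuals(self):
        # in the large-residual regime (λ=2 so δ²e^λ ≈ 7.4) the excess loss
        # over the zero-residual baseline is smaller for ν=1 than ν=100
        lam = np.full(1, 2.0)
        excess = {}
        for nu in (1.0, 100.0):
            at = student_t_nll(np.ones(1), lam, nu).item()
            base = student_t_nll(np.zeros(1), lam, nu).item()
            excess[nu] = at - base
        assert excess[1.0] < excess[100.0]

    def test_differentiable_in_all_arguments(self, rng):
        delta = Tensor(rng.uniform(-1, 1, (3, 3)), requires_grad=True)
        lam = Tensor(rng.uniform(-1, 1, (3, 3)), requires_grad=True)
        nu = Tensor(np.array(2.5), requires_grad=True)
        student_t_nll(delta, lam, nu).backward()
        assert delta.grad is not None and np.any(delta.grad != 0)
        assert lam.grad is not None and np.any(lam.grad != 0)
        assert nu.grad is not None and np.all(np.isfinite(nu.grad))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="match"):
            student_t_nll(np.zeros((3, 3)), np.zeros((2, 2)), 1.0)

    def test_nonpositive_nu_rejected(self):
        for bad in (0.0, -1.0):
            with pytest.raises(ValueError, match="positive"):
                student_t_nll(np.zeros((2, 2)), np.zeros((2, 2)), bad)

    def test_finite_for_extreme_lambda(self):
        # clamping keeps e^λ finite even for absurd λ
        val = student_t_nll(np.ones((2, 2)), np.full((2, 2), 1e4), 2.0).item()
        assert np.isfinite(val)


class TestGaussianNLL:
    def test_standard_normal_mode(self):
        val = gaussian_nll(np.zeros(1), np.zeros(1)).item()
        assert val == pytest.approx(0.5 * np.log(2 * np.pi), rel=1e-12)

    def test_two_pixel_closed_form(self):
        val = gaussian_nll(np.array([1.0, -1.0]), np.zeros(2)).item()
        assert val == pytest.approx(np.log(2 * np.pi) + 1.0, rel=1e-12)


class TestNuRecovery:
    @pytest.mark.parametrize("nu_star", [2.0, 4.0])
    def test_mle_recovers_true_dof(self, nu_star):
        r = sample_t_residuals(10_000, nu_star, seed=7)
        fit = fit_nu_mle(r)
        assert abs(fit - nu_star) / nu_star < 0.15


class TestBaselineLosses:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.mask = (rng.random((6, 6)) < 0.3).astype(np.uint8)
        self.prob = np.clip(self.mask + rng.normal(0, 0.2, (6, 6)), 0, 1)

    def test_mae_identity_is_zero(self):
        assert baseline_loss("mae", self.mask.astype(float), self.mask).item() == 0.0

    def test_gce_small_q_approaches_cross_entropy(self):
        gce = baseline_loss("gce", self.prob, self.mask, {"q": 1e-5}).item()
        ce = cross_entropy(self.prob, self.mask).item()
        assert gce == pytest.approx(ce, rel=1e-3)

    def test_tloss_fixed_reduces_to_student_t(self):
        nu = 3.0
        tl = baseline_loss("tloss_fixed", self.prob, self.mask, {"nu": nu}).item()
        direct = student_t_nll(self.prob - self.mask, np.zeros((6, 6)), nu).item()
        assert tl == pytest.approx(direct, rel=1e-12)

    @pytest.mark.parametrize("name", ["gce", "sce", "rce", "ngce", "mae"])
    def test_finite_and_nonnegative(self, name):
        val = baseline_loss(name, self.prob, self.mask).item()
        assert np.isfinite(val) and val >= 0

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown baseline"):
            baseline_loss("focal", self.prob, self.mask)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            baseline_loss("mae", self.prob * 2 + 0.5, self.mask)


class TestLossConfig:
    def test_epsilon_must_be_positive(self):
        with pytest.raises(ValueError):
            LossConfig(epsilon=0.0)

    def test_reduction_sum_vs_mean(self, rng):
        deltas = rng.uniform(-1, 1, (4, 3, 3))
        lam = np.zeros((3, 3))
        s = student_t_nll(deltas, lam, 2.0, LossConfig(reduction="sum")).item()
        m = student_t_nll(deltas, lam, 2.0, LossConfig(reduction="mean")).item()
        assert s == pytest.approx(4 * m, rel=1e-12)
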