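"""GRL semantics, classifier heads, cross-entropy, total objective."""

import math

import numpy as np
import pytest

from neurofuse.autodiff import Parameter, Tensor
from neurofuse.heads import (DiseaseHead, HeadsParams, SiteHead,
                             cross_entropy, grl, total_loss)


class TestGRL:
    def test_forward_is_identity_bit_exact(self, rng):
        z = Tensor(rng.normal(size=(4, 8)))
        assert np.array_equal(grl(z).data, z.data)

    def test_backward_negates_unit_gradient(self, rng):
        z = Parameter(rng.normal(size=(3, 5)))
        grl(z).sum().backward()
        np.testing.assert_array_equal(z.grad, -np.ones((3, 5)))

    def test_adversarial_gradient_matches_finite_differences(self, rng):
        """grad of beta*L_S w.r.t. upstream parameters equals
        -beta * dL_S/dtheta on a small dense model."""
        beta = 0.1
        theta = Parameter(rng.normal(size=(4, 3)))  # upstream "fusion" map
        w_site = Parameter(rng.normal(size=(3, 4)))
        x = rng.normal(size=(5, 4))
        sites = np.array([0, 1, 2, 3, 0])

        def loss_through_grl():
            z = Tensor(x) @ theta
            return cross_entropy(grl(z) @ w_site, sites) * beta

        def site_loss_plain(data=None):
            z = x @ theta.data
            logits = z @ w_site.data
            logits -= logits.max(axis=1, keepdims=True)
            logp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
            return -logp[np.arange(5), sites].mean()

        theta.grad = None
        loss_through_grl().backward()
        eps = 1e-6
        for ix in [(0, 0), (1, 2), (3, 1)]:
            old = theta.data[ix]
            theta.data[ix] = old + eps
            fp = site_loss_plain()
            theta.data[ix] = old - eps
            fm = site_loss_plain()
            theta.data[ix] = old
            fd = (fp - fm) / (2 * eps)  # dL_S/dtheta
            assert abs(theta.grad[ix] - (-beta * fd)) < 1e-4 * max(
                abs(fd), 1e-3)


class TestClassifierHeads:
    def test_disease_head_input_width_is_three_embeddings(self, rng):
        head = DiseaseHead(HeadsParams(d_out=128), np.random.default_rng(0))
        assert head.linear.weight.shape == (384, 2)

    def test_zero_weights_give_bias_logits(self, rng):
        head = DiseaseHead(HeadsParams(d_out=4), np.random.default_rng(0))
        head.linear.weight.data[:] = 0.0
        head.linear.bias.data[:] = [0.3, -0.7]
        z = Tensor(rng.normal(size=(3, 4)))
        out = head(z, z, z).data
        np.testing.assert_allclose(out, np.tile([0.3, -0.7], (3, 1)))

    def test_disease_head_matches_hand_multiplication(self, rng):
        head = DiseaseHead(HeadsParams(d_out=2), np.random.default_rng(1))
        z_ts, z_gm, z_f = (rng.normal(size=(2, 2)) for _ in range(3))
        got = head(Tensor(z_ts), Tensor(z_gm), Tensor(z_f)).data
        cat = np.concatenate([z_ts, z_gm, z_f], axis=1)
        want = cat @ head.linear.weight.data + head.linear.bias.data
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_site_head_full_cohort_layout(self, rng):
        head = SiteHead(HeadsParams(d_out=8, n_sites=25),
                        np.random.default_rng(0))
        out = head(Tensor(rng.normal(size=(3, 8))))
        assert out.shape == (3, 25)

    def test_site_head_forward_identical_with_and_without_grl(self, rng):
        head = SiteHead(HeadsParams(d_out=4, n_sites=3),
                        np.random.default_rng(0))
        z = Tensor(rng.normal(size=(2, 4)))
        np.testing.assert_array_equal(head(z, apply_grl=True).data,
                                      head(z, apply_grl=False).data)

    def test_mismatched_embedding_width_rejected(self, rng):
        head = DiseaseHead(HeadsParams(d_out=4), np.random.default_rng(0))
        z = Tensor(rng.normal(size=(2, 4)))
        bad = Tensor(rng.normal(size=(2, 5)))
        with pytest.raises(ValueError):
            head(z, z, bad)


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        logits = Tensor(np.array([[100.0, -100.0], [-100.0, 100.0]]))
        assert cross_entropy(logits, np.array([0, 1])).item() < 1e-12

    def test_uniform_prediction_binary_is_ln2(self):
        logits = Tensor(np.zeros((4, 2)))
        assert abs(cross_entropy(logits, np.array([0, 1, 0, 1])).item()
                   - math.log(2)) < 1e-12

    def test_uniform_prediction_25_sites_is_ln25(self):
        logits = Tensor(np.zeros((3, 25)))
        assert abs(cross_entropy(logits, np.array([0, 12, 24])).item()
                   - math.log(25)) < 1e-12

    def test_label_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy(Tensor(np.zeros((2, 2))), np.array([0, 2]))

    def test_logit_shift_invariance(self, rng):
        logits = rng.normal(size=(6, 4))
        y = rng.integers(0, 4, size=6)
        a = cross_entropy(Tensor(logits), y).item()
        b = cross_entropy(Tensor(logits + 123.456), y).item()
        assert abs(a - b) < 1e-9


class TestTotalLoss:
    def test_beta_zero_reduces_to_disease_loss(self, rng):
        ld = Tensor(1.234)
        ls = Tensor(5.0)
        bundle = total_loss(ld, ls, beta=0.0)
        assert bundle.total.item() == pytest.approx(1.234)
        assert bundle.reported_objective == pytest.approx(1.234)

    def test_default_beta_arithmetic(self):
        bundle = total_loss(Tensor(1.0), Tensor(2.0), beta=0.1)
        assert bundle.total.item() == pytest.approx(1.1)
        assert bundle.reported_objective == pytest.approx(0.7)

    def test_monotone_in_disease_loss(self):
        lo = total_loss(Tensor(0.5), Tensor(2.0), beta=0.2).total.item()
        hi = total_loss(Tensor(1.5), Tensor(2.0), beta=0.2).total.item()
        assert hi > lo

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            total_loss(Tensor(1.0), Tensor(1.0), beta=1.0)

    def test_beta_zero_site_head_receives_no_gradient(self, rng):
        w_site = Parameter(rng.normal(size=(4, 3)))
        z = Tensor(rng.normal(size=(2, 4)))
        ld = cross_entropy(Tensor(rng.normal(size=(2, 2))), np.array([0, 1]))
        ls = cross_entropy(grl(z) @ w_site, np.array([0, 1]))
        bundle = total_loss(ld, ls, beta=0.0)
        bundle.total.backward()
        assert w_site.grad is None or np.allclose(w_site.grad, 0.0)


class TestUpdateDirections:
    def test_one_step_moves_site_head_down_and_features_up_in_site_loss(
            self, rng):
        """On a toy model one optimization step decreases L_S w.r.t. the
        site head while the shared features move to increase L_S."""
        from neurofuse.nn import AdamW

        x = rng.normal(size=(8, 3))
        y = rng.integers(0, 2, size=8)
        sites = rng.integers(0, 3, size=8)
        theta_m = Parameter(rng.normal(size=(3, 4)) * 0.5)
        w_d = Parameter(rng.normal(size=(4, 2)) * 0.5)
        w_s = Parameter(rng.normal(size=(4, 3)) * 0.5)

        def losses():
            z = Tensor(x) @ theta_m
            ld = cross_entropy(z @ w_d, y)
            ls = cross_entropy(grl(z) @ w_s, sites)
            return ld, ls

        def site_loss_at(theta_m_data, w_s_data):
            z = x @ theta_m_data
            logits = z @ w_s_data
            logits = logits - logits.max(axis=1, keepdims=True)
            logp = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))
            return -logp[np.arange(8), sites].mean()

        before_head = site_loss_at(theta_m.data.copy(), w_s.data.copy())
        theta0 = theta_m.data.copy()
        ws0 = w_s.data.copy()
        opt = AdamW([theta_m, w_d, w_s], lr=1e-3, weight_decay=0.0,
                    clip_norm=None)
        ld, ls = losses()
        bundle = total_loss(ld, ls, beta=0.3)
        opt.zero_grad()
        bundle.total.backward()
        opt.step()
        # site head moved to decrease L_S (features frozen at old values)
        assert site_loss_at(theta0, w_s.data) < before_head
        # features moved to increase L_S (head frozen at old values)
        assert site_loss_at(theta_m.data, ws0) > before_head
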