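"""The estimation network: conditioning shapes, masking schedule, WGAN-GP
loss identities, differentiable reconstruction against closed forms and
finite differences, bounded generated parameters, inference batching and
candidate selection."""

import numpy as np
import pytest

import epgan._autodiff as ad
from conftest import make_leak_only
from epgan import datagen as dg
from epgan import hh_core as hh
from epgan import protocols as pr
from epgan._autodiff import Tensor, grad
from epgan.gan import (
    EPGAN,
    Critic,
    DifferentiableHH,
    Encoder,
    Generator,
    MaskSchedule,
    discriminator_loss,
    generator_loss,
    mask_rate,
    reconstruct_voltage,
    select_best_candidate,
    TrainConfig,
)

RNG = lambda s=0: np.random.default_rng(s)  # noqa: E731


def small_model(records, **kw):
    args = dict(mode="small", epochs=2, batch_size=4, critic_steps=2,
                latent_size=64, gen_widths=(64, 64, 32), critic_widths=(32, 16, 8),
                seed=0)
    args.update(kw)
    m = EPGAN(**args)
    return m


class TestMaskSchedule:
    def test_endpoints_and_linearity(self):
        sched = MaskSchedule(total_epochs=21)
        assert mask_rate(0, sched) == 0.75
        assert mask_rate(20, sched) == 0.0
        assert mask_rate(10, sched) == pytest.approx(0.375)
        rates = [mask_rate(e, sched) for e in range(21)]
        np.testing.assert_allclose(np.diff(rates), np.diff(rates)[0])

    def test_out_of_range_epoch(self):
        sched = MaskSchedule(total_epochs=5)
        with pytest.raises(ValueError):
            mask_rate(5, sched)
        with pytest.raises(ValueError):
            mask_rate(-1, sched)


class TestEncoder:
    def test_latent_and_conditioning_sizes(self):
        enc = Encoder(1024, RNG(0))
        v = RNG(1).normal(size=(2, 11, 350))
        s = np.zeros((2, 11, 350))
        iv = RNG(2).normal(size=(2, 18))
        cond = enc(v, s, iv)
        assert cond.shape == (2, 1042)  # 1024 latent + 18 currents

    def test_variable_step_count_accepted(self):
        enc = Encoder(32, RNG(0))
        v = RNG(1).normal(size=(3, 11, 350))
        s = np.zeros_like(v)
        iv = np.zeros((3, 18))
        full = enc(v, s, iv)
        partial = enc(v, s, iv, keep=[0, 4, 7, 9, 10])
        assert full.shape == partial.shape == (3, 50)
        assert not np.allclose(full.data, partial.data)

    def test_deterministic_in_eval(self):
        enc = Encoder(16, RNG(0))
        v = RNG(1).normal(size=(2, 5, 350))
        s, iv = np.zeros_like(v), np.zeros((2, 18))
        np.testing.assert_array_equal(enc(v, s, iv).data, enc(v, s, iv).data)

    def test_all_masked_raises(self):
        enc = Encoder(16, RNG(0))
        v = np.zeros((1, 3, 350))
        with pytest.raises(ValueError):
            enc(v, v, np.zeros((1, 18)), keep=[])


class TestGeneratorOutputs:
    @pytest.mark.parametrize("mode,n_out", [("small", 47), ("large", 175)])
    def test_output_dimension_per_mode(self, mode, n_out):
        space = hh.build_parameter_space(mode)
        diff = DifferentiableHH(space)
        assert diff.n_train == n_out
        gen = Generator(50, n_out, RNG(0), widths=(32, 32, 16))
        out = gen(Tensor(RNG(1).normal(size=(4, 50))))
        assert out.shape == (4, n_out)
        assert np.all(np.abs(out.data) <= 1.0)

    def test_rescaled_values_within_bounds_and_endpoints(self, space_small):
        diff = DifferentiableHH(space_small)
        z = np.clip(RNG(2).normal(size=(8, 47)), -1, 1)
        full = diff.full_params(Tensor(z)).data
        assert np.all(full >= space_small.lower - 1e-12)
        assert np.all(full <= space_small.upper + 1e-12)
        hi = diff.full_params(Tensor(np.ones((1, 47)))).data[0]
        tr = space_small.trainable
        np.testing.assert_allclose(hi[tr], space_small.upper[tr])
        lo = diff.full_params(Tensor(-np.ones((1, 47)))).data[0]
        np.testing.assert_allclose(lo[tr], space_small.lower[tr])


class TestDiscriminatorLoss:
    def test_constant_critic_gives_lambda(self, space_small):
        critic = Critic(10, 5, RNG(0), widths=(8, 8, 4))
        for p in critic.parameters():
            p.data[:] = 0.0  # D == 0 everywhere, zero input gradient
        cond = Tensor(np.zeros((6, 10)))
        real = RNG(1).normal(size=(6, 5))
        fake = RNG(2).normal(size=(6, 5))
        loss, parts = discriminator_loss(critic, cond, real, fake, lam=10.0, rng=RNG(3))
        assert loss.item() == pytest.approx(10.0, abs=1e-4)
        assert parts["wasserstein"] == pytest.approx(0.0)

    def test_lambda_zero_identical_batches(self):
        critic = Critic(4, 3, RNG(0), widths=(8, 8, 4))
        cond = Tensor(np.zeros((5, 4)))
        x = RNG(1).normal(size=(5, 3))
        loss, _ = discriminator_loss(critic, cond, x, x.copy(), lam=0.0, rng=RNG(2))
        assert loss.item() == pytest.approx(0.0, abs=1e-12)

    def test_linear_critic_penalty_closed_form(self):
        """D(cond, p) = w.p: gradient norm is ||w|| for every interpolate."""
        critic = Critic(2, 4, RNG(0), widths=(4, 4, 4))
        w = np.array([0.3, -1.2, 0.5, 2.0])
        # build an explicitly linear critic: first layer passes p through,
        # other layers identity-like is fiddly; instead test via direct graph
        p_hat = Tensor(RNG(1).normal(size=(7, 4)), requires_grad=True)
        d = ad.tsum(p_hat * Tensor(w), axis=1)
        g = grad(ad.tsum(d), p_hat, create_graph=True)
        norm = ad.sqrt(ad.tsum(g * g, axis=1))
        pen = ad.tmean((norm - 1.0) ** 2)
        assert pen.item() == pytest.approx((np.linalg.norm(w) - 1.0) ** 2, rel=1e-9)


class TestReconstruction:
    def test_zero_derivative_model_constant(self, space_small):
        pv = make_leak_only(space_small, g_leak=0.0)
        t = 4.0 + 0.02 * np.arange(350)
        V = np.full((1, 350), -63.0)
        w = pr.WindowedInput(t, V, np.zeros_like(V), hh.steady_state_iv(pv), np.array([0.0]))
        out = reconstruct_voltage(pv, w)
        np.testing.assert_allclose(out, -63.0, atol=1e-12)

    def test_first_sample_equals_v_init(self, tiny_corpus):
        r = tiny_corpus[0]
        out = reconstruct_voltage(r.params, r.windowed)
        np.testing.assert_allclose(out[:, 0], r.windowed.V[:, 0], atol=1e-12)

    def test_truth_params_match_on_slow_leak_fixture(self, space_small):
        """Single-segment Euler rebuild vs a fine-step integration: < 1 mV
        on a slow RC membrane with gentle stimuli."""
        pv = make_leak_only(space_small, g_leak=0.1, c_m=8.0)
        proto = pr.build_protocol(-0.5, 0.25, 0.5, "current")
        ts = pr.simulate_current_clamp(pv, proto, dt=0.05)
        w = pr.window_traces(ts, hh.steady_state_iv(pv))
        out = reconstruct_voltage(pv, w, h=20.0)
        assert np.abs(out - w.V).max() < 1.0

    def test_one_step_anchoring_truth_floor_small(self, tiny_corpus):
        r = tiny_corpus[0]
        out = reconstruct_voltage(r.params, r.windowed, anchor_every=1)
        assert np.abs(out - r.windowed.V).mean() < 2.0

    def test_differentiable_iv_equals_analytic(self, space_small):
        diff = DifferentiableHH(space_small)
        rng = RNG(4)
        pv = dg.sample_parameter_set(space_small, rng)
        z = space_small.normalize(pv.values)[space_small.trainable][None, :]
        got = diff.steady_iv(diff.full_params(Tensor(z))).data[0]
        np.testing.assert_allclose(got, hh.steady_state_iv(pv).currents, atol=1e-8)


class TestGeneratorLoss:
    def make_batch(self, space, B=2, L=3, T=30, seed=0):
        rng = RNG(seed)
        diff = DifferentiableHH(space)
        v = rng.normal(-60, 8, size=(B, L, T))
        s = rng.normal(0, 4, size=(B, L, T))
        iv = rng.normal(0, 25, size=(B, 18))
        z = rng.uniform(-0.6, 0.6, size=(B, diff.n_train))
        return diff, v, s, iv, z

    def test_components_match_scalar_loop(self, space_small):
        diff, v, s, iv, z = self.make_batch(space_small)
        cfg = TrainConfig(anchor_every=1)
        critic = Critic(10, diff.n_train, RNG(1), widths=(8, 8, 4))
        cond = Tensor(np.zeros((2, 10)))
        fake = Tensor(z)
        total, parts = generator_loss(critic, cond, fake, diff, v, s, iv, cfg)
        P = diff.full_params(Tensor(z))
        v_rec = diff.reconstruct(P, v, s, cfg.h, anchor_every=1).data
        j_v = np.mean([np.abs(v[b] - v_rec[b]).sum() for b in range(2)])
        iv_pred = diff.steady_iv(P).data
        j_iv = np.mean([np.abs(iv[b] - iv_pred[b]).sum() for b in range(2)])
        assert parts["j_v"] == pytest.approx(j_v, rel=1e-12)
        assert parts["j_iv"] == pytest.approx(j_iv, rel=1e-12)
        d = critic(cond, fake).data
        assert parts["j_adv"] == pytest.approx(-d.mean(), rel=1e-9)
        assert total.item() == pytest.approx(
            cfg.w_adv * parts["j_adv"] + cfg.w_v * j_v + cfg.w_iv * j_iv, rel=1e-9
        )

    def test_perfect_reconstruction_leaves_only_adversarial(self, space_small):
        """If the reconstruction and I-V match the truth exactly, J_V = J_IV = 0.

        Fixture: a pure capacitor (all conductances zero), whose teacher-
        forced Euler rebuild is exact when the truth itself is the Euler
        sequence of the stimulus."""
        diff = DifferentiableHH(space_small)
        pv = make_leak_only(space_small, g_leak=0.0, c_m=4.0)
        z = space_small.normalize(pv.values)[space_small.trainable][None, :]
        T = 40
        rng = RNG(3)
        s = rng.normal(0.0, 5.0, size=(1, 2, T))
        v = np.empty((1, 2, T))
        v[..., 0] = -60.0
        for t in range(1, T):
            v[..., t] = v[..., t - 1] + 20.0 * s[..., t - 1] / 4.0
        iv_true = np.zeros((1, 18))  # no conductances, no currents
        cfg = TrainConfig(anchor_every=1)
        critic = Critic(4, diff.n_train, RNG(2), widths=(4, 4, 4))
        total, parts = generator_loss(
            critic, Tensor(np.zeros((1, 4))), Tensor(z), diff, v, s, iv_true, cfg
        )
        assert parts["j_v"] == pytest.approx(0.0, abs=1e-9)
        assert parts["j_iv"] == pytest.approx(0.0, abs=1e-9)
        assert total.item() == pytest.approx(parts["j_adv"], abs=1e-9)

    @pytest.mark.parametrize("mode", ["small", "large"])
    def test_gradients_match_finite_differences(self, mode):
        """End-to-end J_V + J_IV gradient through the reconstruction graph."""
        space = hh.build_parameter_space(mode)
        diff = DifferentiableHH(space)
        rng = RNG(7)
        B, L, T = 2, 2, 15
        v = rng.normal(-60, 8, size=(B, L, T))
        s = rng.normal(0, 4, size=(B, L, T))
        iv = rng.normal(0, 25, size=(B, 18))
        z0 = rng.uniform(-0.5, 0.5, size=(B, diff.n_train))

        def loss(zd):
            z = Tensor(zd, requires_grad=True)
            P = diff.full_params(z)
            vr = diff.reconstruct(P, v, s, 20.0, anchor_every=1)
            jv = ad.tsum(ad.absolute(Tensor(v) - vr))
            jiv = ad.tsum(ad.absolute(Tensor(iv) - diff.steady_iv(P)))
            return z, jv + jiv

        z, out = loss(z0)
        gz = grad(out, z).data
        eps = 1e-5
        checked = 0
        for i in rng.choice(diff.n_train, size=12, replace=False):
            zp, zm = z0.copy(), z0.copy()
            zp[0, i] += eps
            zm[0, i] -= eps
            fd = (loss(zp)[1].item() - loss(zm)[1].item()) / (2 * eps)
            # skip entries where central differences are pure cancellation
            # noise (the loss is ~1e4, so |fd| below ~1e-3 is unresolvable)
            if abs(fd) > 1e-3:
                assert gz[0, i] == pytest.approx(fd, rel=1e-3, abs=1e-5)
                checked += 1
        assert checked >= 5


class TestTrainingLoop:
    def test_smoke_history_finite_and_deterministic(self, tiny_corpus):
        m1 = small_model(tiny_corpus).fit(tiny_corpus)
        assert len(m1.history_) == 2
        for ep in m1.history_:
            assert all(np.isfinite(v) for v in ep.values())
        m2 = small_model(tiny_corpus).fit(tiny_corpus)
        for a, b in zip(m1.history_, m2.history_):
            for k in a:
                assert a[k] == b[k]

    def test_mode_mismatch_rejected(self, tiny_corpus):
        with pytest.raises(ValueError, match="mode"):
            small_model(tiny_corpus, mode="large").fit(tiny_corpus)

    def test_candidates_recorded_at_cadence(self, tiny_corpus):
        m = small_model(tiny_corpus, epochs=3, eval_cadence=2)
        m.fit(tiny_corpus, eval_inputs=[tiny_corpus[0].windowed])
        epochs = [e for e, _ in m.candidates_]
        assert epochs == [0, 2]


class TestInference:
    def test_batched_equals_sequential_and_in_bounds(self, tiny_corpus, space_small):
        m = small_model(tiny_corpus).fit(tiny_corpus)
        inputs = [r.windowed for r in tiny_corpus[:4]]
        batched = m.predict(inputs)
        assert len(batched) == 4
        for w, pv in zip(inputs, batched):
            single = m.predict([w])[0]
            np.testing.assert_allclose(pv.values, single.values, atol=1e-9)
            assert np.all(pv.values >= space_small.lower - 1e-9)
            assert np.all(pv.values <= space_small.upper + 1e-9)

    def test_unfitted_predict_raises(self, tiny_corpus):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            small_model(tiny_corpus).predict([tiny_corpus[0].windowed])

    def test_mixed_trace_counts_accepted(self, tiny_corpus):
        from epgan.evaluation import ablate_traces

        m = small_model(tiny_corpus).fit(tiny_corpus)
        inputs = [tiny_corpus[0].windowed, ablate_traces(tiny_corpus[1].windowed, 0.5)]
        out = m.predict(inputs)
        assert len(out) == 2


class TestSelectBestCandidate:
    def test_single_candidate_returned(self, tiny_corpus, cc_protocol):
        r = tiny_corpus[0]
        best = select_best_candidate([r.params], r.windowed, cc_protocol)
        assert best is r.params

    def test_truth_params_win_and_equal_brute_force(self, tiny_corpus, cc_protocol):
        from epgan.evaluation import evaluate_candidate

        r = tiny_corpus[0]
        decoys = [tiny_corpus[i].params for i in (1, 2, 3)]
        cands = decoys[:1] + [r.params] + decoys[1:]
        best, scores = select_best_candidate(
            cands, r.windowed, cc_protocol, return_details=True
        )
        assert best is r.params
        brute = [evaluate_candidate(c, r.windowed, cc_protocol).mean for c in cands]
        np.testing.assert_allclose(scores, brute)
        assert np.argmin(brute) == 1

    def test_empty_candidates_raise(self, tiny_corpus, cc_protocol):
        with pytest.raises(ValueError):
            select_best_candidate([], tiny_corpus[0].windowed, cc_protocol)
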