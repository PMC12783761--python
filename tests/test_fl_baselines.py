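"""Baseline aggregations, losses and the clinical logistic model."""

import numpy as np
import pytest

from fedlesion import backbones as bb
from fedlesion import fl_baselines as fb
from fedlesion import hfl_core as hfl
from fedlesion import nn


def small_models(n=2, seed=0):
    return [bb.build_backbone(bb.default_spec("tiny_global", seed=seed))
            for _ in range(n)]


class TestFedAvg:
    def test_equal_sizes_simple_mean(self):
        a, b = small_models(2)
        b.load_state([p + 1.0 for p in a.state()])
        pv = fb.fedavg_aggregate([fb.ParamVector.from_model(a),
                                  fb.ParamVector.from_model(b)], [5, 5])
        for avg, pa in zip(pv.values, a.state()):
            np.testing.assert_allclose(avg, pa + 0.5)

    def test_size_weighted_mean(self):
        a, b = small_models(2)
        b.load_state([p + 4.0 for p in a.state()])
        pv = fb.fedavg_aggregate([fb.ParamVector.from_model(a),
                                  fb.ParamVector.from_model(b)], [3, 1])
        for avg, pa in zip(pv.values, a.state()):
            np.testing.assert_allclose(avg, pa + 1.0)

    def test_single_client_identity(self):
        a, = small_models(1)
        pv = fb.fedavg_aggregate([fb.ParamVector.from_model(a)], [7])
        for avg, pa in zip(pv.values, a.state()):
            np.testing.assert_array_equal(avg, pa)

    def test_permutation_commutes(self):
        a, b = small_models(2)
        b.load_state([p + 2.0 for p in a.state()])
        pa, pb = fb.ParamVector.from_model(a), fb.ParamVector.from_model(b)
        fwd = fb.fedavg_aggregate([pa, pb], [3, 1])
        rev = fb.fedavg_aggregate([pb, pa], [1, 3])
        for x, y in zip(fwd.values, rev.values):
            np.testing.assert_allclose(x, y)

    def test_signature_mismatch_rejected(self):
        a, = small_models(1)
        c = bb.build_backbone(bb.default_spec("tiny_local", seed=0))
        with pytest.raises(ValueError, match="signature"):
            fb.fedavg_aggregate([fb.ParamVector.from_model(a),
                                 fb.ParamVector.from_model(c)], [1, 1])


class TestFedProx:
    @pytest.fixture()
    def batch(self):
        rng = np.random.default_rng(0)
        return rng.random((4, 64, 64, 1)), np.array([0, 1, 0, 1])

    def test_mu_zero_is_plain_step(self, batch):
        images, labels = batch
        m1, m2 = small_models(2, seed=3)
        gref = [p + 1.0 for p in m1.state()]
        fb.fedprox_local_step(m1, gref, images, labels, mu=0.0, lr=0.05)
        m2.set_training(True)
        x = nn.Tensor(images.transpose(0, 3, 1, 2))
        logits, _ = m2.forward(x)
        loss = nn.softmax_cross_entropy(logits, labels)
        opt = nn.SGD(m2.parameters(), 0.05)
        opt.zero_grad()
        loss.backward()
        opt.step()
        for a, b in zip(m1.state(), m2.state()):
            np.testing.assert_array_equal(a, b)

    def test_large_mu_pulls_toward_global(self, batch):
        """When the proximal gradient dominates the (bounded) CE gradient,
        the distance to the global reference shrinks every step."""
        images, labels = batch
        model, = small_models(1, seed=3)
        gref = [0.5 * p for p in model.state()]
        gaps = []
        for _ in range(5):
            fb.fedprox_local_step(model, gref, images, labels, mu=100.0,
                                  lr=0.002)
            gaps.append(sum(float(((p.data - g) ** 2).sum()) for p, g in
                            zip(model.parameters(), gref)))
        assert all(a > b for a, b in zip(gaps, gaps[1:]))

    def test_one_step_matches_finite_differences(self, batch):
        images, labels = batch
        model, = small_models(1, seed=4)
        gref = [p * 0.5 for p in model.state()]
        before = model.state()
        mu, lr = 0.3, 0.05
        fb.fedprox_local_step(model, gref, images, labels, mu=mu, lr=lr)
        after = model.state()

        probe, = small_models(1, seed=4)
        buffers = {id(p) for mod in probe.submodules()
                   if isinstance(mod, nn.BatchNorm2d)
                   for p in (mod.running_mean, mod.running_var)}

        def objective():
            probe.set_training(True)
            x = nn.Tensor(images.transpose(0, 3, 1, 2))
            logits, _ = probe.forward(x)
            total = float(nn.softmax_cross_entropy(logits, labels).data)
            for p, g in zip(probe.parameters(), gref):
                if id(p) in buffers:
                    continue
                total += 0.5 * mu * float(((p.data - g) ** 2).sum())
            return total

        rng = np.random.default_rng(1)
        for pi, param in enumerate(probe.parameters()):
            if id(param) in buffers:
                continue
            flat = param.data.reshape(-1)
            for j in rng.choice(flat.size, size=min(2, flat.size),
                                replace=False):
                old = flat[j]
                flat[j] = old + 1e-6
                lp = objective()
                flat[j] = old - 1e-6
                lm = objective()
                flat[j] = old
                fd = (lp - lm) / 2e-6
                got = (before[pi].reshape(-1)[j]
                       - after[pi].reshape(-1)[j]) / lr
                assert got == pytest.approx(fd, abs=1e-5)

    def test_negative_mu_rejected(self, batch):
        images, labels = batch
        model, = small_models(1)
        with pytest.raises(ValueError):
            fb.fedprox_local_step(model, model.state(), images, labels,
                                  mu=-1.0, lr=0.05)


class TestMoonLoss:
    def test_closed_form_value(self):
        """cos(z, zg)=1 and cos(z, zp)=0 at tau=1 gives log(1 + e^-1)."""
        z = np.array([1.0, 0.0])
        loss = fb.moon_contrastive_loss(z, z, np.array([0.0, 1.0]), tau=1.0)
        assert loss == pytest.approx(np.log(1 + np.exp(-1)), abs=1e-4)

    def test_equal_references_give_log2_any_tau(self):
        z = np.array([0.3, -0.7, 0.2])
        g = np.array([1.0, 1.0, 0.0])
        for tau in (0.1, 1.0, 7.0):
            assert fb.moon_contrastive_loss(z, g, g, tau) == \
                pytest.approx(np.log(2))

    def test_cosine_scale_invariance(self):
        rng = np.random.default_rng(2)
        z, g, p = rng.random(4), rng.random(4), rng.random(4)
        assert fb.moon_contrastive_loss(3 * z, g, p, 0.5) == \
            pytest.approx(fb.moon_contrastive_loss(z, g, p, 0.5))

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            fb.moon_contrastive_loss(np.zeros(3), np.ones(3), np.ones(3), 1.0)

    def test_batch_op_matches_scalar_and_finite_differences(self):
        rng = np.random.default_rng(3)
        zd = rng.random((5, 6))
        zg, zp = rng.random((5, 6)), rng.random((5, 6))
        z = nn.Tensor(zd.copy(), requires_grad=True)
        loss = fb.moon_loss_batch(z, zg, zp, tau=0.7)
        scalar = np.mean([fb.moon_contrastive_loss(zd[i], zg[i], zp[i], 0.7)
                          for i in range(5)])
        assert float(loss.data) == pytest.approx(scalar, rel=1e-10)
        loss.backward()
        for i, j in [(0, 0), (2, 3), (4, 5)]:
            old = zd[i, j]
            for sign, store in [(1, "p"), (-1, "m")]:
                z2 = zd.copy()
                z2[i, j] = old + sign * 1e-7
                val = float(fb.moon_loss_batch(nn.Tensor(z2), zg, zp,
                                               0.7).data)
                if sign == 1:
                    lp = val
                else:
                    lm = val
            assert z.grad[i, j] == pytest.approx((lp - lm) / 2e-7, abs=1e-6)


class TestFedProto:
    def test_single_client_prototype_is_mean(self):
        ps = fb.local_prototypes(np.array([[1.0, 0.0], [3.0, 2.0]]),
                                 np.array([0, 0]))
        np.testing.assert_allclose(ps.centroids[0], [2.0, 1.0])

    def test_weighted_global_prototype(self):
        a = fb.PrototypeSet({0: np.array([0.0, 0.0])}, {0: 1})
        b = fb.PrototypeSet({0: np.array([2.0, 2.0])}, {0: 3})
        g = fb.fedproto_round([a, b])
        np.testing.assert_allclose(g.centroids[0], [1.5, 1.5])

    def test_regularizer_zero_at_prototype(self):
        z = np.array([0.4, -0.2])
        assert fb.prototype_regularizer(z, z) == 0.0

    def test_no_classes_rejected(self):
        with pytest.raises(ValueError):
            fb.fedproto_round([])


class TestKDLoss:
    def test_identical_logits_zero(self):
        logits = np.array([1.2, -0.3])
        assert fb.kd_distill_loss(logits, logits, 2.0) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        """teacher (0.9, 0.1), student (0.5, 0.5) at T=1:
        0.9 ln 1.8 + 0.1 ln 0.2 = 0.3681 nats."""
        t = np.log(np.array([0.9, 0.1]))
        s = np.log(np.array([0.5, 0.5]))
        assert fb.kd_distill_loss(s, t, 1.0) == pytest.approx(0.3681,
                                                              abs=5e-5)

    def test_logit_shift_invariance(self):
        rng = np.random.default_rng(0)
        s, t = rng.random(3), rng.random(3)
        base = fb.kd_distill_loss(s, t, 2.0)
        assert fb.kd_distill_loss(s + 5, t, 2.0) == pytest.approx(base)
        assert fb.kd_distill_loss(s, t - 3, 2.0) == pytest.approx(base)

    def test_batch_op_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        sd = rng.random((4, 2))
        td = rng.random((4, 2))
        s = nn.Tensor(sd.copy(), requires_grad=True)
        loss = fb.kd_loss_batch(s, td, temperature=2.0)
        loss.backward()
        for i, j in [(0, 0), (3, 1)]:
            old = sd[i, j]
            s2 = sd.copy()
            s2[i, j] = old + 1e-7
            lp = float(fb.kd_loss_batch(nn.Tensor(s2), td, 2.0).data)
            s2[i, j] = old - 1e-7
            lm = float(fb.kd_loss_batch(nn.Tensor(s2), td, 2.0).data)
            assert s.grad[i, j] == pytest.approx((lp - lm) / 2e-7, abs=1e-6)

    def test_bad_temperature_rejected(self):
        with pytest.raises(ValueError):
            fb.kd_distill_loss(np.ones(2), np.ones(2), 0.0)


class TestCdtm:
    def test_single_center_equals_local_training(self, tiny_cohort):
        import fedlesion.synthetic_cohort as sc
        ds = sc.CenterDataset(profile=tiny_cohort[0].profile,
                              train=tiny_cohort[0].train[:8],
                              test=tiny_cohort[0].test[:2])
        spec = bb.default_spec("tiny_global", seed=1)
        cfg = hfl.FederationConfig(rounds=2, seed=6)
        m1 = fb.cdtm_train([ds], spec, cfg)
        # plain training with the identical seed and batch stream
        m2 = bb.build_backbone(spec)
        m2.set_training(True)
        rng = np.random.default_rng(cfg.seed)
        images, labels = ds.pixels("train"), ds.labels("train")
        opt = nn.SGD(m2.parameters(), cfg.lr)
        for _ in range(cfg.rounds * cfg.local_epochs):
            for bidx in hfl._epoch_batches(rng, len(images), cfg.batch_size):
                x = nn.Tensor(images[bidx].transpose(0, 3, 1, 2))
                logits, _ = m2.forward(x)
                loss = nn.softmax_cross_entropy(logits, labels[bidx])
                opt.zero_grad()
                loss.backward()
                opt.step()
        for a, b in zip(m1.state(), m2.state()):
            np.testing.assert_array_equal(a, b)

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError):
            fb.cdtm_train([], bb.default_spec("tiny_global"),
                          hfl.FederationConfig(rounds=1))


class TestClinicalModel:
    def test_intercept_only_returns_prevalence(self):
        cov = np.ones((20, 4))
        labels = np.r_[np.ones(5), np.zeros(15)]
        model = fb.clinical_model_fit(cov, labels)
        np.testing.assert_allclose(model.predict_proba(cov),
                                   np.full(20, 0.25), atol=1e-6)

    def test_recovers_known_logistic_law(self):
        rng = np.random.default_rng(0)
        n = 2000
        cov = np.column_stack([rng.normal(60, 10, n),
                               rng.integers(0, 2, n),
                               rng.integers(0, 2, n),
                               rng.integers(0, 2, n)]).astype(float)
        true_beta = np.array([0.05, 0.8, -0.5, 1.2])
        eta = (cov - cov.mean(0)) @ true_beta - 0.5
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        model = fb.clinical_model_fit(cov, y)
        got = model.coef / model.sds * 1.0  # back to raw scale
        np.testing.assert_allclose(got, true_beta, atol=0.15)

    def test_score_monotone_in_positive_covariate(self):
        rng = np.random.default_rng(1)
        cov = rng.normal(size=(200, 4))
        y = (cov[:, 0] + 0.3 * rng.normal(size=200) > 0).astype(float)
        model = fb.clinical_model_fit(cov, y)
        assert model.coef[0] > 0
        lo = model.predict_proba(np.array([[0.0, 0, 0, 0]]))
        hi = model.predict_proba(np.array([[1.0, 0, 0, 0]]))
        assert hi > lo

    def test_perfect_separation_warns_and_caps(self):
        cov = np.column_stack([np.r_[np.zeros(10), np.ones(10)],
                               np.zeros(20), np.zeros(20), np.zeros(20)])
        y = np.r_[np.zeros(10), np.ones(10)]
        with pytest.warns(RuntimeWarning, match="separation"):
            model = fb.clinical_model_fit(cov, y)
        assert model.separation_warning
        assert np.abs(model.coef).max() <= 15.0

    def test_against_reference_implementation(self):
        """Coefficients agree with statsmodels Logit on a clean dataset."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        cov = rng.normal(size=(300, 4))
        y = (rng.random(300) < 1 / (1 + np.exp(-(0.5 * cov[:, 0]
                                                 - 0.3 * cov[:, 2])))) * 1.0
        model = fb.clinical_model_fit(cov, y)
        xs = (cov - model.means) / model.sds
        ref = sm.Logit(y, sm.add_constant(xs)).fit(disp=0)
        np.testing.assert_allclose(model.intercept, ref.params[0], atol=1e-6)
        np.testing.assert_allclose(model.coef, ref.params[1:], atol=1e-6)
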