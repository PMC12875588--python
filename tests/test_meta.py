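"""Episodic task sampling and the two-level MAML optimization, checked
against closed forms on an analytic quadratic task family."""

import numpy as np
import pytest

from peelnet.meta import (
    DomainDataset,
    EpisodeTask,
    MetaConfig,
    adapt_and_evaluate,
    direct_transfer_evaluate,
    inner_adapt,
    meta_gradient,
    meta_train,
    meta_update,
    sample_task,
)
from peelnet.nn import ptree


class Quadratic:
    """Scalar objective L(theta) = 0.5 * (theta - c)^2.

    The batch's label array carries the target c, so support and query sets
    define a two-level objective with known closed forms:
    inner:  theta_K = c + (1 - alpha)^K (theta - c)
    outer:  dL_q/dtheta = (1 - alpha)^K (theta_K - c_q)
    """

    def loss_and_grad(self, p, batch):
        c = float(np.mean(batch[1]))
        th = p["w"]
        return float(0.5 * np.sum((th - c) ** 2)), {"w": th - c}

    def predict(self, p, x):
        return np.zeros(len(x) if hasattr(x, "__len__") else 1)

    @staticmethod
    def take(x, idx):
        return x


@pytest.fixture()
def quad():
    return Quadratic()


@pytest.fixture()
def theta0():
    return {"w": np.array([3.0])}


class TestInnerAdapt:
    def test_zero_rate_returns_initialization(self, quad, theta0):
        out = inner_adapt(quad, theta0, (None, np.array([1.0])), 0.0, 5)
        np.testing.assert_array_equal(out["w"], theta0["w"])

    @pytest.mark.parametrize("steps", [1, 2, 5])
    def test_matches_closed_form(self, quad, theta0, steps):
        alpha, c = 0.1, 1.0
        out = inner_adapt(quad, theta0, (None, np.array([c])), alpha, steps)
        expected = c + (1 - alpha) ** steps * (3.0 - c)
        assert out["w"][0] == pytest.approx(expected, rel=1e-12)

    def test_initialization_never_mutated(self, quad, theta0):
        before = theta0["w"].copy()
        inner_adapt(quad, theta0, (None, np.array([0.0])), 0.5, 10)
        np.testing.assert_array_equal(theta0["w"], before)

    def test_non_finite_loss_raises(self, theta0):
        class Diverging:
            def loss_and_grad(self, p, batch):
                return float("nan"), {"w": np.zeros(1)}

        with pytest.raises(FloatingPointError):
            inner_adapt(Diverging(), theta0, (None, None), 0.1, 1)


class TestMetaGradient:
    def _task(self, c_support, c_query):
        return EpisodeTask(None, np.array([c_support]), None, np.array([c_query]))

    @pytest.mark.parametrize("steps,alpha", [(1, 0.1), (2, 0.1), (5, 0.3)])
    def test_second_order_matches_hand_derivation(self, quad, theta0, steps, alpha):
        c_s, c_q = 1.0, 0.5
        cfg = MetaConfig(inner_lr=alpha, inner_steps=steps)
        grad, _ = meta_gradient(quad, theta0, [self._task(c_s, c_q)], cfg)
        th_k = c_s + (1 - alpha) ** steps * (3.0 - c_s)
        expected = (1 - alpha) ** steps * (th_k - c_q)
        assert grad["w"][0] == pytest.approx(expected, rel=1e-6)

    def test_first_and_second_order_agree_when_k_zero(self, quad, theta0):
        task = self._task(1.0, 0.5)
        g1, _ = meta_gradient(quad, theta0, [task], MetaConfig(inner_steps=0, order="first"))
        g2, _ = meta_gradient(quad, theta0, [task], MetaConfig(inner_steps=0, order="second"))
        np.testing.assert_allclose(g1["w"], g2["w"], rtol=1e-12)

    def test_gradients_sum_over_tasks(self, quad, theta0):
        cfg = MetaConfig(inner_lr=0.1, inner_steps=1)
        t1, t2 = self._task(1.0, 0.5), self._task(2.0, 0.0)
        g_both, _ = meta_gradient(quad, theta0, [t1, t2], cfg)
        g1, _ = meta_gradient(quad, theta0, [t1], cfg)
        g2, _ = meta_gradient(quad, theta0, [t2], cfg)
        np.testing.assert_allclose(g_both["w"], g1["w"] + g2["w"], rtol=1e-10)


class TestMetaUpdate:
    def test_zero_outer_rate_leaves_theta(self, quad, theta0):
        cfg = MetaConfig(outer_lr=0.0, inner_lr=0.1, inner_steps=1)
        task = EpisodeTask(None, np.array([1.0]), None, np.array([0.5]))
        out, _ = meta_update(quad, theta0, [task], cfg)
        np.testing.assert_array_equal(out["w"], theta0["w"])

    def test_requires_tasks(self, quad, theta0):
        with pytest.raises(ValueError):
            meta_update(quad, theta0, [], MetaConfig())

    def test_theta_not_modified_in_place(self, quad, theta0):
        before = theta0["w"].copy()
        task = EpisodeTask(None, np.array([1.0]), None, np.array([0.5]))
        meta_update(quad, theta0, [task], MetaConfig(inner_lr=0.1, inner_steps=2))
        np.testing.assert_array_equal(theta0["w"], before)


def _domain(n_per_class=8, n_classes=4, seed=0, role="source"):
    rng = np.random.default_rng(seed)
    y = np.repeat(np.arange(n_classes), n_per_class)
    x = rng.normal(0, 1, (len(y), 2))
    return DomainDataset("dev", x, y, role=role)


class TestSampleTask:
    def test_support_and_query_sizes(self):
        domain = _domain(n_per_class=25)
        cfg = MetaConfig(n_way=4, k_shot=5, query_per_class=15)
        task = sample_task(domain, cfg, np.random.default_rng(0))
        assert len(task.support_y) == 20
        assert len(task.query_y) == 60
        for c in range(4):
            assert (task.support_y == c).sum() == 5
            assert (task.query_y == c).sum() == 15

    def test_support_query_disjoint(self):
        domain = _domain(n_per_class=10)
        cfg = MetaConfig(k_shot=5, query_per_class=5)
        for seed in range(10):
            task = sample_task(domain, cfg, np.random.default_rng(seed))
            sup = {tuple(row) for row in task.support_x}
            qry = {tuple(row) for row in task.query_x}
            assert not (sup & qry)

    def test_fixed_seed_identical_task(self):
        domain = _domain(n_per_class=12)
        cfg = MetaConfig()
        a = sample_task(domain, cfg, np.random.default_rng(3))
        b = sample_task(domain, cfg, np.random.default_rng(3))
        np.testing.assert_array_equal(a.support_x, b.support_x)
        np.testing.assert_array_equal(a.query_y, b.query_y)

    def test_insufficient_samples_raise(self):
        domain = _domain(n_per_class=5)
        with pytest.raises(ValueError):
            sample_task(domain, MetaConfig(k_shot=5), np.random.default_rng(0))


class _NearestMean:
    """Trainable class-mean classifier over 2-D features: loss is squared
    distance of each sample to its class parameter vector."""

    def __init__(self, n_classes=4):
        self.n_classes = n_classes

    def init_params(self, seed=0):
        rng = np.random.default_rng(seed)
        return {"mu": rng.normal(0, 0.1, (self.n_classes, 2))}

    def loss_and_grad(self, p, batch):
        x, y = batch
        mu = p["mu"]
        diff = x - mu[y]
        loss = float(0.5 * np.mean(np.sum(diff**2, axis=1)))
        g = np.zeros_like(mu)
        np.add.at(g, y, -diff / len(y))
        return loss, {"mu": g}

    def predict(self, p, x):
        d = ((x[:, None, :] - p["mu"][None]) ** 2).sum(-1)
        return d.argmin(1)

    @staticmethod
    def take(x, idx):
        return x[idx]


def _clustered_domain(seed, role, offset=0.0):
    rng = np.random.default_rng(seed)
    centers = np.array([[0, 0], [3, 0], [0, 3], [3, 3]], dtype=float) + offset
    y = np.repeat(np.arange(4), 15)
    x = centers[y] + rng.normal(0, 0.4, (len(y), 2))
    return DomainDataset("dev", x, y, role=role)


class TestMetaTrainAndEvaluate:
    def test_zero_iterations_returns_initialization(self):
        model = _NearestMean()
        src = _clustered_domain(0, "source")
        cfg = MetaConfig(meta_iterations=0, inner_lr=0.1, inner_steps=2, query_per_class=5)
        p0 = model.init_params(0)
        theta, log = meta_train(src, model, cfg, np.random.default_rng(0), init_params=p0)
        np.testing.assert_array_equal(theta["mu"], p0["mu"])
        assert log["query_loss"] == []

    def test_deterministic_trajectory(self):
        model = _NearestMean()
        src = _clustered_domain(0, "source")
        cfg = MetaConfig(meta_iterations=3, inner_lr=0.1, inner_steps=2, query_per_class=5, tasks_per_batch=2)
        a, _ = meta_train(src, model, cfg, np.random.default_rng(1), init_params=model.init_params(0))
        b, _ = meta_train(src, model, cfg, np.random.default_rng(1), init_params=model.init_params(0))
        np.testing.assert_array_equal(a["mu"], b["mu"])

    def test_meta_train_requires_source_role(self):
        model = _NearestMean()
        tgt = _clustered_domain(0, "target")
        with pytest.raises(ValueError):
            meta_train(tgt, model, MetaConfig(), np.random.default_rng(0))

    def test_direct_transfer_on_source_distribution_is_high(self):
        model = _NearestMean()
        src = _clustered_domain(0, "source")
        cfg = MetaConfig(meta_iterations=40, inner_lr=0.2, outer_lr=0.2, inner_steps=3, query_per_class=5, tasks_per_batch=2)
        theta, _ = meta_train(src, model, cfg, np.random.default_rng(0), init_params=model.init_params(0))
        same = _clustered_domain(99, "target")
        res = direct_transfer_evaluate(model, theta, same)
        assert res["accuracy"] > 0.9

    def test_adaptation_beats_direct_under_shift(self):
        model = _NearestMean()
        src = _clustered_domain(0, "source")
        cfg = MetaConfig(meta_iterations=40, inner_lr=0.2, outer_lr=0.2, inner_steps=5, query_per_class=5, tasks_per_batch=2)
        theta, _ = meta_train(src, model, cfg, np.random.default_rng(0), init_params=model.init_params(0))
        shifted = _clustered_domain(7, "target", offset=1.5)
        direct = direct_transfer_evaluate(model, theta, shifted)
        rep = adapt_and_evaluate(model, theta, shifted, cfg, np.random.default_rng(2), n_runs=10)
        assert rep.n_runs == 10
        assert rep.mean_accuracy > direct["accuracy"]

    def test_adapt_reports_mean_and_sample_std(self):
        model = _NearestMean()
        tgt = _clustered_domain(3, "target")
        cfg = MetaConfig(inner_lr=0.1, inner_steps=2)
        rep = adapt_and_evaluate(model, model.init_params(0), tgt, cfg, np.random.default_rng(0), n_runs=4)
        assert rep.mean_accuracy == pytest.approx(np.mean(rep.per_run_accuracy))
        assert rep.std_accuracy == pytest.approx(np.std(rep.per_run_accuracy, ddof=1))

    def test_empty_target_rejected(self):
        model = _NearestMean()
        with pytest.raises(ValueError):
            direct_transfer_evaluate(model, model.init_params(0), DomainDataset("d", np.zeros((0, 2)), np.zeros(0, dtype=int), role="target"))
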