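"""Cross-device adaptation by model-agnostic meta-learning (MAML).

Each capture device is a domain.  Meta-training builds N-way K-shot episodes
from the source domain; the inner loop takes K plain gradient-descent steps
on an episode's support set, the outer loop updates the shared
initialization from the aggregated query losses.  The meta-gradient is
second-order by default: reverse accumulation through the inner trajectory,
with the required Hessian-vector products computed by central finite
differences of the support gradient (exact for quadratic losses, a
standard controlled approximation otherwise).  A first-order mode simply
uses the query gradient at the adapted parameters.

Any model exposing ``loss_and_grad(params, (X, y))``, ``predict(params, X)``
and ``take(X, idx)`` can be meta-trained, which is what makes the procedure
model-agnostic; the package uses it with the multi-stream classifier and,
in tests, with analytic toy objectives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .nn import ptree
from .nn.optim import Adam, SGD
from .nn.ptree import ParamTree

__all__ = [
    "MetaConfig",
    "EpisodeTask",
    "DomainDataset",
    "sample_task",
    "inner_adapt",
    "meta_gradient",
    "meta_update",
    "meta_train",
    "direct_transfer_evaluate",
    "adapt_and_evaluate",
    "AdaptationReport",
]


@dataclass(frozen=True)
class MetaConfig:
    """Episodic meta-learning settings.

    ``inner_lr`` (alpha) drives the K plain gradient steps of task
    adaptation; ``outer_lr`` (beta) the meta-update, applied through Adam by
    default.  ``order`` selects second-order meta-gradients (default) or the
    first-order approximation.
    """

    inner_lr: float = 0.01
    outer_lr: float = 1e-3
    inner_steps: int = 5
    n_way: int = 4
    k_shot: int = 5
    query_per_class: int = 15
    tasks_per_batch: int = 4
    meta_iterations: int = 100
    order: str = "second"
    outer_optimizer: str = "adam"
    hvp_eps: float = 1e-3

    def __post_init__(self):
        # Zero rates are degenerate but well-defined (no-op updates); they
        # are allowed so the identity contracts can be expressed directly.
        if self.inner_lr < 0 or self.outer_lr < 0:
            raise ValueError("learning rates must be non-negative")
        if self.inner_steps < 0:
            raise ValueError("inner_steps must be >= 0")
        if self.order not in ("second", "first"):
            raise ValueError("order must be 'second' or 'first'")


@dataclass(frozen=True)
class EpisodeTask:
    """One N-way K-shot episode: class-balanced support set and a disjoint
    query set drawn from the same domain."""

    support_x: object
    support_y: np.ndarray
    query_x: object
    query_y: np.ndarray


@dataclass(frozen=True)
class DomainDataset:
    """Labeled samples from one capture device."""

    device_id: str
    x: object  # arrays or tuple of arrays, first axis = samples
    y: np.ndarray
    role: str = "source"

    def __post_init__(self):
        if self.role not in ("source", "target"):
            raise ValueError("role must be 'source' or 'target'")

    def n_samples(self) -> int:
        return len(self.y)

    def min_per_class(self) -> int:
        _, counts = np.unique(self.y, return_counts=True)
        return int(counts.min())


def _take(model, x, idx):
    return model.take(x, idx) if hasattr(model, "take") else x[idx]


def sample_task(
    domain: DomainDataset,
    config: MetaConfig,
    rng: np.random.Generator,
    model=None,
    query_per_class: int | None = None,
) -> EpisodeTask:
    """Stratified episode draw: exactly ``k_shot`` support and up to
    ``query_per_class`` query samples per class, disjoint."""
    qpc = config.query_per_class if query_per_class is None else query_per_class
    sup_idx, qry_idx = [], []
    classes = np.unique(domain.y)
    if len(classes) < config.n_way:
        raise ValueError(f"domain has {len(classes)} classes, need {config.n_way}")
    for c in classes[: config.n_way]:
        pool = np.flatnonzero(domain.y == c)
        if len(pool) < config.k_shot + 1:
            raise ValueError(f"class {c}: {len(pool)} samples < k_shot+1")
        pool = pool[rng.permutation(len(pool))]
        sup_idx.append(pool[: config.k_shot])
        qry_idx.append(pool[config.k_shot : config.k_shot + qpc])
    sup = np.concatenate(sup_idx)
    qry = np.concatenate(qry_idx)
    return EpisodeTask(
        support_x=_take(model, domain.x, sup),
        support_y=domain.y[sup],
        query_x=_take(model, domain.x, qry),
        query_y=domain.y[qry],
    )


def inner_adapt(
    model,
    params: ParamTree,
    support: tuple,
    inner_lr: float,
    steps: int,
    return_trajectory: bool = False,
):
    """K steps of plain gradient descent on the support loss, starting from
    ``params`` (which is never modified)."""
    theta = ptree.copy(params)
    trajectory = [ptree.copy(theta)] if return_trajectory else None
    for _ in range(steps):
        loss, grads = model.loss_and_grad(theta, support)
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite support loss during adaptation")
        theta = ptree.add(theta, grads, scale=-inner_lr)
        if return_trajectory:
            trajectory.append(ptree.copy(theta))
    if return_trajectory:
        return theta, trajectory
    return theta


def _hvp(model, theta: ParamTree, batch, v: ParamTree, eps: float) -> ParamTree:
    """Hessian-vector product of the batch loss at theta with v, by central
    finite differences of the gradient."""
    vnorm = ptree.norm(v)
    if vnorm == 0:
        return ptree.zeros_like(v)
    r = eps / vnorm
    _, g_plus = model.loss_and_grad(ptree.add(theta, v, scale=r), batch)
    _, g_minus = model.loss_and_grad(ptree.add(theta, v, scale=-r), batch)
    return {k: (g_plus[k] - g_minus[k]) / (2 * r) for k in v}


def meta_gradient(model, params: ParamTree, tasks: list[EpisodeTask], config: MetaConfig):
    """Gradient of the summed query losses with respect to the shared
    initialization, plus the mean query loss (diagnostic).

    Second order: with theta_{k+1} = theta_k - alpha g_k, the adjoint v is
    initialized to the query gradient at theta_K and pulled back through
    each inner step as v <- v - alpha H(theta_k) v.
    """
    total = ptree.zeros_like(params)
    qloss_sum = 0.0
    for task in tasks:
        support = (task.support_x, task.support_y)
        query = (task.query_x, task.query_y)
        theta_k, traj = inner_adapt(
            model, params, support, config.inner_lr, config.inner_steps, return_trajectory=True
        )
        qloss, g_query = model.loss_and_grad(theta_k, query)
        qloss_sum += qloss
        if config.order == "first" or config.inner_steps == 0:
            ptree.add_(total, g_query)
            continue
        v = g_query
        for k in range(config.inner_steps - 1, -1, -1):
            hv = _hvp(model, traj[k], support, v, config.hvp_eps)
            v = ptree.add(v, hv, scale=-config.inner_lr)
        ptree.add_(total, v)
    return total, qloss_sum / max(len(tasks), 1)


def meta_update(model, params: ParamTree, tasks: list[EpisodeTask], config: MetaConfig, optimizer=None):
    """One outer-loop step from a batch of tasks; returns (new params, mean
    query loss).  ``params`` is not modified."""
    if not tasks:
        raise ValueError("need at least one task")
    grad, qloss = meta_gradient(model, params, tasks, config)
    if optimizer is None:
        optimizer = SGD(lr=config.outer_lr)
    new_params = optimizer.step(ptree.copy(params), grad, lr=config.outer_lr)
    return new_params, qloss


def meta_train(
    source: DomainDataset,
    model,
    config: MetaConfig,
    rng: np.random.Generator,
    init_params: ParamTree | None = None,
    verbose: bool = False,
):
    """Full meta-training loop on the source domain (episodic sampling,
    inner adaptation, outer update).  Returns the meta-initialization and a
    per-iteration log of query loss and accuracy."""
    if source.role != "source":
        raise ValueError("meta_train expects a source-role domain")
    params = ptree.copy(init_params) if init_params is not None else model.init_params(
        int(rng.integers(2**31 - 1))
    )
    opt = Adam(lr=config.outer_lr) if config.outer_optimizer == "adam" else SGD(lr=config.outer_lr)
    log = {"query_loss": [], "query_acc": []}
    for it in range(config.meta_iterations):
        tasks = [sample_task(source, config, rng, model=model) for _ in range(config.tasks_per_batch)]
        params, qloss = meta_update(model, params, tasks, config, optimizer=opt)
        accs = []
        for t in tasks:
            adapted = inner_adapt(model, params, (t.support_x, t.support_y), config.inner_lr, config.inner_steps)
            accs.append(float(np.mean(model.predict(adapted, t.query_x) == t.query_y)))
        log["query_loss"].append(qloss)
        log["query_acc"].append(float(np.mean(accs)))
        if verbose:
            print(f"meta-iter {it:3d} query_loss {qloss:.4f} query_acc {log['query_acc'][-1]:.3f}")
    return params, log


def direct_transfer_evaluate(model, params: ParamTree, target: DomainDataset) -> dict:
    """Zero-adaptation evaluation of the shared parameters on the full
    target domain."""
    if target.n_samples() == 0:
        raise ValueError("empty target domain")
    pred = model.predict(params, target.x)
    return {"accuracy": float(np.mean(pred == target.y)), "n": target.n_samples()}


@dataclass(frozen=True)
class AdaptationReport:
    per_run_accuracy: list[float]
    mean_accuracy: float
    std_accuracy: float
    n_runs: int


def adapt_and_evaluate(
    model,
    params: ParamTree,
    target: DomainDataset,
    config: MetaConfig,
    rng: np.random.Generator,
    n_runs: int = 10,
) -> AdaptationReport:
    """Few-shot adaptation on the target domain: per run, draw ``k_shot``
    labeled images per class as a support set, adapt with the inner loop,
    and evaluate on all remaining target samples; repeated over ``n_runs``
    support draws.  Reports per-run accuracy, mean and sample STD."""
    if target.role != "target":
        raise ValueError("adapt_and_evaluate expects a target-role domain")
    if target.min_per_class() < config.k_shot + 1:
        raise ValueError("target domain too small for k-shot adaptation")
    accs = []
    for _ in range(n_runs):
        sup_idx = []
        for c in np.unique(target.y):
            pool = np.flatnonzero(target.y == c)
            pool = pool[rng.permutation(len(pool))]
            sup_idx.append(pool[: config.k_shot])
        sup = np.concatenate(sup_idx)
        rest = np.setdiff1d(np.arange(target.n_samples()), sup)
        support = (_take(model, target.x, sup), target.y[sup])
        adapted = inner_adapt(model, params, support, config.inner_lr, config.inner_steps)
        pred = model.predict(adapted, _take(model, target.x, rest))
        accs.append(float(np.mean(pred == target.y[rest])))
    return AdaptationReport(
        per_run_accuracy=accs,
        mean_accuracy=float(np.mean(accs)),
        std_accuracy=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        n_runs=n_runs,
    )
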