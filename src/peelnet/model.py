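"""Three-branch multi-stream classifier with channel-level interaction.

One branch sees the whole specimen, one the exocarp patch, one the albedo
patch; all three share the same four-stage residual backbone architecture
(but not weights).  At the output of a chosen residual stage (stage 2 by
default) the branches exchange information by channel replacement: a random
10% of the whole-image branch's channels overwrite the corresponding
channels in each local branch, and afterwards an independent random 5% of
each local branch's channels are injected back into the whole-image branch,
exocarp first, albedo second.  After the remaining stages, each branch's
final map is compressed to 512 channels by a 1x1 convolution, globally
average-pooled, concatenated into a 1536-d fused vector and classified by a
linear softmax head; auxiliary per-branch heads receive the same
cross-entropy loss so each branch stays discriminative on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import ops
from .nn.layers import Backbone, BackboneConfig, Conv, Linear
from .nn.optim import Adam, cosine_lr
from .nn.ptree import ParamTree

__all__ = [
    "InteractionConfig",
    "FusionConfig",
    "TrainConfig",
    "replace_channels",
    "sample_channel_indices",
    "interaction_forward",
    "interaction_reverse",
    "classification_loss",
    "MultiStreamClassifier",
    "SingleStreamClassifier",
    "train_classifier",
]

BRANCHES = ("full", "exocarp", "albedo")


@dataclass(frozen=True)
class InteractionConfig:
    """Channel-replacement interaction settings.

    ``forward_ratio`` is the fraction of whole-branch channels injected into
    each local branch; ``reverse_ratio`` the fraction injected back from each
    local branch.  ``stage`` is the residual stage (1-4) after which the
    exchange happens.  At evaluation time indices are drawn from ``seed`` so
    inference is deterministic; during training they are resampled per step
    unless ``freeze_indices`` is set.  ``reverse_uses_original`` makes the
    reverse phase read the pre-interaction local maps instead of the updated
    ones.
    """

    forward_ratio: float = 0.10
    reverse_ratio: float = 0.05
    stage: int = 2
    seed: int = 0
    active: bool = True
    freeze_indices: bool = False
    reverse_uses_original: bool = False

    def __post_init__(self):
        if not (0.0 <= self.forward_ratio <= 1.0 and 0.0 <= self.reverse_ratio <= 1.0):
            raise ValueError("interaction ratios must be in [0, 1]")
        if self.stage not in (1, 2, 3, 4):
            raise ValueError("interaction stage must be in {1, 2, 3, 4}")


@dataclass(frozen=True)
class FusionConfig:
    compress_dim: int = 512
    n_classes: int = 4

    @property
    def fused_dim(self) -> int:
        return 3 * self.compress_dim


@dataclass(frozen=True)
class TrainConfig:
    """Classifier training settings (Adam with cosine-annealed rate and
    early stopping on validation accuracy)."""

    lr: float = 1e-4
    epochs: int = 80
    batch_size: int = 16
    patience: int = 20
    aux_weight: float = 1.0
    min_lr: float = 0.0
    warmup_epochs: int = 2
    #: Retrain from a fresh initialization if best validation accuracy
    #: stays below ``restart_threshold`` (at most ``restarts`` times) —
    #: small from-scratch models occasionally draw a bad start.
    restarts: int = 1
    restart_threshold: float = 0.9


def replace_channels(target: np.ndarray, source: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Copy of ``target`` with the channels in ``idx`` taken from ``source``.

    Maps may be (C, h, w) or batched (N, C, h, w); shapes must match and the
    inputs are left unmodified.
    """
    target = np.asarray(target)
    source = np.asarray(source)
    if target.shape != source.shape:
        raise ValueError(f"shape mismatch: {target.shape} vs {source.shape}")
    idx = np.asarray(idx, dtype=np.intp)
    if idx.size and (len(np.unique(idx)) != idx.size):
        raise ValueError("channel indices must be distinct")
    c_axis = target.ndim - 3
    c = target.shape[c_axis]
    if idx.size and (idx.min() < 0 or idx.max() >= c):
        raise ValueError("channel index out of range")
    out = target.copy()
    if idx.size:
        if c_axis == 0:
            out[idx] = source[idx]
        else:
            out[:, idx] = source[:, idx]
    return out


def sample_channel_indices(n_channels: int, ratio: float, rng: np.random.Generator) -> np.ndarray:
    """floor(ratio * C) distinct channel indices, drawn uniformly without
    replacement from the given generator; returned sorted."""
    if not (0.0 <= ratio <= 1.0):
        raise ValueError("ratio must be in [0, 1]")
    k = int(np.floor(ratio * n_channels))
    return np.sort(rng.choice(n_channels, size=k, replace=False))


def interaction_forward(
    full: np.ndarray,
    exocarp: np.ndarray,
    albedo: np.ndarray,
    config: InteractionConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward phase: one shared index set of whole-branch channels is
    injected into both local branches.  Returns (E', A', indices)."""
    if not config.active:
        return exocarp, albedo, np.empty(0, dtype=np.intp)
    c = full.shape[full.ndim - 3]
    idx = sample_channel_indices(c, config.forward_ratio, rng)
    return (
        replace_channels(exocarp, full, idx),
        replace_channels(albedo, full, idx),
        idx,
    )


def interaction_reverse(
    full: np.ndarray,
    exocarp_upd: np.ndarray,
    albedo_upd: np.ndarray,
    config: InteractionConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reverse phase: independent 5% index sets from the exocarp then the
    albedo branch overwrite whole-branch channels (the albedo injection may
    overwrite channels the exocarp injection just set).  Returns
    (F', exocarp indices, albedo indices)."""
    if not config.active:
        return full, np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    c = full.shape[full.ndim - 3]
    idx_e = sample_channel_indices(c, config.reverse_ratio, rng)
    idx_a = sample_channel_indices(c, config.reverse_ratio, rng)
    mid = replace_channels(full, exocarp_upd, idx_e)
    return replace_channels(mid, albedo_upd, idx_a), idx_e, idx_a


def classification_loss(probs: np.ndarray, y_onehot: np.ndarray, eps: float = 1e-12) -> float:
    """Cross-entropy -sum_k y_k log p_k, averaged over the batch if 2-D."""
    p = np.maximum(np.asarray(probs, dtype=np.float64), eps)
    y = np.asarray(y_onehot, dtype=np.float64)
    if p.ndim == 1:
        return float(-np.sum(y * np.log(p)))
    return float(-np.sum(y * np.log(p)) / p.shape[0])


def _onehot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(y), n_classes), dtype=np.float32)
    out[np.arange(len(y)), y] = 1.0
    return out


class MultiStreamClassifier:
    """Three-branch backbone with channel interaction, fusion and auxiliary
    heads, exposed functionally: all weights live in a parameter tree."""

    def __init__(
        self,
        backbone: BackboneConfig | None = None,
        interaction: InteractionConfig | None = None,
        fusion: FusionConfig | None = None,
        aux_weight: float = 1.0,
    ):
        self.backbone_cfg = backbone or BackboneConfig.reduced()
        self.interaction = interaction or InteractionConfig()
        self.fusion = fusion or FusionConfig()
        self.aux_weight = aux_weight
        self.backbones = {b: Backbone(self.backbone_cfg, name=b) for b in BRANCHES}
        cout = self.backbone_cfg.out_channels
        self.compress = {b: Conv(f"cmp.{b}", cout, self.fusion.compress_dim, 1) for b in BRANCHES}
        self.head = Linear("head", self.fusion.fused_dim, self.fusion.n_classes, std=0.01)
        self.aux = {b: Linear(f"aux.{b}", cout, self.fusion.n_classes, std=0.01) for b in BRANCHES}
        self._frozen_idx: tuple | None = None
        if self.interaction.freeze_indices:
            rng = np.random.default_rng(self.interaction.seed)
            c = self.backbone_cfg.stage_channels(self.interaction.stage)
            self._frozen_idx = (
                sample_channel_indices(c, self.interaction.forward_ratio, rng),
                sample_channel_indices(c, self.interaction.reverse_ratio, rng),
                sample_channel_indices(c, self.interaction.reverse_ratio, rng),
            )

    # -- parameters ---------------------------------------------------------

    def init_params(self, seed: int = 0) -> ParamTree:
        rng = np.random.default_rng(seed)
        params: ParamTree = {}
        for b in BRANCHES:
            self.backbones[b].init(params, rng)
            self.compress[b].init(params, rng)
            self.aux[b].init(params, rng)
        self.head.init(params, rng)
        return params

    def init_fusion_params(self, seed: int = 0) -> ParamTree:
        """Initialize only the fusion stack (per-branch 1x1 compression and
        classifier head) — enough to run :meth:`fuse_and_classify` on
        externally supplied stage-4 maps."""
        rng = np.random.default_rng(seed)
        params: ParamTree = {}
        for b in BRANCHES:
            self.compress[b].init(params, rng)
        self.head.init(params, rng)
        return params

    # -- interaction index schedule -----------------------------------------

    def _draw_indices(self, rng: np.random.Generator | None):
        cfg = self.interaction
        if not cfg.active or cfg.forward_ratio == 0 and cfg.reverse_ratio == 0:
            pass
        if self._frozen_idx is not None:
            return self._frozen_idx
        r = rng if rng is not None else np.random.default_rng(cfg.seed)
        c = self.backbone_cfg.stage_channels(cfg.stage)
        i_fwd = sample_channel_indices(c, cfg.forward_ratio, r)
        i_exo = sample_channel_indices(c, cfg.reverse_ratio, r)
        i_alb = sample_channel_indices(c, cfg.reverse_ratio, r)
        return i_fwd, i_exo, i_alb

    # -- forward / backward --------------------------------------------------

    def _forward(self, p: ParamTree, x: tuple[np.ndarray, np.ndarray, np.ndarray], rng=None):
        cfg = self.interaction
        stage = cfg.stage
        mid, caches = {}, {}
        for b, xb in zip(BRANCHES, x):
            bb = self.backbones[b]
            h, stem_c = bb.forward_stem(p, xb.astype(np.float32, copy=False))
            h, st_c = bb.forward_stages(p, h, 1, stage)
            mid[b] = h
            caches[b] = {"stem": stem_c, "pre": st_c}
        interacted = dict(mid)
        idx = (np.empty(0, dtype=np.intp),) * 3
        if cfg.active:
            i_fwd, i_exo, i_alb = self._draw_indices(rng)
            idx = (i_fwd, i_exo, i_alb)
            e_upd = replace_channels(mid["exocarp"], mid["full"], i_fwd)
            a_upd = replace_channels(mid["albedo"], mid["full"], i_fwd)
            src_e = mid["exocarp"] if cfg.reverse_uses_original else e_upd
            src_a = mid["albedo"] if cfg.reverse_uses_original else a_upd
            f_mid = replace_channels(mid["full"], src_e, i_exo)
            f_upd = replace_channels(f_mid, src_a, i_alb)
            interacted = {"full": f_upd, "exocarp": e_upd, "albedo": a_upd}
        final = {}
        for b in BRANCHES:
            bb = self.backbones[b]
            h, st_c = bb.forward_stages(p, interacted[b], stage + 1, 4)
            caches[b]["post"] = st_c
            final[b] = h
        # Fusion: 1x1 compress -> GAP -> concat -> linear head.
        pooled, aux_logits = {}, {}
        for b in BRANCHES:
            z, cc = self.compress[b].forward(p, final[b])
            zp, gc = ops.gap_forward(z)
            caches[b]["cmp"] = cc
            caches[b]["gap"] = gc
            pooled[b] = zp
            bp, bgc = ops.gap_forward(final[b])
            al, alc = self.aux[b].forward(p, bp)
            caches[b]["auxgap"] = bgc
            caches[b]["aux"] = alc
            aux_logits[b] = al
        fused = np.concatenate([pooled[b] for b in BRANCHES], axis=1)
        logits, head_c = self.head.forward(p, fused)
        cache = {"branch": caches, "head": head_c, "idx": idx, "final_shapes": {b: final[b].shape for b in BRANCHES}}
        return logits, aux_logits, cache

    def forward_logits(self, p: ParamTree, x, rng: np.random.Generator | None = None):
        """Fused-head logits and per-branch auxiliary logits for one batch."""
        logits, aux_logits, _ = self._forward(p, x, rng=rng)
        return logits, aux_logits

    def predict_proba(self, p: ParamTree, x, batch_size: int = 64) -> np.ndarray:
        n = x[0].shape[0]
        out = []
        for i in range(0, n, batch_size):
            xb = tuple(a[i : i + batch_size] for a in x)
            logits, _, _ = self._forward(p, xb, rng=None)
            out.append(ops.softmax(logits))
        return np.concatenate(out, axis=0)

    def predict(self, p: ParamTree, x, batch_size: int = 64) -> np.ndarray:
        return self.predict_proba(p, x, batch_size).argmax(axis=1)

    def fuse_features(self, p: ParamTree, final_maps: dict[str, np.ndarray]) -> np.ndarray:
        """Per-branch 1x1 compression and global pooling of stage-4 maps,
        concatenated into the fused vector of length ``3 * compress_dim``."""
        pooled = []
        for b in BRANCHES:
            fm = final_maps[b]
            if fm.shape[-3] != self.backbone_cfg.out_channels:
                raise ValueError(
                    f"branch {b}: expected {self.backbone_cfg.out_channels} channels, got {fm.shape[-3]}"
                )
            z, _ = self.compress[b].forward(p, fm)
            zp, _ = ops.gap_forward(z)
            pooled.append(zp)
        fused = np.concatenate(pooled, axis=1)
        if fused.shape[1] != self.fusion.fused_dim:
            raise ValueError("fused dimension mismatch")
        return fused

    def fuse_and_classify(self, p: ParamTree, final_maps: dict[str, np.ndarray]) -> np.ndarray:
        """Fusion head alone: compress, pool, concatenate, classify."""
        fused = self.fuse_features(p, final_maps)
        logits, _ = self.head.forward(p, fused)
        return ops.softmax(logits)

    def loss_and_grad(self, p: ParamTree, batch, rng: np.random.Generator | None = None):
        """Total loss (fused + auxiliary cross-entropies) and its gradient."""
        x, y = batch
        y1h = _onehot(np.asarray(y), self.fusion.n_classes)
        logits, aux_logits, cache = self._forward(p, x, rng=rng)
        loss, _, ce_c = ops.softmax_xent_forward(logits, y1h)
        grads: ParamTree = {}
        dlogits = ops.softmax_xent_backward(ce_c)
        dfused = self.head.backward(p, dlogits, cache["head"], grads)
        cdim = self.fusion.compress_dim
        dfinal = {}
        for i, b in enumerate(BRANCHES):
            bc = cache["branch"][b]
            dz = ops.gap_backward(dfused[:, i * cdim : (i + 1) * cdim], bc["gap"])
            dfinal[b] = self.compress[b].backward(p, dz, bc["cmp"], grads)
        if self.aux_weight > 0:
            for b in BRANCHES:
                bc = cache["branch"][b]
                aloss, _, ac = ops.softmax_xent_forward(aux_logits[b], y1h)
                loss += self.aux_weight * aloss
                dal = ops.softmax_xent_backward(ac, weight=self.aux_weight)
                dbp = self.aux[b].backward(p, dal, bc["aux"], grads)
                dfinal[b] = dfinal[b] + ops.gap_backward(dbp, bc["auxgap"])
        # Back through the post-interaction stages.
        dmid_upd = {}
        for b in BRANCHES:
            bb = self.backbones[b]
            dmid_upd[b] = bb.backward_stages(p, dfinal[b], cache["branch"][b]["post"], grads)
        # Back through the channel-replacement interaction.
        cfg = self.interaction
        if cfg.active:
            i_fwd, i_exo, i_alb = cache["idx"]
            df_upd = dmid_upd["full"]
            de_upd = dmid_upd["exocarp"].copy()
            da_upd = dmid_upd["albedo"].copy()
            de_orig = np.zeros_like(de_upd)
            da_orig = np.zeros_like(da_upd)
            # F' = replace(F_mid, src_a, i_alb); F_mid = replace(F, src_e, i_exo)
            df_mid = df_upd.copy()
            if i_alb.size:
                if cfg.reverse_uses_original:
                    da_orig[:, i_alb] += df_upd[:, i_alb]
                else:
                    da_upd[:, i_alb] += df_upd[:, i_alb]
                df_mid[:, i_alb] = 0
            df = df_mid.copy()
            if i_exo.size:
                if cfg.reverse_uses_original:
                    de_orig[:, i_exo] += df_mid[:, i_exo]
                else:
                    de_upd[:, i_exo] += df_mid[:, i_exo]
                df[:, i_exo] = 0
            # E' = replace(E, F, i_fwd); A' = replace(A, F, i_fwd)
            de = de_upd.copy()
            da = da_upd.copy()
            if i_fwd.size:
                df = df.copy()
                df[:, i_fwd] += de_upd[:, i_fwd] + da_upd[:, i_fwd]
                de[:, i_fwd] = 0
                da[:, i_fwd] = 0
            dmid = {"full": df, "exocarp": de + de_orig, "albedo": da + da_orig}
        else:
            dmid = dmid_upd
        # Back through the pre-interaction stages and stems.
        for b in BRANCHES:
            bb = self.backbones[b]
            dh = bb.backward_stages(p, dmid[b], cache["branch"][b]["pre"], grads)
            bb.backward_stem(p, dh, cache["branch"][b]["stem"], grads)
        return loss, grads

    @staticmethod
    def take(x, idx):
        """Select samples from a three-crop input tuple."""
        return tuple(a[idx] for a in x)


class SingleStreamClassifier:
    """Whole-image-only baseline: one backbone, global pooling, linear head."""

    def __init__(self, backbone: BackboneConfig | None = None, n_classes: int = 4):
        self.backbone_cfg = backbone or BackboneConfig.reduced()
        self.n_classes = n_classes
        self.backbone = Backbone(self.backbone_cfg, name="bb")
        self.head = Linear("head", self.backbone_cfg.out_channels, n_classes, std=0.01)

    def init_params(self, seed: int = 0) -> ParamTree:
        rng = np.random.default_rng(seed)
        params: ParamTree = {}
        self.backbone.init(params, rng)
        self.head.init(params, rng)
        return params

    def _forward(self, p: ParamTree, x):
        h, stem_c = self.backbone.forward_stem(p, x.astype(np.float32, copy=False))
        h, st_c = self.backbone.forward_stages(p, h, 1, 4)
        pooled, gc = ops.gap_forward(h)
        logits, hc = self.head.forward(p, pooled)
        return logits, (stem_c, st_c, gc, hc)

    def predict_proba(self, p: ParamTree, x, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            logits, _ = self._forward(p, x[i : i + batch_size])
            out.append(ops.softmax(logits))
        return np.concatenate(out, axis=0)

    def predict(self, p: ParamTree, x, batch_size: int = 64) -> np.ndarray:
        return self.predict_proba(p, x, batch_size).argmax(axis=1)

    def loss_and_grad(self, p: ParamTree, batch, rng=None):
        x, y = batch
        y1h = _onehot(np.asarray(y), self.n_classes)
        logits, (stem_c, st_c, gc, hc) = self._forward(p, x)
        loss, _, ce_c = ops.softmax_xent_forward(logits, y1h)
        grads: ParamTree = {}
        dpooled = self.head.backward(p, ops.softmax_xent_backward(ce_c), hc, grads)
        dh = ops.gap_backward(dpooled, gc)
        dh = self.backbone.backward_stages(p, dh, st_c, grads)
        self.backbone.backward_stem(p, dh, stem_c, grads)
        return loss, grads

    @staticmethod
    def take(x, idx):
        return x[idx]


def _accuracy(model, p, x, y) -> float:
    return float(np.mean(model.predict(p, x) == y))


def train_classifier(
    model,
    params: ParamTree,
    train_data: tuple,
    val_data: tuple | None,
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
    verbose: bool = False,
) -> tuple[ParamTree, dict]:
    """Mini-batch Adam training with cosine-annealed learning rate, early
    stopping on validation accuracy, and a validation-gated restart from a
    fresh initialization.  Returns the best parameters and a history dict
    (per-epoch loss and accuracies)."""
    best_p, best_hist = _train_once(model, params, train_data, val_data, config, seed, verbose)
    attempts = 0
    while (
        val_data is not None
        and attempts < config.restarts
        and (best_hist["best_val_acc"] or 0.0) < config.restart_threshold
        and hasattr(model, "init_params")
    ):
        attempts += 1
        reseed = seed + attempts * 1000003
        p_retry, h_retry = _train_once(
            model, model.init_params(reseed), train_data, val_data, config, reseed, verbose
        )
        if (h_retry["best_val_acc"] or 0.0) > (best_hist["best_val_acc"] or 0.0):
            best_p, best_hist = p_retry, h_retry
    best_hist["restarts_used"] = attempts
    return best_p, best_hist


def _train_once(
    model,
    params: ParamTree,
    train_data: tuple,
    val_data: tuple | None,
    config: TrainConfig,
    seed: int,
    verbose: bool,
) -> tuple[ParamTree, dict]:
    rng = np.random.default_rng(seed)
    opt = Adam(lr=config.lr)
    x_tr, y_tr = train_data
    n = len(y_tr)
    best_p, best_acc, best_epoch = params, -1.0, -1
    history = {"loss": [], "val_acc": [], "lr": []}
    for epoch in range(config.epochs):
        lr = cosine_lr(config.lr, epoch, config.epochs, config.min_lr, config.warmup_epochs)
        order = rng.permutation(n)
        ep_loss = 0.0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            batch = (model.take(x_tr, idx), y_tr[idx])
            loss, grads = model.loss_and_grad(params, batch, rng=rng)
            params = opt.step(params, grads, lr=lr)
            ep_loss += loss * len(idx)
        history["loss"].append(ep_loss / n)
        history["lr"].append(lr)
        if val_data is not None:
            acc = _accuracy(model, params, val_data[0], val_data[1])
            history["val_acc"].append(acc)
            if acc > best_acc:
                best_acc, best_p, best_epoch = acc, {k: v.copy() for k, v in params.items()}, epoch
            elif epoch - best_epoch >= config.patience:
                break
        else:
            best_p = params
        if verbose:
            va = history["val_acc"][-1] if val_data is not None else float("nan")
            print(f"epoch {epoch:3d} loss {history['loss'][-1]:.4f} val_acc {va:.3f}")
    history["best_val_acc"] = best_acc if val_data is not None else None
    return best_p, history
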