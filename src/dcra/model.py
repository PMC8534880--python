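"""The deep coupling recurrent auto-encoder (DCRA).

Two single-modality recurrent auto-encoders (an EEG-like and an EOG-like
stream) are tied at their 10-unit coupling codes by a joint loss

    L = (1 - alpha) * (L_E + L_O) + alpha * S

where L_E, L_O are the squared-error reconstruction losses of each
auto-encoder and S is the cross-modal coupling loss between the two codes
f_E, f_O. With the Euclidean variant (DCRA_E) S is the squared Euclidean
distance; with the learned-metric variant (DCRA_M) S is the squared
Mahalanobis distance (f_E - f_O)' M (f_E - f_O) under a PGDM-learned PSD
matrix M, which is fitted beforehand from single-modality codes and frozen
during network training. alpha = 0 decouples the objective into two
independent auto-encoders; alpha = 1 ignores reconstruction entirely.

PERCLOS predictions come from a linear head on the concatenated codes.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datagen import LabeledSession, discretize_perclos, standardize_session
from .gru import (DRAParams, DivergenceError, PretrainConfig, decode,
                  default_decoder_spec, default_encoder_spec, encode,
                  pretrain_layers)
from .metric import MetricMatrix, build_pair_sets, pgdm_fit
from .nn import Adam, Tensor

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "DCRAParams",
    "JointLossBreakdown",
    "joint_loss",
    "train_dcra",
    "train_dra",
    "learn_metric_from_session",
    "fuse_features",
    "fit_head",
    "predict_perclos",
    "alpha_sweep",
    "subseed",
]


def subseed(seed: int, name: str) -> int:
    """Derive a named, reproducible child seed (< 2^31) from one global seed.

    Keeping each consumer (init, pretraining, batching, pair sampling) on its
    own stream makes single-modality and coupled runs byte-comparable.
    """
    ss = np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults follow the reference architecture:
    Adam, learning rate 0.001, batch size 32, 10-unit coupling layer)."""

    alpha: float = 0.4
    code_dim: int = 10
    lr: float = 0.001
    batch_size: int = 32
    fine_tune_epochs: int = 100
    pretrain_steps: int = 60
    early_stop_tol: float = 1e-5
    early_stop_patience: int = 5
    coupling_form: str = "mahalanobis"   # or "bilinear" (the literal printed form)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.coupling_form not in ("mahalanobis", "bilinear"):
            raise ValueError("coupling_form must be 'mahalanobis' or 'bilinear'")
        if self.code_dim < 1 or self.batch_size < 1:
            raise ValueError("code_dim and batch_size must be positive")


@dataclass
class DCRAParams:
    """The coupled model: two auto-encoders, the coupling weight, the (fixed)
    metric, and the PERCLOS regression head."""

    ae_e: DRAParams
    ae_o: DRAParams
    alpha: float
    metric: MetricMatrix | None = None      # None -> Euclidean coupling
    coupling_form: str = "mahalanobis"
    head_W: np.ndarray | None = None
    head_b: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.metric is not None and self.metric.d != self.ae_e.code_dim:
            raise ValueError("metric dimension must equal code_dim")
        if self.ae_e.code_dim != self.ae_o.code_dim:
            raise ValueError("the two auto-encoders must share code_dim")

    @property
    def code_dim(self) -> int:
        return self.ae_e.code_dim

    def trainable(self) -> list[Tensor]:
        return self.ae_e.trainable() + self.ae_o.trainable()


@dataclass(frozen=True)
class JointLossBreakdown:
    """One evaluation of the joint loss and its three components."""

    L_total: float
    L_E: float
    L_O: float
    S_coupling: float
    alpha: float

    def recombines(self, tol: float = 1e-10) -> bool:
        expected = (1 - self.alpha) * (self.L_E + self.L_O) + self.alpha * self.S_coupling
        return abs(self.L_total - expected) <= tol


def _coupling_term(f_e, f_o, metric: MetricMatrix | None, form: str, tape: bool):
    if form == "bilinear":
        M = np.eye(f_e.shape[-1]) if metric is None else metric.M
        if tape:
            return ((f_e @ Tensor(M)) * f_o).sum(axis=1).mean()
        return float(np.mean(np.einsum("nd,de,ne->n", f_e, M, f_o)))
    delta = f_e - f_o
    if metric is None:
        if tape:
            return (delta**2).sum(axis=1).mean()
        return float(np.mean((delta**2).sum(axis=1)))
    if tape:
        return ((delta @ Tensor(metric.M)) * delta).sum(axis=1).mean()
    return float(np.mean(np.einsum("nd,de,ne->n", delta, metric.M, delta)))


def _forward_joint(model: DCRAParams, x_e, x_o, training: bool, tape: bool):
    T = x_e.shape[1]
    f_e = encode(model.ae_e, x_e, training=training, tape=tape)
    f_o = encode(model.ae_o, x_o, training=training, tape=tape)
    z_e = decode(model.ae_e, f_e, T, training=training, tape=tape)
    z_o = decode(model.ae_o, f_o, x_o.shape[1], training=training, tape=tape)
    # squared Euclidean (Frobenius) reconstruction error per epoch, batch mean
    if tape:
        batch = x_e.shape[0]
        L_e = ((z_e - Tensor(x_e)) ** 2).sum() / batch
        L_o = ((z_o - Tensor(x_o)) ** 2).sum() / batch
    else:
        L_e = float(np.sum((z_e - x_e) ** 2) / x_e.shape[0])
        L_o = float(np.sum((z_o - x_o) ** 2) / x_o.shape[0])
    S = _coupling_term(f_e, f_o, model.metric, model.coupling_form, tape)
    total = (1 - model.alpha) * (L_e + L_o) + model.alpha * S
    return total, L_e, L_o, S


def joint_loss(model: DCRAParams, x_e: np.ndarray, x_o: np.ndarray) -> JointLossBreakdown:
    """Evaluate the joint loss (inference statistics, no gradients).

    x_e, x_o are (batch, T, dim) or single (T, dim) sequences.
    """
    x_e = np.asarray(x_e, dtype=np.float64)
    x_o = np.asarray(x_o, dtype=np.float64)
    if x_e.ndim == 2:
        x_e = x_e[None]
    if x_o.ndim == 2:
        x_o = x_o[None]
    if x_e.shape[0] != x_o.shape[0]:
        raise ValueError("modalities must have the same batch size")
    total, L_e, L_o, S = _forward_joint(model, x_e, x_o, training=False, tape=False)
    return JointLossBreakdown(float(total), L_e, L_o, S, model.alpha)


def _build_modality_ae(features: np.ndarray, config: TrainConfig, tag: str) -> DRAParams:
    """Pretrained encoder + freshly initialized decoder/projection for one
    modality (`tag` is 'e' or 'o'; it keys the seed streams)."""
    dim = features.shape[2]
    enc, traces = pretrain_layers(
        features, default_encoder_spec(dim),
        PretrainConfig(steps=config.pretrain_steps, batch_size=config.batch_size,
                       lr=config.lr,
                       seed=subseed(config.seed, f"pretrain_{tag}")),
    )
    for li, tr in enumerate(traces, start=1):
        if tr:
            logger.debug("pretrain %s layer %d: loss %.4f -> %.4f", tag, li, tr[0], tr[-1])
    rng = np.random.default_rng(subseed(config.seed, f"init_{tag}"))
    dec = default_decoder_spec(dim).build(config.code_dim, rng)
    enc_out = enc.layers[-1].params.units
    bound = 1.0 / np.sqrt(enc_out)
    proj_W = Tensor(rng.uniform(-bound, bound, size=(enc_out, config.code_dim)),
                    requires_grad=True)
    proj_b = Tensor(np.zeros(config.code_dim), requires_grad=True)
    return DRAParams(enc, dec, proj_W, proj_b)


def _fine_tune(model: DCRAParams, x_e: np.ndarray, x_o: np.ndarray,
               config: TrainConfig) -> list[JointLossBreakdown]:
    n = x_e.shape[0]
    opt = Adam(model.trainable(), lr=config.lr)
    rng = np.random.default_rng(subseed(config.seed, "batch"))
    trace: list[JointLossBreakdown] = []
    epoch_means: list[float] = []
    for _ in range(config.fine_tune_epochs):
        perm = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            total, L_e, L_o, S = _forward_joint(
                model, x_e[idx], x_o[idx], training=True, tape=True)
            if not np.isfinite(total.item()):
                raise DivergenceError("joint fine-tuning loss became non-finite")
            opt.zero_grad()
            total.backward()
            opt.step()
            trace.append(JointLossBreakdown(
                total.item(), L_e.item(), L_o.item(),
                S.item() if isinstance(S, Tensor) else float(S), config.alpha))
            epoch_losses.append(total.item())
        epoch_means.append(float(np.mean(epoch_losses)))
        if len(epoch_means) > config.early_stop_patience:
            recent = epoch_means[-(config.early_stop_patience + 1):]
            rel = abs(recent[0] - recent[-1]) / max(abs(recent[0]), 1e-12)
            if rel < config.early_stop_tol:
                break
    return trace


def train_dcra(session: LabeledSession, config: TrainConfig,
               metric_mode: str = "euclidean",
               metric: MetricMatrix | None = None,
               ) -> tuple[DCRAParams, list[JointLossBreakdown]]:
    """Train the coupled model on a (standardized) session.

    Greedy layer-wise pretraining of both encoders, then joint fine-tuning of
    everything under the joint loss with Adam. With ``metric_mode='learned'``
    a PGDM metric is required (fitted beforehand and frozen); pass it in or it
    is learned here from single-modality codes.

    Returns (model, per-step loss trace).
    """
    if metric_mode not in ("euclidean", "learned"):
        raise ValueError("metric_mode must be 'euclidean' or 'learned'")
    if metric_mode == "learned" and metric is None:
        metric = learn_metric_from_session(session, config)
    if metric_mode == "euclidean":
        metric = None

    ae_e = _build_modality_ae(session.features_e, config, "e")
    ae_o = _build_modality_ae(session.features_o, config, "o")
    model = DCRAParams(ae_e, ae_o, alpha=config.alpha, metric=metric,
                       coupling_form=config.coupling_form)
    trace = _fine_tune(model, session.features_e, session.features_o, config)
    return model, trace


def train_dra(features: np.ndarray, config: TrainConfig, tag: str,
              ) -> tuple[DRAParams, list[float]]:
    """Train one single-modality deep recurrent auto-encoder.

    Uses the same seed streams and batch order as the corresponding branch of
    a coupled run, so an alpha = 0 coupled run and two independent runs are
    step-for-step comparable.
    """
    ae = _build_modality_ae(features, config, tag)
    n = features.shape[0]
    opt = Adam(ae.trainable(), lr=config.lr)
    rng = np.random.default_rng(subseed(config.seed, "batch"))
    trace: list[float] = []
    for _ in range(config.fine_tune_epochs):
        perm = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            xb = features[idx]
            f = encode(ae, xb, training=True, tape=True)
            z = decode(ae, f, xb.shape[1], training=True, tape=True)
            loss = ((z - Tensor(xb)) ** 2).sum() / xb.shape[0]
            if not np.isfinite(loss.item()):
                raise DivergenceError("auto-encoder fine-tuning diverged")
            opt.zero_grad()
            loss.backward()
            opt.step()
            trace.append(loss.item())
    return ae, trace


def learn_metric_from_session(session: LabeledSession, config: TrainConfig,
                              thresholds: tuple[float, ...] = (0.35, 0.70),
                              max_pairs: int = 500) -> MetricMatrix:
    """PGDM metric from single-modality auto-encoder codes.

    Both modalities' codes live in the shared coupling space, so they are
    pooled as samples (labels: discretized PERCLOS, one per epoch, repeated
    for each modality); the learned M is code_dim x code_dim.
    """
    cfg = replace(config, alpha=0.0)
    ae_e, _ = train_dra(session.features_e, cfg, "e")
    ae_o, _ = train_dra(session.features_o, cfg, "o")
    codes = np.vstack([encode(ae_e, session.features_e),
                       encode(ae_o, session.features_o)])
    labels = np.array([discretize_perclos(p, thresholds) for p in session.perclos])
    labels = np.concatenate([labels, labels])
    if len(np.unique(labels)) < 2:
        raise ValueError("PERCLOS labels collapse to one class; cannot learn a metric")
    pairs = build_pair_sets(codes, labels, max_pairs=max_pairs,
                            seed=subseed(config.seed, "pairs"))
    metric, _ = pgdm_fit(pairs)
    return metric


def fuse_features(model: DCRAParams, x_e: np.ndarray, x_o: np.ndarray) -> np.ndarray:
    """Concatenated coupling codes [f_E ; f_O] (length 2 * code_dim)."""
    x_e = np.asarray(x_e, dtype=np.float64)
    x_o = np.asarray(x_o, dtype=np.float64)
    f_e = encode(model.ae_e, x_e)
    f_o = encode(model.ae_o, x_o)
    return np.concatenate([f_e, f_o], axis=-1)


def _lstsq_head(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    n, d = X.shape
    A = np.hstack([X, np.ones((n, 1))])
    if n < d + 1:
        logger.warning("under-determined head fit (n=%d < %d); ridge fallback", n, d + 1)
        lam = 1e-3
        beta = np.linalg.solve(A.T @ A + lam * np.eye(d + 1), A.T @ y)
    else:
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta[:-1], float(beta[-1])


def fit_head(model: DCRAParams, x_e: np.ndarray, x_o: np.ndarray,
             labels: np.ndarray) -> DCRAParams:
    """Least-squares affine map from fused codes to PERCLOS (in place)."""
    fused = fuse_features(model, x_e, x_o)
    model.head_W, model.head_b = _lstsq_head(fused, np.asarray(labels, dtype=np.float64))
    return model


def predict_perclos(model: DCRAParams, x_e: np.ndarray, x_o: np.ndarray) -> np.ndarray:
    """PERCLOS predictions from fused codes, clipped to [0, 1]."""
    if model.head_W is None:
        raise ValueError("regression head not fitted; call fit_head first")
    fused = fuse_features(model, x_e, x_o)
    pred = fused @ model.head_W + model.head_b
    return np.clip(pred, 0.0, 1.0)


def alpha_sweep(session: LabeledSession, alphas, config: TrainConfig,
                k: int = 3, metric_mode: str = "euclidean",
                metric: MetricMatrix | None = None) -> pd.DataFrame:
    """Cross-validated RMSE for each coupling weight (shared seed).

    Returns a table with one row per alpha.
    """
    from .evaluation import kfold_cv  # local import: evaluation has no model dep

    alphas = list(alphas)
    if len(alphas) < 2:
        raise ValueError("need at least two alpha values")
    if any(not 0.0 <= a <= 1.0 for a in alphas):
        raise ValueError("alpha values must lie in [0, 1]")
    rows = []
    for a in alphas:
        cfg = replace(config, alpha=float(a))
        report = kfold_cv(session, make_dcra_trainer(cfg, metric_mode, metric),
                          k=k, seed=config.seed)
        rows.append({"alpha": float(a), "cv_rmse": report.pooled_rmse,
                     "cv_pcc": report.pooled_pcc})
    return pd.DataFrame(rows)


def make_dcra_trainer(config: TrainConfig, metric_mode: str = "euclidean",
                      metric: MetricMatrix | None = None):
    """Trainer closure for the cross-validation harness: standardizes with
    train-fold statistics, trains a DCRA, fits the head, and returns a
    predictor over raw (unstandardized) inputs."""

    def trainer(train_session: LabeledSession):
        ze, stats_e = standardize_session(train_session.features_e,
                                          train_session.features_e)
        zo, stats_o = standardize_session(train_session.features_o,
                                          train_session.features_o)
        std = LabeledSession(ze, zo, train_session.events, train_session.perclos,
                             latent=train_session.latent)
        model, _ = train_dcra(std, config, metric_mode=metric_mode, metric=metric)
        fit_head(model, ze, zo, std.perclos)

        def predict(x_e: np.ndarray, x_o: np.ndarray) -> np.ndarray:
            me, se = stats_e
            mo, so = stats_o
            return predict_perclos(model, (x_e - me) / se, (x_o - mo) / so)

        return predict

    return trainer
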