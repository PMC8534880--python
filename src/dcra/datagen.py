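"""Synthetic multimodal vigilance sessions and PERCLOS labelling.

Real vigilance-monitoring data pairs per-epoch physiological feature matrices
(an EEG-like stream and an EOG-like stream) with a continuous PERCLOS label —
the fraction of eye-tracker events in which the eyes were blinking or closed.
The generator here emulates that structure: a slowly drifting latent vigilance
state drives both feature streams (through fixed shared loadings) and the
eye-event rates from which PERCLOS is computed, so the two modalities carry
correlated information about the same latent process, plus modality-specific
dynamics and observation noise that they do not share.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EventRateParams",
    "SyntheticConfig",
    "EyeEventCounts",
    "LabeledSession",
    "perclos",
    "generate_session",
    "discretize_perclos",
    "standardize",
    "standardize_session",
]


@dataclass(frozen=True)
class EventRateParams:
    """Log-linear Poisson rates for the four eye-event types per epoch.

    Each rate is exp(intercept + slope * v) where v in [0,1] is the latent
    vigilance-loss state. Blink and closure rates increase with v; fixation
    and saccade rates decrease, so mean PERCLOS rises monotonically in v.
    """

    blink_intercept: float = 2.5
    blink_slope: float = 1.0
    clos_intercept: float = 1.7
    clos_slope: float = 2.5
    fixation_intercept: float = 4.0
    fixation_slope: float = -1.5
    saccade_intercept: float = 3.7
    saccade_slope: float = -1.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic session generator.

    The latent state is an AR(1) process squashed to [0,1] by a logistic; each
    modality observes (shared loading x latent) plus a modality-specific AR(1)
    component and white Gaussian noise.
    """

    n_epochs: int = 300
    steps_per_epoch: int = 8
    dim_e: int = 36
    dim_o: int = 25
    latent_ar_coeff: float = 0.95
    latent_innovation_sd: float = 0.3
    shared_loading_scale: float = 1.0
    specific_ar_coeff: float = 0.8
    specific_scale_e: float = 0.3
    specific_scale_o: float = 0.3
    noise_sd_e: float = 0.3
    noise_sd_o: float = 0.3
    event_rate_params: EventRateParams = field(default_factory=EventRateParams)
    seed: int = 0

    def __post_init__(self):
        if self.n_epochs < 1 or self.steps_per_epoch < 1:
            raise ValueError("n_epochs and steps_per_epoch must be >= 1")
        if self.dim_e < 1 or self.dim_o < 1:
            raise ValueError("feature dimensions must be >= 1")
        if not abs(self.latent_ar_coeff) < 1:
            raise ValueError("|latent_ar_coeff| must be < 1 (stationarity)")
        if not abs(self.specific_ar_coeff) < 1:
            raise ValueError("|specific_ar_coeff| must be < 1")
        if min(self.noise_sd_e, self.noise_sd_o, self.latent_innovation_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.shared_loading_scale <= 0:
            raise ValueError("shared_loading_scale must be > 0")


@dataclass(frozen=True)
class EyeEventCounts:
    """Eye-tracker event counts within one epoch."""

    blink: int
    fixation: int
    saccade: int
    clos: int

    def __post_init__(self):
        if min(self.blink, self.fixation, self.saccade, self.clos) < 0:
            raise ValueError("event counts must be non-negative")

    @property
    def total(self) -> int:
        return self.blink + self.fixation + self.saccade + self.clos


@dataclass
class LabeledSession:
    """Paired per-epoch feature sequences for two modalities with labels.

    features_e : (n_epochs, T, dim_e) EEG-like stream
    features_o : (n_epochs, T, dim_o) EOG-like stream
    events     : per-epoch eye-event counts
    perclos    : (n_epochs,) labels in [0, 1]
    latent     : (n_epochs,) ground-truth vigilance state (synthetic only)
    """

    features_e: np.ndarray
    features_o: np.ndarray
    events: list[EyeEventCounts]
    perclos: np.ndarray
    latent: np.ndarray | None = None

    def __post_init__(self):
        self.features_e = np.asarray(self.features_e, dtype=np.float64)
        self.features_o = np.asarray(self.features_o, dtype=np.float64)
        self.perclos = np.asarray(self.perclos, dtype=np.float64)
        n = len(self.perclos)
        if self.features_e.shape[0] != n or self.features_o.shape[0] != n:
            raise ValueError("feature arrays and perclos lengths disagree")
        if self.events and len(self.events) != n:
            raise ValueError("events length disagrees with perclos")
        if not (np.isfinite(self.features_e).all() and np.isfinite(self.features_o).all()):
            raise ValueError("feature arrays contain non-finite values")
        if self.perclos.min() < 0 or self.perclos.max() > 1:
            raise ValueError("perclos labels must lie in [0, 1]")

    @property
    def n_epochs(self) -> int:
        return len(self.perclos)


def perclos(events: EyeEventCounts) -> float:
    """PERCLOS = (blink + closure) / (blink + fixation + saccade + closure)."""
    if events.total == 0:
        raise ValueError("PERCLOS undefined: all event counts are zero")
    return (events.blink + events.clos) / events.total


def discretize_perclos(p: float, thresholds: tuple[float, ...] = (0.35, 0.70)) -> int:
    """Map a PERCLOS value to a vigilance class (count of thresholds below p).

    The default cut points (0.35, 0.70) follow the awake / tired / drowsy
    convention used with PERCLOS labels.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"PERCLOS must lie in [0, 1], got {p}")
    thresholds = tuple(thresholds)
    if any(not 0 < t < 1 for t in thresholds) or list(thresholds) != sorted(set(thresholds)):
        raise ValueError("thresholds must be strictly ascending within (0, 1)")
    return int(sum(t < p for t in thresholds))


def _ar1(rng: np.random.Generator, n: int, coeff: float, sd: float,
         shape: tuple[int, ...] = ()) -> np.ndarray:
    """Stationary AR(1) path of length n (extra dims vary independently)."""
    out = np.empty((n, *shape))
    stat_sd = sd / np.sqrt(1.0 - coeff**2) if sd > 0 else 0.0
    out[0] = rng.normal(0.0, stat_sd or 0.0, size=shape)
    innov = rng.normal(0.0, sd, size=(n - 1, *shape)) if n > 1 else None
    for t in range(1, n):
        out[t] = coeff * out[t - 1] + innov[t - 1]
    return out


def generate_session(config: SyntheticConfig) -> LabeledSession:
    """Draw one synthetic labelled session, reproducible from config.seed."""
    ss = np.random.SeedSequence(config.seed)
    rng_latent, rng_load, rng_e, rng_o, rng_ev = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    n, T = config.n_epochs, config.steps_per_epoch

    # latent vigilance-loss state: AR(1), logistic-squashed to [0,1]
    u = _ar1(rng_latent, n, config.latent_ar_coeff, config.latent_innovation_sd)
    v = 1.0 / (1.0 + np.exp(-u))

    # fixed shared loadings per modality (nonzero by construction)
    def loadings(rng, dim):
        lam = rng.uniform(0.3, 1.0, size=dim) * rng.choice([-1.0, 1.0], size=dim)
        return lam * config.shared_loading_scale

    lam_e = loadings(rng_load, config.dim_e)
    lam_o = loadings(rng_load, config.dim_o)

    def modality(rng, dim, lam, spec_scale, noise_sd):
        shared = v[:, None, None] * lam[None, None, :]          # (n, 1, dim)
        spec = spec_scale * _ar1(
            rng, n * T, config.specific_ar_coeff, 1.0, (dim,)
        ).reshape(n, T, dim)
        noise = rng.normal(0.0, noise_sd, size=(n, T, dim)) if noise_sd > 0 else 0.0
        return shared + spec + noise

    x_e = modality(rng_e, config.dim_e, lam_e, config.specific_scale_e, config.noise_sd_e)
    x_o = modality(rng_o, config.dim_o, lam_o, config.specific_scale_o, config.noise_sd_o)

    p = config.event_rate_params
    rates = np.stack([
        np.exp(p.blink_intercept + p.blink_slope * v),
        np.exp(p.fixation_intercept + p.fixation_slope * v),
        np.exp(p.saccade_intercept + p.saccade_slope * v),
        np.exp(p.clos_intercept + p.clos_slope * v),
    ], axis=1)
    counts = rng_ev.poisson(rates)
    events = []
    for row in counts:
        if row.sum() == 0:       # degenerate draw: ensure PERCLOS is defined
            row[1] = 1
        events.append(EyeEventCounts(int(row[0]), int(row[1]), int(row[2]), int(row[3])))
    labels = np.array([perclos(ev) for ev in events])

    return LabeledSession(x_e, x_o, events, labels, latent=v)


def standardize(train: np.ndarray, apply_to: np.ndarray):
    """Z-score `apply_to` columns using `train` column statistics.

    Returns (standardized, (mean, sd)). Zero-variance columns get unit scale
    (and a warning), so constant features map to zero rather than NaN.
    """
    train = np.asarray(train, dtype=np.float64)
    apply_to = np.asarray(apply_to, dtype=np.float64)
    if train.shape[0] < 2:
        raise ValueError("need at least 2 training rows to standardize")
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    zero = sd == 0
    if zero.any():
        logger.warning("standardize: %d zero-variance column(s); scale set to 1",
                       int(zero.sum()))
        sd = np.where(zero, 1.0, sd)
    return (apply_to - mean) / sd, (mean, sd)


def standardize_session(train_feats: np.ndarray, apply_feats: np.ndarray):
    """Standardize (n, T, d) session features using train-set statistics."""
    n, T, d = train_feats.shape
    flat_train = train_feats.reshape(n * T, d)
    m, t2, d2 = apply_feats.shape
    flat_apply = apply_feats.reshape(m * t2, d2)
    z, stats = standardize(flat_train, flat_apply)
    return z.reshape(m, t2, d2), stats
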