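"""Synthetic fusion study: does coupling two modalities help?

One experiment per seed: generate a synthetic session whose two feature
streams load on the same latent vigilance process, then, per contiguous
cross-validation fold:

* train a decoupled model (alpha = 0) — its two halves double as the
  single-modality baselines;
* fit the PGDM Mahalanobis metric from that model's coupling codes (the
  separate preparatory step the learned-metric variant prescribes);
* train the Euclidean-coupling variant (DCRA_E) and the learned-metric
  variant (DCRA_M) at alpha in {0.4, 1};
* measure held-out prediction RMSE from the fused codes, and the mean
  held-out Euclidean code distance ||f_E - f_O|| for the Euclidean runs
  (that distance is the very loss their coupling term minimizes).

The study asks three questions mirroring the method's claims: the coupling
term pulls the two codes together (distance falls as alpha rises from 0);
the fused learned-metric model predicts PERCLOS better than either modality
alone; and a moderate alpha beats both extremes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datagen import (LabeledSession, SyntheticConfig, discretize_perclos,
                      generate_session, standardize_session)
from .evaluation import contiguous_folds, pcc, rmse
from .gru import encode
from .metric import build_pair_sets, pgdm_fit
from .model import (TrainConfig, _lstsq_head, fit_head, predict_perclos,
                    subseed, train_dcra)

__all__ = ["FusionResult", "fusion_experiment", "STUDY_ALPHAS"]

STUDY_ALPHAS = (0.0, 0.4, 1.0)


@dataclass
class FusionResult:
    """Pooled cross-validated quantities for one seed."""

    seed: int
    rmse_by_alpha: dict[float, float]       # learned-metric variant (alpha=0 shared)
    rmse_by_alpha_euclidean: dict[float, float]
    code_dist_by_alpha: dict[float, float]  # mean held-out ||f_E - f_O||, Euclidean runs
    rmse_single_e: float                    # E-code-only baseline (alpha=0 model)
    rmse_single_o: float                    # O-code-only baseline (alpha=0 model)
    pcc_fused: float                        # learned-metric variant at moderate alpha

    @property
    def rmse_fused(self) -> float:
        interior = [a for a in self.rmse_by_alpha if 0.0 < a < 1.0]
        return self.rmse_by_alpha[interior[0]] if interior else min(self.rmse_by_alpha.values())

    @property
    def fused_beats_single(self) -> bool:
        return self.rmse_fused < min(self.rmse_single_e, self.rmse_single_o)


def _single_modality_predictions(ae, feats_train, feats_test, y_train):
    codes_train = encode(ae, feats_train)
    w, b = _lstsq_head(codes_train, y_train)
    return np.clip(encode(ae, feats_test) @ w + b, 0.0, 1.0)


def fusion_experiment(seed: int,
                      data_config: SyntheticConfig | None = None,
                      train_config: TrainConfig | None = None,
                      k: int = 3) -> FusionResult:
    """Run the full fusion study for one seed; see the module docstring."""
    data_config = data_config or SyntheticConfig(n_epochs=240, seed=seed)
    if data_config.seed != seed:
        data_config = replace(data_config, seed=seed)
    train_config = train_config or TrainConfig(
        fine_tune_epochs=25, pretrain_steps=40, seed=seed)
    if train_config.seed != seed:
        train_config = replace(train_config, seed=seed)

    session = generate_session(data_config)
    n = session.n_epochs
    folds = contiguous_folds(n, k)
    alphas = STUDY_ALPHAS

    preds_m = {a: np.empty(n) for a in alphas}
    preds_e = {a: np.empty(n) for a in alphas}
    dists = {a: [] for a in alphas}
    pred_single_e = np.empty(n)
    pred_single_o = np.empty(n)

    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        ze_tr, stats_e = standardize_session(session.features_e[train_idx],
                                             session.features_e[train_idx])
        zo_tr, stats_o = standardize_session(session.features_o[train_idx],
                                             session.features_o[train_idx])
        ze_te = (session.features_e[test_idx] - stats_e[0]) / stats_e[1]
        zo_te = (session.features_o[test_idx] - stats_o[0]) / stats_o[1]
        y_tr = session.perclos[train_idx]
        std_sess = LabeledSession(ze_tr, zo_tr, [], y_tr)

        def evaluate(model, alpha, store_pred, measure_dist):
            fit_head(model, ze_tr, zo_tr, y_tr)
            store_pred[alpha][test_idx] = predict_perclos(model, ze_te, zo_te)
            if measure_dist:
                f_e = encode(model.ae_e, ze_te)
                f_o = encode(model.ae_o, zo_te)
                dists[alpha].append(np.linalg.norm(f_e - f_o, axis=1))

        # decoupled run: shared between variants, provides the baselines
        m0, _ = train_dcra(std_sess, replace(train_config, alpha=0.0))
        evaluate(m0, 0.0, preds_m, measure_dist=True)
        preds_e[0.0][test_idx] = preds_m[0.0][test_idx]
        pred_single_e[test_idx] = _single_modality_predictions(
            m0.ae_e, ze_tr, ze_te, y_tr)
        pred_single_o[test_idx] = _single_modality_predictions(
            m0.ae_o, zo_tr, zo_te, y_tr)

        # metric from the decoupled model's codes, pooled across modalities
        codes = np.vstack([encode(m0.ae_e, ze_tr), encode(m0.ae_o, zo_tr)])
        labels = np.array([discretize_perclos(p) for p in y_tr])
        labels = np.concatenate([labels, labels])
        pairs = build_pair_sets(codes, labels, max_pairs=500,
                                seed=subseed(seed, "pairs"))
        metric, _ = pgdm_fit(pairs)

        for a in (0.4, 1.0):
            cfg = replace(train_config, alpha=float(a))
            me, _ = train_dcra(std_sess, cfg, metric_mode="euclidean")
            evaluate(me, a, preds_e, measure_dist=True)
            mm, _ = train_dcra(std_sess, cfg, metric_mode="learned", metric=metric)
            evaluate(mm, a, preds_m, measure_dist=False)

    y = session.perclos
    return FusionResult(
        seed=seed,
        rmse_by_alpha={a: rmse(y, preds_m[a]) for a in alphas},
        rmse_by_alpha_euclidean={a: rmse(y, preds_e[a]) for a in alphas},
        code_dist_by_alpha={a: float(np.concatenate(dists[a]).mean()) for a in alphas},
        rmse_single_e=rmse(y, pred_single_e),
        rmse_single_o=rmse(y, pred_single_o),
        pcc_fused=pcc(y, preds_m[0.4]),
    )
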