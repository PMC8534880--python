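"""Regression metrics, cross-validation, and nonparametric model comparison.

RMSE and the Pearson correlation coefficient are the standard evaluation pair
for PERCLOS regression. Model comparison across datasets uses the Friedman
test on per-dataset ranks followed by the Nemenyi post-hoc: two algorithms
differ significantly when their average order values (mean ranks, AOV) differ
by more than the critical difference

    CD = q_alpha * sqrt(k (k + 1) / (6 N))

with k algorithms, N datasets, and q_alpha from the studentized-range table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datagen import LabeledSession

__all__ = [
    "EvalReport",
    "RankTable",
    "rmse",
    "pcc",
    "kfold_cv",
    "contiguous_folds",
    "rank_algorithms",
    "friedman_statistic",
    "nemenyi_cd",
    "nemenyi_q_alpha",
    "cd_diagram",
]

# studentized range q_alpha / sqrt(2) at alpha = 0.05 for k = 2..10
# (the usual Nemenyi-test table)
_Q_ALPHA_05 = {2: 1.960, 3: 2.343, 4: 2.569, 5: 2.728, 6: 2.850,
               7: 2.949, 8: 3.031, 9: 3.102, 10: 3.164}


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean squared error."""
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.size == 0 or y.shape != yhat.shape:
        raise ValueError("vectors must be non-empty and of equal length")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def pcc(y: np.ndarray, yhat: np.ndarray) -> float:
    """Pearson correlation coefficient."""
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("vectors must be of equal length >= 2")
    yc = y - y.mean()
    pc = yhat - yhat.mean()
    denom = np.sqrt((yc**2).sum() * (pc**2).sum())
    if denom == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.clip((yc * pc).sum() / denom, -1.0, 1.0))


@dataclass
class EvalReport:
    """Per-fold and pooled cross-validation metrics."""

    fold_rmse: list[float]
    fold_pcc: list[float]
    pooled_rmse: float
    pooled_pcc: float
    n: int
    folds: list[np.ndarray] = field(repr=False)
    y: np.ndarray = field(repr=False, default=None)
    yhat: np.ndarray = field(repr=False, default=None)


def contiguous_folds(n: int, k: int) -> list[np.ndarray]:
    """Contiguous time-block folds (sizes differ by at most one).

    Blocks rather than shuffled folds: the sessions are time series, and
    shuffling would leak temporally adjacent epochs across the split.
    """
    if k > n:
        raise ValueError(f"k={k} folds exceed n={n} samples")
    if k < 2:
        raise ValueError("need k >= 2 folds")
    return [idx for idx in np.array_split(np.arange(n), k)]


def kfold_cv(session: LabeledSession, trainer, k: int = 5, seed: int = 0) -> EvalReport:
    """K-fold cross-validation over a labelled session.

    `trainer(train_session)` must return a predictor
    `predict(x_e, x_o) -> yhat`; standardization and head fitting are the
    trainer's responsibility and must use the training folds only (the
    bundled DCRA trainer does exactly that).
    """
    n = session.n_epochs
    folds = contiguous_folds(n, k)
    y_all = np.empty(n)
    yhat_all = np.empty(n)
    fold_rmse, fold_pcc = [], []
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        train_sess = LabeledSession(
            session.features_e[train_idx], session.features_o[train_idx],
            [session.events[i] for i in train_idx] if session.events else [],
            session.perclos[train_idx],
            latent=None if session.latent is None else session.latent[train_idx],
        )
        predict = trainer(train_sess)
        yhat = np.asarray(predict(session.features_e[test_idx],
                                  session.features_o[test_idx]), dtype=np.float64)
        y = session.perclos[test_idx]
        y_all[test_idx] = y
        yhat_all[test_idx] = yhat
        fold_rmse.append(rmse(y, yhat))
        try:
            fold_pcc.append(pcc(y, yhat))
        except ValueError:
            fold_pcc.append(np.nan)
    return EvalReport(fold_rmse, fold_pcc,
                      pooled_rmse=rmse(y_all, yhat_all),
                      pooled_pcc=pcc(y_all, yhat_all),
                      n=n, folds=folds, y=y_all, yhat=yhat_all)


@dataclass
class RankTable:
    """Per-dataset algorithm ranks and average order values."""

    scores: pd.DataFrame          # datasets x algorithms
    ranks: pd.DataFrame           # same shape, 1 = best, average ranks on ties
    aov: pd.Series                # mean rank per algorithm

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    @property
    def N(self) -> int:
        return self.scores.shape[0]


def rank_algorithms(scores, lower_is_better: bool = True,
                    algorithms=None, datasets=None) -> RankTable:
    """Rank algorithms per dataset (1 = best; average ranks on ties)."""
    df = pd.DataFrame(np.asarray(scores, dtype=np.float64),
                      index=datasets, columns=algorithms)
    if df.shape[1] < 2 or df.shape[0] < 1:
        raise ValueError("need >= 2 algorithms and >= 1 dataset")
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError("scores contain non-finite values")
    vals = df.to_numpy() if lower_is_better else -df.to_numpy()
    ranks = rankdata(vals, method="average", axis=1)
    ranks_df = pd.DataFrame(ranks, index=df.index, columns=df.columns)
    return RankTable(scores=df, ranks=ranks_df, aov=ranks_df.mean(axis=0))


def friedman_statistic(ranks) -> float:
    """Friedman chi-square from a (datasets x algorithms) rank matrix:

        chi2_F = 12 / (N k (k+1)) * sum_j R_j^2 - 3 N (k+1)

    with R_j the rank sum of algorithm j.
    """
    R = ranks.ranks.to_numpy() if isinstance(ranks, RankTable) else np.asarray(ranks, dtype=np.float64)
    if R.ndim != 2 or R.shape[1] < 2:
        raise ValueError("need a (datasets x algorithms) matrix with k >= 2")
    N, k = R.shape
    Rj = R.sum(axis=0)
    return float(12.0 / (N * k * (k + 1)) * (Rj**2).sum() - 3.0 * N * (k + 1))


def nemenyi_q_alpha(k: int, alpha: float = 0.05) -> float:
    """Built-in q_alpha table (alpha = 0.05, k <= 10)."""
    if alpha != 0.05:
        raise ValueError("built-in table covers alpha = 0.05 only; pass q_alpha directly")
    if k not in _Q_ALPHA_05:
        raise ValueError(f"built-in table covers 2 <= k <= 10, got k={k}")
    return _Q_ALPHA_05[k]


def nemenyi_cd(k: int, N: int, q_alpha: float | None = None) -> float:
    """Nemenyi critical difference CD = q_alpha * sqrt(k (k+1) / (6 N))."""
    if k < 2 or N < 1:
        raise ValueError("need k >= 2 algorithms and N >= 1 datasets")
    if q_alpha is None:
        q_alpha = nemenyi_q_alpha(k)
    if q_alpha < 0:
        raise ValueError("q_alpha must be non-negative")
    return float(q_alpha * np.sqrt(k * (k + 1) / (6.0 * N)))


def cd_diagram(rank_table: RankTable, cd: float, path=None):
    """Critical-difference diagram + pairwise significance table.

    Each algorithm gets a dot at its AOV with a horizontal segment of length
    CD centred on it; non-overlapping segments mean a significant difference.
    Returns a boolean DataFrame with entry (i, j) True when
    |AOV_i - AOV_j| > CD. If `path` is given the diagram is saved there.
    """
    aov = rank_table.aov
    diff = np.abs(aov.to_numpy()[:, None] - aov.to_numpy()[None, :])
    significant = pd.DataFrame(diff > cd, index=aov.index, columns=aov.index)

    if path is not None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 0.6 * len(aov) + 1.2))
        order = aov.sort_values()
        for y, (name, value) in enumerate(order.items()):
            ax.plot([value - cd / 2, value + cd / 2], [y, y], lw=2, color="tab:blue")
            ax.plot([value], [y], "o", color="tab:red")
        ax.set_yticks(range(len(order)))
        ax.set_yticklabels(order.index)
        ax.set_xlabel("average order value (mean rank)")
        ax.set_title(f"critical difference = {cd:.3f}")
        ax.invert_yaxis()
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)

    return significant
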