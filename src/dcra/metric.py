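"""Mahalanobis distance and PGDM (probabilistic global distance metric)
learning.

PGDM poses metric learning as the convex program

    min_M  sum_{(i,j) in S} ||x_i - x_j||_M^2
    s.t.   sum_{(i,j) in D} ||x_i - x_j||_M >= 1,   M >= 0 (PSD)

where S holds same-class pairs and D different-class pairs, and
||x||_M = sqrt(x' M x). The program is optimized here through its
unconstrained surrogate

    g(M) = sum_S ||x_i - x_j||_M^2  -  log( sum_D ||x_i - x_j||_M )

by projected gradient descent (gradient step, symmetrize, clip negative
eigenvalues), with a final positive rescale of M so the D-constraint holds;
rescaling leaves the minimizer's direction unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

__all__ = [
    "MetricMatrix",
    "PairSets",
    "mahalanobis",
    "build_pair_sets",
    "pgdm_loss",
    "pgdm_fit",
    "psd_project",
]

_SYM_TOL = 1e-10
_EIG_TOL = 1e-10


@dataclass(frozen=True)
class MetricMatrix:
    """Symmetric PSD matrix M with a factorization M = P P'."""

    M: np.ndarray
    P: np.ndarray

    def __post_init__(self):
        M = np.asarray(self.M, dtype=np.float64)
        P = np.asarray(self.P, dtype=np.float64)
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "P", P)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("M must be square")
        if np.abs(M - M.T).max() > _SYM_TOL:
            raise ValueError("M must be symmetric")
        w = np.linalg.eigvalsh(M)
        if w.min() < -_EIG_TOL:
            raise ValueError(f"M must be PSD (min eigenvalue {w.min():.3e})")
        if np.abs(P @ P.T - M).max() > 1e-8:
            raise ValueError("factor P does not satisfy M = P P'")

    @property
    def d(self) -> int:
        return self.M.shape[0]

    @classmethod
    def identity(cls, d: int) -> "MetricMatrix":
        return cls(np.eye(d), np.eye(d))


def psd_project(A: np.ndarray) -> MetricMatrix:
    """Project a square matrix to the PSD cone: symmetrize, clip eigenvalues.

    The factor P is rebuilt from the eigendecomposition of the clipped matrix.
    """
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.isfinite(A).all():
        raise ValueError("input contains non-finite entries")
    S = 0.5 * (A + A.T)
    w, V = np.linalg.eigh(S)
    w = np.clip(w, 0.0, None)
    M = (V * w) @ V.T
    M = 0.5 * (M + M.T)  # kill symmetry round-off
    P = V * np.sqrt(w)
    return MetricMatrix(M, P)


def mahalanobis(metric: MetricMatrix, x: np.ndarray, y: np.ndarray) -> float:
    """d_M(x, y) = sqrt((x-y)' M (x-y)), clipped at 0 against round-off."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != (metric.d,) or y.shape != (metric.d,):
        raise ValueError("vector dimension does not match the metric")
    delta = x - y
    return float(np.sqrt(max(delta @ metric.M @ delta, 0.0)))


@dataclass
class PairSets:
    """Same-class (S) and different-class (D) index pairs over a feature set."""

    S: list[tuple[int, int]]
    D: list[tuple[int, int]]
    features: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        n = self.features.shape[0]
        all_pairs = self.S + self.D
        if any(not (0 <= i < n and 0 <= j < n) for i, j in all_pairs):
            raise ValueError("pair index out of range")
        if set(self.S) & set(self.D):
            raise ValueError("S and D must be disjoint")

    def diffs(self, which: str) -> np.ndarray:
        pairs = self.S if which == "S" else self.D
        if not pairs:
            return np.empty((0, self.features.shape[1]))
        idx = np.asarray(pairs)
        return self.features[idx[:, 0]] - self.features[idx[:, 1]]


def build_pair_sets(features: np.ndarray, labels: np.ndarray,
                    max_pairs: int = 1000, seed: int = 0) -> PairSets:
    """Enumerate same-/different-class pairs, subsampling each set uniformly
    (without replacement) to at most `max_pairs`, reproducibly from `seed`."""
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if features.shape[0] != labels.shape[0]:
        raise ValueError("features and labels lengths disagree")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes (D would be empty)")
    same, diff = [], []
    for i, j in combinations(range(len(labels)), 2):
        (same if labels[i] == labels[j] else diff).append((i, j))
    rng = np.random.default_rng(seed)

    def sample(pairs):
        if len(pairs) <= max_pairs:
            return list(pairs)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        return [pairs[k] for k in sorted(idx)]

    return PairSets(S=sample(same), D=sample(diff), features=features)


def _dists_sq(M: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    return np.clip(np.einsum("nd,de,ne->n", deltas, M, deltas), 0.0, None)


def pgdm_loss(metric: MetricMatrix | np.ndarray, pairs: PairSets) -> float:
    """g(M) = sum_S d_M^2 - log(sum_D d_M)."""
    M = metric.M if isinstance(metric, MetricMatrix) else np.asarray(metric)
    s_term = _dists_sq(M, pairs.diffs("S")).sum()
    d_sum = np.sqrt(_dists_sq(M, pairs.diffs("D"))).sum()
    if d_sum <= 0:
        raise ValueError("sum of different-class distances is zero; log undefined")
    return float(s_term - np.log(d_sum))


def _pgdm_grad(M: np.ndarray, dS: np.ndarray, dD: np.ndarray) -> np.ndarray:
    grad = dS.T @ dS if len(dS) else np.zeros_like(M)
    d = np.sqrt(_dists_sq(M, dD))
    total = d.sum()
    nz = d > 1e-12
    if nz.any() and total > 0:
        weights = 0.5 / d[nz]
        grad -= (dD[nz].T * weights) @ dD[nz] / total
    return grad


def pgdm_fit(pairs: PairSets, max_iter: int = 200, step: float = 0.1,
             tol: float = 1e-6) -> tuple[MetricMatrix, list[float]]:
    """Fit M by projected gradient descent on g(M).

    Starts from the identity; each iteration takes a gradient step, then
    projects back to the PSD cone. The step size is halved whenever a proposal
    would increase the loss, so the accepted-loss trace is non-increasing.
    After convergence M is rescaled (a positive scalar) so the different-class
    distance sum meets the >= 1 constraint.

    Returns (metric, loss trace).
    """
    if not pairs.D:
        raise ValueError("D must be non-empty to fit a metric")
    d = pairs.features.shape[1]
    M = np.eye(d)
    dS, dD = pairs.diffs("S"), pairs.diffs("D")
    trace = [pgdm_loss(M, pairs)] if max_iter > 0 else []
    for _ in range(max_iter):
        grad = _pgdm_grad(M, dS, dD)
        accepted = False
        while step > 1e-14:
            cand = psd_project(M - step * grad).M
            # exact line search along the scale direction: g(cM) is minimized
            # at c* = 1 / (2 sum_S d_M^2), which rebalances the two terms
            A = _dists_sq(cand, dS).sum()
            if A > 0:
                scaled = cand / (2.0 * A)
                try:
                    if pgdm_loss(scaled, pairs) < pgdm_loss(cand, pairs):
                        cand = scaled
                except ValueError:
                    pass
            try:
                cand_loss = pgdm_loss(cand, pairs)
            except ValueError:
                cand_loss = np.inf
            if not np.isfinite(cand_loss):
                step *= 0.5
                continue
            if cand_loss <= trace[-1] + 1e-15:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        rel_change = abs(trace[-1] - cand_loss) / max(abs(trace[-1]), 1.0)
        M = cand
        trace.append(cand_loss)
        step *= 1.1
        if rel_change < tol:
            break

    metric = psd_project(M)
    d_sum = np.sqrt(_dists_sq(metric.M, dD)).sum()
    if 0 < d_sum < 1.0:
        metric = psd_project(metric.M / d_sum**2)
    return metric, trace
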