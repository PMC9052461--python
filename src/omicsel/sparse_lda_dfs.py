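"""Discriminative feature selection via row-sparse regularized LDA.

A projection W (one column per discriminant direction, #classes - 1 of
them) is fit by minimizing

    trace(W' (Sw + eps I) W) + reg * ||W||_{2,p}^p      s.t.  W' Sb W = I,

where Sw and Sb are the within- and between-class scatter matrices and
||W||_{2,p}^p = sum_i ||w_i||_2^p penalizes entire rows, driving the
rows of uninformative features toward zero.  The l2,p term (0 < p <= 2)
is handled by iteratively reweighted least squares: with the diagonal
reweighting D fixed, the constrained quadratic is a generalized
eigenproblem; D is then refreshed from the new row norms.  The smoothed
objective is non-increasing across iterations.  Features are ranked by
descending row norm ||w_i||_2 — all features are scored at once, there
is no greedy loop.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .data_model import (ClassLabels, CriterionParams, Method, OmicsMatrix,
                         SelectionResult, StepTrace)

__all__ = ["ScatterPair", "scatter_matrices", "dfs_rank"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScatterPair:
    """Between- and within-class scatter; Sb + Sw = total scatter."""

    Sb: np.ndarray
    Sw: np.ndarray
    class_sizes: tuple[int, ...]


def scatter_matrices(data: OmicsMatrix, labels: ClassLabels) -> ScatterPair:
    """Standard scatter matrices about the class means.

    Sb = sum_c n_c (m_c - m)(m_c - m)';  Sw = sum_c sum_{x in c} (x - m_c)(x - m_c)'.
    Sb has rank at most #classes - 1.
    """
    if list(data.sample_ids) != list(labels.sample_ids):
        raise ValueError("data and labels must be aligned on samples")
    X = data.values  # d x n
    y = labels.codes()
    counts = np.bincount(y, minlength=labels.n_classes)
    if (counts == 0).any():
        empty = [labels.class_names[c] for c in np.flatnonzero(counts == 0)]
        raise ValueError(f"classes with no samples: {empty}")
    grand = X.mean(axis=1, keepdims=True)
    d = X.shape[0]
    Sb = np.zeros((d, d))
    Sw = np.zeros((d, d))
    for c in range(labels.n_classes):
        grp = X[:, y == c]
        mc = grp.mean(axis=1, keepdims=True)
        diff = mc - grand
        Sb += counts[c] * (diff @ diff.T)
        centered = grp - mc
        Sw += centered @ centered.T
    return ScatterPair(Sb=Sb, Sw=Sw, class_sizes=tuple(int(c) for c in counts))


def _objective(W: np.ndarray, Sw_eps: np.ndarray, reg: float, p: float,
               delta: float) -> float:
    row_sq = (W ** 2).sum(axis=1)
    return float(np.trace(W.T @ Sw_eps @ W)
                 + reg * ((row_sq + delta) ** (p / 2)).sum())


def dfs_rank(data: OmicsMatrix, labels: ClassLabels,
             params: CriterionParams | None = None,
             *, eps: float = 1e-8, delta: float = 1e-8,
             tol: float = 1e-6, max_iter: int = 50) -> SelectionResult:
    """Rank features by the row norms of the sparse LDA projection.

    ``params.dfs_p`` is the sparsity exponent (0 < p <= 2; p = 2 is the
    smooth ridge case that converges in one step), ``params.dfs_reg``
    the regularization weight.  If the relative objective decrease has
    not fallen below ``tol`` after ``max_iter`` IRLS sweeps the best
    iterate is returned with ``converged=False``.
    """
    params = params or CriterionParams()
    if params.dfs_reg <= 0:
        raise ValueError("dfs_reg must be positive")
    p, reg = params.dfs_p, params.dfs_reg

    pair = scatter_matrices(data, labels)
    d = data.n_features
    m = labels.n_classes - 1
    Sw_eps = pair.Sw + (eps * max(np.trace(pair.Sw) / d, 1.0)) * np.eye(d)

    sb_scale = np.linalg.norm(pair.Sb)
    if sb_scale == 0:
        log.warning("between-class scatter is zero; ranking is arbitrary")
        row_norms = np.zeros(d)
        converged = True
    else:
        W = np.zeros((d, m))
        D = np.ones(d)
        obj_prev = np.inf
        converged = False
        for it in range(max_iter):
            A = Sw_eps + reg * np.diag(D)
            evals, evecs = scipy.linalg.eigh(pair.Sb, A)
            # top m generalized eigenpairs; rescale to satisfy W'SbW = I
            order = np.argsort(evals)[::-1][:m]
            lam = evals[order]
            V = evecs[:, order]
            good = lam > 1e-12 * max(lam.max(), 1.0)
            W = V[:, good] / np.sqrt(lam[good])
            obj = _objective(W, Sw_eps, reg, p, delta)
            if obj_prev - obj <= tol * max(abs(obj_prev), 1.0):
                converged = True
                break
            obj_prev = obj
            row_sq = (W ** 2).sum(axis=1)
            D = (p / 2.0) * (row_sq + delta) ** ((p - 2.0) / 2.0)
        if not converged:
            log.warning("DFS did not converge in %d iterations", max_iter)
        row_norms = np.sqrt((W ** 2).sum(axis=1))

    # descending row norm, ties toward the lower original index
    order = np.lexsort((np.arange(d), -row_norms))
    k = min(params.k, d)
    top = order[:k]
    trace = tuple(StepTrace(feature_id=data.feature_ids[i],
                            relevance=float(row_norms[i]),
                            redundancy=0.0,
                            score=float(row_norms[i])) for i in top)
    return SelectionResult(method=Method.DFS, params=params,
                           selected=tuple(data.feature_ids[i] for i in top),
                           trace=trace, converged=converged)


def dfs_objective_trace(data: OmicsMatrix, labels: ClassLabels,
                        params: CriterionParams | None = None,
                        *, eps: float = 1e-8, delta: float = 1e-8,
                        max_iter: int = 30) -> np.ndarray:
    """Objective value after each IRLS sweep (diagnostic; used to verify
    the monotone-descent property of the solver)."""
    params = params or CriterionParams()
    p, reg = params.dfs_p, params.dfs_reg
    pair = scatter_matrices(data, labels)
    d = data.n_features
    m = labels.n_classes - 1
    Sw_eps = pair.Sw + (eps * max(np.trace(pair.Sw) / d, 1.0)) * np.eye(d)
    if np.linalg.norm(pair.Sb) == 0:
        return np.array([])
    D = np.ones(d)
    objs = []
    for _ in range(max_iter):
        A = Sw_eps + reg * np.diag(D)
        evals, evecs = scipy.linalg.eigh(pair.Sb, A)
        order = np.argsort(evals)[::-1][:m]
        lam = evals[order]
        V = evecs[:, order]
        good = lam > 1e-12 * max(lam.max(), 1.0)
        W = V[:, good] / np.sqrt(lam[good])
        objs.append(_objective(W, Sw_eps, reg, p, delta))
        row_sq = (W ** 2).sum(axis=1)
        D = (p / 2.0) * (row_sq + delta) ** ((p - 2.0) / 2.0)
    return np.array(objs)
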