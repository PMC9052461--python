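"""SVM recursive feature elimination with correlation-bias reduction.

Plain SVM-RFE trains a linear SVM, scores each surviving feature by its
squared weight (summed over the one-vs-rest models in the multiclass
case), and discards the lowest-scoring batch each round.  When a group
of features is highly correlated the group shares its weight mass, so
every member looks individually weak and the whole group can be flushed
out early.  The correlation-bias-reduction (CBR) rule counters this: a
feature marked for elimination is deferred to a later round when its
absolute Pearson correlation with any *unmarked* survivor reaches
``cbr_tau`` — unless deferral would empty the batch, in which case the
single lowest-scoring marked feature is eliminated to guarantee
progress.  Ranking is survivors first (by final score), then reverse
elimination order.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.svm import LinearSVC

from .data_model import (ClassLabels, CriterionParams, Method, OmicsMatrix,
                         SelectionResult, StepTrace)

__all__ = ["EliminationRound", "EliminationTrace", "svm_rfe_cbr_rank"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EliminationRound:
    surviving: tuple[str, ...]
    scores: tuple[float, ...]
    eliminated: tuple[str, ...]
    deferred: tuple[str, ...]


@dataclass(frozen=True)
class EliminationTrace:
    rounds: tuple[EliminationRound, ...]

    def all_eliminated(self) -> tuple[str, ...]:
        out: list[str] = []
        for r in self.rounds:
            out.extend(r.eliminated)
        return tuple(out)


def _svm_scores(X: np.ndarray, y: np.ndarray, C: float, seed: int) -> np.ndarray:
    """Per-feature sum of squared weights over the one-vs-rest models.

    Features are standardized within the call so weight magnitudes stay
    comparable across rounds.
    """
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    clf = LinearSVC(C=C, loss="squared_hinge", multi_class="ovr",
                    random_state=seed, max_iter=20000, tol=1e-5)
    clf.fit(Xs, y)
    w = np.atleast_2d(clf.coef_)
    return (w ** 2).sum(axis=0)


def svm_rfe_cbr_rank(data: OmicsMatrix, labels: ClassLabels,
                     params: CriterionParams | None = None,
                     *, C: float = 1.0, seed: int = 0,
                     return_trace: bool = False):
    """Backward-elimination ranking with the CBR deferral rule.

    ``params.rfe_step`` features (default: ceil(10% of survivors)) are
    marked for elimination each round; the CBR rule may defer marked
    features that are strongly correlated (|r| >= ``params.cbr_tau``)
    with unmarked survivors.  Elimination stops when ``params.k``
    features survive.  With ``cbr_tau = 1.0`` the rule never fires and
    the procedure is textbook SVM-RFE.
    """
    params = params or CriterionParams()
    if list(data.sample_ids) != list(labels.sample_ids):
        raise ValueError("data and labels must be aligned on samples")
    if labels.n_classes < 2:
        raise ValueError("need at least 2 classes")
    y = labels.codes()
    d = data.n_features
    k = min(params.k, d)

    alive = list(range(d))
    rounds: list[EliminationRound] = []
    eliminated_order: list[int] = []   # chronological
    X_full = data.values.T             # samples x features
    final_scores = np.zeros(d)

    it = 0
    while len(alive) > k:
        it += 1
        Xa = X_full[:, alive]
        try:
            scores = _svm_scores(Xa, y, C, seed)
        except Exception as exc:
            raise RuntimeError(f"SVM training failed at elimination round {it} "
                               f"({len(alive)} survivors): {exc}") from exc
        for local, g in enumerate(alive):
            final_scores[g] = scores[local]

        step = params.rfe_step or max(1, math.ceil(0.1 * len(alive)))
        step = min(step, len(alive) - k)
        order = np.lexsort((np.arange(len(alive)), scores))  # ascending, tie: low idx
        marked = list(order[:step])
        unmarked = np.array([i for i in range(len(alive)) if i not in set(marked)],
                            dtype=int)

        deferred: list[int] = []
        to_kill: list[int] = []
        if params.cbr_tau < 1.0 and unmarked.size:
            # |Pearson r| between marked features and unmarked survivors
            corr = np.abs(np.corrcoef(Xa, rowvar=False))
            for m_ in marked:
                if np.nanmax(corr[m_, unmarked]) >= params.cbr_tau:
                    deferred.append(m_)
                else:
                    to_kill.append(m_)
        else:
            to_kill = marked
        if not to_kill:
            # deferral must not stall the loop: drop the weakest marked feature
            weakest = marked[0]
            deferred.remove(weakest)
            to_kill = [weakest]

        kill_global = [alive[i] for i in to_kill]
        # within a round, eliminate weaker features "earlier": ascending score
        kill_global.sort(key=lambda g: (final_scores[g],
                                        g))
        rounds.append(EliminationRound(
            surviving=tuple(data.feature_ids[g] for g in alive),
            scores=tuple(float(s) for s in scores),
            eliminated=tuple(data.feature_ids[g] for g in kill_global),
            deferred=tuple(data.feature_ids[alive[i]] for i in deferred)))
        eliminated_order.extend(kill_global)
        kill_set = set(kill_global)
        alive = [g for g in alive if g not in kill_set]

    if alive and len(alive) <= X_full.shape[1]:
        # final scores on the surviving set
        try:
            scores = _svm_scores(X_full[:, alive], y, C, seed)
            for local, g in enumerate(alive):
                final_scores[g] = scores[local]
        except Exception as exc:
            raise RuntimeError(f"SVM training failed on final survivor set: {exc}") from exc

    # survivors by descending final score (tie: low index), then reverse
    # elimination order
    survivors = sorted(alive, key=lambda g: (-final_scores[g], g))
    ranking = survivors + list(reversed(eliminated_order))
    top = ranking[:k]
    trace = tuple(StepTrace(feature_id=data.feature_ids[g],
                            relevance=float(final_scores[g]),
                            redundancy=0.0,
                            score=float(final_scores[g])) for g in top)
    result = SelectionResult(method=Method.SVM_RFE_CBR, params=params,
                             selected=tuple(data.feature_ids[g] for g in top),
                             trace=trace)
    if return_trace:
        return result, EliminationTrace(tuple(rounds))
    return result
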