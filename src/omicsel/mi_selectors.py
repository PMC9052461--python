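"""Greedy forward feature selection over incremental MI criteria.

Six criteria share one greedy loop: at each step the candidate feature
maximizing ``relevance - redundancy`` is appended to the selected set S.
Relevance is the (normalized, for INMIFS/VWMRmR) mutual information with
the class; redundancy aggregates pairwise (N)MI with the members of S:

    MIFS     I(f;C) - beta * sum_s I(f_s;f)
    MIFS-U   I(f;C) - beta * sum_s [I(f_s;C)/H(f_s)] * I(f;f_s)
    mRMR     I(f;C) - (1/|S|) * sum_s I(f;f_s)
    NMIFS    I(f;C) - (1/|S|) * sum_s NMI(f;f_s)
    INMIFS   NMI(C;f) - (1/|S|) * sum_s NMI(f_s;f)
    VWMRmR   NMI(C;f) - (1 + w|S|/k) * (1/|S|) * sum_s NMI(f;f_s)

With S empty every criterion reduces to its relevance term.  Pairwise
values are computed once per selected feature and cached; ties at the
argmax break toward the lowest original feature index.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_model import (ClassLabels, CriterionParams, DiscretizedMatrix,
                         Method, SelectionResult, StepTrace)
from .infotheory import entropy, mutual_information, normalized_mi

__all__ = ["SelectionState", "new_state", "score_candidate", "greedy_select"]

log = logging.getLogger(__name__)

_MI_METHODS = (Method.MIFS, Method.MIFS_U, Method.MRMR, Method.NMIFS,
               Method.INMIFS, Method.VWMRMR)
_NORMALIZED_RELEVANCE = (Method.INMIFS, Method.VWMRMR)


@dataclass
class SelectionState:
    """Incremental caches for one greedy run.

    ``pair_mi`` / ``pair_nmi`` hold, for each already-selected feature,
    its (N)MI against every feature; redundancy running sums are updated
    when a feature enters S.
    """

    states: np.ndarray                 # d x n discretized data
    y: np.ndarray                      # class codes
    feature_ids: tuple[str, ...]
    relevance: np.ndarray              # I or NMI with the class, per method
    h_feature: np.ndarray              # H(f) per feature
    rel_raw: np.ndarray                # raw I(f;C) (MIFS-U weighting)
    selected: list[int] = field(default_factory=list)
    sum_mi: np.ndarray | None = None         # sum_s I(f_s; .)
    sum_nmi: np.ndarray | None = None        # sum_s NMI(f_s; .)
    sum_weighted: np.ndarray | None = None   # sum_s [I(f_s;C)/H(f_s)] I(f_s; .)
    pair_mi: dict[int, np.ndarray] = field(default_factory=dict)
    pair_nmi: dict[int, np.ndarray] = field(default_factory=dict)

    def index_of(self, feature_id: str) -> int:
        return self.feature_ids.index(feature_id)


def _needs_nmi(method: Method) -> bool:
    return method in (Method.NMIFS, Method.INMIFS, Method.VWMRMR)


def new_state(method: Method, data: DiscretizedMatrix,
              labels: ClassLabels) -> SelectionState:
    """Precompute class relevance and per-feature entropies."""
    if list(data.sample_ids) != list(labels.sample_ids):
        raise ValueError("data and labels must be aligned on samples")
    y = labels.codes()
    S = data.states
    d = S.shape[0]
    rel_raw = np.array([mutual_information(S[i], y) for i in range(d)])
    h = np.array([entropy(S[i]) for i in range(d)])
    if method in _NORMALIZED_RELEVANCE:
        rel = np.array([normalized_mi(S[i], y) for i in range(d)])
    else:
        rel = rel_raw
    st = SelectionState(states=S, y=y, feature_ids=data.feature_ids,
                        relevance=rel, h_feature=h, rel_raw=rel_raw)
    st.sum_mi = np.zeros(d)
    st.sum_nmi = np.zeros(d)
    st.sum_weighted = np.zeros(d)
    return st


def _pairwise_rows(state: SelectionState, s: int) -> tuple[np.ndarray, np.ndarray]:
    """(N)MI of selected feature s against every feature, cached."""
    if s not in state.pair_mi:
        d = state.states.shape[0]
        row_mi = np.empty(d)
        row_nmi = np.empty(d)
        for j in range(d):
            row_mi[j] = mutual_information(state.states[s], state.states[j])
            row_nmi[j] = normalized_mi(state.states[s], state.states[j])
        state.pair_mi[s] = row_mi
        state.pair_nmi[s] = row_nmi
    return state.pair_mi[s], state.pair_nmi[s]


def _redundancy(method: Method, state: SelectionState,
                params: CriterionParams) -> np.ndarray:
    """Redundancy term of the criterion, vectorized over candidates."""
    m = len(state.selected)
    d = state.states.shape[0]
    if m == 0:
        return np.zeros(d)
    if method is Method.MIFS:
        return params.beta * state.sum_mi
    if method is Method.MIFS_U:
        return params.beta * state.sum_weighted
    if method is Method.MRMR:
        return state.sum_mi / m
    if method is Method.NMIFS:
        return state.sum_nmi / m
    if method is Method.INMIFS:
        return state.sum_nmi / m
    if method is Method.VWMRMR:
        return (1.0 + params.w * m / params.k) * state.sum_nmi / m
    raise ValueError(f"{method} is not an incremental MI criterion")


def score_candidate(method: Method, feature_id: str, state: SelectionState,
                    params: CriterionParams) -> float:
    """Criterion value for one candidate given the current selected set."""
    i = state.index_of(feature_id)
    if i in state.selected:
        raise ValueError(f"{feature_id!r} is already selected")
    red = _redundancy(method, state, params)
    return float(state.relevance[i] - red[i])


def _advance(state: SelectionState, pick: int) -> None:
    """Add feature ``pick`` to S and fold its pairwise rows into the sums."""
    row_mi, row_nmi = _pairwise_rows(state, pick)
    state.sum_mi += row_mi
    state.sum_nmi += row_nmi
    h = state.h_feature[pick]
    if h > 0:
        state.sum_weighted += (state.rel_raw[pick] / h) * row_mi
    else:
        log.warning("MIFS-U weighting skipped for constant feature %r",
                    state.feature_ids[pick])
    state.selected.append(pick)


def greedy_select(method: Method, data: DiscretizedMatrix, labels: ClassLabels,
                  params: CriterionParams | None = None) -> SelectionResult:
    """Run the greedy forward loop for ``method`` until k features are chosen.

    Step 1 picks the argmax of relevance alone; each later step the argmax
    of the full criterion over the remaining features.  Ties break toward
    the lowest original feature index (``np.argmax`` convention).
    """
    method = Method(method)
    if method not in _MI_METHODS:
        raise ValueError(f"{method.value} is not a greedy MI criterion")
    params = params or CriterionParams()
    d = data.n_features
    if d == 0:
        raise ValueError("empty feature set")
    k = min(params.k, d)

    state = new_state(method, data, labels)
    trace: list[StepTrace] = []
    for _ in range(k):
        red = _redundancy(method, state, params)
        total = state.relevance - red
        total[state.selected] = -np.inf
        pick = int(np.argmax(total))
        trace.append(StepTrace(feature_id=data.feature_ids[pick],
                               relevance=float(state.relevance[pick]),
                               redundancy=float(red[pick]),
                               score=float(total[pick])))
        _advance(state, pick)

    selected = tuple(data.feature_ids[i] for i in state.selected)
    return SelectionResult(method=method, params=params,
                           selected=selected, trace=tuple(trace))
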