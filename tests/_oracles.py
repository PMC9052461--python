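"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own information-theory and
selection code paths: probabilities come from explicit contingency-table
enumeration with ``collections.Counter`` and criteria are re-evaluated
from scratch at every greedy step.
"""
from __future__ import annotations

import math
from collections import Counter


def oracle_entropy(x) -> float:
    n = len(x)
    return -sum((c / n) * math.log2(c / n) for c in Counter(x).values())


def oracle_joint_entropy(x, y) -> float:
    n = len(x)
    return -sum((c / n) * math.log2(c / n)
                for c in Counter(zip(x, y)).values())


def oracle_mi(x, y) -> float:
    """sum_{a,b} p(a,b) log2[ p(a,b) / (p(a) p(b)) ]"""
    n = len(x)
    px = {a: c / n for a, c in Counter(x).items()}
    py = {b: c / n for b, c in Counter(y).items()}
    mi = 0.0
    for (a, b), c in Counter(zip(x, y)).items():
        p = c / n
        mi += p * math.log2(p / (px[a] * py[b]))
    return max(mi, 0.0)


def oracle_nmi(x, y) -> float:
    denom = min(oracle_entropy(x), oracle_entropy(y))
    if denom == 0:
        return 0.0
    return oracle_mi(x, y) / denom


def oracle_criterion(method: str, i: int, selected: list[int], states, y,
                     beta: float, w: float, k: int) -> float:
    """Re-evaluate one greedy criterion from raw contingency counts."""
    rows = [list(r) for r in states]
    yy = list(y)
    if method in ("INMIFS", "VWMRmR"):
        rel = oracle_nmi(rows[i], yy)
    else:
        rel = oracle_mi(rows[i], yy)
    if not selected:
        return rel
    m = len(selected)
    if method == "MIFS":
        red = beta * sum(oracle_mi(rows[s], rows[i]) for s in selected)
    elif method == "MIFS-U":
        red = 0.0
        for s in selected:
            h = oracle_entropy(rows[s])
            if h > 0:
                red += (oracle_mi(rows[s], yy) / h) * oracle_mi(rows[i], rows[s])
        red *= beta
    elif method == "mRMR":
        red = sum(oracle_mi(rows[i], rows[s]) for s in selected) / m
    elif method == "NMIFS":
        red = sum(oracle_nmi(rows[i], rows[s]) for s in selected) / m
    elif method == "INMIFS":
        red = sum(oracle_nmi(rows[s], rows[i]) for s in selected) / m
    elif method == "VWMRmR":
        red = (1 + w * m / k) * sum(oracle_nmi(rows[i], rows[s])
                                    for s in selected) / m
    else:
        raise ValueError(method)
    return rel - red


def oracle_step_scores(method: str, selected: list[int], states, y,
                       beta: float, w: float, k: int) -> dict[int, float]:
    """Criterion value of every remaining candidate at the current step."""
    d = len(states)
    return {i: oracle_criterion(method, i, selected, states, y, beta, w, k)
            for i in range(d) if i not in selected}
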