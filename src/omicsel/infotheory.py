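"""Plug-in information measures on discrete vectors, in bits.

Maximum-likelihood (plug-in) estimation with no smoothing or bias
correction: probabilities are relative frequencies of the observed
states.  All logarithms are base 2 — the representation-entropy scale
reported downstream is only consistent with base-2 entropies.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "JointCounts",
    "joint_counts",
    "entropy",
    "mutual_information",
    "normalized_mi",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class JointCounts:
    """Contingency table of two discrete vectors."""

    states_x: tuple
    states_y: tuple
    counts: np.ndarray
    n: int


def joint_counts(x, y) -> JointCounts:
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    sx, ix = np.unique(x, return_inverse=True)
    sy, iy = np.unique(y, return_inverse=True)
    counts = np.zeros((sx.size, sy.size), dtype=np.int64)
    np.add.at(counts, (ix, iy), 1)
    return JointCounts(tuple(sx.tolist()), tuple(sy.tolist()), counts, x.size)


def _entropy_from_counts(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def entropy(x) -> float:
    """Shannon entropy H(x) in bits over the observed states."""
    x = np.asarray(x)
    if x.size == 0:
        raise ValueError("entropy of an empty vector is undefined")
    _, counts = np.unique(x, return_counts=True)
    return _entropy_from_counts(counts, x.size)


def mutual_information(x, y) -> float:
    """I(x;y) = H(x) + H(y) - H(x,y) in bits, clamped at 0.

    The plug-in estimate can dip a rounding error below zero; anything
    above -1e-9 is clamped to exactly 0.
    """
    jc = joint_counts(x, y)
    hx = _entropy_from_counts(jc.counts.sum(axis=1), jc.n)
    hy = _entropy_from_counts(jc.counts.sum(axis=0), jc.n)
    hxy = _entropy_from_counts(jc.counts.ravel(), jc.n)
    mi = hx + hy - hxy
    return max(mi, 0.0)


def normalized_mi(x, y) -> float:
    """I(x;y) / min(H(x), H(y)), in [0, 1]; 0 when either entropy is 0.

    A constant vector carries no information, so the 0/0 case is defined
    as 0 by convention.
    """
    jc = joint_counts(x, y)
    hx = _entropy_from_counts(jc.counts.sum(axis=1), jc.n)
    hy = _entropy_from_counts(jc.counts.sum(axis=0), jc.n)
    denom = min(hx, hy)
    if denom == 0.0:
        log.debug("normalized_mi: zero-entropy input, returning 0 by convention")
        return 0.0
    hxy = _entropy_from_counts(jc.counts.ravel(), jc.n)
    nmi = (hx + hy - hxy) / denom
    return float(min(max(nmi, 0.0), 1.0))
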