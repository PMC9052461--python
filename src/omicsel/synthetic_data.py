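"""Seeded generator of multi-omics-like datasets with planted ground truth.

The generator emulates the shape of a z-scale omics profile with three
imbalanced outcome classes: a minority of class-informative features
(Gaussian, per-class mean shifts in within-class sigma units), groups of
redundant features (noisy copies of informative parents tuned to a
target Pearson correlation), and class-independent noise features
(Gaussian, or heavy-tailed Student t to stress discretization).  The
planted informative/redundant/noise partition is returned so selectors
can be scored by recovery.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ClassLabels, OmicsMatrix

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "recovery_count"]


@dataclass(frozen=True)
class GroundTruth:
    """Planted partition of the generated features."""

    informative_ids: tuple[str, ...]
    redundant_ids: tuple[str, ...]
    parent_of: dict  # redundant id -> informative parent id
    noise_ids: tuple[str, ...]

    def write(self, path) -> None:
        rows = ([{"feature_id": f, "role": "informative", "parent": ""}
                 for f in self.informative_ids]
                + [{"feature_id": f, "role": "redundant",
                    "parent": self.parent_of[f]} for f in self.redundant_ids]
                + [{"feature_id": f, "role": "noise", "parent": ""}
                   for f in self.noise_ids])
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; defaults mirror the benchmark's data scale.

    161 samples in three imbalanced classes (31/96/34: favorable,
    intermediate, poor), on the order of a thousand continuous features
    of which a minority carry class signal.  ``effect_size`` is the
    class-mean shift in within-class sigma units; ``redundancy_r`` the
    target correlation between a redundant copy and its parent.
    """

    class_sizes: tuple[int, ...] = (31, 96, 34)
    class_names: tuple[str, ...] = ("favorable", "intermediate", "poor")
    n_informative: int = 60
    n_redundant: int = 120
    n_noise: int = 800
    effect_size: float = 1.0
    redundancy_r: float = 0.8
    heavy_tail: bool = False
    noise_df: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_sizes) != len(self.class_names):
            raise ValueError("one class name per class size")
        if len(self.class_sizes) < 2 or any(c < 1 for c in self.class_sizes):
            raise ValueError("need >= 2 classes with >= 1 sample each")
        if not (0 <= self.redundancy_r < 1):
            raise ValueError("redundancy_r must lie in [0, 1)")
        if min(self.n_informative, self.n_redundant, self.n_noise) < 0:
            raise ValueError("feature counts must be non-negative")
        if self.n_redundant > 0 and self.n_informative == 0:
            raise ValueError("redundant copies need informative parents")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(sum(self.class_sizes))

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise


def generate(spec: SyntheticSpec) -> tuple[OmicsMatrix, ClassLabels, GroundTruth]:
    """Draw one dataset; bit-identical for a given spec (seed included)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    n_classes = len(spec.class_sizes)
    y = np.repeat(np.arange(n_classes), spec.class_sizes)

    inf_ids = tuple(f"INF{i + 1:04d}" for i in range(spec.n_informative))
    red_ids = tuple(f"RED{i + 1:04d}" for i in range(spec.n_redundant))
    nse_ids = tuple(f"NSE{i + 1:04d}" for i in range(spec.n_noise))

    blocks = []
    # informative: unit-variance Gaussian noise + one-vs-rest mean pattern;
    # each feature elevates one class, drawn under the seed, and the shift
    # is centered so the feature stays zero-mean overall
    informative = rng.standard_normal((spec.n_informative, n))
    up_class = rng.integers(0, n_classes, size=spec.n_informative)
    for i in range(spec.n_informative):
        shift = np.where(y == up_class[i], spec.effect_size, 0.0)
        informative[i] += shift - shift.mean()
    blocks.append(informative)

    # redundant: r * standardized parent + sqrt(1 - r^2) * fresh noise
    parent_of: dict[str, str] = {}
    if spec.n_redundant:
        r = spec.redundancy_r
        parents = rng.integers(0, spec.n_informative, size=spec.n_redundant)
        redundant = np.empty((spec.n_redundant, n))
        for j in range(spec.n_redundant):
            p = informative[parents[j]]
            p_std = (p - p.mean()) / p.std()
            redundant[j] = r * p_std + np.sqrt(1 - r * r) * rng.standard_normal(n)
            parent_of[red_ids[j]] = inf_ids[parents[j]]
        blocks.append(redundant)

    if spec.n_noise:
        if spec.heavy_tail:
            noise = rng.standard_t(spec.noise_df, size=(spec.n_noise, n))
        else:
            noise = rng.standard_normal((spec.n_noise, n))
        blocks.append(noise)

    values = np.vstack(blocks) if blocks else np.empty((0, n))
    feature_ids = inf_ids + red_ids + nse_ids
    sample_ids = tuple(f"S{i + 1:04d}" for i in range(n))
    labels = ClassLabels(sample_ids,
                         tuple(spec.class_names[c] for c in y),
                         spec.class_names)
    matrix = OmicsMatrix(feature_ids, sample_ids, values)
    truth = GroundTruth(informative_ids=inf_ids, redundant_ids=red_ids,
                        parent_of=parent_of, noise_ids=nse_ids)
    return matrix, labels, truth


def recovery_count(selected, truth: GroundTruth) -> int:
    """Number of distinct planted informative features represented in a
    selected list; a redundant copy credits its parent."""
    hit = set()
    informative = set(truth.informative_ids)
    for f in selected:
        if f in informative:
            hit.add(f)
        elif f in truth.parent_of:
            hit.add(truth.parent_of[f])
    return len(hit)
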