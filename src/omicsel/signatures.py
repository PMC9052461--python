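"""Cross-method signature intersection and Venn-region counting.

The signature of a dataset is the strict intersection of the top-k
feature lists produced by the different selection methods; the full
2^m - 1 Venn region counts are reported alongside for overlap audits.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .data_model import SelectionResult

__all__ = ["SignatureSet", "intersect_signatures"]


@dataclass(frozen=True)
class SignatureSet:
    dataset_name: str
    methods: tuple[str, ...]
    #: region key = tuple of method names containing the feature (sorted by
    #: ``methods`` order); value = count of features exactly in that region
    region_counts: dict
    #: feature -> tuple of containing methods
    membership: dict
    core: tuple[str, ...]
    majority: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"feature_id": f,
                 "n_methods": len(ms),
                 "region": "&".join(ms)}
                for f, ms in sorted(self.membership.items())]
        return pd.DataFrame(rows, columns=["feature_id", "n_methods", "region"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def intersect_signatures(results: Sequence[SelectionResult],
                         dataset_name: str = "",
                         feature_universe: Iterable[str] | None = None
                         ) -> SignatureSet:
    """Intersect the selected lists of >= 2 methods over one feature universe.

    ``core`` is the strict all-method intersection (the signature);
    ``majority`` (features in more than half the lists) is provided as an
    optional softer notion but is not the default signature.  If
    ``feature_universe`` is given, any selected feature outside it is an
    error — lists from different universes must not be intersected.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 selection results to intersect")
    methods = tuple(r.method.value for r in results)
    if len(set(methods)) != len(methods):
        raise ValueError(f"duplicate methods in results: {methods}")
    if feature_universe is not None:
        universe = set(feature_universe)
        for r in results:
            stray = set(r.selected) - universe
            if stray:
                raise ValueError(
                    f"{r.method.value} selected features outside the shared "
                    f"universe: {sorted(stray)[:5]}")

    lists = {m: set(r.selected) for m, r in zip(methods, results)}
    union = set().union(*lists.values())
    membership = {f: tuple(m for m in methods if f in lists[m]) for f in union}
    region_counts: dict = {}
    for ms in membership.values():
        region_counts[ms] = region_counts.get(ms, 0) + 1
    core = tuple(sorted(f for f, ms in membership.items() if len(ms) == len(methods)))
    majority = tuple(sorted(f for f, ms in membership.items()
                            if len(ms) > len(methods) / 2))
    return SignatureSet(dataset_name=dataset_name, methods=methods,
                        region_counts=region_counts, membership=membership,
                        core=core, majority=majority)
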