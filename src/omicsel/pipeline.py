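"""End-to-end driver: align -> normalize -> filter -> discretize ->
select (all methods) -> evaluate -> intersect signatures -> report.

Each omics profile is processed independently.  The discretized matrix
feeds the MI-family selectors and RR(nmi) only; the continuous
normalized matrix feeds DFS, SVM-RFE-CBR, the classifiers, RR(pearson)
and the representation entropy.  Any stage failure is surfaced with the
stage name — no partial silent results.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .data_model import (ClassLabels, CriterionParams, Method, OmicsMatrix,
                         SelectionResult, align, write_labels, write_matrix)
from .evaluation import (CLASSIFIERS, DEFAULT_GRIDS, cv_accuracy,
                         redundancy_rate, representation_entropy)
from .mi_selectors import greedy_select
from .preprocess import (differential_filter, discretize,
                         drop_constant_features, zscore_normalize)
from .signatures import SignatureSet, intersect_signatures
from .sparse_lda_dfs import dfs_rank
from .svm_rfe_cbr import svm_rfe_cbr_rank
from .synthetic_data import SyntheticSpec, generate, recovery_count

__all__ = ["PipelineConfig", "PipelineStageError", "select_features",
           "run_pipeline"]

log = logging.getLogger(__name__)

DEFAULT_METHODS = tuple(m.value for m in Method.compared())


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; serialized into the report."""

    matrix_path: str | None = None
    labels_path: str | None = None
    synthetic: SyntheticSpec | None = None
    dataset_name: str = "dataset"
    alpha: float = 0.05
    prior_df: float = 0.0
    methods: tuple[str, ...] = DEFAULT_METHODS
    classifiers: tuple[str, ...] = CLASSIFIERS
    folds: int = 10
    repeats: int = 10
    seed: int = 0
    tune: bool = False
    params: CriterionParams = field(default_factory=CriterionParams)
    outdir: str | None = None

    def __post_init__(self) -> None:
        known = {m.value for m in Method}
        unknown = [m for m in self.methods if m not in known]
        if unknown:
            raise ValueError(f"unsupported methods: {unknown}")
        if self.params.k < 1:
            raise ValueError("k must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.matrix_path is None and self.synthetic is None:
            raise ValueError("either input paths or a synthetic spec is required")


def select_features(method: Method | str, normalized: OmicsMatrix,
                    discretized, labels: ClassLabels,
                    params: CriterionParams, seed: int = 0) -> SelectionResult:
    """Dispatch one method to its representation: MI criteria consume the
    discretized matrix; DFS and SVM-RFE-CBR the continuous one."""
    method = Method.from_string(method) if isinstance(method, str) else method
    if method is Method.DFS:
        return dfs_rank(normalized, labels, params)
    if method is Method.SVM_RFE_CBR:
        return svm_rfe_cbr_rank(normalized, labels, params, seed=seed)
    return greedy_select(method, discretized, labels, params)


def _stage(name: str):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> tuple[dict, SignatureSet]:
    """Execute all stages; return (report dict, signature set).

    The report carries full parameter provenance (method parameters
    including w and beta, seeds, stage sizes) and, on synthetic input,
    planted-recovery counts per method.
    """
    from .data_model import read_labels, read_matrix  # local: optional I/O

    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    truth = None

    @_stage("load")
    def load():
        nonlocal truth
        if config.synthetic is not None:
            matrix, labels, truth = generate(config.synthetic)
        else:
            matrix = read_matrix(config.matrix_path)
            labels = read_labels(config.labels_path)
        return align(matrix, labels)

    matrix, labels = load()

    @_stage("normalize")
    def normalize():
        return zscore_normalize(drop_constant_features(matrix))

    normalized = normalize()

    @_stage("differential_filter")
    def diff():
        res = differential_filter(normalized, labels, alpha=config.alpha,
                                  prior_df=config.prior_df)
        if len(res.kept_ids) == 0:
            raise ValueError(f"no feature passed p < {config.alpha}")
        if outdir:
            res.write(outdir / "differential.tsv")
        return res

    diff_result = diff()
    filtered = normalized.subset_features(diff_result.kept_ids)

    @_stage("discretize")
    def disc():
        return discretize(filtered)

    discretized = disc()

    effective_k = min(config.params.k, filtered.n_features)
    results: list[SelectionResult] = []
    for m in config.methods:

        @_stage(f"select[{m}]")
        def run_one(m=m):
            return select_features(m, filtered, discretized, labels,
                                   config.params, seed=config.seed)

        res = run_one()
        results.append(res)
        if outdir:
            res.write(outdir / f"ranking_{m.replace('/', '_')}.tsv")

    report: dict = {
        "dataset": config.dataset_name,
        "omicsel_version": __version__,
        "config": {
            "alpha": config.alpha,
            "prior_df": config.prior_df,
            "k": effective_k,
            "methods": list(config.methods),
            "classifiers": list(config.classifiers),
            "folds": config.folds,
            "repeats": config.repeats,
            "seed": config.seed,
            "tune": config.tune,
            "params": asdict(config.params),
            "synthetic": asdict(config.synthetic) if config.synthetic else None,
        },
        "n_samples": matrix.n_samples,
        "n_features_input": matrix.n_features,
        "n_features_significant": len(diff_result.kept_ids),
        "methods": {},
    }

    for res in results:

        @_stage(f"evaluate[{res.method.value}]")
        def evaluate(res=res):
            feats = list(res.selected)
            block: dict = {"selected": feats, "converged": res.converged,
                           "accuracy": {}}
            for clf in config.classifiers:
                grid = DEFAULT_GRIDS.get(clf) if config.tune else None
                est = cv_accuracy(filtered, labels, feats, clf,
                                  folds=config.folds, repeats=config.repeats,
                                  seed=config.seed, tuning=grid)
                block["accuracy"][clf] = {"mean_pct": est.mean_pct,
                                          "std_pct": est.std_pct,
                                          "best_params": est.best_params}
            cont = filtered.subset_features(feats)
            discs = discretized.subset_features(feats)
            if len(feats) >= 2:
                block["rr_nmi"] = redundancy_rate(discs, sim="nmi")
                block["rr_pearson"] = redundancy_rate(cont, sim="pearson")
                block["representation_entropy"] = \
                    representation_entropy(cont).entropy_bits
            if truth is not None:
                block["recovery"] = recovery_count(feats, truth)
            return block

        report["methods"][res.method.value] = evaluate(res)

    signature = None
    if len(results) >= 2:

        @_stage("signatures")
        def sign():
            sig = intersect_signatures(results, dataset_name=config.dataset_name,
                                       feature_universe=filtered.feature_ids)
            if outdir:
                sig.write(outdir / "signature.tsv")
            return sig

        signature = sign()
        report["signature"] = {
            "core": list(signature.core),
            "core_size": len(signature.core),
            "majority_size": len(signature.majority),
            "region_counts": {"&".join(k): v
                              for k, v in sorted(signature.region_counts.items())},
        }
        if truth is not None:
            planted = set(truth.informative_ids)
            report["signature"]["core_equals_planted"] = \
                set(signature.core) == planted
    else:
        report["signature"] = None  # intersection needs >= 2 methods

    if outdir:
        write_matrix(filtered, outdir / "normalized_filtered.tsv")
        write_labels(labels, outdir / "labels.tsv")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report, signature
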