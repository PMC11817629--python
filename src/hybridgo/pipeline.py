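"""End-to-end convenience pipeline over the library modules.

Chains filtering → k-NN imputation → PCA → feature assembly → bootstrap ×
cross-validation on a dataset, for one classifier family and feature mode.
This is the path the examples, command line, and the package's own
calibration checks exercise; each stage is the public function from its
module, so results are identical to running the stages by hand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluate import BootstrapEval, evaluate_bootstraps
from .features import (
    FeatureTable,
    assemble_features,
    encode_knowledge,
    metabolite_corr_features,
)
from .genesets import SplitPlan, make_split_plan
from .io import OmicsMatrix, RunConfig
from .models import CVResult, ModelSpec, cross_validate
from .preprocess import PCModel, filter_matrix, knn_impute, pca_gene_features
from .synthetic import SyntheticDataset

__all__ = ["PreparedData", "prepare_data", "run_cv", "CVOutcome"]


@dataclass
class PreparedData:
    """Preprocessed inputs ready for feature assembly and training."""

    expression: OmicsMatrix  # filtered and imputed
    pcs: PCModel
    extras: pd.DataFrame  # metabolite-correlation + knowledge columns
    positives: set[str]
    universe: set[str]

    def assemble(self, n_pc: int, mode: str) -> FeatureTable:
        return assemble_features(self.pcs, n_pc, extras=self.extras, mode=mode)


def prepare_data(
    expression: OmicsMatrix,
    metabolites: OmicsMatrix | None,
    knowledge: pd.Series | None,
    positives: set[str],
    config: RunConfig | None = None,
    max_components: int | None = None,
) -> PreparedData:
    """Filter, impute, extract PCs, and build the extra feature columns.

    ``positives`` is intersected with the genes surviving the filter.  The
    number of fitted components defaults to what the largest requested
    model variant needs.
    """
    config = config or RunConfig()
    filtered, _ = filter_matrix(expression, config.max_missing)
    complete = knn_impute(filtered, config.knn_k)

    extras_blocks: list[pd.DataFrame] = []
    if metabolites is not None:
        met = metabolites
        if config.metabolites:
            met = met.subset_rows(list(config.metabolites))
        extras_blocks.append(
            metabolite_corr_features(
                complete, met, alpha=config.alpha, dof=config.spearman_dof
            )
        )
    if knowledge is not None:
        extras_blocks.append(encode_knowledge(knowledge, genes=complete.row_ids))
    if extras_blocks:
        extras = pd.concat(extras_blocks, axis=1)
    else:
        extras = pd.DataFrame(index=complete.data.index)

    if max_components is None:
        max_components = max(config.pc_counts) + extras.shape[1]
    max_components = min(max_components, min(complete.shape))
    pcs = pca_gene_features(
        complete, n_components=max_components, scale_axis=config.scale_axis
    )
    universe = set(complete.row_ids)
    return PreparedData(
        expression=complete,
        pcs=pcs,
        extras=extras,
        positives=positives & universe,
        universe=universe,
    )


def prepare_synthetic(
    dataset: SyntheticDataset,
    config: RunConfig | None = None,
    use_knowledge: bool = True,
    use_metabolites: bool = True,
    max_components: int | None = None,
) -> PreparedData:
    """Prepare a synthetic dataset's pieces for training."""
    return prepare_data(
        dataset.expression,
        dataset.metabolites if use_metabolites else None,
        dataset.knowledge if use_knowledge else None,
        set(dataset.positive_genes),
        config=config,
        max_components=max_components,
    )


@dataclass
class CVOutcome:
    """Cross-validated performance of one pipeline configuration."""

    cv: CVResult
    evaluation: BootstrapEval
    plan: SplitPlan
    features: FeatureTable

    @property
    def mean_auroc(self) -> float:
        return float(self.evaluation.mean["auroc"])


def run_cv(
    prepared: PreparedData,
    mode: str = "hybrid",
    algorithm: str = "random_forest",
    n_pc: int = 5,
    n_bootstrap: int = 20,
    n_folds: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> CVOutcome:
    """Bootstrap × k-fold cross-validation for one (algorithm, n_pc, mode)."""
    table = prepared.assemble(n_pc, mode)
    plan = make_split_plan(
        prepared.positives,
        set(table.gene_ids),
        n_bootstrap=n_bootstrap,
        n_folds=n_folds,
        master_seed=seed,
    )
    spec = ModelSpec(algorithm=algorithm, seed=seed)
    cv = cross_validate(table, plan, spec)
    evaluation = evaluate_bootstraps(cv.probs, cv.labels, threshold=threshold)
    return CVOutcome(cv=cv, evaluation=evaluation, plan=plan, features=table)
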