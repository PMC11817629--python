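"""Expression-matrix preprocessing: filtering, imputation, PCA features.

The pipeline mirrors the standard multi-omics cleanup for cell-line panels:
drop samples and then genes/metabolites with more than ``max_missing``
missing values or zero variance, impute the remainder with k-nearest
neighbours under a NaN-aware Euclidean distance, then extract per-gene
principal-component scores from the z-score normalized matrix for use as
classifier features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics.pairwise import nan_euclidean_distances

from .io import OmicsMatrix

__all__ = [
    "FilterReport",
    "FilterResult",
    "filter_matrix",
    "knn_impute",
    "PCModel",
    "pca_gene_features",
    "component_similarity",
    "subsample_robustness",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    """Identifiers removed by filtering, with the rule that removed each."""

    removed: list[tuple[str, str, str]] = field(default_factory=list)  # (id, axis, reason)

    def add(self, ident: str, axis: str, reason: str) -> None:
        self.removed.append((ident, axis, reason))

    @property
    def removed_rows(self) -> list[str]:
        return [i for i, ax, _ in self.removed if ax == "row"]

    @property
    def removed_cols(self) -> list[str]:
        return [i for i, ax, _ in self.removed if ax == "column"]


class FilterResult(NamedTuple):
    matrix: OmicsMatrix
    report: FilterReport


def filter_matrix(matrix: OmicsMatrix, max_missing: float = 0.30) -> FilterResult:
    """Drop samples, then rows, exceeding the missingness cut or with sd 0.

    Columns (samples) with a missing fraction > ``max_missing`` are removed
    first; then rows with missing fraction > ``max_missing`` or zero standard
    deviation over their observed entries.  The two passes repeat until
    nothing changes, so the operation is idempotent.
    """
    if not 0 < max_missing < 1:
        raise ValueError(f"max_missing must be in (0,1), got {max_missing}")
    frame = matrix.data
    report = FilterReport()
    while True:
        changed = False
        col_miss = frame.isna().mean(axis=0)
        bad_cols = col_miss.index[col_miss > max_missing]
        if len(bad_cols):
            for c in bad_cols:
                report.add(str(c), "column", f"missing fraction {col_miss[c]:.3f} > {max_missing}")
            frame = frame.drop(columns=bad_cols)
            changed = True
        if frame.shape[1] == 0:
            raise ValueError("matrix empty after filtering: all samples removed")
        row_miss = frame.isna().mean(axis=1)
        row_sd = frame.std(axis=1, ddof=0)  # over observed entries
        bad_missing = row_miss > max_missing
        bad_sd = (row_sd == 0) | row_sd.isna()
        for r in frame.index[bad_missing]:
            report.add(str(r), "row", f"missing fraction {row_miss[r]:.3f} > {max_missing}")
        for r in frame.index[bad_sd & ~bad_missing]:
            report.add(str(r), "row", "zero standard deviation over observed entries")
        bad_rows = frame.index[bad_missing | bad_sd]
        if len(bad_rows):
            frame = frame.drop(index=bad_rows)
            changed = True
        if frame.shape[0] == 0:
            raise ValueError("matrix empty after filtering: all rows removed")
        if not changed:
            break
    return FilterResult(OmicsMatrix(frame), report)


# ---------------------------------------------------------------------------
# k-NN imputation
# ---------------------------------------------------------------------------


def knn_impute(matrix: OmicsMatrix, k: int = 5) -> OmicsMatrix:
    """Impute missing cells from the k nearest rows under NaN-aware distance.

    Nearness is Euclidean distance over coordinates observed in both rows,
    rescaled by the fraction of usable coordinates.  Each missing cell is
    replaced by the unweighted mean of the observed values in that column
    over the k nearest rows; if none of those k rows is observed in the
    column, the column mean is used (and logged).  Observed entries are
    preserved exactly.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if matrix.is_complete:
        return OmicsMatrix(matrix.data.copy())
    X = matrix.values.copy()
    if np.isnan(X).all(axis=1).any():
        bad = [matrix.row_ids[i] for i in np.flatnonzero(np.isnan(X).all(axis=1))]
        raise ValueError(f"rows with no observed entries cannot be imputed: {bad}")
    dist = nan_euclidean_distances(X, X)
    np.fill_diagonal(dist, np.inf)
    dist[np.isnan(dist)] = np.inf  # pairs with no shared observed coordinate
    col_means = np.nanmean(X, axis=0)
    out = X.copy()
    miss_rows, miss_cols = np.nonzero(np.isnan(X))
    order_cache: dict[int, np.ndarray] = {}
    for i in set(miss_rows.tolist()):
        order_cache[i] = np.argsort(dist[i], kind="stable")[:k]
    for i, j in zip(miss_rows, miss_cols):
        donors = X[order_cache[i], j]
        donors = donors[~np.isnan(donors)]
        if donors.size == 0:
            log.info(
                "knn_impute: cell (%s, %s): all %d nearest rows missing; "
                "falling back to column mean",
                matrix.row_ids[i], matrix.col_ids[j], k,
            )
            out[i, j] = col_means[j]
        else:
            out[i, j] = donors.mean()
    return OmicsMatrix(pd.DataFrame(out, index=matrix.row_ids, columns=matrix.col_ids))


# ---------------------------------------------------------------------------
# PCA gene features
# ---------------------------------------------------------------------------


@dataclass
class PCModel:
    """PCA of the (z-scored) expression matrix with genes as observations.

    ``loadings`` are the sample-space component directions (components ×
    samples); ``scores`` are the per-gene coordinates used as features
    (genes × components).
    """

    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame
    n_genes: int
    n_samples: int
    normalization: str

    def __post_init__(self) -> None:
        evr = np.asarray(self.explained_variance_ratio, dtype=float)
        if (evr < -1e-12).any():
            raise ValueError("explained-variance fractions must be nonnegative")
        if (np.diff(evr) > 1e-9).any():
            raise ValueError("explained-variance fractions must be non-increasing")
        if evr.sum() > 1 + 1e-6:
            raise ValueError("explained-variance fractions must sum to <= 1")
        if self.scores.shape[0] != self.n_genes:
            raise ValueError("gene scores row count must equal gene count")
        self.explained_variance_ratio = evr

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    @property
    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_ratio)

    def n_for_variance(self, target: float) -> int:
        """Smallest component count with cumulative explained variance >= target."""
        if target >= 1:
            raise ValueError(f"variance target must be < 1, got {target}")
        cum = self.cumulative_variance
        hits = np.nonzero(cum >= target)[0]
        if hits.size == 0:
            raise ValueError(
                f"variance target {target} unattainable: "
                f"{self.n_components} components reach {cum[-1]:.4f}"
            )
        return int(hits[0]) + 1


def _zscore_rows(frame: pd.DataFrame) -> pd.DataFrame:
    mu = frame.mean(axis=1)
    sd = frame.std(axis=1, ddof=0)
    if (sd == 0).any():
        bad = frame.index[sd == 0].tolist()
        raise ValueError(f"cannot z-score constant rows: {bad}")
    return frame.sub(mu, axis=0).div(sd, axis=0)


def pca_gene_features(
    matrix: OmicsMatrix,
    n_components: int | None = None,
    variance_target: float | None = None,
    scale_axis: str = "gene",
) -> PCModel:
    """Z-score the matrix and run PCA with genes as observations.

    With ``scale_axis='gene'`` (default) each gene row is standardized across
    samples before PCA so components capture co-expression pattern rather
    than abundance scale; ``'sample'`` standardizes columns instead.  When
    ``variance_target`` is given, the returned component count is the
    smallest whose cumulative explained variance reaches the target.
    Components follow a deterministic sign convention: each component's
    largest-magnitude loading is positive.
    """
    if not matrix.is_complete:
        raise ValueError("PCA requires a complete matrix; impute first")
    if (n_components is None) == (variance_target is None):
        raise ValueError("give exactly one of n_components or variance_target")
    frame = matrix.data
    if scale_axis == "gene":
        Z = _zscore_rows(frame)
    elif scale_axis == "sample":
        Z = _zscore_rows(frame.T).T
    else:
        raise ValueError(f"scale_axis must be 'gene' or 'sample', got {scale_axis}")

    max_comp = min(Z.shape)
    if n_components is not None and n_components > max_comp:
        raise ValueError(
            f"n_components ({n_components}) exceeds min(genes, samples) = {max_comp}"
        )
    # fit the full spectrum so variance targets and ratios use total variance
    pca = PCA(n_components=max_comp, svd_solver="full")
    scores = pca.fit_transform(Z.to_numpy())
    comps = pca.components_
    # sign convention: largest-|loading| entry positive
    for c in range(comps.shape[0]):
        peak = np.argmax(np.abs(comps[c]))
        if comps[c, peak] < 0:
            comps[c] = -comps[c]
            scores[:, c] = -scores[:, c]
    evr = pca.explained_variance_ratio_

    model = PCModel(
        loadings=pd.DataFrame(
            comps,
            index=[f"PC{i+1}" for i in range(comps.shape[0])],
            columns=frame.columns,
        ),
        explained_variance_ratio=evr,
        scores=pd.DataFrame(
            scores,
            index=frame.index,
            columns=[f"PC{i+1}" for i in range(comps.shape[0])],
        ),
        n_genes=frame.shape[0],
        n_samples=frame.shape[1],
        normalization=f"zscore_{scale_axis}",
    )
    if variance_target is not None:
        n_components = model.n_for_variance(variance_target)
    return PCModel(
        loadings=model.loadings.iloc[:n_components],
        explained_variance_ratio=model.explained_variance_ratio[:n_components],
        scores=model.scores.iloc[:, :n_components],
        n_genes=model.n_genes,
        n_samples=model.n_samples,
        normalization=model.normalization,
    )


def component_similarity(a: PCModel, b: PCModel) -> pd.DataFrame:
    """|cosine| similarity between the two models' loading vectors.

    Compared over the intersection of shared variables (samples); invariant
    to sign flips of either component.  Entries lie in [0, 1].
    """
    shared = [c for c in a.loadings.columns if c in set(b.loadings.columns)]
    if len(shared) == 0:
        raise ValueError("no shared variables between the two models")
    if len(shared) < 2:
        raise ValueError("need at least 2 shared variables to compare loadings")
    A = a.loadings.loc[:, shared].to_numpy()
    B = b.loadings.loc[:, shared].to_numpy()
    A = A / np.linalg.norm(A, axis=1, keepdims=True)
    B = B / np.linalg.norm(B, axis=1, keepdims=True)
    sim = np.abs(A @ B.T)
    return pd.DataFrame(sim, index=a.loadings.index, columns=b.loadings.index)


def subsample_robustness(
    matrix: OmicsMatrix,
    n_components: int,
    fraction: float = 0.5,
    seed: int = 0,
    scale_axis: str = "gene",
) -> pd.Series:
    """|cosine| between baseline PCs and PCs from a random gene subsample.

    Mirrors the robustness diagnostic of refitting components on a random
    fraction of genes and comparing loading directions to the full-data
    baseline.  Returns the per-component |cosine| for the first
    ``n_components`` components (best match on the diagonal).
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0,1), got {fraction}")
    base = pca_gene_features(matrix, n_components=n_components, scale_axis=scale_axis)
    rng = np.random.default_rng(seed)
    n_rows = matrix.shape[0]
    take = rng.choice(n_rows, size=max(2, int(round(fraction * n_rows))), replace=False)
    sub = OmicsMatrix(matrix.data.iloc[np.sort(take)])
    alt = pca_gene_features(sub, n_components=n_components, scale_axis=scale_axis)
    sim = component_similarity(base, alt)
    return pd.Series(np.diag(sim.to_numpy()), index=sim.index, name="abs_cosine")
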