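"""Per-gene feature construction for the hybrid classifiers.

Three feature families are combined into one gene × feature table:

* principal-component scores of the expression matrix (from
  :mod:`hybridgo.preprocess`),
* metabolite-correlation features — per-gene Spearman rho against each
  metabolite profile over shared samples, zeroed when not significant and
  variance-stabilized with the Fisher transformation z = arctanh(rho),
* knowledge scores in {1, 0, −1} one-hot encoded into two Boolean columns
  (positive, negative); the "no classification" column is redundant and
  implicit in (0, 0).

Transcriptomics-only comparator tables replace the extra features with the
same number of additional PC features so both arms have equal width.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import OmicsMatrix
from .preprocess import PCModel

__all__ = [
    "FeatureTable",
    "metabolite_corr_features",
    "encode_knowledge",
    "assemble_features",
]

log = logging.getLogger(__name__)

#: |rho| clamp applied before arctanh so perfect correlations stay finite
RHO_CLAMP = 1 - 1e-12

KNOWLEDGE_COLUMNS = ("knowledge_pos", "knowledge_neg")


@dataclass
class FeatureTable:
    """Gene × feature matrix with per-feature provenance tags.

    Provenance is one of ``pc``, ``metabolite_corr``, ``knowledge_pos``,
    ``knowledge_neg``.  The table never contains missing values.
    """

    values: pd.DataFrame
    provenance: pd.Series  # feature name -> tag

    def __post_init__(self) -> None:
        if self.values.isna().to_numpy().any():
            raise ValueError("feature table must not contain missing values")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dup}")
        if list(self.provenance.index) != list(self.values.columns):
            raise ValueError("provenance must cover exactly the feature columns")
        for col in self.values.columns:
            if self.provenance[col].startswith("knowledge"):
                vals = set(self.values[col].unique())
                if not vals <= {0.0, 1.0}:
                    raise ValueError(f"knowledge column {col} must be Boolean")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# metabolite correlation features
# ---------------------------------------------------------------------------


def _spearman_pvalues(rho: np.ndarray, n: int, dof: int | None) -> np.ndarray:
    """Two-sided p-values for Spearman rho via the t approximation.

    ``t = rho * sqrt((n - 2) / (1 - rho^2))`` referred to a Student-t with
    ``n - 2`` degrees of freedom by default; ``dof`` overrides the reference
    distribution's degrees of freedom (the statistic keeps n − 2).
    """
    df_ref = (n - 2) if dof is None else dof
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(np.abs(t), df_ref)
    p[np.isnan(t)] = 0.0  # |rho| == 1: infinitely significant
    return p


def metabolite_corr_features(
    expr: OmicsMatrix,
    metab: OmicsMatrix,
    alpha: float = 0.05,
    dof: int | None = None,
) -> pd.DataFrame:
    """One Fisher-z Spearman-correlation feature column per metabolite row.

    For each gene and metabolite: Spearman rho over the shared samples
    (average ranks for ties), two-sided p-value from the t approximation on
    n − 2 degrees of freedom, rho set to 0 when p >= ``alpha``, then
    z = arctanh(rho) with |rho| clamped to 1 − 1e−12.  Constant gene rows
    have undefined rho and yield a 0 feature (logged).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    shared = [c for c in expr.col_ids if c in set(metab.col_ids)]
    if len(shared) < 4:
        raise ValueError(
            f"need at least 4 shared samples between expression and "
            f"metabolites, got {len(shared)}"
        )
    X = expr.data.loc[:, shared].to_numpy()
    M = metab.data.loc[:, shared].to_numpy()
    if np.isnan(X).any() or np.isnan(M).any():
        raise ValueError("correlation features require complete matrices; impute first")
    n = len(shared)

    # rank-transform rows (average ranks for ties), then Pearson on ranks
    RX = stats.rankdata(X, axis=1)
    RM = stats.rankdata(M, axis=1)
    RXc = RX - RX.mean(axis=1, keepdims=True)
    RMc = RM - RM.mean(axis=1, keepdims=True)
    x_ss = np.sqrt((RXc**2).sum(axis=1))
    m_ss = np.sqrt((RMc**2).sum(axis=1))
    const_genes = x_ss == 0
    if const_genes.any():
        log.info(
            "metabolite_corr_features: %d constant gene rows; features set to 0",
            int(const_genes.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (RXc @ RMc.T) / np.outer(x_ss, m_ss)
    rho = np.nan_to_num(rho, nan=0.0)

    out = np.empty_like(rho)
    for j in range(rho.shape[1]):
        r = rho[:, j].copy()
        p = _spearman_pvalues(r, n, dof)
        r[p >= alpha] = 0.0
        r = np.clip(r, -RHO_CLAMP, RHO_CLAMP)
        out[:, j] = np.arctanh(r)
    return pd.DataFrame(out, index=expr.row_ids, columns=metab.row_ids)


# ---------------------------------------------------------------------------
# knowledge encoding
# ---------------------------------------------------------------------------


def encode_knowledge(
    scores: pd.Series, genes: list[str] | None = None
) -> pd.DataFrame:
    """One-hot encode {1, 0, −1} knowledge scores into two Boolean columns.

    1 → (1, 0), 0 → (0, 1), −1 → (0, 0); no third column is emitted.  Genes
    requested via ``genes`` but absent from the score table are assigned −1
    (no classification) and therefore encode to (0, 0).
    """
    bad = set(pd.unique(scores)) - {1, 0, -1}
    if bad:
        raise ValueError(f"knowledge scores must be in {{1,0,-1}}, got {sorted(bad)}")
    if genes is not None:
        scores = scores.reindex(genes, fill_value=-1)
    return pd.DataFrame(
        {
            KNOWLEDGE_COLUMNS[0]: (scores == 1).astype(float),
            KNOWLEDGE_COLUMNS[1]: (scores == 0).astype(float),
        },
        index=scores.index,
    )


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def assemble_features(
    pcs: PCModel,
    n_pc: int,
    extras: pd.DataFrame | None = None,
    mode: str = "hybrid",
    extra_provenance: pd.Series | None = None,
) -> FeatureTable:
    """Build the gene × feature table for one model variant.

    In ``hybrid`` mode the table holds the first ``n_pc`` PC scores plus the
    ``extras`` columns (metabolite correlations and/or knowledge encodings).
    In ``transcriptomics_only`` mode the extras are replaced with the same
    number of additional PC features, so a 5-PC + 2-knowledge hybrid is
    matched by a 7-PC transcriptomics-only table.

    Genes are aligned across sources by ID intersection; knowledge columns
    in ``extras`` should already default to (0, 0) for unscored genes (see
    :func:`encode_knowledge`), so only genes genuinely absent from an
    expression-derived source are dropped (and logged).
    """
    if mode not in ("hybrid", "transcriptomics_only"):
        raise ValueError(f"mode must be 'hybrid' or 'transcriptomics_only', got {mode!r}")
    n_extra = 0 if extras is None else extras.shape[1]
    total_pc = n_pc if mode == "hybrid" else n_pc + n_extra
    if total_pc > pcs.n_components:
        raise ValueError(
            f"{total_pc} PC features requested but model has {pcs.n_components}"
        )
    pc_block = pcs.scores.iloc[:, :total_pc]

    if mode == "transcriptomics_only" or extras is None or n_extra == 0:
        table = pc_block
        prov = pd.Series("pc", index=table.columns)
        return FeatureTable(table.copy(), prov)

    genes = [g for g in pc_block.index if g in set(extras.index)]
    if not genes:
        raise ValueError("no genes shared between PC scores and extra features")
    dropped = len(pc_block.index) - len(genes)
    if dropped:
        log.info("assemble_features: dropped %d genes absent from extras", dropped)
    table = pd.concat([pc_block.loc[genes], extras.loc[genes]], axis=1)
    if extra_provenance is None:
        extra_provenance = pd.Series(
            [
                col if col in KNOWLEDGE_COLUMNS else "metabolite_corr"
                for col in extras.columns
            ],
            index=extras.columns,
        )
    prov = pd.concat(
        [pd.Series("pc", index=pc_block.columns), extra_provenance.loc[extras.columns]]
    )
    return FeatureTable(table, prov)
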