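"""Synthetic multi-omics datasets with planted functional structure.

The generator emulates the statistical shape of the real inputs the
annotation framework consumes — a gene × sample expression matrix with
low-rank co-expression structure, one or two metabolite profiles correlated
with a designated gene subset, noisy categorical knowledge scores in
{1, 0, −1}, and a positive gene set tied to the planted structure — so the
whole pipeline can be exercised end to end without any external download.

Model: expression = loadings · factors + Gaussian noise, with latent factor
scores and background loadings i.i.d. standard normal.  Positive genes carry
a mean shift of ``signal_strength`` on their loading for factor 1 (the
metabolite-generating factor) or, for the fraction of positives not tied to
the metabolite, on factor 2 — so all positives are separable through the
leading principal components, but only ``metabolite_assoc_frac`` of them
correlate with the metabolite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import OmicsMatrix, write_gene_sets, write_matrix

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_dataset", "write_dataset"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-structure generator.

    The defaults define the study conditions used throughout the package's
    tests and examples: a 400-gene × 60-sample matrix with 3 latent factors,
    unit noise, 50 positive genes shifted by 2 on their signal-factor
    loading, half of them metabolite-associated, knowledge scores that agree
    with the truth 90% of the time and cover 90% of genes, and 5% of
    expression entries missing at random.  Factor scales decay geometrically
    (``factor_decay``) so the expression matrix has the decaying eigenvalue
    spectrum of real panels and the leading components are identifiable.
    """

    n_genes: int = 400
    n_samples: int = 60
    n_factors: int = 3
    noise_sd: float = 1.0
    n_positive: int = 50
    signal_strength: float = 2.0
    metabolite_assoc_frac: float = 0.5
    knowledge_accuracy: float = 0.9
    knowledge_coverage: float = 0.9
    missing_frac: float = 0.05
    factor_decay: float = 0.7
    paired_metabolite: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_samples", "n_factors", "n_positive"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.n_positive >= self.n_genes:
            raise ValueError(
                f"n_positive ({self.n_positive}) must be < n_genes ({self.n_genes})"
            )
        if self.n_factors > min(self.n_genes, self.n_samples):
            raise ValueError(
                f"n_factors ({self.n_factors}) must be <= "
                f"min(n_genes, n_samples) = {min(self.n_genes, self.n_samples)}"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be nonnegative, got {self.noise_sd}")
        if not 0 < self.factor_decay <= 1:
            raise ValueError(f"factor_decay must be in (0,1], got {self.factor_decay}")
        for name in ("metabolite_assoc_frac", "knowledge_accuracy",
                     "knowledge_coverage", "missing_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class SyntheticDataset:
    """One generated dataset plus the ground truth that was planted."""

    expression: OmicsMatrix
    metabolites: OmicsMatrix
    knowledge: pd.Series  # per-gene score in {1, 0, -1}
    truth: pd.Series  # per-gene binary label
    config: SyntheticConfig
    factors: pd.DataFrame = field(repr=False, default=None)  # latent scores
    associated_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.truth) != self.expression.shape[0]:
            raise ValueError("truth length must equal expression row count")
        bad = set(self.knowledge.unique()) - {1, 0, -1}
        if bad:
            raise ValueError(f"knowledge scores outside {{1,0,-1}}: {sorted(bad)}")

    @property
    def positive_genes(self) -> list[str]:
        return list(self.truth.index[self.truth == 1])


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one dataset; identical config (including seed) is bit-identical."""
    rng = np.random.default_rng(config.seed)
    g, s, k = config.n_genes, config.n_samples, config.n_factors

    gene_ids = [f"g{i:05d}" for i in range(1, g + 1)]
    sample_ids = [f"s{j:04d}" for j in range(1, s + 1)]

    # geometric decay of factor scales yields the decaying eigenvalue
    # spectrum seen in real expression panels, so the leading components
    # are well separated and stable under gene subsampling
    scales = config.factor_decay ** np.arange(k)
    factors = scales[:, None] * rng.standard_normal((k, s))
    loadings = rng.standard_normal((g, k))

    # plant the class signal: positives shifted on factor 1 (metabolite-
    # associated fraction) or factor 2 (the rest; factor 1 if only 1 factor)
    positives = np.sort(rng.choice(g, size=config.n_positive, replace=False))
    n_assoc = int(round(config.metabolite_assoc_frac * config.n_positive))
    assoc = positives[:n_assoc]
    non_assoc = positives[n_assoc:]
    loadings[assoc, 0] += config.signal_strength
    alt_factor = 1 if k >= 2 else 0
    loadings[non_assoc, alt_factor] += config.signal_strength

    expr = loadings @ factors + config.noise_sd * rng.standard_normal((g, s))

    # metabolite profile(s): factor-1 scores plus noise
    met_rows = {"metab_1": factors[0] + config.noise_sd * rng.standard_normal(s)}
    if config.paired_metabolite:
        met_rows["metab_2"] = factors[0] + config.noise_sd * rng.standard_normal(s)
    metab = pd.DataFrame(met_rows, index=sample_ids).T

    truth = np.zeros(g, dtype=int)
    truth[positives] = 1

    # knowledge scores: agree with truth w.p. accuracy, flipped otherwise,
    # then withheld (-1) w.p. 1 - coverage
    agree = rng.random(g) < config.knowledge_accuracy
    scores = np.where(agree, truth, 1 - truth)
    covered = rng.random(g) < config.knowledge_coverage
    scores = np.where(covered, scores, -1)

    # missing completely at random in expression
    if config.missing_frac > 0:
        miss = rng.random((g, s)) < config.missing_frac
        expr = expr.astype(float)
        expr[miss] = np.nan

    expr_frame = pd.DataFrame(expr, index=gene_ids, columns=sample_ids)
    return SyntheticDataset(
        expression=OmicsMatrix(expr_frame),
        metabolites=OmicsMatrix(metab),
        knowledge=pd.Series(scores, index=gene_ids, name="score"),
        truth=pd.Series(truth, index=gene_ids, name="label"),
        config=config,
        factors=pd.DataFrame(
            factors, index=[f"factor_{i+1}" for i in range(k)], columns=sample_ids
        ),
        associated_genes=[gene_ids[i] for i in assoc],
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset in the same formats the real pipeline reads.

    Emits expression TSV, metabolite TSV, a two-column knowledge table, and
    a GMT file with the true positive gene set; returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "metabolites": out / "metabolites.tsv",
        "knowledge": out / "knowledge.tsv",
        "gene_sets": out / "true_positives.gmt",
    }
    write_matrix(dataset.expression, paths["expression"])
    write_matrix(dataset.metabolites, paths["metabolites"])
    dataset.knowledge.rename_axis("gene_id").to_frame().to_csv(
        paths["knowledge"], sep="\t"
    )
    write_gene_sets(
        {"true_positives": dataset.positive_genes},
        paths["gene_sets"],
        descriptions={"true_positives": "planted positive gene set"},
    )
    return paths
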