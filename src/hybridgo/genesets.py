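"""Positive-set construction, balanced negative sampling, and split plans.

The training regime is positive–unlabeled: genes annotated to a GO term
under accepted evidence codes form the positive class, and an equal number
of negatives is drawn at random (without replacement) from the unannotated
remainder.  Because any single negative draw biases the model, the draw is
repeated over many bootstrap iterations; each iteration carries its own
stratified k-fold assignment over positives ∪ negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import AnnotationTable, spawn_seeds

__all__ = [
    "EXPERIMENTAL_CODES",
    "HIGH_THROUGHPUT_CODES",
    "SEQUENCE_SIMILARITY_CODES",
    "EvidencePolicy",
    "BootstrapSplit",
    "SplitPlan",
    "build_positive_set",
    "sample_negatives",
    "make_split_plan",
]

#: GO experimental evidence codes
EXPERIMENTAL_CODES = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})
#: GO high-throughput experimental evidence codes
HIGH_THROUGHPUT_CODES = frozenset({"HTP", "HDA", "HMP", "HGI", "HEP"})
#: GO sequence-similarity evidence codes (opt-in for sparsely annotated terms)
SEQUENCE_SIMILARITY_CODES = frozenset({"ISS", "ISO", "ISA", "ISM"})


@dataclass(frozen=True)
class EvidencePolicy:
    """Which annotation evidence codes admit a gene to the positive set.

    The default whitelist accepts experimental and high-throughput codes;
    low-confidence computational/inferred annotations (e.g. IEA) are
    excluded.  ``allow_sequence_similarity`` additionally admits the
    ISS family — useful for small terms where experimental evidence alone
    leaves too few positives for training.
    """

    whitelist: frozenset[str] = EXPERIMENTAL_CODES | HIGH_THROUGHPUT_CODES
    allow_sequence_similarity: bool = False

    def __post_init__(self) -> None:
        if not self.whitelist:
            raise ValueError("evidence whitelist must be nonempty")

    def accepted(self) -> frozenset[str]:
        if self.allow_sequence_similarity:
            return self.whitelist | SEQUENCE_SIMILARITY_CODES
        return frozenset(self.whitelist)


@dataclass
class PositiveSetReport:
    term: str
    kept: int
    removed: int
    removed_genes: list[str]


def build_positive_set(
    annotations: AnnotationTable,
    term: str,
    policy: EvidencePolicy | None = None,
) -> tuple[set[str], PositiveSetReport]:
    """Genes with at least one annotation to ``term`` under an accepted code."""
    policy = policy or EvidencePolicy()
    sub = annotations.for_term(term)
    if sub.empty:
        raise ValueError(f"term {term!r} not present in annotation table")
    accepted = policy.accepted()
    ok = sub["evidence_code"].isin(accepted)
    positives = set(sub.loc[ok, "gene_id"])
    all_genes = set(sub["gene_id"])
    removed = sorted(all_genes - positives)
    if not positives:
        raise ValueError(
            f"term {term!r}: no gene passes the evidence policy "
            f"(accepted codes: {sorted(accepted)})"
        )
    report = PositiveSetReport(
        term=term, kept=len(positives), removed=len(removed), removed_genes=removed
    )
    return positives, report


def sample_negatives(
    universe: Iterable[str], positives: Iterable[str], seed: int
) -> set[str]:
    """Draw |positives| negatives without replacement from universe \\ positives."""
    positives = set(positives)
    pool = sorted(set(universe) - positives)
    if len(pool) < len(positives):
        raise ValueError(
            f"negative pool ({len(pool)}) smaller than positive set ({len(positives)})"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(pool), size=len(positives), replace=False)
    return {pool[i] for i in picked}


@dataclass
class BootstrapSplit:
    """One bootstrap iteration: its negative set and fold assignment."""

    negatives: frozenset[str]
    folds: dict[str, int]  # gene -> fold in 1..n_folds, over positives ∪ negatives
    seed: int

    def fold_genes(self, fold: int) -> set[str]:
        return {g for g, f in self.folds.items() if f == fold}


@dataclass
class SplitPlan:
    """The full bootstrap × fold training plan for one term."""

    positives: frozenset[str]
    n_folds: int
    master_seed: int
    iterations: list[BootstrapSplit] = field(default_factory=list)

    @property
    def n_bootstrap(self) -> int:
        return len(self.iterations)

    def to_frame(self) -> pd.DataFrame:
        """Serialize for audit: one row per (iteration, gene)."""
        rows = []
        for b, it in enumerate(self.iterations):
            for gene, fold in sorted(it.folds.items()):
                rows.append(
                    {
                        "iteration": b,
                        "gene_id": gene,
                        "label": int(gene in self.positives),
                        "fold": fold,
                    }
                )
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(Path(path), sep="\t", index=False)


def _assign_folds(
    positives: list[str], negatives: list[str], n_folds: int, rng: np.random.Generator
) -> dict[str, int]:
    """Stratified fold assignment with global size balance.

    Positives are shuffled and dealt round-robin over folds; negatives
    continue the deal from where the positives stopped.  Per fold this keeps
    |positives − negatives| within 1 while total fold sizes differ by at
    most 1.
    """
    folds: dict[str, int] = {}
    pos = list(positives)
    neg = list(negatives)
    rng.shuffle(pos)
    rng.shuffle(neg)
    i = 0
    for g in pos:
        folds[g] = i % n_folds + 1
        i += 1
    for g in neg:
        folds[g] = i % n_folds + 1
        i += 1
    return folds


def make_split_plan(
    positives: Iterable[str],
    universe: Iterable[str],
    n_bootstrap: int = 100,
    n_folds: int = 5,
    master_seed: int = 0,
) -> SplitPlan:
    """Build the bootstrap × fold plan, reproducible from ``master_seed``.

    Each iteration draws an independent balanced negative set and a
    stratified fold assignment so every fold holds a near-equal number of
    positives and negatives.
    """
    positives = sorted(set(positives))
    universe = set(universe)
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if len(positives) < n_folds:
        raise ValueError(
            f"need at least n_folds ({n_folds}) positives, got {len(positives)}"
        )
    missing = [g for g in positives if g not in universe]
    if missing:
        raise ValueError(f"positives absent from universe: {missing[:5]}")
    plan = SplitPlan(
        positives=frozenset(positives), n_folds=n_folds, master_seed=master_seed
    )
    seeds = spawn_seeds(master_seed, n_bootstrap)
    for seed in seeds:
        negatives = sample_negatives(universe, positives, seed)
        rng = np.random.default_rng(seed + 1)
        folds = _assign_folds(positives, sorted(negatives), n_folds, rng)
        plan.iterations.append(
            BootstrapSplit(negatives=frozenset(negatives), folds=folds, seed=seed)
        )
    return plan
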