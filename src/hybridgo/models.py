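"""Classifier training under the bootstrap × cross-validation regime.

Four classifier families (random forest, decision tree, Gaussian naive
Bayes, RBF SVM with probability calibration) are trained on balanced
positive/negative gene sets.  For evaluation, each bootstrap iteration runs
stratified k-fold cross-validation and every labeled gene receives exactly
one out-of-fold probability per iteration.  For annotating unlabeled genes,
one model per bootstrap is retrained on the iteration's full balanced set;
per-gene probabilities are averaged over bootstraps within each PC-count
variant, and the final report is the mean ± standard error across variants
(the PC-variant ensemble).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureTable
from .genesets import SplitPlan
from .io import spawn_seeds

__all__ = [
    "ALGORITHMS",
    "ModelSpec",
    "make_classifier",
    "CVResult",
    "cross_validate",
    "audit_no_leakage",
    "fit_full",
    "predict_unlabeled",
    "PredictionTable",
    "train_matrix",
    "TrainCell",
]

#: canonical algorithm names with common aliases
ALGORITHMS = {
    "random_forest": "random_forest",
    "rf": "random_forest",
    "decision_tree": "decision_tree",
    "dt": "decision_tree",
    "naive_bayes": "naive_bayes",
    "nb": "naive_bayes",
    "svm": "svm",
    "svm_probabilistic": "svm",
    "svc": "svm",
}


@dataclass(frozen=True)
class ModelSpec:
    """One classifier family with hyperparameters and a seed."""

    algorithm: str = "random_forest"
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm.lower() not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; "
                f"choose from {sorted(set(ALGORITHMS.values()))}"
            )

    @property
    def canonical(self) -> str:
        return ALGORITHMS[self.algorithm.lower()]


def make_classifier(spec: ModelSpec, seed: int | None = None):
    """Instantiate the scikit-learn estimator for a spec.

    Library-conventional defaults: RF with 100 trees and sqrt-features per
    split; unlimited-depth decision tree; Gaussian naive Bayes; RBF SVM with
    Platt-scaled probabilities.  All overridable via ``hyperparameters``.
    """
    seed = spec.seed if seed is None else seed
    hp = dict(spec.hyperparameters)
    algo = spec.canonical
    if algo == "random_forest":
        hp.setdefault("n_estimators", 100)
        hp.setdefault("max_features", "sqrt")
        return RandomForestClassifier(random_state=seed, **hp)
    if algo == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **hp)
    if algo == "naive_bayes":
        return GaussianNB(**hp)
    if algo == "svm":
        hp.setdefault("kernel", "rbf")
        # Platt-style sigmoid calibration via internal CV gives probabilities
        base = SVC(random_state=seed, **hp)
        return CalibratedClassifierCV(base, method="sigmoid", cv=3, ensemble=False)
    raise AssertionError(algo)


def _positive_proba(model, X: np.ndarray) -> np.ndarray:
    """Probability of the positive (label 1) class, whatever the class order."""
    proba = model.predict_proba(X)
    idx = list(model.classes_).index(1)
    return proba[:, idx]


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    """Out-of-fold probabilities plus the training memberships for auditing."""

    probs: dict[int, pd.Series]  # iteration -> gene_id -> out-of-fold probability
    labels: dict[int, pd.Series]  # iteration -> gene_id -> 0/1 label
    memberships: list[tuple[int, int, frozenset, frozenset]]  # (iter, fold, train, test)

    def iterations(self) -> list[int]:
        return sorted(self.probs)


def cross_validate(
    features: FeatureTable, plan: SplitPlan, spec: ModelSpec
) -> CVResult:
    """Run the full bootstrap × k-fold regime on the labeled genes.

    For each bootstrap iteration and fold, a fresh model is trained on the
    other folds only; each labeled gene receives exactly one out-of-fold
    probability per iteration.  Deterministic given ``spec.seed`` and the
    plan.
    """
    missing = [g for it in plan.iterations for g in it.folds if g not in set(features.gene_ids)]
    if missing:
        raise ValueError(
            f"{len(set(missing))} plan genes missing from the feature table, "
            f"e.g. {sorted(set(missing))[:5]}"
        )
    X_all = features.values
    probs: dict[int, pd.Series] = {}
    labels: dict[int, pd.Series] = {}
    memberships: list[tuple[int, int, frozenset, frozenset]] = []
    model_seeds = spawn_seeds(spec.seed, plan.n_bootstrap * plan.n_folds)
    si = 0
    for b, it in enumerate(plan.iterations):
        fold_probs: dict[str, float] = {}
        genes = sorted(it.folds)
        y = pd.Series({g: int(g in plan.positives) for g in genes})
        for fold in range(1, plan.n_folds + 1):
            test = sorted(it.fold_genes(fold))
            train = [g for g in genes if it.folds[g] != fold]
            y_train = y.loc[train]
            if y_train.nunique() < 2:
                raise ValueError(
                    f"degenerate training fold: iteration {b}, fold {fold} "
                    f"has a single class in training data"
                )
            model = make_classifier(spec, seed=model_seeds[si])
            si += 1
            model.fit(X_all.loc[train].to_numpy(), y_train.to_numpy())
            p = _positive_proba(model, X_all.loc[test].to_numpy())
            fold_probs.update(zip(test, p))
            memberships.append((b, fold, frozenset(train), frozenset(test)))
        probs[b] = pd.Series(fold_probs).loc[genes]
        labels[b] = y
    return CVResult(probs=probs, labels=labels, memberships=memberships)


def audit_no_leakage(cv: CVResult) -> bool:
    """Prove no out-of-fold prediction came from a model that saw its gene.

    Raises if any test gene appears in its own fold's training rows or if a
    gene was predicted by more than one fold within an iteration.
    """
    seen: dict[int, set] = {}
    for b, fold, train, test in cv.memberships:
        overlap = train & test
        if overlap:
            raise AssertionError(
                f"leakage: iteration {b} fold {fold} trains on test genes {sorted(overlap)[:5]}"
            )
        prev = seen.setdefault(b, set())
        dup = prev & test
        if dup:
            raise AssertionError(
                f"iteration {b}: genes predicted by multiple folds: {sorted(dup)[:5]}"
            )
        prev |= test
    for b, p in cv.probs.items():
        if set(p.index) != seen.get(b, set()):
            raise AssertionError(f"iteration {b}: predictions do not cover all folds")
    return True


# ---------------------------------------------------------------------------
# full-data models and unlabeled-gene prediction
# ---------------------------------------------------------------------------


@dataclass
class FittedEnsemble:
    """One fitted model per (variant, bootstrap), with its feature names."""

    models: dict[tuple[str, int], object]
    feature_names: dict[str, list[str]]
    variants: list[str]
    n_bootstrap: int


def fit_full(
    features_by_variant: Mapping[str, FeatureTable],
    plan: SplitPlan,
    spec: ModelSpec,
) -> FittedEnsemble:
    """Train one model per (PC-count variant, bootstrap) on the full balanced set."""
    variants = list(features_by_variant)
    models: dict[tuple[str, int], object] = {}
    feature_names: dict[str, list[str]] = {}
    model_seeds = spawn_seeds(spec.seed, len(variants) * plan.n_bootstrap)
    si = 0
    for variant in variants:
        table = features_by_variant[variant]
        feature_names[variant] = table.feature_names
        for b, it in enumerate(plan.iterations):
            genes = sorted(it.folds)
            y = np.array([int(g in plan.positives) for g in genes])
            model = make_classifier(spec, seed=model_seeds[si])
            si += 1
            model.fit(table.values.loc[genes].to_numpy(), y)
            models[(variant, b)] = model
    return FittedEnsemble(
        models=models,
        feature_names=feature_names,
        variants=variants,
        n_bootstrap=plan.n_bootstrap,
    )


@dataclass
class PredictionTable:
    """Per-gene probabilities averaged within variants, then across variants.

    ``mean_prob`` is the arithmetic mean of the per-variant means and ``se``
    their sample standard deviation divided by sqrt(#variants); with one
    variant the SE is 0.
    """

    variant_means: pd.DataFrame  # genes × variants

    @property
    def gene_ids(self) -> list[str]:
        return list(self.variant_means.index)

    @property
    def n_models(self) -> int:
        return self.variant_means.shape[1]

    @property
    def mean_prob(self) -> pd.Series:
        return self.variant_means.mean(axis=1).rename("mean_prob")

    @property
    def se(self) -> pd.Series:
        k = self.n_models
        if k < 2:
            return pd.Series(0.0, index=self.variant_means.index, name="se")
        sd = self.variant_means.std(axis=1, ddof=1)
        return (sd / np.sqrt(k)).rename("se")

    def frame(self, threshold: float | None = None) -> pd.DataFrame:
        """Report frame with the columns the prediction TSV uses."""
        out = pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "mean_prob": self.mean_prob.to_numpy(),
                "se": self.se.to_numpy(),
                "n_models": self.n_models,
            }
        )
        thr = 0.5 if threshold is None else threshold
        out["class_at_threshold"] = (out["mean_prob"] >= thr).astype(int)
        return out

    def formatted(self) -> pd.Series:
        """Render ``mean (se)`` to four decimals, e.g. ``0.7716 (0.0230)``."""
        return pd.Series(
            [
                f"{m:.4f} ({s:.4f})"
                for m, s in zip(self.mean_prob, self.se)
            ],
            index=self.gene_ids,
            name="prob",
        )


def predict_unlabeled(
    ensemble: FittedEnsemble,
    features_by_variant: Mapping[str, FeatureTable],
    gene_ids: list[str],
) -> PredictionTable:
    """Score unlabeled genes with every (variant, bootstrap) model.

    Probabilities are averaged over bootstraps within each variant; the
    PredictionTable then exposes mean ± SE across variants.
    """
    cols = {}
    for variant in ensemble.variants:
        table = features_by_variant[variant]
        if table.feature_names != ensemble.feature_names[variant]:
            raise ValueError(
                f"feature mismatch for variant {variant!r}: "
                f"training used {ensemble.feature_names[variant]}, "
                f"prediction table has {table.feature_names}"
            )
        X = table.values.loc[gene_ids].to_numpy()
        acc = np.zeros(len(gene_ids))
        for b in range(ensemble.n_bootstrap):
            acc += _positive_proba(ensemble.models[(variant, b)], X)
        cols[variant] = acc / ensemble.n_bootstrap
    return PredictionTable(pd.DataFrame(cols, index=gene_ids))


# ---------------------------------------------------------------------------
# the full algorithm × pc-count × mode training matrix
# ---------------------------------------------------------------------------


@dataclass
class TrainCell:
    """Result of one (algorithm, pc_count, mode) training cell."""

    algorithm: str
    pc_count: int
    mode: str
    cv: CVResult
    mean_auroc: float


def train_matrix(
    assemble,  # callable (n_pc, mode) -> FeatureTable
    plan: SplitPlan,
    algorithms: list[str],
    pc_counts: list[int],
    master_seed: int = 0,
) -> dict[tuple[str, int, str], TrainCell]:
    """Run every (algorithm × pc_count × mode) cell of the comparison grid.

    ``assemble`` builds the feature table for a requested PC count and mode
    (``hybrid`` or ``transcriptomics_only``); each cell runs the full
    bootstrap × CV regime and records its mean out-of-fold AUROC.  The
    hybrid-vs-transcriptomics contrast for an algorithm is the paired
    difference across its cells.
    """
    from .evaluate import compute_metrics  # local import to avoid a cycle

    results: dict[tuple[str, int, str], TrainCell] = {}
    seeds = spawn_seeds(master_seed, len(algorithms) * len(pc_counts) * 2)
    si = 0
    for algorithm in algorithms:
        for n_pc in pc_counts:
            for mode in ("hybrid", "transcriptomics_only"):
                spec = ModelSpec(algorithm=algorithm, seed=seeds[si])
                si += 1
                try:
                    table = assemble(n_pc, mode)
                    cv = cross_validate(table, plan, spec)
                    aurocs = [
                        compute_metrics(cv.probs[b], cv.labels[b]).auroc
                        for b in cv.iterations()
                    ]
                except Exception as exc:
                    raise RuntimeError(
                        f"cell (algorithm={algorithm}, pc_count={n_pc}, "
                        f"mode={mode}) failed: {exc}"
                    ) from exc
                results[(algorithm, n_pc, mode)] = TrainCell(
                    algorithm=algorithm,
                    pc_count=n_pc,
                    mode=mode,
                    cv=cv,
                    mean_auroc=float(np.mean(aurocs)),
                )
    return results
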