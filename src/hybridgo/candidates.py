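"""Candidate nomination: probability ranking and the triple-classifier gate.

A gene becomes a candidate only when three independent classifiers — e.g.
mitochondrial localization, transmembrane transporter activity, and the
target metabolic-process term — all assign it a mean probability strictly
above the gate threshold (default 0.80).  Genes already annotated to one of
the terms are overridden to probability 1.0 on that axis before gating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import PredictionTable

__all__ = ["rank_by_probability", "triple_gate", "GateTable"]

log = logging.getLogger(__name__)

GATE_AXES = ("mito", "transporter", "target")


def rank_by_probability(
    preds: PredictionTable, gene_subset: list[str] | None = None
) -> pd.DataFrame:
    """Rank genes by mean ensemble probability, descending.

    Ties break lexicographically on gene ID for determinism.  When a
    ``gene_subset`` is given (e.g. one protein family), only those genes are
    ranked; requested genes absent from the table are warned about and
    listed in the log.  The report renders ``mean (SE)`` to four decimals.
    """
    if not preds.gene_ids:
        raise ValueError("prediction table is empty")
    frame = pd.DataFrame(
        {
            "mean_prob": preds.mean_prob,
            "se": preds.se,
            "prob": preds.formatted(),
        }
    )
    if gene_subset is not None:
        unknown = sorted(set(gene_subset) - set(frame.index))
        if unknown:
            log.warning(
                "rank_by_probability: %d requested genes not in table: %s",
                len(unknown), unknown,
            )
        frame = frame.loc[[g for g in gene_subset if g in frame.index]]
    # deterministic tie-break: stable sort on gene id first, then prob
    frame = frame.sort_index(kind="stable").sort_values(
        "mean_prob", ascending=False, kind="stable"
    )
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return frame.rename_axis("gene_id")


@dataclass
class GateTable:
    """Triple-gate results for a gene universe.

    ``table`` has per-axis probability/SE/annotated columns plus ``passed``;
    ``removed_fraction`` is the share of the universe the gate eliminated.
    """

    table: pd.DataFrame
    threshold: float

    @property
    def passed(self) -> pd.DataFrame:
        return self.table[self.table["passed"]]

    @property
    def removed_fraction(self) -> float:
        return 1.0 - self.table["passed"].mean()


def _axis_columns(
    preds: PredictionTable, annotated: set[str], genes: list[str]
) -> tuple[pd.Series, pd.Series, pd.Series]:
    prob = preds.mean_prob.loc[genes].copy()
    se = preds.se.loc[genes].copy()
    flag = pd.Series([g in annotated for g in genes], index=genes)
    # annotated override: probability exactly 1.0, SE 0, flagged
    prob[flag] = 1.0
    se[flag] = 0.0
    return prob, se, flag


def triple_gate(
    mito: PredictionTable,
    transporter: PredictionTable,
    target: PredictionTable,
    annotated_sets: dict[str, set[str]] | None = None,
    threshold: float = 0.80,
) -> GateTable:
    """Apply the three-classifier candidate gate.

    All three tables must share one gene universe.  ``annotated_sets`` maps
    the axis names ``mito``, ``transporter``, ``target`` to genes already
    annotated to the corresponding term; those genes are assigned
    probability 1.0 (SE 0, flagged) on that axis only.  A gene passes iff
    all three probabilities are strictly greater than ``threshold``.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    annotated_sets = annotated_sets or {}
    unknown = set(annotated_sets) - set(GATE_AXES)
    if unknown:
        raise ValueError(f"unknown annotated-set keys: {sorted(unknown)}")
    tables = dict(zip(GATE_AXES, (mito, transporter, target)))
    universes = {axis: set(t.gene_ids) for axis, t in tables.items()}
    base = universes["mito"]
    for axis, uni in universes.items():
        if uni != base:
            diff = len(uni.symmetric_difference(base))
            raise ValueError(
                f"gene universe mismatch between 'mito' and {axis!r}: "
                f"symmetric difference of {diff} genes"
            )
    genes = sorted(base)
    cols: dict[str, pd.Series] = {}
    passed = pd.Series(True, index=genes)
    for axis, preds in tables.items():
        prob, se, flag = _axis_columns(preds, annotated_sets.get(axis, set()), genes)
        cols[f"{axis}_prob"] = prob
        cols[f"{axis}_se"] = se
        cols[f"{axis}_annotated"] = flag
        passed &= prob > threshold
    frame = pd.DataFrame(cols)
    frame["min_prob"] = frame[[f"{a}_prob" for a in GATE_AXES]].min(axis=1)
    frame["passed"] = passed
    frame = frame.sort_values(
        "min_prob", ascending=False, kind="stable"
    ).rename_axis("gene_id")
    return GateTable(table=frame, threshold=threshold)
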