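"""Tabular formats, in-memory containers, and run configuration.

Everything the pipeline touches on disk is plain text: TSV matrices (genes or
metabolites as rows, sample IDs as header), GMT gene sets, flat annotation
tables with GO evidence codes, YAML run configuration, and TSV prediction
reports.  Readers validate and reject malformed input rather than silently
coercing it; every writer produces files its paired reader loads losslessly.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "ConfigError",
    "OmicsMatrix",
    "AnnotationTable",
    "RunConfig",
    "read_matrix",
    "write_matrix",
    "read_gene_sets",
    "write_gene_sets",
    "read_annotations",
    "write_annotations",
    "read_predictions",
    "write_predictions",
    "load_config",
    "spawn_seeds",
]

#: cell values (after stripping) treated as missing on read
NA_MARKERS = {"", "NA", "NaN", "nan"}


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ConfigError(ValueError):
    """A configuration value or key is invalid."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class OmicsMatrix:
    """Rectangular numeric matrix (genes or metabolites × samples).

    Missing values are encoded as NaN in ``data``; :attr:`mask` exposes them
    as a boolean array.  Row and column identifiers must be unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate row identifiers: {dup}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate column identifiers: {dup}")
        # enforce a float matrix so the NaN mask is well defined
        self.data = self.data.astype(float)

    # -- basic views --------------------------------------------------------
    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the entry is missing."""
        return self.data.isna().to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def is_complete(self) -> bool:
        return not bool(self.data.isna().to_numpy().any())

    def subset_rows(self, ids: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.data.loc[list(ids)])

    def subset_cols(self, ids: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.data.loc[:, list(ids)])


@dataclass
class AnnotationTable:
    """Flat (gene_id, term_id, evidence_code) records, deduplicated on load."""

    records: pd.DataFrame

    COLUMNS = ("gene_id", "term_id", "evidence_code")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.records.columns]
        if missing:
            raise FormatError(f"annotation table lacks columns: {missing}")
        rec = self.records.loc[:, list(self.COLUMNS)].astype(str)
        if (rec["evidence_code"].str.len() == 0).any():
            raise FormatError("empty evidence code in annotation table")
        self.records = rec.drop_duplicates(ignore_index=True)

    def terms(self) -> list[str]:
        return sorted(self.records["term_id"].unique())

    def for_term(self, term_id: str) -> pd.DataFrame:
        return self.records[self.records["term_id"] == term_id]


# ---------------------------------------------------------------------------
# matrix TSV/CSV
# ---------------------------------------------------------------------------


def _sniff_sep(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_matrix(path: str | Path) -> OmicsMatrix:
    """Read a row-ID × sample matrix from TSV (or CSV, sniffed from header).

    First column holds row identifiers, header holds sample identifiers.
    Empty cells and ``NA``/``NaN`` mark missing values.  Ragged rows,
    duplicate identifiers, and non-numeric cells raise :class:`FormatError`
    with the offending line number.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise FormatError(f"{path}: empty file")
        sep = _sniff_sep(first)
        fh.seek(0)
        reader = csv.reader(fh, delimiter=sep)
        header = next(reader)
        n_cols = len(header)
        if n_cols < 2:
            raise FormatError(f"{path}: header has no sample columns")
        col_ids = [c.strip() for c in header[1:]]
        row_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, rec in enumerate(reader, start=2):
            if not rec or (len(rec) == 1 and not rec[0].strip()):
                continue  # trailing blank line
            if len(rec) != n_cols:
                raise FormatError(
                    f"{path}: line {lineno}: expected {n_cols} fields, got {len(rec)}"
                )
            row_ids.append(rec[0].strip())
            vals = []
            for j, cell in enumerate(rec[1:], start=2):
                cell = cell.strip()
                if cell in NA_MARKERS:
                    vals.append(math.nan)
                else:
                    try:
                        vals.append(float(cell))
                    except ValueError:
                        raise FormatError(
                            f"{path}: line {lineno}, field {j}: "
                            f"non-numeric value {cell!r}"
                        ) from None
            rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    seen: set[str] = set()
    for rid in row_ids:
        if rid in seen:
            raise FormatError(f"{path}: duplicate row identifier {rid!r}")
        seen.add(rid)
    frame = pd.DataFrame(rows, index=row_ids, columns=col_ids, dtype=float)
    return OmicsMatrix(frame)


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with ``NA`` for missing entries (lossless)."""
    matrix.data.to_csv(Path(path), sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read GMT: one set per line as ``name <tab> description <tab> genes...``."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT line needs name, description "
                    f"and at least one gene (got {len(parts)} fields)"
                )
            name = parts[0].strip()
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            genes = {g.strip() for g in parts[2:] if g.strip()}
            if not genes:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} is empty")
            sets[name] = genes
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return sets


def write_gene_sets(
    sets: Mapping[str, Iterable[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    descriptions = descriptions or {}
    with Path(path).open("w") as fh:
        for name, genes in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a flat TSV of (gene_id, term_id, evidence_code) records.

    An optional header line naming exactly those columns is skipped.
    """
    path = Path(path)
    recs: list[tuple[str, str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = [p.strip() for p in line.split("\t")]
            if lineno == 1 and tuple(parts) == AnnotationTable.COLUMNS:
                continue
            if len(parts) != 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected 3 tab-separated fields, "
                    f"got {len(parts)}"
                )
            if not parts[2]:
                raise FormatError(f"{path}: line {lineno}: empty evidence code")
            recs.append(tuple(parts))  # type: ignore[arg-type]
    if not recs:
        raise FormatError(f"{path}: no annotation records")
    return AnnotationTable(pd.DataFrame(recs, columns=list(AnnotationTable.COLUMNS)))


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    table.records.to_csv(Path(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# prediction tables
# ---------------------------------------------------------------------------

PREDICTION_COLUMNS = ["gene_id", "mean_prob", "se", "n_models", "class_at_threshold"]


def write_predictions(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a prediction report TSV preserving 12 significant digits."""
    missing = [c for c in PREDICTION_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"prediction table lacks columns: {missing}")
    out = frame.loc[:, PREDICTION_COLUMNS]
    out.to_csv(Path(path), sep="\t", index=False, float_format="%.12g")


def read_predictions(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(Path(path), sep="\t")
    missing = [c for c in PREDICTION_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: prediction table lacks columns: {missing}")
    return frame


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Resolved settings for one classification run.

    Defaults follow the framework's standard operating point: 30% missingness
    cut, k=5 imputation, alpha=0.05 correlation significance, PC-feature
    variants of 5/14/30/50, 100 bootstrap negative samplings with five-fold
    cross-validation, a 0.75 confusion-matrix threshold, a 0.80 candidate
    gate, and a 0.6/0.4 confident-annotation band.
    """

    term: str = "term"
    algorithm: str = "random_forest"
    pc_counts: tuple[int, ...] = (5, 14, 30, 50)
    hybrid: bool = True
    knowledge: str | None = None
    metabolites: tuple[str, ...] = ()
    n_bootstrap: int = 100
    n_folds: int = 5
    alpha: float = 0.05
    knn_k: int = 5
    max_missing: float = 0.30
    confusion_threshold: float = 0.75
    gate_threshold: float = 0.80
    confident_upper: float = 0.6
    confident_lower: float = 0.4
    variance_targets: tuple[float, ...] = (0.93, 0.95, 0.97, 0.98)
    spearman_dof: int | None = None  # None = n-2; set 2 for the literal reading
    scale_axis: str = "gene"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.max_missing < 1:
            raise ConfigError(f"max_missing must be in (0,1), got {self.max_missing}")
        for name in ("alpha", "confusion_threshold", "gate_threshold",
                     "confident_upper", "confident_lower"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must be in (0,1), got {v}")
        if self.confident_lower >= self.confident_upper:
            raise ConfigError("confident_lower must be below confident_upper")
        self.pc_counts = tuple(int(c) for c in self.pc_counts)
        if any(b <= a for a, b in zip(self.pc_counts, self.pc_counts[1:])):
            raise ConfigError(f"pc_counts must be strictly increasing: {self.pc_counts}")
        if not self.pc_counts or min(self.pc_counts) < 1:
            raise ConfigError("pc_counts must contain positive counts")
        if self.n_bootstrap < 1:
            raise ConfigError("n_bootstrap must be >= 1")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if self.knn_k < 1:
            raise ConfigError("knn_k must be >= 1")
        if self.scale_axis not in ("gene", "sample"):
            raise ConfigError(f"scale_axis must be 'gene' or 'sample', got {self.scale_axis}")
        self.metabolites = tuple(self.metabolites)
        self.variance_targets = tuple(float(t) for t in self.variance_targets)

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; unknown keys are an error."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"{path}: unknown configuration keys: {unknown}")
    for key in ("pc_counts", "metabolites", "variance_targets"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from one master seed.

    Uses NumPy's seed-sequence machinery so any single bootstrap or model is
    reproducible in isolation from (master_seed, index).
    """
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]
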