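"""Expression containers and I/O.

The pipeline's central object is a genes × cells (or genes × conditions)
real-valued matrix.  Single-cell values are on a log2-expression-above-
detection-limit scale where 0 encodes "undetected"; condition-level values
are FPKM.  Raw single-cell qPCR data arrive as cycle-threshold (Ct)
matrices and are converted here to the normalized scale used by every
downstream stage.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ExpressionMatrix",
    "CtMatrix",
    "GeneAnnotation",
    "NormalizedCt",
    "read_expression_table",
    "read_expression_mtx",
    "write_expression_table",
    "normalize_ct",
    "write_report",
    "CATEGORIES",
]

CATEGORIES = ("cytokine", "surface_receptor", "transcription_factor", "other")

#: JSON/TSV reports round floats to this many significant digits so that a
#: write → read cycle reproduces values bit-identically at that precision.
REPORT_PRECISION = 10


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Rectangular genes × cells expression matrix with per-cell metadata.

    Parameters
    ----------
    gene_ids, cell_ids
        Unique row / column identifiers.
    values
        Non-negative float matrix, shape ``(len(gene_ids), len(cell_ids))``.
    cell_meta
        Optional per-cell metadata, e.g. ``{"cell7": {"gate_label": "G4P",
        "generation": 4}}``.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    cell_meta: dict[str, dict[str, Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"cell {self.cell_ids[bad[1]]!r}"
            )
        if (self.values < 0).any():
            bad = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative expression at gene {self.gene_ids[bad[0]]!r}, "
                f"cell {self.cell_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, cell_meta: dict[str, dict[str, Any]] | None = None
    ) -> "ExpressionMatrix":
        return cls(
            gene_ids=list(map(str, frame.index)),
            cell_ids=list(map(str, frame.columns)),
            values=frame.to_numpy(dtype=float),
            cell_meta=cell_meta or {},
        )

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index(gene)]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        idx = [self.gene_index(g) for g in genes]
        return ExpressionMatrix(genes, list(self.cell_ids), self.values[idx], dict(self.cell_meta))


@dataclass
class CtMatrix:
    """Raw qPCR cycle-threshold matrix; NaN is the undetected sentinel."""

    gene_ids: list[str]
    cell_ids: list[str]
    ct: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.ct = np.asarray(self.ct, dtype=float)
        if self.ct.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("Ct matrix shape does not match identifier lists")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        detected = ~np.isnan(self.ct)
        if np.isinf(self.ct).any():
            raise ValueError("infinite Ct value; use NaN as the undetected sentinel")
        if (self.ct[detected] <= 0).any():
            raise ValueError("detected Ct values must be > 0 cycles")

    @property
    def detected(self) -> np.ndarray:
        return ~np.isnan(self.ct)


class NormalizedCt(NamedTuple):
    matrix: ExpressionMatrix
    n_undetected: int


def normalize_ct(ct: CtMatrix, lod_ct: float = 28.0) -> NormalizedCt:
    """Convert Ct values to log2 expression above the limit of detection.

    Uses the standard single-cell qPCR transform ``e = max(0, LOD − Ct)``:
    one PCR cycle is one doubling, so expression is measured in log2 units
    above the detection limit.  Undetected entries (NaN sentinel) map to 0.

    Returns the normalized :class:`ExpressionMatrix` together with the
    number of undetected entries that were zero-filled.
    """
    if lod_ct <= 0:
        raise ValueError("lod_ct must be positive")
    detected = ct.detected
    if (ct.ct[detected] > lod_ct).any():
        warnings.warn(
            "detected Ct values above the limit of detection were clipped to 0 expression",
            stacklevel=2,
        )
    expr = np.where(detected, np.maximum(0.0, lod_ct - ct.ct), 0.0)
    matrix = ExpressionMatrix(list(ct.gene_ids), list(ct.cell_ids), expr)
    return NormalizedCt(matrix=matrix, n_undetected=int((~detected).sum()))


class GeneAnnotation:
    """Gene → functional category map (case-insensitive lookup).

    Categories are the screen's reporting bins: ``cytokine``,
    ``surface_receptor``, ``transcription_factor``; unannotated genes fall
    back to ``other``.  An optional per-gene ``is_suppressor`` flag marks
    genes with documented immunosuppressive roles.
    """

    def __init__(
        self,
        categories: Mapping[str, str] | None = None,
        is_suppressor: Mapping[str, bool] | None = None,
    ):
        self._cat: dict[str, str] = {}
        self._sup: dict[str, bool] = {}
        for gene, cat in (categories or {}).items():
            if cat not in CATEGORIES:
                raise ValueError(
                    f"unknown category {cat!r} for gene {gene!r}; expected one of {CATEGORIES}"
                )
            self._cat[gene.lower()] = cat
        for gene, flag in (is_suppressor or {}).items():
            self._sup[gene.lower()] = bool(flag)

    def category(self, gene: str) -> str:
        return self._cat.get(gene.lower(), "other")

    def is_suppressor(self, gene: str) -> bool:
        return self._sup.get(gene.lower(), False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneAnnotation":
        """Read a TSV with columns gene, category[, is_suppressor]."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"gene", "category"}
        if not required.issubset(df.columns):
            raise ValueError(f"annotation table must have columns {sorted(required)}")
        sup = {}
        if "is_suppressor" in df.columns:
            sup = {
                g: str(v).strip().lower() in {"1", "true", "yes"}
                for g, v in zip(df["gene"], df["is_suppressor"])
            }
        return cls(dict(zip(df["gene"], df["category"])), sup)


def _sniff_sep(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    head = path.read_text().splitlines()[0] if path.stat().st_size else ""
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_expression_table(
    path: str | Path,
    layout: str = "genes_in_rows",
    delimiter: str | None = None,
    cell_meta: dict[str, dict[str, Any]] | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression table into an :class:`ExpressionMatrix`.

    ``layout`` declares whether rows are genes (default) or cells; the
    returned matrix is always genes × cells.  Empty or non-numeric body
    cells are hard errors that name their coordinates — silent imputation
    would corrupt downstream rank statistics.
    """
    path = Path(path)
    if layout not in {"genes_in_rows", "cells_in_rows"}:
        raise ValueError("layout must be 'genes_in_rows' or 'cells_in_rows'")
    sep = _sniff_sep(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.map(str)
    _check_unique(list(df.index), "row")
    _check_unique(list(df.columns), "column")
    numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raw = df.iat[r, c]
        kind = "empty cell" if (pd.isna(raw) or str(raw).strip() == "") else f"non-numeric cell {raw!r}"
        raise ValueError(f"{kind} at row {df.index[r]!r}, column {df.columns[c]!r} in {path}")
    if layout == "cells_in_rows":
        numeric = numeric.T
    return ExpressionMatrix.from_frame(numeric, cell_meta=cell_meta)


def read_expression_mtx(
    mtx_path: str | Path, genes_path: str | Path, cells_path: str | Path
) -> ExpressionMatrix:
    """Read MatrixMarket coordinate input with gene/cell id sidecar files.

    Entries absent from the triplet file are zeros by format convention.
    """
    genes = [line.strip() for line in Path(genes_path).read_text().splitlines() if line.strip()]
    cells = [line.strip() for line in Path(cells_path).read_text().splitlines() if line.strip()]
    mat = scipy.io.mmread(str(mtx_path))
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    return ExpressionMatrix(genes, cells, dense)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a genes × cells TSV (floats at report precision)."""
    frame = matrix.to_frame().map(lambda v: _round_sig(v))
    frame.to_csv(path, sep="\t", float_format=f"%.{REPORT_PRECISION}g")


def _round_sig(x: Any) -> Any:
    if isinstance(x, (float, np.floating)):
        if math.isnan(x) or math.isinf(x):
            return float(x)
        return float(f"{float(x):.{REPORT_PRECISION}g}")
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, np.ndarray):
        return [_round_sig(v) for v in x.tolist()]
    if isinstance(x, dict):
        return {k: _round_sig(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round_sig(v) for v in x]
    if isinstance(x, (np.bool_,)):
        return bool(x)
    return x


def write_report(result: Any, stem: str | Path) -> tuple[Path, Path]:
    """Serialize a pipeline result to ``<stem>.json`` and ``<stem>.tsv``.

    The object must expose ``to_records()`` (list of flat dicts, the TSV
    twin) and may expose ``to_summary()`` (scalar fields included in the
    JSON).  Field order is deterministic and floats are rounded to a fixed
    number of significant digits so reload reproduces values exactly at
    that precision.  Zeros are preserved as 0, never null.
    """
    stem = Path(stem)
    if hasattr(result, "to_records"):
        records = result.to_records()
    elif isinstance(result, list):
        records = result
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}: no to_records()")
    records = [_round_sig(dict(r)) for r in records]
    payload: dict[str, Any] = {}
    if hasattr(result, "to_summary"):
        payload.update(_round_sig(result.to_summary()))
    payload["records"] = records
    stem.parent.mkdir(parents=True, exist_ok=True)
    json_path = stem.with_suffix(".json")
    tsv_path = stem.with_suffix(".tsv")
    try:
        json_path.write_text(json.dumps(payload, indent=1, sort_keys=False) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write report to {json_path}: {exc}") from exc
    if records:
        pd.DataFrame.from_records(records).to_csv(tsv_path, sep="\t", index=False)
    else:
        tsv_path.write_text("")
    return json_path, tsv_path
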