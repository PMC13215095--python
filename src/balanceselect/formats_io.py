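"""Readers, writers and validated containers for every external format the
toolkit touches.

Three containers travel through the whole pipeline:

* :class:`ExpressionMatrix` — a genes x samples numeric matrix with a
  two-level sample labelling (one "case" class such as tumor, one "control"
  class such as normal tissue).
* :class:`GeneSetCollection` — named gene sets, the in-memory form of a GMT
  file (Broad/MSigDB dialect: name, free-text description, member ids).
* :class:`DETable` — a per-gene differential-expression result table
  (gene, logFC, p, adjusted p) either computed internally or adapted from
  an external tool's export.

Gene identifiers are opaque, case-sensitive strings; no symbol/accession
conversion is attempted. Loading is strict: duplicate ids, non-numeric
cells, missing class labels and ambiguous delimiters are errors, never
silently repaired.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "DETable",
    "FormatError",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_de_table",
    "write_de_table",
    "write_report",
]

#: sample-class labels that are recognised as the "case" class when the
#: caller does not designate one explicitly.
_CASE_CONVENTIONS = ("case", "tumor", "tumour", "disease")


class FormatError(ValueError):
    """Raised for any malformed or inconsistent external input."""


def _detect_delimiter(first_line: str) -> str:
    has_tab = "\t" in first_line
    has_comma = "," in first_line
    if has_tab and has_comma:
        raise FormatError(
            "ambiguous delimiter: header contains both tabs and commas"
        )
    if has_tab:
        return "\t"
    if has_comma:
        return ","
    raise FormatError("could not detect delimiter (expected tab or comma)")


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A validated two-class expression matrix.

    Parameters
    ----------
    values
        DataFrame with gene ids as index and sample ids as columns. All
        entries must be finite numbers.
    classes
        Mapping (as a Series indexed by sample id) from sample id to one of
        exactly two class labels; every class must have >= 2 samples.
    case_label, control_label
        Which of the two labels plays the "case" (e.g. tumor) and
        "control" (e.g. normal) role.
    scale
        Free-text tag recording the user-declared scale of the values
        (e.g. "log2-normalized", "tpm"); not interpreted.
    """

    values: pd.DataFrame
    classes: pd.Series
    case_label: str
    control_label: str
    scale: str = "unspecified"

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene id(s): {dups}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample id(s): {dups}")
        if any(not g for g in v.index) or any(not s for s in v.columns):
            raise FormatError("empty gene or sample identifier")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric cell in expression matrix")
        if not np.isfinite(arr).all():
            raise FormatError("expression matrix contains NaN/Inf")
        missing = [s for s in v.columns if s not in self.classes.index]
        if missing:
            raise FormatError(f"sample(s) missing from class map: {missing}")
        self.classes = self.classes.loc[list(v.columns)].astype(str)
        labels = sorted(self.classes.unique())
        if len(labels) != 2:
            raise FormatError(
                f"expected exactly two classes, got {len(labels)}: {labels}"
            )
        if {self.case_label, self.control_label} != set(labels):
            raise FormatError(
                f"case/control labels {self.case_label!r}/{self.control_label!r} "
                f"do not match observed labels {labels}"
            )
        counts = self.classes.value_counts()
        if (counts < 2).any():
            raise FormatError("each class needs >= 2 samples")

    # -- convenience views --------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def case_mask(self) -> np.ndarray:
        return (self.classes == self.case_label).to_numpy()

    @property
    def n_case(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_control(self) -> int:
        return int((~self.case_mask).sum())

    @property
    def X(self) -> np.ndarray:
        """Samples x genes array (sklearn orientation)."""
        return self.values.to_numpy().T

    @property
    def y(self) -> np.ndarray:
        """Binary class vector aligned with :attr:`X`; 1 = case."""
        return self.case_mask.astype(int)

    def case_values(self, gene_id: str) -> np.ndarray:
        return self.values.loc[gene_id].to_numpy()[self.case_mask]

    def control_values(self, gene_id: str) -> np.ndarray:
        return self.values.loc[gene_id].to_numpy()[~self.case_mask]

    def subset(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"gene(s) not in matrix: {missing}")
        return ExpressionMatrix(
            values=self.values.loc[list(gene_ids)].copy(),
            classes=self.classes.copy(),
            case_label=self.case_label,
            control_label=self.control_label,
            scale=self.scale,
        )

    def swap_labels(self) -> "ExpressionMatrix":
        """Return a copy with the case/control roles exchanged."""
        return ExpressionMatrix(
            values=self.values.copy(),
            classes=self.classes.copy(),
            case_label=self.control_label,
            control_label=self.case_label,
            scale=self.scale,
        )


def read_expression(
    path: str | Path,
    class_map_path: str | Path,
    case_label: str | None = None,
    scale: str = "unspecified",
) -> ExpressionMatrix:
    """Load an expression TSV/CSV (genes in rows, first column = gene id)
    together with a two-column sample -> class map.

    ``case_label`` designates the case class; if omitted, a label matching a
    common convention ("case", "tumor", ...) is used, otherwise an explicit
    designation is required.
    """
    path, class_map_path = Path(path), Path(class_map_path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise FormatError(f"{path}: empty file")
    sep = _detect_delimiter(header.rstrip("\n"))
    df = pd.read_csv(path, sep=sep, index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise FormatError(f"{path}: duplicate gene id(s): {dups}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from None

    with open(class_map_path) as fh:
        cheader = fh.readline()
    if not cheader.strip():
        raise FormatError(f"{class_map_path}: empty file")
    csep = _detect_delimiter(cheader.rstrip("\n"))
    cmap = pd.read_csv(class_map_path, sep=csep, dtype=str)
    if cmap.shape[1] < 2:
        raise FormatError(f"{class_map_path}: expected two columns")
    classes = pd.Series(
        cmap.iloc[:, 1].values, index=cmap.iloc[:, 0].values, dtype=str
    )
    labels = sorted(set(classes))
    if len(labels) != 2:
        raise FormatError(
            f"expected exactly two classes, got {len(labels)}: {labels}"
        )
    if case_label is None:
        conventional = [l for l in labels if l.lower() in _CASE_CONVENTIONS]
        if len(conventional) != 1:
            raise FormatError(
                f"cannot infer which of {labels} is the case class; "
                "pass case_label explicitly"
            )
        case_label = conventional[0]
    if case_label not in labels:
        raise FormatError(f"case label {case_label!r} not among {labels}")
    control_label = next(l for l in labels if l != case_label)
    return ExpressionMatrix(
        values=df, classes=classes, case_label=case_label,
        control_label=control_label, scale=scale,
    )


def write_expression(
    matrix: ExpressionMatrix, path: str | Path, class_map_path: str | Path
) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")
    pd.DataFrame(
        {"sample_id": matrix.sample_ids,
         "label": matrix.classes.loc[matrix.sample_ids].values}
    ).to_csv(class_map_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GeneSetCollection (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets: mapping set name -> (description, member list)."""

    sets: dict[str, tuple[str, list[str]]]
    collection_label: str = "custom"

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} has no members")
            if len(set(members)) != len(members):
                raise FormatError(f"gene set {name!r} members not deduplicated")

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, collection_label: str | None = None) -> GeneSetCollection:
    """Parse a GMT file (tab-separated: name, description, member ids).

    Member lists are deduplicated preserving first occurrence; lines with
    fewer than three fields and duplicate set names are errors.
    """
    path = Path(path)
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    if not lines:
        raise FormatError(f"{path}: empty GMT file")
    for i, line in enumerate(lines, 1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{i}: expected >= 3 tab-separated fields")
        name, desc, *members = fields
        if name in sets:
            raise FormatError(f"{path}:{i}: duplicate set name {name!r}")
        deduped = list(dict.fromkeys(m for m in members if m))
        if not deduped:
            raise FormatError(f"{path}:{i}: set {name!r} has no members")
        sets[name] = (desc, deduped)
    return GeneSetCollection(
        sets=sets, collection_label=collection_label or path.stem
    )


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# DETable
# ---------------------------------------------------------------------------

_DE_COLUMNS = ["gene_id", "logfc", "pvalue", "padj"]


@dataclass
class DETable:
    """Per-gene differential-expression results from one method."""

    table: pd.DataFrame  # columns gene_id, logfc, pvalue, padj (+ extras)
    method_label: str = "unknown"

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _DE_COLUMNS if c not in t.columns]
        if missing:
            raise FormatError(f"DE table missing column(s): {missing}")
        if len(t) == 0:
            raise FormatError("DE table has no rows")
        if t["gene_id"].duplicated().any():
            dups = sorted(t.loc[t["gene_id"].duplicated(), "gene_id"].unique())
            raise FormatError(f"duplicate gene id(s) in DE table: {dups}")
        for col in ("pvalue", "padj"):
            vals = t[col].to_numpy(dtype=float)
            if ((vals < 0) | (vals > 1)).any() or np.isnan(vals).any():
                raise FormatError(f"{col} outside [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])

    def significant(self, alpha: float = 0.05, lfc_min: float = 1.0) -> list[str]:
        """Genes with padj < alpha and |logFC| > lfc_min."""
        t = self.table
        mask = (t["padj"] < alpha) & (t["logfc"].abs() > lfc_min)
        return list(t.loc[mask, "gene_id"])


def read_de_table(
    path: str | Path,
    method_label: str,
    column_map: Mapping[str, str] | str | Path | None = None,
) -> DETable:
    """Adapt an externally produced DE result table into a :class:`DETable`.

    ``column_map`` maps canonical names (gene_id, logfc, pvalue, padj) to the
    file's column names; it may be a dict or a path to a YAML/JSON file.
    Columns already canonically named need no mapping.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise FormatError(f"{path}: empty file")
    sep = _detect_delimiter(header.rstrip("\n"))
    df = pd.read_csv(path, sep=sep)
    if len(df) == 0:
        raise FormatError(f"{path}: no rows")
    if isinstance(column_map, (str, Path)):
        text = Path(column_map).read_text()
        column_map = yaml.safe_load(text)
    column_map = dict(column_map or {})
    rename = {v: k for k, v in column_map.items()}
    df = df.rename(columns=rename)
    missing = [c for c in _DE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: cannot map required column(s) {missing}; "
            f"available: {list(df.columns)}"
        )
    df = df[_DE_COLUMNS].copy()
    df["gene_id"] = df["gene_id"].astype(str)
    return DETable(table=df, method_label=method_label)


def write_de_table(table: DETable, path: str | Path) -> None:
    table.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def write_report(
    frame: pd.DataFrame, summary: Mapping, tsv_path: str | Path, json_path: str | Path
) -> None:
    """Write a result table as TSV plus a machine-readable JSON summary."""
    frame.to_csv(tsv_path, sep="\t", index=False)
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
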