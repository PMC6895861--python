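"""Readers and writers for the pipeline's tabular formats.

Formats: TSV expression matrix (gene-id first column, sample header row),
Broad-dialect GMT gene sets (name TAB description TAB gene...), TSV sample
annotations, TSV score tables and JSON statistics reports.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    GeneSet,
    ScoreTable,
    SignatureDefinition,
    validate_annotations,
    validate_expression_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_sets_gmt",
    "write_gene_sets_gmt",
    "read_annotations",
    "write_annotations",
    "write_score_table",
    "write_json",
]

_DUP_POLICIES = ("mean", "max", "first")


def read_expression_matrix(
    path: str | Path,
    delimiter: str = "\t",
    duplicate_policy: str = "mean",
) -> pd.DataFrame:
    """Read a genes x samples abundance matrix from a delimited text file.

    The first column holds gene identifiers and the header row holds sample
    identifiers. Duplicate gene rows are collapsed according to
    ``duplicate_policy`` ("mean" default, "max" or "first") with a logged
    warning. Non-numeric cells, negative or missing values, and matrices with
    fewer than two samples raise ``ValueError``.
    """
    if duplicate_policy not in _DUP_POLICIES:
        raise ValueError(
            f"duplicate_policy must be one of {_DUP_POLICIES}, got {duplicate_policy!r}"
        )
    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    expr = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad][0]
            raise ValueError(
                f"non-numeric value {raw.loc[gene, col]!r} at gene {gene!r}, "
                f"sample {col!r} in {path}"
            )
        expr[col] = converted
    if expr.index.duplicated().any():
        dup_genes = expr.index[expr.index.duplicated()].unique().tolist()
        logger.warning(
            "collapsing %d duplicated gene id(s) by %s: %s",
            len(dup_genes),
            duplicate_policy,
            dup_genes[:5],
        )
        expr = collapse_duplicate_genes(expr, policy=duplicate_policy)
    return validate_expression_matrix(expr)


def collapse_duplicate_genes(expr: pd.DataFrame, policy: str = "mean") -> pd.DataFrame:
    """Collapse duplicate gene rows, preserving first-appearance order."""
    if policy not in _DUP_POLICIES:
        raise ValueError(f"unknown duplicate policy {policy!r}")
    if policy == "first":
        out = expr[~expr.index.duplicated(keep="first")]
    else:
        grouped = expr.groupby(level=0, sort=False)
        out = grouped.mean() if policy == "mean" else grouped.max()
        out = out.loc[expr.index.drop_duplicates()]
    return out


def write_expression_matrix(
    expr: pd.DataFrame, path: str | Path, delimiter: str = "\t"
) -> None:
    expr.to_csv(path, sep=delimiter, index_label="gene_id")


def read_gene_sets_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a Broad-dialect GMT file.

    Each line is ``name TAB description TAB gene [TAB gene ...]``; the
    description is discarded. Duplicate genes within a set are dropped (order
    preserved) with a logged warning; a line with fewer than three fields is a
    format error reported with its line number.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields "
                    f"(name, description, genes), got {len(fields)}"
                )
            name, _description, *genes = fields
            genes = [g for g in genes if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                logger.warning(
                    "%s:%d: gene set %r contains %d duplicate gene(s); dropped",
                    path,
                    lineno,
                    name,
                    len(genes) - len(unique),
                )
            sets.append(GeneSet(name=name, genes=tuple(unique)))
    return sets


def write_gene_sets_gmt(
    gene_sets: Iterable[GeneSet], path: str | Path, description: str = "na"
) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, description, *gs.genes]) + "\n")


def signatures_to_gene_sets(sigs: Sequence[SignatureDefinition]) -> list[GeneSet]:
    """Flatten signatures to GMT-writable gene sets (``<name>_up`` / ``_down``)."""
    out: list[GeneSet] = []
    for sig in sigs:
        out.append(GeneSet(name=f"{sig.name}_up", genes=sig.up_set.genes))
        if sig.down_set is not None:
            out.append(GeneSet(name=f"{sig.name}_down", genes=sig.down_set.genes))
    return out


def gene_sets_to_signatures(gene_sets: Sequence[GeneSet]) -> list[SignatureDefinition]:
    """Pair ``<name>_up`` / ``<name>_down`` gene sets back into signatures.

    Sets without an ``_up``/``_down`` suffix become one-sided signatures.
    """
    by_name = {gs.name: gs for gs in gene_sets}
    sigs: list[SignatureDefinition] = []
    consumed: set[str] = set()
    for gs in gene_sets:
        if gs.name in consumed:
            continue
        if gs.name.endswith("_up"):
            base = gs.name[: -len("_up")]
            down = by_name.get(f"{base}_down")
            consumed.add(gs.name)
            if down is not None:
                consumed.add(down.name)
            sigs.append(
                SignatureDefinition(
                    name=base,
                    up_set=GeneSet(name=f"{base}_up", genes=gs.genes),
                    down_set=down,
                )
            )
        elif gs.name.endswith("_down"):
            base = gs.name[: -len("_down")]
            if f"{base}_up" in by_name:
                continue  # paired by the _up branch
            consumed.add(gs.name)
            sigs.append(SignatureDefinition(name=base, up_set=gs, down_set=None))
        else:
            consumed.add(gs.name)
            sigs.append(SignatureDefinition(name=gs.name, up_set=gs, down_set=None))
    return sigs


def read_annotations(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a sample-annotation table (must contain a ``sample_id`` column)."""
    ann = pd.read_csv(path, sep=delimiter)
    if "sample_id" not in ann.columns:
        raise ValueError(f"{path}: annotation table must have a 'sample_id' column")
    ann = ann.set_index("sample_id")
    ann.index = ann.index.astype(str)
    return validate_annotations(ann)


def write_annotations(ann: pd.DataFrame, path: str | Path, delimiter: str = "\t") -> None:
    ann.to_csv(path, sep=delimiter, index_label="sample_id")


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    """Write scores as TSV with a per-signature coverage sidecar JSON."""
    path = Path(path)
    table.scores.to_csv(path, sep="\t", index_label="sample_id")
    sidecar = path.with_suffix(path.suffix + ".coverage.json")
    write_json({"coverage": table.coverage.round(6).to_dict()}, sidecar)


def write_json(obj: object, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj: object) -> object:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    if isinstance(obj, (pd.Series,)):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")
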