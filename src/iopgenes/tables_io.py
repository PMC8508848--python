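"""Readers/writers for the tabular evidence formats and the packaged fixtures.

Every evidence table is plain TSV (UTF-8, header row required); CSV is
accepted through the ``delimiter`` argument. Missing cells are the literal
``NA`` (any of ``NA``/``na``/empty accepted on read) and are written back as
``NA``. Expression rows that list several contexts in one cell
("TM, SC" with two FPKM values) are exploded into one record per context.
"""

from __future__ import annotations

import logging
import math
import warnings
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .records import (
    ClusterExpressionRecord,
    ConcentrationRecord,
    DifferentialExpressionRecord,
    ExpressionEvidenceRecord,
    GroupedExpressionMatrix,
    VariantAnnotationRecord,
    normalize_symbol,
)

logger = logging.getLogger(__name__)

SCHEMAS = {
    "de": ("gene", "fold_change", "p_value"),
    "expression": ("gene", "context", "fpkm"),
    "ocular_db": ("gene", "context", "plier", "dabg_avg", "dabg_range"),
    "variant": ("snp", "gene", "histone_modification", "enhancer_or_promoter", "eqtl_tissues"),
    "cluster": ("gene", "cluster", "median_expression"),
    "concentration": ("label", "nm", "nm_sd", "pg_per_ml", "pg_per_ml_sd", "n"),
}

_MISSING = {"", "na", "nan"}

FIXTURE_ROW_COUNTS = {
    # printed-table row counts; tables 3-5 explode to more records (multi-
    # context cells / one row per tissue column)
    "table1": 10,
    "table2": 17,
    "table3": 24,
    "table4": 24,
    "table5": 24,
    "table6": 15,
    "table7": 4,
    "table9": 4,
}

_FIXTURE_SCHEMA = {
    "table1": "de",
    "table2": "de",
    "table3": "expression",
    "table4": "ocular_db",
    "table5": "expression",
    "table6": "variant",
    "table7": "de",
    "table9": "concentration",
}


class SchemaError(ValueError):
    """Raised when a file's header does not match the requested schema."""


class RowError(ValueError):
    """Raised when a data cell cannot be parsed; carries the 1-based line."""

    def __init__(self, line: int, message: str) -> None:
        super().__init__(f"line {line}: {message}")
        self.line = line


def _is_missing(cell: object) -> bool:
    if cell is None:
        return True
    if isinstance(cell, float) and math.isnan(cell):
        return True
    return str(cell).strip().lower() in _MISSING


def _parse_float(cell: object, line: int, column: str) -> Optional[float]:
    if _is_missing(cell):
        return None
    try:
        return float(str(cell).strip())
    except ValueError as exc:
        raise RowError(line, f"unparseable numeric cell {cell!r} in column {column!r}") from exc


def _parse_bool(cell: object, line: int, column: str) -> bool:
    text = str(cell).strip().lower()
    if text in {"yes", "true", "1"}:
        return True
    if text in {"no", "false", "0"}:
        return False
    raise RowError(line, f"unparseable boolean cell {cell!r} in column {column!r}")


def _read_frame(path: Union[str, Path], schema: str, delimiter: str = "\t") -> pd.DataFrame:
    if schema not in SCHEMAS and schema != "matrix":
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS) + ['matrix']}")
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    if schema != "matrix":
        for col in SCHEMAS[schema]:
            if col not in df.columns:
                raise SchemaError(f"{path}: missing required column {col!r} for schema {schema!r}")
    return df


def read_table(
    path: Union[str, Path],
    schema: str,
    delimiter: str = "\t",
):
    """Parse a tabular evidence file into typed records.

    ``schema`` is one of ``de``, ``expression``, ``ocular_db``, ``variant``,
    ``cluster``, ``concentration`` or ``matrix`` (the latter returns a
    :class:`GroupedExpressionMatrix`-ready DataFrame, see
    :func:`read_matrix`). Row order is preserved; duplicate (gene, context)
    keys in expression tables raise a warning but both rows are kept.
    """
    if schema == "matrix":
        return _read_frame(path, "matrix", delimiter)
    df = _read_frame(path, schema, delimiter)
    records: list = []
    seen_keys: set = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        row = dict(zip(df.columns, row))
        if schema == "de":
            records.append(
                DifferentialExpressionRecord(
                    gene=normalize_symbol(row["gene"]),
                    fold_change=_parse_float(row["fold_change"], i, "fold_change"),
                    p_value=_parse_float(row["p_value"], i, "p_value"),
                )
            )
        elif schema == "expression":
            records.extend(_explode_expression_row(row, i, seen_keys))
        elif schema == "ocular_db":
            records.append(_parse_ocular_row(row, i, seen_keys))
        elif schema == "variant":
            records.append(_parse_variant_row(row, i))
        elif schema == "cluster":
            med = _parse_float(row["median_expression"], i, "median_expression")
            records.append(
                ClusterExpressionRecord(
                    gene=normalize_symbol(row["gene"]),
                    cluster=str(row["cluster"]).strip(),
                    median_expression=0.0 if med is None else med,
                )
            )
        elif schema == "concentration":
            records.append(
                ConcentrationRecord(
                    label=str(row["label"]).strip(),
                    value_pg_per_ml=_parse_float(row["pg_per_ml"], i, "pg_per_ml"),
                    sd_pg_per_ml=_parse_float(row["pg_per_ml_sd"], i, "pg_per_ml_sd"),
                    n=int(row["n"]),
                    value_nm=_parse_float(row["nm"], i, "nm"),
                    sd_nm=_parse_float(row["nm_sd"], i, "nm_sd"),
                )
            )
    return records


def _warn_duplicate(key: tuple, line: int, seen: set) -> None:
    if key in seen:
        warnings.warn(f"duplicate (gene, context) key {key} at line {line}; both rows kept", stacklevel=4)
    seen.add(key)


def _explode_expression_row(row: dict, line: int, seen: set) -> list[ExpressionEvidenceRecord]:
    gene = normalize_symbol(row["gene"])
    contexts = [c.strip() for c in str(row["context"]).split(",")]
    fpkm_cell = row["fpkm"]
    if _is_missing(fpkm_cell):
        values: list[Optional[float]] = [None] * len(contexts)
    else:
        values = [_parse_float(v, line, "fpkm") for v in str(fpkm_cell).split(",")]
    if len(values) != len(contexts):
        raise RowError(line, f"{len(contexts)} contexts but {len(values)} FPKM values")
    out = []
    for ctx, val in zip(contexts, values):
        _warn_duplicate((gene, ctx), line, seen)
        out.append(ExpressionEvidenceRecord(gene=gene, context=ctx, fpkm=val))
    return out


def _parse_ocular_row(row: dict, line: int, seen: set) -> ExpressionEvidenceRecord:
    gene = normalize_symbol(row["gene"])
    ctx = str(row["context"]).strip()
    _warn_duplicate((gene, ctx), line, seen)
    rng_cell = row["dabg_range"]
    rng: Optional[tuple[float, float]] = None
    if not _is_missing(rng_cell):
        lo, hi = str(rng_cell).split("-", 1)
        rng = (float(lo), float(hi))
    return ExpressionEvidenceRecord(
        gene=gene,
        context=ctx,
        plier=_parse_float(row["plier"], line, "plier"),
        dabg_avg=_parse_float(row["dabg_avg"], line, "dabg_avg"),
        dabg_range=rng,
    )


def _parse_variant_row(row: dict, line: int) -> VariantAnnotationRecord:
    raw = str(row["eqtl_tissues"]).strip()
    tissues: tuple[str, ...] = ()
    if raw and raw.lower() not in {"none"} | _MISSING:
        tissues = tuple(t.strip() for t in raw.split(";") if t.strip())
    return VariantAnnotationRecord(
        snp=str(row["snp"]).strip(),
        gene=normalize_symbol(row["gene"]),
        histone_modification=_parse_bool(row["histone_modification"], line, "histone_modification"),
        enhancer_or_promoter=_parse_bool(row["enhancer_or_promoter"], line, "enhancer_or_promoter"),
        eqtl_tissues=tissues,
    )


def write_table(records: Sequence, schema: str, path: Union[str, Path], delimiter: str = "\t") -> None:
    """Write typed records back to disk; round-trips with :func:`read_table`."""
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    cols = SCHEMAS[schema]
    rows = []
    for rec in records:
        if schema == "de":
            rows.append((rec.gene, _fmt(rec.fold_change), _fmt(rec.p_value)))
        elif schema == "expression":
            rows.append((rec.gene, rec.context, _fmt(rec.fpkm)))
        elif schema == "ocular_db":
            rng = "NA" if rec.dabg_range is None else f"{_fmt(rec.dabg_range[0])}-{_fmt(rec.dabg_range[1])}"
            rows.append((rec.gene, rec.context, _fmt(rec.plier), _fmt(rec.dabg_avg), rng))
        elif schema == "variant":
            rows.append(
                (
                    rec.snp,
                    rec.gene,
                    "Yes" if rec.histone_modification else "No",
                    "Yes" if rec.enhancer_or_promoter else "No",
                    "; ".join(rec.eqtl_tissues) if rec.eqtl_tissues else "None",
                )
            )
        elif schema == "cluster":
            rows.append((rec.gene, rec.cluster, _fmt(rec.median_expression)))
        elif schema == "concentration":
            rows.append(
                (rec.label, _fmt(rec.value_nm), _fmt(rec.sd_nm), _fmt(rec.value_pg_per_ml), _fmt(rec.sd_pg_per_ml), str(rec.n))
            )
    pd.DataFrame(rows, columns=list(cols)).to_csv(path, sep=delimiter, index=False)


def _fmt(value: Optional[float]) -> str:
    if value is None:
        return "NA"
    return repr(value)


def load_fixture(name: str):
    """Load one of the packaged printed-table transcriptions.

    Known names: table1/table2/table7 (differential expression),
    table3/table5 (FPKM expression), table4 (ocular-database PLIER/DABG),
    table6 (variant annotation), table9 (estradiol concentrations).
    Multi-context rows are exploded, so tables 3-5 return more records than
    printed rows; :data:`FIXTURE_ROW_COUNTS` records the printed counts.
    """
    if name not in _FIXTURE_SCHEMA:
        raise KeyError(f"unknown fixture {name!r}; expected one of {sorted(_FIXTURE_SCHEMA)}")
    ref = resources.files("iopgenes.data").joinpath(f"{name}.tsv")
    with resources.as_file(ref) as path:
        return read_table(path, _FIXTURE_SCHEMA[name])


def read_matrix(
    matrix_path: Union[str, Path],
    groups_path: Union[str, Path],
    delimiter: str = "\t",
) -> GroupedExpressionMatrix:
    """Read an expression matrix TSV (first column = gene symbol) plus a
    two-column sample->group TSV into a :class:`GroupedExpressionMatrix`."""
    df = pd.read_csv(matrix_path, sep=delimiter, index_col=0)
    df.index = [normalize_symbol(g) for g in df.index]
    gmap = pd.read_csv(groups_path, sep=delimiter, dtype=str)
    gmap.columns = [c.strip().lower() for c in gmap.columns]
    if not {"sample", "group"} <= set(gmap.columns):
        raise SchemaError(f"{groups_path}: expected columns 'sample' and 'group'")
    groups = dict(zip(gmap["sample"], gmap["group"]))
    return GroupedExpressionMatrix(values=df, groups=groups)


def write_matrix(matrix: GroupedExpressionMatrix, matrix_path: Union[str, Path], groups_path: Union[str, Path]) -> None:
    matrix.values.to_csv(matrix_path, sep="\t", index_label="gene")
    pd.DataFrame(
        {"sample": list(matrix.values.columns), "group": [matrix.groups[s] for s in matrix.values.columns]}
    ).to_csv(groups_path, sep="\t", index=False)
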