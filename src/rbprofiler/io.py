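"""Readers and writers for the plain-text formats the pipeline consumes.

All tables are tab-separated.  An expression dataset is three files: an
intensity table (first column probeset id, header row of sample ids), a
detection-p table of identical shape, and a two-column probeset->gene
annotation table.  Alternatively a single table may interleave detection
columns GEO-style (headers containing "DETECTION").
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    ExpressionMatrix,
    GeneCensus,
    GroupDesign,
    PathwayDB,
    ValidationError,
    normalize_symbol,
)

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def _read_table(path: str | os.PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, dtype={0: str},
            float_precision="round_trip",
        )
    except ValueError as exc:
        raise ValidationError(f"{path}: unparseable table: {exc}") from exc
    df.index = df.index.astype(str)
    if not df.index.is_unique:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValidationError(f"{path}: duplicate probeset id(s): {dups}")
    # reject non-numeric cells with a row-numbered message
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            row = df.index.get_loc(bad[0]) + 2  # +1 header, +1 one-based
            raise ValidationError(
                f"{path}: unparseable value in column {col!r} at row {row} "
                f"(probeset {bad[0]!r})"
            )
        df[col] = coerced
    return df


def read_annotation(path: str | os.PathLike) -> pd.Series:
    """Read a two-column probeset -> gene symbol TSV (header optional)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: annotation needs two columns")
    first = str(df.iloc[0, 0]).lower()
    if first in {"probeset", "probeset_id", "probe", "id"}:
        df = df.iloc[1:]
    df = df.dropna(subset=[0, 1])
    ann = pd.Series(df[1].values, index=df[0].values, dtype=object)
    ann = ann[~ann.index.duplicated(keep="first")]
    return ann.map(normalize_symbol)


def read_expression_table(
    path: str | os.PathLike,
    annotation_path: str | os.PathLike,
    detection_path: str | os.PathLike | None = None,
) -> ExpressionMatrix:
    """Load an expression dataset into a validated :class:`ExpressionMatrix`.

    ``detection_path`` names the parallel detection-p table.  If omitted,
    ``path`` must interleave detection columns whose headers contain the
    word ``DETECTION`` (series-matrix convention).
    """
    table = _read_table(path)
    if detection_path is not None:
        intensities = table
        detection = _read_table(detection_path)
    else:
        det_cols = [c for c in table.columns if "DETECTION" in c.upper()]
        if not det_cols:
            raise ValidationError(
                f"{path}: no detection table given and no DETECTION columns found"
            )
        intensities = table[[c for c in table.columns if c not in det_cols]]
        detection = table[det_cols]
        import re
        detection.columns = [
            re.sub("(?i)detection", "", c).strip(" _.-") for c in det_cols
        ]
        detection = detection[list(intensities.columns)]
    if intensities.shape != detection.shape:
        raise ValidationError(
            "intensity/detection shape mismatch: "
            f"{intensities.shape} vs {detection.shape}"
        )
    if list(intensities.index) != list(detection.index):
        raise ValidationError("intensity and detection probeset ids differ")
    if set(intensities.columns) != set(detection.columns):
        raise ValidationError("intensity and detection sample ids differ")
    detection = detection[list(intensities.columns)]
    annotation = read_annotation(annotation_path)
    annotation = annotation[annotation.index.isin(intensities.index)]
    return ExpressionMatrix(
        intensities=intensities, detection_p=detection, annotation=annotation
    )


def write_expression_table(
    matrix: ExpressionMatrix,
    path: str | os.PathLike,
    detection_path: str | os.PathLike,
    annotation_path: str | os.PathLike,
) -> None:
    """Write the three-file representation; round-trips to full precision."""
    matrix.intensities.to_csv(
        path, sep="\t", float_format=_FLOAT_FMT, index_label="probeset_id"
    )
    matrix.detection_p.to_csv(
        detection_path, sep="\t", float_format=_FLOAT_FMT, index_label="probeset_id"
    )
    matrix.annotation.rename("gene_symbol").to_csv(
        annotation_path, sep="\t", header=False
    )


def read_group_design(
    path: str | os.PathLike,
    contrasts: list[tuple[str, str]] | None = None,
) -> GroupDesign:
    """Read a two-column (sample_id, group) TSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: group design needs two columns")
    first = str(df.iloc[0, 0]).lower()
    if first in {"sample", "sample_id"}:
        df = df.iloc[1:]
    groups = pd.Series(df[1].values, index=df[0].values, dtype=object)
    return GroupDesign(groups=groups, contrasts=contrasts or [])


def write_group_design(design: GroupDesign, path: str | os.PathLike) -> None:
    design.groups.rename("group").to_csv(path, sep="\t", header=False)


def read_gene_census(path: str | os.PathLike) -> GeneCensus:
    """Read a one-symbol-per-line (or TSV, first column) gene census.

    Symbols are uppercased and deduplicated; the number of raw lines read is
    kept so callers can report how many duplicates were collapsed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    symbols: list[str] = []
    metadata: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            sym = normalize_symbol(fields[0])
            if not sym:
                continue
            symbols.append(sym)
            if len(fields) > 1:
                metadata[sym] = {"extra": fields[1:]}
    if not symbols:
        raise ValidationError(f"{path}: empty gene census")
    return GeneCensus(
        symbols=frozenset(symbols), metadata=metadata, n_lines_read=len(symbols)
    )


def write_gene_census(census: GeneCensus, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for sym in sorted(census.symbols):
            fh.write(sym + "\n")


def read_gmt(path: str | os.PathLike) -> PathwayDB:
    """Read standard GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pathways: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: malformed GMT line {lineno} (<3 fields)"
                )
            name, desc, *genes = fields
            genes = [normalize_symbol(g) for g in genes if g.strip()]
            if not genes:
                raise ValidationError(
                    f"{path}: GMT line {lineno} ({name!r}) has no genes"
                )
            if name in pathways:
                raise ValidationError(f"{path}: duplicate pathway name {name!r}")
            pathways[name] = frozenset(genes)
            descriptions[name] = desc
    if not pathways:
        raise ValidationError(f"{path}: empty GMT file")
    return PathwayDB(pathways=pathways, descriptions=descriptions)


def write_gmt(db: PathwayDB, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, genes in db.items():
            desc = db.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")
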