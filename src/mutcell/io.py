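"""Readers and writers for the external formats the pipeline touches.

Formats: GDC-dialect MAF (tab-separated, ``#`` comment lines), GMT gene-set
collections, genes x samples / cells x samples TSV matrices, and a survival
table (sample, time, event). All text I/O is UTF-8 with '.' as the decimal
point.

TCGA sample barcodes differ in their trailing portion across assays (DNA vs
RNA aliquots), so matrices and MAF records are matched on a truncated barcode
prefix; 15 characters corresponds to the TCGA "sample" level.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

MAF_REQUIRED_COLUMNS = ("Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode")

#: TCGA sample-level barcode prefix length (project-tss-participant-sample).
DEFAULT_BARCODE_LENGTH = 15


@dataclasses.dataclass(frozen=True)
class MafRecord:
    """One somatic-variant line of a MAF file (the fields the pipeline uses)."""

    gene_symbol: str
    variant_classification: str
    sample_barcode: str

    def __post_init__(self) -> None:
        for field in ("gene_symbol", "variant_classification", "sample_barcode"):
            if not getattr(self, field):
                raise ValidationError(f"MafRecord.{field} must be non-empty")


def truncate_barcodes(ids: Iterable[str], length: int | None = DEFAULT_BARCODE_LENGTH) -> list[str]:
    """Truncate sample barcodes to ``length`` characters (None = no truncation)."""
    if length is None:
        return [str(i) for i in ids]
    return [str(i)[:length] for i in ids]


def read_maf(path: str | Path) -> list[MafRecord]:
    """Parse a GDC-dialect MAF into records, in file order.

    Columns are located by header name (order-independent, case-sensitive
    after whitespace trimming); lines starting with ``#`` are comments.
    An empty data section yields an empty list.
    """
    path = Path(path)
    header: list[str] | None = None
    idx: dict[str, int] = {}
    records: list[MafRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                for col in MAF_REQUIRED_COLUMNS:
                    if col not in header:
                        raise FormatError(f"{path}: MAF header is missing required column {col!r}")
                idx = {col: header.index(col) for col in MAF_REQUIRED_COLUMNS}
                continue
            try:
                values = {col: fields[i].strip() for col, i in idx.items()}
            except IndexError:
                raise FormatError(f"{path}:{lineno}: truncated MAF data line") from None
            for col, v in values.items():
                if not v:
                    raise FormatError(f"{path}:{lineno}: empty {col} field")
            records.append(
                MafRecord(
                    gene_symbol=values["Hugo_Symbol"],
                    variant_classification=values["Variant_Classification"],
                    sample_barcode=values["Tumor_Sample_Barcode"],
                )
            )
    if header is None:
        raise FormatError(f"{path}: no header line found")
    return records


def _read_tsv_matrix(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment=None)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed TSV ({exc})") from exc
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate sample ids {dupes}")
    try:
        out = df.astype(np.float64)
    except (TypeError, ValueError):
        bad = None
        for j, col in enumerate(df.columns):
            conv = pd.to_numeric(df[col], errors="coerce")
            mask = conv.isna()
            if mask.any():
                bad = (df.index[mask.to_numpy().argmax()], col)
                break
        where = f" at gene {bad[0]!r}, sample {bad[1]!r}" if bad else ""
        raise FormatError(f"{path}: non-numeric cell in {what} matrix{where}") from None
    if out.isna().to_numpy().any():
        i, j = np.argwhere(out.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric or missing cell at row {out.index[i]!r}, column {out.columns[j]!r}"
        )
    if not np.isfinite(out.to_numpy()).all():
        raise ValidationError(f"{path}: {what} matrix contains non-finite values")
    return out


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column = gene ids).

    Duplicate gene rows are collapsed by keeping the row with the highest
    mean; duplicate sample columns are an error. Values must be finite.
    """
    df = _read_tsv_matrix(path, "expression")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expression matrix needs >=2 samples, got {df.shape[1]}")
    if df.index.has_duplicates:
        means = df.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        keep_pos = (
            pd.Series(np.arange(len(df))[order], index=df.index[order])
            .groupby(level=0, sort=False)
            .first()
        )
        kept = sorted(keep_pos.to_numpy())
        df = df.iloc[kept]
    return df


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labelled numeric TSV matrix without expression-specific rules."""
    return _read_tsv_matrix(path, "numeric")


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> Path:
    """Write a labelled matrix as TSV; round-trips bit-identically via read."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path, sep="\t", index_label=matrix.index.name or "id")
    return path


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered name -> gene-list mapping.

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``; within-set
    duplicate genes are dropped (first occurrence kept).
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name = fields[0].strip()
            if not name:
                raise FormatError(f"{path}:{lineno}: empty gene-set name")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            genes = list(dict.fromkeys(g.strip() for g in fields[2:] if g.strip()))
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = genes
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path, description: str = "na") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
    return path


def read_survival(
    path: str | Path,
    sample_col: str = "sample",
    time_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Read a survival TSV into a frame indexed by sample with columns time, event.

    ``time`` must be > 0 (units are the caller's, days or months); ``event``
    is 1 for an observed death/event and 0 for censoring.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in (sample_col, time_col, event_col):
        if col not in df.columns:
            raise FormatError(f"{path}: survival table missing column {col!r}")
    out = pd.DataFrame(
        {
            "time": pd.to_numeric(df[time_col], errors="coerce").to_numpy(),
            "event": pd.to_numeric(df[event_col], errors="coerce").to_numpy(),
        },
        index=pd.Index(df[sample_col].astype(str), name="sample"),
    )
    return validate_survival(out, source=str(path))


def validate_survival(df: pd.DataFrame, source: str = "survival table") -> pd.DataFrame:
    if df.index.has_duplicates:
        raise ValidationError(f"{source}: duplicate sample ids")
    if df["time"].isna().any() or df["event"].isna().any():
        raise FormatError(f"{source}: non-numeric time or event values")
    if (df["time"] <= 0).any():
        bad = df.index[df["time"] <= 0][0]
        raise ValidationError(f"{source}: non-positive survival time for sample {bad!r}")
    if not df["event"].isin([0, 1]).all():
        raise ValidationError(f"{source}: event must be 0 (censored) or 1 (event)")
    out = df[["time", "event"]].copy()
    out["time"] = out["time"].astype(float)
    out["event"] = out["event"].astype(int)
    return out


def write_survival(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label="sample")
    return path
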