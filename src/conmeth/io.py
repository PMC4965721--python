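"""Readers and writers for the pipeline's plain-text formats.

Everything on disk is TSV/BED with 0-based half-open coordinates:

* coverage TSV  -- ``chrom  pos  meth_reads  total_reads`` per CpG per sample
* BED3/BED6     -- annotation tracks and region exports
* gene models   -- ``transcript_id chrom strand txStart txEnd cdsStart cdsEnd
  exonStarts exonEnds [gene_id]`` with comma-joined exon coordinate lists
* expression    -- wide matrix (transcript_id x sample) or long
  ``transcript_id  sample_id  fpkm``
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

__all__ = [
    "CoverageParseError",
    "read_coverage",
    "write_coverage",
    "read_bed",
    "write_bed",
    "read_gene_models",
    "write_gene_models",
    "read_expression",
    "write_expression",
]

COVERAGE_COLUMNS = ["chrom", "pos", "meth_reads", "total_reads"]

GENE_MODEL_COLUMNS = [
    "transcript_id",
    "chrom",
    "strand",
    "txStart",
    "txEnd",
    "cdsStart",
    "cdsEnd",
    "exonStarts",
    "exonEnds",
]


class CoverageParseError(ValueError):
    """Raised when a coverage TSV violates the format contract."""


def read_coverage(path) -> pd.DataFrame:
    """Read a per-CpG coverage TSV into a validated, sorted DataFrame.

    Duplicate (chrom, pos) entries are merged by summing counts, with a
    warning.  Rows with non-integer counts or meth_reads > total_reads
    raise :class:`CoverageParseError` naming the 1-based file line.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", header=None, names=COVERAGE_COLUMNS, dtype=str, comment="#"
    )
    if df.shape[1] != 4:
        raise CoverageParseError(f"{path}: expected 4 tab-separated columns")
    parsed = {}
    for col in ("pos", "meth_reads", "total_reads"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            line = int(df.index[bad][0]) + 1
            raise CoverageParseError(
                f"{path}: line {line}: non-integer value in column '{col}'"
            )
        parsed[col] = vals.astype("int64")
    out = pd.DataFrame({"chrom": df["chrom"].astype(str), **parsed})
    over = out["meth_reads"] > out["total_reads"]
    if over.any():
        line = int(out.index[over][0]) + 1
        raise CoverageParseError(
            f"{path}: line {line}: meth_reads exceeds total_reads"
        )
    if (out["meth_reads"] < 0).any() or (out["pos"] < 0).any():
        raise CoverageParseError(f"{path}: negative positions or counts")
    if out.duplicated(["chrom", "pos"]).any():
        warnings.warn(
            f"{path}: duplicate CpG positions merged by count summation",
            stacklevel=2,
        )
        out = out.groupby(["chrom", "pos"], as_index=False, sort=False).sum()
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_coverage(df: pd.DataFrame, path) -> None:
    df[COVERAGE_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6 (0-based half-open) into chrom/start/end[/name/score/strand]."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype("int64")
    df["end"] = df["end"].astype("int64")
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: BED intervals must have start < end")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def _split_ints(s: str) -> tuple[int, ...]:
    return tuple(int(x) for x in str(s).rstrip(",").split(",") if x != "")


def read_gene_models(path) -> pd.DataFrame:
    """Read a gene-model TSV; exonStarts/exonEnds become tuples of ints."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_MODEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: gene-model TSV missing columns {missing}")
    df["exonStarts"] = df["exonStarts"].map(_split_ints)
    df["exonEnds"] = df["exonEnds"].map(_split_ints)
    if "gene_id" not in df.columns:
        df["gene_id"] = df["transcript_id"]
    return df


def write_gene_models(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in ("exonStarts", "exonEnds"):
        out[col] = out[col].map(lambda xs: ",".join(str(int(x)) for x in xs))
    cols = GENE_MODEL_COLUMNS + (["gene_id"] if "gene_id" in out else [])
    out[cols].to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    """Read expression as a wide transcript x sample matrix.

    Accepts either the wide format (first column ``transcript_id``) or
    the long format ``transcript_id  sample_id  fpkm``.
    """
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:3]) == ["transcript_id", "sample_id", "fpkm"]:
        wide = df.pivot(index="transcript_id", columns="sample_id", values="fpkm")
        wide.columns.name = None
        return wide
    if df.columns[0] != "transcript_id":
        raise ValueError(f"{path}: first column must be 'transcript_id'")
    wide = df.set_index("transcript_id")
    if (wide.values < 0).any():
        raise ValueError(f"{path}: expression values must be non-negative")
    return wide


def write_expression(df: pd.DataFrame, path) -> None:
    # full repr precision so the table round-trips losslessly
    df.to_csv(path, sep="\t", index_label="transcript_id")
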