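"""Readers and writers for the pipeline's on-disk artifacts.

The canonical table format is long-form TSV: one row per gene x sample, where a
sample is identified by the tuple (condition, tissue, replicate, timepoint_min).
All writers emit a stable column order and a ``# tudecay <version>`` header
comment; all readers accept their own writers' output (round-trip identity).
Log messages go to standard error; results only to files or standard output.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .errors import DataError, FormatError

__all__ = [
    "SAMPLE_KEYS",
    "EXPR_COLUMNS",
    "ExpressionMatrix",
    "read_expression_table",
    "write_expression_table",
    "read_fasta_utrs",
    "read_ct_table",
    "read_config",
    "write_config",
    "write_table",
    "read_table",
    "file_checksum",
]

log = logging.getLogger("tudecay")

#: Columns that jointly identify one array ("sample") in a pulse-chase series.
SAMPLE_KEYS = ["condition", "tissue", "replicate", "timepoint_min"]

#: Canonical long-format expression columns.
EXPR_COLUMNS = ["gene_id", *SAMPLE_KEYS, "intensity", "is_spikein"]

_HEADER = "# tudecay 0.1.0\n"

_RNA_ALPHABET = set("ACGU")


@dataclass
class ExpressionMatrix:
    """Gene x sample labeled-signal intensities with sample metadata.

    Parameters
    ----------
    data:
        Long-format frame with columns :data:`EXPR_COLUMNS` and optionally
        ``background_floor`` (per-sample detection floor, replicated per row).
    array_scales:
        Optional per-array metadata recorded by the simulator (true scale
        factor and floor); provenance only, never written by the TSV writer.
    """

    data: pd.DataFrame
    array_scales: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in EXPR_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"expression matrix missing column(s): {missing}")
        if (self.data["intensity"] < 0).any():
            raise FormatError("negative intensity values are not allowed")
        self.data = self.data.reset_index(drop=True)

    # -- views -------------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.data.loc[~self.data["is_spikein"], "gene_id"].unique())

    @property
    def samples(self) -> pd.DataFrame:
        return self.data[SAMPLE_KEYS].drop_duplicates().reset_index(drop=True)

    def gene_rows(self) -> pd.DataFrame:
        """Rows for real genes; spike-in rows never enter result tables."""
        return self.data.loc[~self.data["is_spikein"]]

    def spikein_rows(self) -> pd.DataFrame:
        return self.data.loc[self.data["is_spikein"]]

    def floor_for(self, sample: tuple) -> float:
        """Background floor for one sample tuple, 0.0 if none recorded."""
        if "background_floor" not in self.data.columns:
            return 0.0
        mask = pd.Series(True, index=self.data.index)
        for key, value in zip(SAMPLE_KEYS, sample):
            mask &= self.data[key] == value
        vals = self.data.loc[mask, "background_floor"]
        return float(vals.iloc[0]) if len(vals) else 0.0


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a long-format expression TSV into an :class:`ExpressionMatrix`.

    Duplicate (gene, sample) rows are averaged with a logged warning.  Missing
    values are simply absent rows, never imputed as zero.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in EXPR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    if df["intensity"].lt(0).any():
        raise FormatError(f"{path}: negative intensity values")
    df["is_spikein"] = df["is_spikein"].astype(bool)
    key = ["gene_id", *SAMPLE_KEYS]
    if df.duplicated(key).any():
        n_dup = int(df.duplicated(key).sum())
        log.warning("%s: averaging %d duplicate (gene, sample) entries", path, n_dup)
        agg = {"intensity": "mean", "is_spikein": "first"}
        if "background_floor" in df.columns:
            agg["background_floor"] = "first"
        df = df.groupby(key, as_index=False, sort=False).agg(agg)
    return ExpressionMatrix(df)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    cols = list(EXPR_COLUMNS)
    if "background_floor" in matrix.data.columns:
        cols.append("background_floor")
    with open(path, "w") as fh:
        fh.write(_HEADER)
        matrix.data[cols].to_csv(fh, sep="\t", index=False)


def read_fasta_utrs(path: str | Path) -> dict[str, str]:
    """Read 3'UTR sequences; DNA is accepted and transcribed to RNA.

    Sequences are upper-cased and T mapped to U.  Any residue outside A/C/G/U
    after that mapping (gaps, ambiguity codes) is a :class:`FormatError`.
    Record id is the token before the first whitespace.
    """
    utrs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper().replace("T", "U")
        if not seq:
            raise FormatError(f"empty sequence for record {record.id!r}")
        bad = set(seq) - _RNA_ALPHABET
        if bad:
            raise FormatError(
                f"illegal character(s) {sorted(bad)} in record {record.id!r}"
            )
        utrs[record.id] = seq
    return utrs


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read RT-qPCR cycle-threshold records.

    Required columns: gene_id, timepoint_min, ct_target, ct_reference (the
    internal-reference transcript, e.g. RpL32).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["gene_id", "timepoint_min", "ct_target", "ct_reference"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    for col in ("ct_target", "ct_reference"):
        vals = df[col]
        if not (vals.notna() & (vals > 0) & (vals != float("inf"))).all():
            raise FormatError(f"{path}: {col} must be finite and positive")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any result table with the standard header comment."""
    with open(path, "w") as fh:
        fh.write(_HEADER)
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_config(path: str | Path) -> dict[str, str]:
    """Read a flat ``key = value`` configuration file (# starts a comment)."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value'")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def write_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER)
        for key, value in config.items():
            fh.write(f"{key} = {value}\n")


def file_checksum(path: str | Path) -> str:
    """md5 of a file's bytes, for run-log provenance."""
    return hashlib.md5(Path(path).read_bytes()).hexdigest()


def intersect_universe(a: pd.Index, b: pd.Index) -> pd.Index:
    shared = a.intersection(b)
    if len(shared) == 0:
        raise DataError("gene universes are disjoint")
    return shared
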