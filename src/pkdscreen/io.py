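"""Readers and writers for the external formats the pipeline touches.

Three formats are supported:

* MaxQuant-style ``proteinGroups`` tab-separated tables (LFQ intensities,
  razor+unique peptide counts, reverse/contaminant flags),
* protein FASTA (plain ``>ACC desc`` or UniProt ``>db|ACC|NAME desc`` headers),
* a known-phosphosite TSV (``accession  position  residue  annotation``),
  the local stand-in for an online phosphosite repository.

All tables are held in memory as pandas DataFrames; missing LFQ values are
NaN (MaxQuant writes ``0`` for unquantified proteins, so ``0`` and blank
cells are both normalised to missing on read).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ConfigurationError, FastaFormatError, TableParseError

logger = logging.getLogger(__name__)

#: Floats in all output tables are written with this many significant digits.
FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# column mapping for proteinGroups-style tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnMap:
    """Names of the proteinGroups columns the pipeline consumes.

    Defaults follow the MaxQuant convention; every name can be remapped for
    tables produced by other quantification tools.
    """

    id: str = "Majority protein IDs"
    gene_names: str = "Gene names"
    peptides: str = "Razor + unique peptides"
    lfq_prefix: str = "LFQ intensity "
    reverse: str = "Reverse"
    contaminant: str = "Potential contaminant"

    def lfq_column(self, sample_label: str) -> str:
        return f"{self.lfq_prefix}{sample_label}"


@dataclass
class ProteinGroupTable:
    """A rectangular protein-group quantification table.

    ``meta`` holds one row per protein group (``group_id``, ``accessions``
    list, ``leading_accession``, ``gene_names`` list, ``razor_unique_peptides``,
    ``reverse``/``contaminant`` flags).  ``lfq`` holds the linear-scale LFQ
    intensity matrix (rows aligned with ``meta``, one column per sample
    label, NaN = not quantified).
    """

    meta: pd.DataFrame
    lfq: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.meta) != len(self.lfq):
            raise ValueError("meta and lfq must have the same number of rows")
        if not self.meta.index.equals(self.lfq.index):
            raise ValueError("meta and lfq must share an index")
        with np.errstate(invalid="ignore"):
            if (self.lfq.to_numpy(dtype=float) < 0).any():
                raise ValueError("LFQ intensities must be nonnegative")

    @property
    def sample_labels(self) -> list[str]:
        return list(self.lfq.columns)

    @property
    def leading_accessions(self) -> list[str]:
        return list(self.meta["leading_accession"])

    def __len__(self) -> int:
        return len(self.meta)


REQUIRED_META = ("group_id", "accessions", "leading_accession", "gene_names",
                 "razor_unique_peptides", "reverse", "contaminant")


def _split_semicolon(cell: object) -> list[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return []
    text = str(cell).strip()
    if not text:
        return []
    return [part.strip() for part in text.split(";") if part.strip()]


def read_protein_groups(
    path: str | Path,
    sample_labels: Sequence[str],
    column_map: ColumnMap | None = None,
    *,
    drop_flagged: bool = True,
    duplicate_policy: str = "error",
) -> ProteinGroupTable:
    """Read a MaxQuant-style proteinGroups TSV.

    Parameters
    ----------
    path:
        Tab-separated file with a header row.
    sample_labels:
        Sample labels whose LFQ columns (``column_map.lfq_prefix + label``)
        are loaded, in this order.
    column_map:
        Column-name mapping; defaults to the MaxQuant names.
    drop_flagged:
        Drop rows marked in the reverse / potential-contaminant columns when
        those columns exist (standard decoy/contaminant hygiene).
    duplicate_policy:
        ``"error"`` (reject duplicate leading accessions) or ``"keep_first"``.
    """
    cmap = column_map or ColumnMap()
    if duplicate_policy not in ("error", "keep_first"):
        raise ConfigurationError(f"unknown duplicate_policy {duplicate_policy!r}")
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    for col in (cmap.id, cmap.peptides):
        if col not in raw.columns:
            raise ConfigurationError(f"mapped column {col!r} not found in {path}")
    lfq_cols = {}
    for label in sample_labels:
        col = cmap.lfq_column(label)
        if col not in raw.columns:
            raise ConfigurationError(f"mapped LFQ column {col!r} not found in {path}")
        lfq_cols[label] = col

    n_raw = len(raw)
    accessions = raw[cmap.id].map(_split_semicolon)
    if (accessions.str.len() == 0).any():
        bad = int(np.flatnonzero(accessions.str.len() == 0)[0])
        raise TableParseError(f"row {bad}: empty identifier in column {cmap.id!r}")

    genes = (raw[cmap.gene_names].map(_split_semicolon)
             if cmap.gene_names in raw.columns else [[] for _ in range(n_raw)])

    try:
        peptides = pd.to_numeric(raw[cmap.peptides]).astype(int)
    except (ValueError, TypeError) as exc:
        raise TableParseError(f"non-numeric peptide count in column {cmap.peptides!r}: {exc}") from exc
    if (peptides < 0).any():
        raise TableParseError(f"negative peptide count in column {cmap.peptides!r}")

    def flag_series(col: str) -> pd.Series:
        if col in raw.columns:
            return raw[col].str.strip() == "+"
        return pd.Series(False, index=raw.index)

    meta = pd.DataFrame({
        "group_id": raw.index.astype(str),
        "accessions": accessions,
        "leading_accession": accessions.str[0],
        "gene_names": pd.Series(list(genes), index=raw.index),
        "razor_unique_peptides": peptides,
        "reverse": flag_series(cmap.reverse),
        "contaminant": flag_series(cmap.contaminant),
    })

    lfq = pd.DataFrame(index=raw.index)
    for label, col in lfq_cols.items():
        cells = raw[col].str.strip().replace("", "nan")
        try:
            values = pd.to_numeric(cells).astype(float)
        except (ValueError, TypeError):
            bad = cells[pd.to_numeric(cells, errors="coerce").isna() & (cells != "nan")]
            row = int(bad.index[0]) if len(bad) else -1
            raise TableParseError(
                f"non-numeric LFQ value {bad.iloc[0]!r} at row {row}, column {col!r}"
            ) from None
        if (values < 0).any():
            row = int(values.index[values < 0][0])
            raise TableParseError(f"negative LFQ value at row {row}, column {col!r}")
        # 0 means "not quantified" in MaxQuant output
        lfq[label] = values.replace(0.0, np.nan)

    if drop_flagged:
        keep = ~(meta["reverse"] | meta["contaminant"])
        meta, lfq = meta[keep], lfq[keep]
        if (~keep).any():
            logger.info("dropped %d reverse/contaminant rows", int((~keep).sum()))

    dup = meta["leading_accession"].duplicated()
    if dup.any():
        if duplicate_policy == "error":
            raise TableParseError(
                f"duplicate leading accession {meta['leading_accession'][dup].iloc[0]!r}"
            )
        meta, lfq = meta[~dup], lfq[~dup]
        logger.info("dropped %d duplicate leading accessions (keep_first)", int(dup.sum()))

    meta = meta.reset_index(drop=True)
    lfq = lfq.reset_index(drop=True)
    logger.info("read %d protein groups (%d raw rows) from %s", len(meta), n_raw, path)
    return ProteinGroupTable(meta=meta, lfq=lfq)


def write_protein_groups(
    table: ProteinGroupTable,
    path: str | Path,
    column_map: ColumnMap | None = None,
) -> Path:
    """Write a :class:`ProteinGroupTable` back to the proteinGroups dialect.

    Missing LFQ cells are written as ``0`` (the MaxQuant convention), so
    ``read_protein_groups(write_protein_groups(t))`` round-trips.
    """
    cmap = column_map or ColumnMap()
    out = pd.DataFrame({
        cmap.id: table.meta["accessions"].map(";".join),
        cmap.gene_names: table.meta["gene_names"].map(";".join),
        cmap.peptides: table.meta["razor_unique_peptides"],
    })
    for label in table.sample_labels:
        out[cmap.lfq_column(label)] = table.lfq[label].fillna(0.0)
    out[cmap.reverse] = np.where(table.meta["reverse"], "+", "")
    out[cmap.contaminant] = np.where(table.meta["contaminant"], "+", "")
    path = Path(path)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with its parsed accession."""

    accession: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise FastaFormatError("empty accession")
        if not self.sequence:
            raise FastaFormatError(f"record {self.accession!r} has an empty sequence")


def _accession_from_header(header_id: str) -> str:
    # UniProt dialect "db|ACC|NAME" -> middle field; otherwise first token.
    parts = header_id.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1]
    return header_id


def read_fasta(path: str | Path, *, duplicate_policy: str = "error") -> list[SequenceRecord]:
    """Read protein sequences; accessions parsed from plain or UniProt headers."""
    if duplicate_policy not in ("error", "keep_first"):
        raise ConfigurationError(f"unknown duplicate_policy {duplicate_policy!r}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "")
        acc = _accession_from_header(rec.id)
        if not seq:
            raise FastaFormatError(f"record {acc!r} in {path} has an empty sequence")
        if acc in seen:
            if duplicate_policy == "error":
                raise FastaFormatError(f"duplicate accession {acc!r} in {path}")
            continue
        seen.add(acc)
        records.append(SequenceRecord(accession=acc, description=rec.description, sequence=seq))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.accession
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# known-phosphosite table
# ---------------------------------------------------------------------------

KNOWN_SITE_COLUMNS = ("accession", "position", "residue", "annotation")


@dataclass
class KnownSiteTable:
    """Known phosphosites keyed by (accession, 1-based position).

    A local snapshot standing in for an online phosphosite repository;
    the pipeline never performs network lookups.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=list(KNOWN_SITE_COLUMNS)))

    def __post_init__(self) -> None:
        missing = set(KNOWN_SITE_COLUMNS) - set(self.df.columns)
        if missing:
            raise ConfigurationError(f"known-site table missing columns {sorted(missing)}")
        if len(self.df):
            if (self.df["position"] < 1).any():
                raise TableParseError("known-site positions must be >= 1")
            bad = ~self.df["residue"].isin(("S", "T", "Y"))
            if bad.any():
                raise TableParseError(
                    f"known-site residue must be S/T/Y, got {self.df['residue'][bad].iloc[0]!r}")
            if self.df.duplicated(subset=["accession", "position"]).any():
                raise TableParseError("duplicate (accession, position) in known-site table")
        self._index = {
            (row.accession, int(row.position)): (row.residue, row.annotation)
            for row in self.df.itertuples()
        }

    def lookup(self, accession: str, position: int) -> tuple[str, str] | None:
        """Return (residue, annotation) for an exact site match, else None."""
        return self._index.get((accession, position))

    def __len__(self) -> int:
        return len(self.df)


def read_known_sites(path: str | Path) -> KnownSiteTable:
    df = pd.read_csv(path, sep="\t", dtype={"accession": str, "residue": str, "annotation": str})
    missing = set(KNOWN_SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"known-site table {path} missing columns {sorted(missing)}")
    try:
        df["position"] = pd.to_numeric(df["position"]).astype(int)
    except (ValueError, TypeError) as exc:
        raise TableParseError(f"non-integer position in {path}: {exc}") from exc
    df["annotation"] = df["annotation"].fillna("")
    return KnownSiteTable(df=df[list(KNOWN_SITE_COLUMNS)])


def write_known_sites(table: KnownSiteTable, path: str | Path) -> Path:
    path = Path(path)
    table.df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# stage outputs
# ---------------------------------------------------------------------------

def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    summary: Mapping[str, object] | None = None,
) -> dict[str, Path]:
    """Write one TSV per stage table plus a JSON run summary.

    Floats are formatted with 6 significant digits; an empty table produces
    a header-only TSV.  Returns the written paths keyed by stage name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
        paths[name] = path
    if summary is not None:
        path = out_dir / "summary.json"
        with open(path, "w") as fh:
            json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths["summary"] = path
    return paths


def _jsonable(obj: object) -> object:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        seq = sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
        return [_jsonable(v) for v in seq]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
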