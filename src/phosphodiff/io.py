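"""Readers and writers for the pipeline's tabular formats.

All tables are tab-separated UTF-8 with a header row; ``NA`` and the empty
string both denote a missing value. Floating-point output is written at 12
significant digits so that write-read round-trips are reproducible in tests.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    AbundanceTable,
    ContrastResult,
    FormatError,
    PhosphopeptideRecord,
    SampleDesign,
    ValidationError,
    contrasts_to_frame,
    frame_to_contrasts,
)

NA_VALUES = ["", "NA"]
FLOAT_FMT = "%.12g"


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path} is empty")
    try:
        return pd.read_csv(path, sep="\t", na_values=NA_VALUES, keep_default_na=False, **kw)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path} has no parseable content") from exc


def read_design(path: str | Path, reference: str | None = None) -> SampleDesign:
    """Read a sample design table (columns sample_id, condition, replicate)."""
    df = _read_tsv(path, dtype={"sample_id": str, "condition": str})
    return SampleDesign(df, reference=reference)


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_abundance(path: str | Path, kind: str = "protein") -> AbundanceTable:
    """Read a feature x sample abundance table; blanks/NA are missing, not zero."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a feature_id column plus >= 1 sample column")
    feat_col = df.columns[0]
    df = df.set_index(feat_col)
    df.index = df.index.astype(str)
    df.index.name = "feature_id"
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: non-numeric cell in column {col!r}: {exc}") from exc
    return AbundanceTable(df, feature_kind=kind)


def write_abundance(table: AbundanceTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", na_rep="NA", float_format=FLOAT_FMT, index_label="feature_id")


def read_phospho_records(path: str | Path) -> list[PhosphopeptideRecord]:
    df = _read_tsv(path, dtype=str)
    required = ["peptide_id", "parent_protein_id", "site_descriptor", "ptmrs_score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    if df["ptmrs_score"].isna().any():
        bad = df.loc[df["ptmrs_score"].isna(), "peptide_id"].tolist()
        raise ValidationError(f"ptmRS score missing for peptide(s): {', '.join(bad)}")
    return [
        PhosphopeptideRecord(
            peptide_id=str(r.peptide_id),
            parent_protein_id=str(r.parent_protein_id),
            site_descriptor=str(r.site_descriptor),
            ptmrs_score=float(r.ptmrs_score),
        )
        for r in df.itertuples(index=False)
    ]


def write_phospho_records(records: list[PhosphopeptideRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "peptide_id": [r.peptide_id for r in records],
            "parent_protein_id": [r.parent_protein_id for r in records],
            "site_descriptor": [r.site_descriptor for r in records],
            "ptmrs_score": [r.ptmrs_score for r in records],
        }
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_contrast(results: list[ContrastResult], path: str | Path) -> None:
    """Write contrast results with a deterministic column order.

    Refuses empty input and re-validates the p_adj >= p_raw invariant before
    touching the file system.
    """
    if not results:
        raise ValidationError("refusing to write an empty contrast result list")
    for r in results:
        if r.p_adj < r.p_raw - 1e-9:
            raise ValidationError(f"p_adj < p_raw for feature {r.feature_id!r}")
    contrasts_to_frame(results).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_contrast(path: str | Path) -> list[ContrastResult]:
    df = _read_tsv(path)
    required = ["feature_id", "log2fc", "p_raw", "p_adj"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    if "direction" not in df.columns:
        df["direction"] = "unchanged"
    df["feature_id"] = df["feature_id"].astype(str)
    return frame_to_contrasts(df)


def read_mapping(path: str | Path, from_col: str = "protein_id", to_col: str = "gene_id") -> dict[str, str]:
    """Read an explicit two-column identifier mapping (e.g. protein -> gene).

    Duplicate source identifiers are an error: ambiguity must never be
    resolved silently.
    """
    df = _read_tsv(path, dtype=str)
    if from_col not in df.columns or to_col not in df.columns:
        raise FormatError(f"{path}: expected columns {from_col!r} and {to_col!r}")
    dup = df[from_col][df[from_col].duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"ambiguous mapping for: {', '.join(dup)}")
    return dict(zip(df[from_col], df[to_col]))


def write_mapping(mapping: dict[str, str], path: str | Path,
                  from_col: str = "protein_id", to_col: str = "gene_id") -> None:
    pd.DataFrame({from_col: list(mapping.keys()), to_col: list(mapping.values())}).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column TSV edge list (extra columns such as scores ignored here)."""
    df = _read_tsv(path, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: edge list needs >= 2 columns")
    a, b = df.columns[:2]
    return [(str(x), str(y)) for x, y in zip(df[a], df[b])]


def read_scored_edge_list(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, dtype={0: str, 1: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: edge list needs >= 2 columns")
    df = df.rename(columns={df.columns[0]: "node_a", df.columns[1]: "node_b"})
    df["node_a"] = df["node_a"].astype(str)
    df["node_b"] = df["node_b"].astype(str)
    return df


def write_edge_list(edges: list[tuple[str, str]], path: str | Path,
                    cols: tuple[str, str] = ("node_a", "node_b")) -> None:
    pd.DataFrame(edges, columns=list(cols)).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, dict]:
    """Read a GMT gene-set file: set_name TAB description TAB member..."""
    path = Path(path)
    sets: dict[str, dict] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: GMT line needs name, description, >= 1 member")
            name, desc = parts[0], parts[1]
            members = {m for m in parts[2:] if m}
            if not members:
                raise FormatError(f"{path}:{ln}: gene set {name!r} is empty")
            sets[name] = {"description": desc, "members": members}
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: dict[str, dict], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, entry in sets.items():
            members = sorted(entry["members"])
            fh.write("\t".join([name, entry.get("description", "")] + members) + "\n")


def ensure_outdir(directory: str | Path, overwrite: bool = False) -> Path:
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(
            f"output directory {directory} exists and is non-empty (pass overwrite=True)"
        )
    directory.mkdir(parents=True, exist_ok=True)
    return directory
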