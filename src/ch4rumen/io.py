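"""Readers and writers for the pipeline's declared text formats.

All files are UTF-8 with `.` decimals and unquoted IDs. Metadata lines
start with `##` (tool version, seed, thresholds) and are skipped by every
reader; the ASV table keeps its QIIME-export-style `#ASV_ID` header line.

Formats:
  trace CSV        cow_id,session_id,timestamp_iso,ch4_ppm_m (one reading/row)
  cow metadata TSV cow_id  parity  milk_yield_kg  dim
  phenotype TSV    cow_id  n_sessions  phenotype_ppm_m  group
  ASV table TSV    rows = features, columns = samples, first column #ASV_ID
  taxonomy TSV     ASV_ID  lineage   (k__;p__;c__;o__;f__;g__ strings)
  group map TSV    sample_id  group
  KO table TSV     PICRUSt2 export style: `function` column + sample columns
  KO lengths TSV   KO  length_bp
  KEGG map TSV     KO  level3  level2
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import skbio

from . import __version__
from .community import ASVTable
from .phenotyping import Session

TRACE_COLUMNS = ["cow_id", "session_id", "timestamp_iso", "ch4_ppm_m"]


class InputFormatError(ValueError):
    """Raised when a declared input file does not match its dialect."""


def _meta_lines(meta: Mapping | None) -> str:
    items = {"tool": f"ch4rumen v{__version__}", **(meta or {})}
    return "".join(f"## {k}={v}\n" for k, v in items.items())


def _open_skipping_meta(path) -> _io.StringIO:
    text = Path(path).read_text(encoding="utf-8")
    kept = [ln for ln in text.splitlines(keepends=True) if not ln.startswith("##")]
    return _io.StringIO("".join(kept))


# ---------------------------------------------------------------- traces

def write_trace_csv(path, sessions: Iterable[Session], meta: Mapping | None = None):
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_meta_lines(meta))
        w = csv.writer(fh)
        w.writerow(TRACE_COLUMNS)
        for s in sessions:
            for r in s.readings:
                w.writerow([s.cow_id, s.session_id, s.timestamp, f"{r:.2f}"])


def parse_trace_csv(path) -> tuple[list[Session], dict]:
    """Read LMD readings grouped into Sessions by (cow_id, session_id).

    Rows with non-numeric or negative readings are skipped and counted in
    the report; a missing required column or an empty file is a hard
    error.
    """
    buf = _open_skipping_meta(path)
    reader = csv.DictReader(buf)
    if reader.fieldnames is None:
        raise InputFormatError(f"{path}: empty trace file")
    missing = [c for c in TRACE_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise InputFormatError(f"{path}: missing required column(s) {missing}")
    grouped: dict[tuple[str, str], list[tuple[str, float]]] = {}
    n_bad = 0
    n_rows = 0
    for row in reader:
        n_rows += 1
        try:
            val = float(row["ch4_ppm_m"])
            if not np.isfinite(val) or val < 0:
                raise ValueError
        except (TypeError, ValueError):
            n_bad += 1
            continue
        key = (row["cow_id"], row["session_id"])
        grouped.setdefault(key, []).append((row["timestamp_iso"] or "", val))
    if n_rows == 0:
        raise InputFormatError(f"{path}: no data rows")
    sessions = []
    for (cid, sid), vals in grouped.items():
        vals.sort(key=lambda t: t[0])
        sessions.append(Session(cow_id=cid, session_id=sid,
                                readings=np.array([v for _, v in vals]),
                                timestamp=vals[0][0]))
    report = {"n_rows": n_rows, "n_bad_rows": n_bad, "n_sessions": len(sessions)}
    return sessions, report


# ------------------------------------------------------------- metadata

def read_cow_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(_open_skipping_meta(path), sep="\t")
    need = {"cow_id", "parity", "milk_yield_kg", "dim"}
    missing = need - set(df.columns)
    if missing:
        raise InputFormatError(f"{path}: missing column(s) {sorted(missing)}")
    return df.rename(columns={"milk_yield_kg": "milk_yield"}).set_index("cow_id")


def write_cow_metadata(path, df: pd.DataFrame, meta: Mapping | None = None):
    out = df.reset_index().rename(columns={"milk_yield": "milk_yield_kg"})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_lines(meta))
        out.to_csv(fh, sep="\t", index=False)


def write_phenotypes(path, cows: pd.DataFrame, meta: Mapping | None = None):
    """cow_id / n_sessions / phenotype_ppm_m / group table."""
    out = cows.reset_index()[["cow_id", "n_sessions", "phenotype"]].rename(
        columns={"phenotype": "phenotype_ppm_m"}
    )
    out["group"] = cows.get("group", "unassigned").to_numpy() if "group" in cows \
        else "unassigned"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_lines(meta))
        out.to_csv(fh, sep="\t", index=False, float_format="%.4f")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(_open_skipping_meta(path), sep="\t").set_index("cow_id")
    return df.rename(columns={"phenotype_ppm_m": "phenotype"})


# ------------------------------------------------------------ ASV table

def write_asv_table(path, table: ASVTable, meta: Mapping | None = None):
    """Feature-rows TSV with `#ASV_ID` first column (QIIME export style)."""
    mat = table.counts.T
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_lines(meta))
        mat.to_csv(fh, sep="\t", index_label="#ASV_ID")


def read_asv_table(path, taxonomy_path=None, groups_path=None) -> ASVTable:
    df = pd.read_csv(_open_skipping_meta(path), sep="\t")
    if df.columns[0] != "#ASV_ID":
        raise InputFormatError(f"{path}: first column must be '#ASV_ID'")
    counts = df.set_index("#ASV_ID").T
    counts.index.name = "sample_id"
    counts.columns.name = None
    lineages = read_taxonomy(taxonomy_path) if taxonomy_path else None
    groups = read_group_map(groups_path) if groups_path else None
    return ASVTable(counts=counts.astype(np.int64), groups=groups, lineages=lineages)


def write_taxonomy(path, lineages: pd.Series, meta: Mapping | None = None):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_lines(meta))
        lineages.rename("lineage").rename_axis("ASV_ID").reset_index().to_csv(
            fh, sep="\t", index=False
        )


def read_taxonomy(path) -> pd.Series:
    df = pd.read_csv(_open_skipping_meta(path), sep="\t")
    if not {"ASV_ID", "lineage"} <= set(df.columns):
        raise InputFormatError(f"{path}: needs columns ASV_ID, lineage")
    return df.set_index("ASV_ID")["lineage"]


def write_group_map(path, groups: pd.Series, meta: Mapping | None = None):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_lines(meta))
        groups.rename("group").rename_axis("sample_id").reset_index().to_csv(
            fh, sep="\t", index=False
        )


def read_group_map(path) -> pd.Series:
    df = pd.read_csv(_open_skipping_meta(path), sep="\t")
    if not {"sample_id", "group"} <= set(df.columns):
        raise InputFormatError(f"{path}: needs columns sample_id, group")
    return df.set_index("sample_id")["group"]


def read_tree(path) -> skbio.TreeNode:
    return skbio.TreeNode.read(str(path))


# ------------------------------------------------------------ KO tables

def write_ko_table(path, counts: pd.DataFrame, meta: Mapping | None = None):
    """PICRUSt2-export-style TSV: `function` column then sample columns."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_lines(meta))
        counts.T.to_csv(fh, sep="\t", index_label="function")


def read_ko_table(path) -> pd.DataFrame:
    df = pd.read_csv(_open_skipping_meta(path), sep="\t")
    if df.columns[0] != "function":
        raise InputFormatError(f"{path}: first column must be 'function'")
    out = df.set_index("function").T
    out.index.name = "sample_id"
    out.columns.name = None
    return out


def write_ko_lengths(path, lengths: pd.Series, meta: Mapping | None = None):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_lines(meta))
        lengths.rename("length_bp").rename_axis("KO").reset_index().to_csv(
            fh, sep="\t", index=False
        )


def read_ko_lengths(path) -> pd.Series:
    df = pd.read_csv(_open_skipping_meta(path), sep="\t")
    if not {"KO", "length_bp"} <= set(df.columns):
        raise InputFormatError(f"{path}: needs columns KO, length_bp")
    return df.set_index("KO")["length_bp"].astype(float)


def write_kegg_map(path, mapping: pd.DataFrame, meta: Mapping | None = None):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_lines(meta))
        mapping.to_csv(fh, sep="\t", index=False)


def read_kegg_map(path) -> pd.DataFrame:
    df = pd.read_csv(_open_skipping_meta(path), sep="\t")
    if not {"KO", "level3", "level2"} <= set(df.columns):
        raise InputFormatError(f"{path}: needs columns KO, level3, level2")
    return df


def write_effects(path, effects: pd.DataFrame, meta: Mapping | None = None):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_lines(meta))
        effects.to_csv(fh, sep="\t", index=False, float_format="%.6g")
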