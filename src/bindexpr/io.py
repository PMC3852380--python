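"""Readers and writers for the plain-text formats the pipeline touches.

BED for peaks / binding regions / regulatory domains, TSV for count
matrices, sample sheets, annotations and result tables, YAML for run
configuration. All genomic output is 0-based half-open (BED native).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .intervals import GenomicInterval, GeneModel

log = logging.getLogger(__name__)

GROUPS = ("A", "B")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> list[tuple[GenomicInterval, str, float]]:
    """Read a BED3/BED6 file into ``(interval, name, score)`` tuples.

    Comment (``#``), ``track`` and ``browser`` lines are skipped. Malformed
    coordinates raise :class:`ValueError` naming the offending line.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else ""
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            try:
                iv = GenomicInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            records.append((iv, name, score))
    return records


def write_bed(records: Iterable[tuple[GenomicInterval, str, float]], path) -> None:
    """Write ``(interval, name, score)`` tuples as BED6."""
    with open(path, "w") as fh:
        for iv, name, score in records:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

@dataclass
class SampleSheet:
    """Maps libraries to cell lines, groups and assays.

    Columns: ``library``, ``cell_line``, ``group`` (A or B), ``assay``
    (binding or expression), ``replicate``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"library", "cell_line", "group", "assay", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if self.table["library"].duplicated().any():
            dupes = self.table.loc[self.table["library"].duplicated(), "library"]
            raise ValueError(f"duplicate library ids: {sorted(set(dupes))}")
        bad_groups = set(self.table["group"]) - set(GROUPS)
        if bad_groups:
            raise ValueError(f"unknown group labels: {sorted(bad_groups)}")
        # each cell line maps to exactly one group
        per_line = self.table.groupby("cell_line")["group"].nunique()
        if (per_line > 1).any():
            raise ValueError(
                f"cell lines in multiple groups: {list(per_line[per_line > 1].index)}"
            )
        for g in GROUPS:
            if not (self.table["group"] == g).any():
                raise ValueError(f"group {g} has no libraries")

    def subset(self, assay: str) -> "SampleSheet":
        sub = self.table[self.table["assay"] == assay].reset_index(drop=True)
        return SampleSheet(sub)

    def groups_for(self, libraries: Sequence[str]) -> pd.Series:
        mapping = self.table.set_index("library")["group"]
        missing = [lib for lib in libraries if lib not in mapping.index]
        if missing:
            raise ValueError(f"libraries absent from sample sheet: {missing}")
        return mapping.loc[list(libraries)]


def read_sample_sheet(path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep="\t", dtype={"library": str}))


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Nonnegative integer counts, features x libraries, with group labels."""

    counts: pd.DataFrame
    groups: pd.Series  # indexed by library, values in GROUPS

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate feature ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate library ids in count matrix")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        self.groups = self.groups.loc[self.counts.columns]

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def libraries(self) -> pd.Index:
        return self.counts.columns

    def libraries_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def pooled_by_cell_line(self, sheet: SampleSheet) -> "CountMatrix":
        """Sum replicate columns within each cell line."""
        mapping = sheet.table.set_index("library")["cell_line"]
        cell = mapping.loc[self.counts.columns]
        pooled = self.counts.T.groupby(cell.values).sum().T
        line_group = sheet.table.drop_duplicates("cell_line").set_index("cell_line")[
            "group"
        ]
        return CountMatrix(pooled, line_group.loc[pooled.columns])


def read_count_table(path, sheet: SampleSheet) -> CountMatrix:
    """Read a TSV count table (first column feature ids, header libraries)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()]
        raise ValueError(f"{path}: duplicate feature ids: {sorted(set(dupes))}")
    vals = df.to_numpy()
    bad = ~np.isfinite(vals) | (vals < 0) | (vals != np.floor(vals))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: invalid count {vals[i, j]!r} at feature "
            f"{df.index[i]!r}, library {df.columns[j]!r}"
        )
    groups = sheet.groups_for(list(df.columns))
    return CountMatrix(df.astype(np.int64), groups)


def write_count_table(cm: CountMatrix, path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="feature")


# ---------------------------------------------------------------------------
# Gene annotation (TSV: gene_id, chrom, start, end, strand; BED coordinates)
# ---------------------------------------------------------------------------

def read_annotation(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    if df["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids")
    genes = [
        GeneModel(
            row.gene_id,
            GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
        )
        for row in df.itertuples()
    ]
    return genes


def write_annotation(genes: Sequence[GeneModel], path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "start": g.interval.start,
            "end": g.interval.end,
            "strand": g.strand,
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

_FLOAT_2DP = ("mean_A", "mean_B", "fold_change", "tss_distance",
              "binding_fold_change", "expression_fold_change")
_SCI_2DP = ("p", "fdr", "binding_fdr", "expression_fdr")


def _format_cell(col: str, value) -> str:
    if pd.isna(value):
        return "N/A"
    if col in _SCI_2DP:
        return f"{value:.2E}"
    if col in _FLOAT_2DP:
        return f"{value:.2f}"
    return str(value)


def write_results(table: pd.DataFrame, path) -> None:
    """Write a differential or pair table as TSV.

    Fold changes and group means print to 2 decimals, p/FDR in scientific
    notation with 2 decimals; missing fold changes (zero denominator) print
    as ``N/A``. Column order is preserved deterministically.
    """
    out = table.copy()
    for col in out.columns:
        out[col] = [_format_cell(col, v) for v in out[col]]
    out.to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["N/A"])
    return df


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_THRESHOLDS = {
    "fdr": 0.05,       # strict: significant means FDR < fdr
    "onoff": 5.0,      # minor-group mean below this => on/off gene
    "min_lines": 2,    # minimum cell-line support for a binding region
}


def load_config(path) -> dict:
    """Load a YAML config, filling in default thresholds."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    merged = dict(DEFAULT_THRESHOLDS)
    merged.update(cfg)
    return merged
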