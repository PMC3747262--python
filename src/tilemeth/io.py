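"""Readers and writers for the tabular formats used throughout the package.

All genomic coordinates are 0-based, half-open, both internally and in BED
output.  Every writer emits a single header line starting with ``#`` that
names the columns; readers require it (except for BED, where the header is
optional to stay compatible with plain browser tracks).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CompletenessError, FormatError

DESIGN_COLUMNS = ["probe_id", "chrom", "start", "end", "locus_id"]
INTENSITY_COLUMNS = ["array_id", "probe_id", "bound", "input"]
SAMPLE_COLUMNS = ["array_id", "subject_id", "group", "cell_type", "replicate"]
PHENOTYPE_COLUMNS = ["subject_id", "analyte", "level"]
GENE_COLUMNS = ["gene_id", "chrom", "tss", "strand", "tes"]
BED_COLUMNS = ["chrom", "start", "end", "name", "score"]


@dataclass
class AnnotationTrack:
    """A named set of genomic intervals (a BED-style regulatory track)."""

    name: str
    intervals: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=BED_COLUMNS))

    def __post_init__(self) -> None:
        df = self.intervals.copy()
        for col in ("name", "score"):
            if col not in df.columns:
                df[col] = "." if col == "name" else 0.0
        df = df[BED_COLUMNS]
        if len(df) and (df["end"] <= df["start"]).any():
            raise FormatError(f"track {self.name!r}: intervals with end <= start")
        self.intervals = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)


def _write_table(
    df: pd.DataFrame, path, float_format: str = "%.6g", provenance: list[str] | None = None
) -> None:
    with open(path, "w") as fh:
        for line in provenance or []:
            fh.write("## " + line + "\n")
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, float_format=float_format)


def _read_table(path, columns: list[str], dtypes: dict | None = None) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
        while first.startswith("##"):  # provenance comments
            first = fh.readline()
        if not first.startswith("#"):
            raise FormatError(f"{path}: expected '#'-prefixed header line")
        names = first.lstrip("#").strip().split("\t")
        if names != columns:
            raise FormatError(f"{path}: header {names} does not match expected columns {columns}")
        body = fh.read()
    if not body.strip():
        return pd.DataFrame({c: pd.Series(dtype=(dtypes or {}).get(c, object)) for c in columns})
    try:
        df = pd.read_csv(_io.StringIO(body), sep="\t", names=columns, dtype=dtypes)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return df


# ---------------------------------------------------------------------------
# probe design


def validate_probe_design(design: pd.DataFrame, source: str = "design") -> pd.DataFrame:
    """Validate and canonically sort a probe design table.

    Probes are sorted by (chrom, start, probe_id); within each locus they must
    be non-overlapping.  Returns the sorted copy.
    """
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise FormatError(f"{source}: missing columns {missing}")
    design = design[DESIGN_COLUMNS].copy()
    design["start"] = design["start"].astype(np.int64)
    design["end"] = design["end"].astype(np.int64)
    bad = design.index[design["end"] <= design["start"]]
    if len(bad):
        raise FormatError(f"{source}: end <= start at row(s) {list(bad[:5])} (0-based data rows)")
    if design["probe_id"].duplicated().any():
        dup = design.loc[design["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise FormatError(f"{source}: duplicated probe_id {dup!r}")
    design = design.sort_values(["chrom", "start", "probe_id"], kind="mergesort").reset_index(drop=True)
    for locus_id, sub in design.groupby("locus_id", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if len(sub) > 1 and (starts[1:] < ends[:-1]).any():
            raise FormatError(f"{source}: overlapping probes within locus {locus_id!r}")
    return design


def write_probe_design(design: pd.DataFrame, path) -> None:
    _write_table(validate_probe_design(design), path)


def read_probe_design(path) -> pd.DataFrame:
    df = _read_table(path, DESIGN_COLUMNS, {"probe_id": str, "chrom": str, "locus_id": str})
    return validate_probe_design(df, source=str(path))


# ---------------------------------------------------------------------------
# BED tracks


def read_bed(path, name: str | None = None) -> AnnotationTrack:
    """Read a BED3+ file (tab or space separated, optional name/score columns)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            elem = parts[3] if len(parts) > 3 else "."
            try:
                score = float(parts[4]) if len(parts) > 4 else 0.0
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            rows.append((chrom, start, end, elem, score))
    df = pd.DataFrame(rows, columns=BED_COLUMNS)
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(str(path)))[0]
    return AnnotationTrack(name=name, intervals=df)


def write_bed(track: AnnotationTrack, path) -> None:
    _write_table(track.intervals, path)


# ---------------------------------------------------------------------------
# intensities


def write_intensities(table: pd.DataFrame, path) -> None:
    _write_table(table[INTENSITY_COLUMNS], path)


def read_intensities(path, design: pd.DataFrame) -> pd.DataFrame:
    """Read a long-format two-channel intensity table and check it against a design.

    Every array present must carry exactly one (bound, input) pair per probe of
    the design; channels must be strictly positive.
    """
    table = _read_table(
        path, INTENSITY_COLUMNS, {"array_id": str, "probe_id": str, "bound": float, "input": float}
    )
    return validate_intensities(table, design, source=str(path))


def validate_intensities(table: pd.DataFrame, design: pd.DataFrame, source: str = "intensities") -> pd.DataFrame:
    if len(table) and ((table["bound"] <= 0) | (table["input"] <= 0)).any():
        bad = table.index[(table["bound"] <= 0) | (table["input"] <= 0)][0]
        raise FormatError(f"{source}: non-positive channel at row {bad}")
    known = set(design["probe_id"])
    unknown = set(table["probe_id"]) - known
    if unknown:
        raise FormatError(f"{source}: probes absent from design: {sorted(unknown)[:5]}")
    for array_id, sub in table.groupby("array_id", sort=False):
        missing = known - set(sub["probe_id"])
        if missing:
            raise CompletenessError(
                f"{source}: array {array_id!r} missing probes {sorted(missing)[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        if sub["probe_id"].duplicated().any():
            raise FormatError(f"{source}: array {array_id!r} has duplicated probe rows")
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# sample sheet / phenotype / gene models


def validate_sample_sheet(sheet: pd.DataFrame, source: str = "samples") -> pd.DataFrame:
    missing = [c for c in SAMPLE_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"{source}: missing columns {missing}")
    sheet = sheet[SAMPLE_COLUMNS].copy()
    sheet["replicate"] = sheet["replicate"].astype(int)
    if sheet["array_id"].duplicated().any():
        raise FormatError(f"{source}: duplicated array_id")
    if sheet.duplicated(subset=["subject_id", "cell_type", "replicate"]).any():
        raise FormatError(f"{source}: duplicated (subject, cell_type, replicate)")
    ngroups = sheet.groupby("subject_id")["group"].nunique()
    if (ngroups > 1).any():
        raise FormatError(f"{source}: subject assigned to more than one group")
    return sheet.reset_index(drop=True)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    _write_table(validate_sample_sheet(sheet), path)


def read_sample_sheet(path) -> pd.DataFrame:
    df = _read_table(path, SAMPLE_COLUMNS, {c: str for c in SAMPLE_COLUMNS[:-1]})
    return validate_sample_sheet(df, source=str(path))


def write_phenotypes(table: pd.DataFrame, path) -> None:
    _write_table(table[PHENOTYPE_COLUMNS], path)


def read_phenotypes(path) -> pd.DataFrame:
    df = _read_table(path, PHENOTYPE_COLUMNS, {"subject_id": str, "analyte": str, "level": float})
    if df.duplicated(subset=["subject_id", "analyte"]).any():
        raise FormatError(f"{path}: duplicated (subject, analyte) pair")
    return df


def validate_gene_models(genes: pd.DataFrame, source: str = "genes") -> pd.DataFrame:
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise FormatError(f"{source}: missing columns {missing}")
    genes = genes[GENE_COLUMNS].copy()
    genes["tss"] = genes["tss"].astype(np.int64)
    genes["tes"] = genes["tes"].astype(np.int64)
    if genes["gene_id"].duplicated().any():
        raise FormatError(f"{source}: duplicated gene_id")
    if not genes["strand"].isin(["+", "-"]).all():
        raise FormatError(f"{source}: strand must be '+' or '-'")
    plus_bad = (genes["strand"] == "+") & (genes["tss"] >= genes["tes"])
    minus_bad = (genes["strand"] == "-") & (genes["tss"] <= genes["tes"])
    if plus_bad.any() or minus_bad.any():
        raise FormatError(f"{source}: tss/tes inconsistent with strand")
    return genes.reset_index(drop=True)


def write_gene_models(genes: pd.DataFrame, path) -> None:
    _write_table(validate_gene_models(genes), path)


def read_gene_models(path) -> pd.DataFrame:
    df = _read_table(path, GENE_COLUMNS, {"gene_id": str, "chrom": str, "strand": str})
    return validate_gene_models(df, source=str(path))


def write_matrix(matrix: pd.DataFrame, path, provenance: list[str] | None = None) -> None:
    """Write a probes x subjects methylation matrix (index probe_id)."""
    out = matrix.reset_index()
    out.columns = ["probe_id"] + list(matrix.columns)
    _write_table(out, path, float_format="%.8g", provenance=provenance)


def read_matrix(path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
        while first.startswith("##"):
            first = fh.readline()
        if not first.startswith("#"):
            raise FormatError(f"{path}: expected '#'-prefixed header line")
        names = first.lstrip("#").strip().split("\t")
        df = pd.read_csv(fh, sep="\t", names=names)
    return df.set_index("probe_id")
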