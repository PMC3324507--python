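"""Tabular IO for pooled-screen artifacts.

All files are tab-separated UTF-8 with a header row. Probes are rows,
samples are columns, matching the per-probe modeling orientation. Column
order of the intensity matrix follows sample-sheet order so that repeated
runs diff cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROBE_COLUMNS = ["probe_id", "target_gene", "is_negative_control", "description"]
SAMPLE_COLUMNS = [
    "sample_id",
    "cell_line",
    "arm",
    "dose",
    "timepoint",
    "replicate",
    "acquisition_date",
    "is_preselection",
]

ARMS = ("vehicle", "treated")
TIMEPOINTS = ("T0", "T1", "T2")


class ValidationError(ValueError):
    """Raised when a table violates the screen's structural invariants."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class IntensityMatrix:
    """Probe x sample signal table with a scale flag (``raw`` or ``log2``).

    ``values`` is a DataFrame indexed by probe_id with sample_id columns.
    Raw-scale values must be non-negative.
    """

    values: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if not self.values.index.is_unique:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids: {dups}")
        if not self.values.columns.is_unique:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if self.scale == "raw" and (self.values.to_numpy() < 0).any():
            raise ValidationError("raw intensities must be non-negative")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.values.copy(), self.scale)


@dataclass
class HitTable:
    """Probes passing the fold-change / p-value thresholds.

    ``probe_hits`` has one row per qualifying probe (probe_id, target_gene,
    log2fc, p, direction); ``gene_summary`` has one row per gene with
    probes_scored. ``universe`` is the set of probe ids that were tested,
    needed for cross-line comparisons.
    """

    probe_hits: pd.DataFrame
    gene_summary: pd.DataFrame
    fc_cut: float = 0.58
    p_cut: float = 0.01
    direction: str = "both"
    universe: tuple = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_probe_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PROBE_COLUMNS if c not in annotation.columns]
    if missing:
        raise ValidationError(f"probe annotation missing columns: {missing}")
    if annotation["probe_id"].duplicated().any():
        dups = annotation.loc[annotation["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValidationError(f"duplicate probe ids in annotation: {dups}")
    neg = annotation["is_negative_control"].astype(bool)
    bad = annotation.loc[neg & (annotation["target_gene"].fillna("") != ""), "probe_id"]
    if len(bad):
        raise ValidationError(
            f"negative-control probes must have empty target_gene: {bad.tolist()}"
        )
    return annotation


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValidationError(f"sample sheet missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids: {dups}")
    bad_arm = set(sheet["arm"]) - set(ARMS)
    if bad_arm:
        raise ValidationError(f"unknown arm labels: {sorted(bad_arm)}")
    bad_tp = set(sheet["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise ValidationError(f"unknown timepoints: {sorted(bad_tp)}")
    pre = sheet["is_preselection"].astype(bool)
    if ((sheet["timepoint"] == "T0") != pre).any():
        raise ValidationError("is_preselection must be true exactly for T0 samples")
    return sheet


def specimen_key(sheet: pd.DataFrame) -> pd.Series:
    """Biological-specimen identity: technical replicates share this key."""
    return (
        sheet["cell_line"].astype(str)
        + "|" + sheet["arm"].astype(str)
        + "|" + sheet["dose"].astype(str)
        + "|" + sheet["timepoint"].astype(str)
        + "|" + sheet["replicate"].astype(str)
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_probe_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "target_gene": str})
    ann["target_gene"] = ann["target_gene"].fillna("")
    if "description" in ann.columns:
        ann["description"] = ann["description"].fillna("")
    ann["is_negative_control"] = ann["is_negative_control"].astype(bool)
    return validate_probe_annotation(ann)


def write_probe_annotation(annotation: pd.DataFrame, path) -> None:
    validate_probe_annotation(annotation)
    annotation.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "acquisition_date": str})
    sheet["is_preselection"] = sheet["is_preselection"].astype(bool)
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    validate_sample_sheet(sheet)
    sheet.to_csv(path, sep="\t", index=False)


def read_matrix(path, annotation: pd.DataFrame, sheet: pd.DataFrame,
                scale: str = "raw") -> IntensityMatrix:
    """Read a probe x sample intensity table and validate it.

    First column must be probe_id; header carries sample ids. Unknown probes
    or samples, duplicate probe rows, and non-numeric cells are hard errors.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate probe rows: {dups}")

    known_probes = set(annotation["probe_id"])
    unknown_probes = [p for p in raw.index if p not in known_probes]
    if unknown_probes:
        raise ValidationError(f"probes absent from annotation: {unknown_probes}")
    known_samples = set(sheet["sample_id"])
    unknown_samples = [s for s in raw.columns if s not in known_samples]
    if unknown_samples:
        raise ValidationError(f"samples absent from sample sheet: {unknown_samples}")

    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        probe_check = pd.to_numeric(raw[col], errors="coerce")
        bad = probe_check.isna() & raw[col].notna()
        if bad.any():
            probe = raw.index[bad.to_numpy().argmax()]
            raise ValidationError(
                f"non-numeric cell at probe {probe!r}, sample {col!r}: "
                f"{raw.loc[probe, col]!r}"
            )
        # astype(float) is correctly rounded (to_numeric's fast path is not),
        # so written matrices read back bit-identically
        values[col] = raw[col].astype(float)
    if values.isna().any().any():
        raise ValidationError("missing values in intensity matrix")

    # column order follows the sample sheet for deterministic serialization
    ordered = [s for s in sheet["sample_id"] if s in values.columns]
    return IntensityMatrix(values[ordered], scale=scale)


def write_matrix(matrix: IntensityMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id", float_format="%.17g")


def write_hit_table(hits: HitTable, probe_path, gene_path) -> None:
    """Write the per-probe hit rows and the per-gene probes_scored summary."""
    probe_cols = ["probe_id", "target_gene", "log2fc", "p", "direction"]
    probes = hits.probe_hits.reindex(columns=probe_cols)
    probes.to_csv(probe_path, sep="\t", index=False, float_format="%.17g")
    gene_cols = ["target_gene", "probes_scored", "log2fc_values", "p_values"]
    genes = hits.gene_summary.reindex(columns=gene_cols)
    genes.to_csv(gene_path, sep="\t", index=False)


def read_geo_style_matrix(path, annotation, sheet, mapping_path, scale="raw"):
    """Adapter for series-matrix-style tables whose columns are array names.

    ``mapping_path`` is a two-column TSV (array_column, sample_id) supplied by
    the user, since the deposited series does not publish the screen's
    sample-sheet metadata.
    """
    mapping = pd.read_csv(mapping_path, sep="\t", dtype=str)
    raw = pd.read_csv(path, sep="\t", index_col=0)
    rename = dict(zip(mapping.iloc[:, 0], mapping.iloc[:, 1]))
    unknown = [c for c in raw.columns if c not in rename]
    if unknown:
        raise ValidationError(f"array columns missing from mapping: {unknown}")
    renamed = raw.rename(columns=rename)
    tmp = renamed.copy()
    tmp.index.name = "probe_id"
    import io

    buf = io.StringIO()
    tmp.to_csv(buf, sep="\t")
    buf.seek(0)
    return read_matrix(buf, annotation, sheet, scale=scale)
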