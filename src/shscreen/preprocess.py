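"""Raw intensities -> analysis-ready matrix.

Fixed stage order: log2 transform, per-sample IQR quality control,
technical-replicate resolution (most recent acquisition wins), quantile
normalization, negative-control background estimation from pre-selection
samples, detection filtering. Each stage emits a machine-readable report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .screenio import IntensityMatrix, ValidationError, specimen_key


@dataclass
class QCReport:
    """Per-sample QC record: log2 IQR plus exclusions with reasons."""

    records: pd.DataFrame  # sample_id, iqr, excluded, reason

    @property
    def excluded(self) -> list:
        return self.records.loc[self.records["excluded"], "sample_id"].tolist()

    @property
    def retained(self) -> list:
        return self.records.loc[~self.records["excluded"], "sample_id"].tolist()


@dataclass
class BackgroundEstimate:
    """Negative-control background thresholds from pre-selection samples.

    per_sample maps each T0 sample id to the percentile of its own
    negative-control intensities; pooled is the same percentile over all T0
    negative-control values, kept as a global fallback.
    """

    per_sample: dict
    pooled: float
    percentile: float
    source_samples: list = field(default_factory=list)


@dataclass
class DetectionMask:
    """Per-probe keep/drop decision from the background filter."""

    records: pd.DataFrame  # probe_id, n_above, n_t0, keep, is_negative_control

    @property
    def kept(self) -> list:
        return self.records.loc[self.records["keep"], "probe_id"].tolist()

    @property
    def dropped(self) -> list:
        return self.records.loc[~self.records["keep"], "probe_id"].tolist()


def log2_transform(matrix: IntensityMatrix, offset: float = 1.0) -> IntensityMatrix:
    """log2(value + offset); the offset tolerates zero intensities."""
    if matrix.scale != "raw":
        raise ValidationError("matrix is already on the log2 scale")
    if (matrix.values.to_numpy() < 0).any():
        raise ValidationError("negative raw intensities")
    return IntensityMatrix(np.log2(matrix.values + offset), scale="log2")


def qc_iqr_filter(matrix: IntensityMatrix, threshold: float = 6.0):
    """Drop outlier samples whose log2 IQR is strictly below the threshold."""
    if matrix.scale != "log2":
        raise ValidationError("IQR QC expects a log2-scale matrix")
    iqr = matrix.values.quantile(0.75) - matrix.values.quantile(0.25)
    excluded = iqr < threshold
    report = QCReport(
        pd.DataFrame(
            {
                "sample_id": matrix.sample_ids,
                "iqr": iqr.to_numpy(),
                "excluded": excluded.to_numpy(),
                "reason": np.where(excluded, "low_iqr", ""),
            }
        )
    )
    keep = [s for s in matrix.sample_ids if not excluded[s]]
    if not keep:
        raise ValidationError("all samples excluded by IQR QC")
    return IntensityMatrix(matrix.values[keep], scale=matrix.scale), report


def resolve_technical_replicates(matrix: IntensityMatrix, sheet: pd.DataFrame):
    """Within each biological specimen, keep only the most recent scan.

    Ties on acquisition_date break lexicographically on sample_id (larger
    wins) so resolution is deterministic.
    """
    sub = sheet[sheet["sample_id"].isin(matrix.sample_ids)].copy()
    sub["specimen"] = specimen_key(sub)
    keep, drop = [], []
    for _, group in sub.groupby("specimen", sort=False):
        if len(group) > 1 and group["acquisition_date"].isna().any():
            raise ValidationError(
                f"missing acquisition dates in duplicated specimen "
                f"{group['specimen'].iloc[0]!r}"
            )
        ranked = group.sort_values(["acquisition_date", "sample_id"])
        keep.append(ranked["sample_id"].iloc[-1])
        drop.extend(ranked["sample_id"].iloc[:-1])
    keep_set = set(keep)
    records = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "iqr": np.nan,
            "excluded": [s not in keep_set for s in matrix.sample_ids],
            "reason": ["" if s in keep_set else "superseded_replicate"
                       for s in matrix.sample_ids],
        }
    )
    kept_cols = [s for s in matrix.sample_ids if s in keep_set]
    return IntensityMatrix(matrix.values[kept_cols], scale=matrix.scale), QCReport(records)


def quantile_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Force every sample onto the common distribution of mean order statistics.

    After normalization all columns share the identical sorted vector and
    each column's within-sample ranks are preserved. Ties within a column
    receive the mean of the reference values across their tied ranks.
    """
    if matrix.scale != "log2":
        raise ValidationError("quantile normalization expects log2 scale")
    values = matrix.values.to_numpy(dtype=float)
    n_probes, n_samples = values.shape
    if n_samples < 2:
        import warnings

        warnings.warn("single-column matrix: quantile normalization is the identity")
        return matrix.copy()

    order = np.argsort(values, axis=0, kind="stable")
    reference = np.sort(values, axis=0).mean(axis=1)

    out = np.empty_like(values)
    for j in range(n_samples):
        col = values[:, j]
        normalized = np.empty(n_probes)
        normalized[order[:, j]] = reference
        # average reference values over runs of tied input values
        sorted_col = col[order[:, j]]
        start = 0
        for end in range(1, n_probes + 1):
            if end == n_probes or sorted_col[end] != sorted_col[start]:
                if end - start > 1:
                    normalized[order[start:end, j]] = reference[start:end].mean()
                start = end
        out[:, j] = normalized
    return IntensityMatrix(
        pd.DataFrame(out, index=matrix.probe_ids, columns=matrix.sample_ids),
        scale="log2",
    )


def _percentile(values: np.ndarray, p: float) -> float:
    """Order statistic at rank 1 + (n-1)p with linear interpolation."""
    return float(np.quantile(np.asarray(values, dtype=float), p, method="linear"))


def estimate_background(
    matrix: IntensityMatrix,
    annotation: pd.DataFrame,
    sheet: pd.DataFrame,
    percentile: float = 0.95,
) -> BackgroundEstimate:
    """Background = the given percentile of negative-control signal,
    estimated only from pre-selection (T0) samples: per-sample thresholds
    plus a pooled global fallback."""
    nc_probes = annotation.loc[annotation["is_negative_control"], "probe_id"]
    nc_present = [p for p in nc_probes if p in matrix.probe_ids]
    if not nc_present:
        raise ValidationError("no negative-control probes in matrix")
    t0 = sheet.loc[
        sheet["is_preselection"].astype(bool) & sheet["sample_id"].isin(matrix.sample_ids),
        "sample_id",
    ].tolist()
    if not t0:
        raise ValidationError("no pre-selection (T0) samples available")

    nc_values = matrix.values.loc[nc_present, t0]
    per_sample = {s: _percentile(nc_values[s].to_numpy(), percentile) for s in t0}
    pooled = _percentile(nc_values.to_numpy().ravel(), percentile)
    return BackgroundEstimate(per_sample, pooled, percentile, source_samples=t0)


def detection_filter(
    matrix: IntensityMatrix,
    background: BackgroundEstimate,
    annotation: pd.DataFrame,
    sheet: pd.DataFrame,
    mode: str = "per-sample",
):
    """Keep a probe iff it exceeds background on a strict majority of T0 samples.

    "Exceeds" is strict (>); a tie on the majority count drops the probe.
    Negative-control probes are dropped unconditionally — they never enter
    downstream modeling.
    """
    if mode not in ("per-sample", "pooled"):
        raise ValidationError(f"unknown background mode {mode!r}")
    t0 = background.source_samples
    n_t0 = len(t0)
    sub = matrix.values[t0]
    if mode == "per-sample":
        thresholds = np.array([background.per_sample[s] for s in t0])
    else:
        thresholds = np.full(n_t0, background.pooled)
    above = (sub.to_numpy() > thresholds[None, :]).sum(axis=1)

    is_nc = (
        annotation.set_index("probe_id")["is_negative_control"]
        .reindex(matrix.probe_ids)
        .fillna(False)
        .astype(bool)
        .to_numpy()
    )
    keep = (above > n_t0 / 2.0) & ~is_nc
    records = pd.DataFrame(
        {
            "probe_id": matrix.probe_ids,
            "n_above": above,
            "n_t0": n_t0,
            "keep": keep,
            "is_negative_control": is_nc,
        }
    )
    mask = DetectionMask(records)
    filtered = IntensityMatrix(matrix.values.loc[keep], scale=matrix.scale)
    return filtered, mask


def run_preprocess(
    matrix: IntensityMatrix,
    annotation: pd.DataFrame,
    sheet: pd.DataFrame,
    iqr_threshold: float = 6.0,
    bg_percentile: float = 0.95,
    bg_mode: str = "per-sample",
    log2_offset: float = 1.0,
):
    """Run the full preprocessing chain in its fixed order.

    Returns (matrix, reports) where reports is a dict with the QC report,
    replicate-resolution report, background estimate and detection mask.
    """
    logm = log2_transform(matrix, offset=log2_offset)
    logm, qc = qc_iqr_filter(logm, threshold=iqr_threshold)
    logm, reps = resolve_technical_replicates(logm, sheet)
    norm = quantile_normalize(logm)
    background = estimate_background(norm, annotation, sheet, percentile=bg_percentile)
    detected, mask = detection_filter(norm, background, annotation, sheet, mode=bg_mode)
    return detected, {
        "qc": qc,
        "replicates": reps,
        "background": background,
        "detection": mask,
    }
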