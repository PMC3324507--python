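"""Per-probe linear modeling of treated-vs-vehicle abundance.

For each detected probe, ordinary least squares is fit over the
post-selection samples with terms for treatment (both drug doses pooled
into one level), timepoint, and replicate. The treatment coefficient is the
log2 treated/vehicle fold change. Variances are optionally moderated by
empirical-Bayes shrinkage toward a pooled prior: the per-probe sample
variance s_g^2 on d_g residual df is combined with a prior (d0, s0^2),

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

and the moderated t = beta_g / (s~_g * sqrt(v)) is referred to a t
distribution on d0 + d_g df. The hyper-parameters are estimated by
moment-matching the log sample variances against a scaled-F model.

Hit calling applies the screen's thresholds (|log2fc| >= 0.58, p <= 0.01,
boundaries inclusive), aggregates qualifying probes per target gene, and
checks cross-cell-line specificity. A permutation F-test flags hairpins
drifting over time in vehicle alone, and hierarchical clustering orders hit
probes for heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.special import digamma, polygamma

from .screenio import HitTable, IntensityMatrix, ValidationError


@dataclass
class DesignMatrix:
    """Indicator design over post-selection samples of one cell line."""

    frame: pd.DataFrame  # rows = sample_id, columns = model terms
    treatment_column: str = "treated"

    @property
    def sample_ids(self) -> pd.Index:
        return self.frame.index


def build_design(sheet: pd.DataFrame, cell_line: str | None = None) -> DesignMatrix:
    """Intercept + treated (doses pooled) + timepoint + replicate indicators.

    T0 samples are excluded; categorical factors are encoded against their
    first level. Degenerate one-level factors contribute no columns. A
    rank-deficient design (e.g. a single-arm sheet) is a hard error.
    """
    post = sheet[~sheet["is_preselection"].astype(bool)].copy()
    if cell_line is not None:
        post = post[post["cell_line"] == cell_line]
    lines = post["cell_line"].unique()
    if len(lines) > 1:
        raise ValidationError(f"design must cover one cell line, got {sorted(lines)}")
    if post.empty:
        raise ValidationError("no post-selection samples")

    cols = {"intercept": np.ones(len(post))}
    cols["treated"] = ((post["arm"] == "treated") | (post["dose"] > 0)).astype(float).to_numpy()
    for factor in ("timepoint", "replicate"):
        levels = sorted(post[factor].unique())
        for level in levels[1:]:
            cols[f"{factor}_{level}"] = (post[factor] == level).astype(float).to_numpy()
    frame = pd.DataFrame(cols, index=post["sample_id"].to_numpy())
    if np.linalg.matrix_rank(frame.to_numpy()) < frame.shape[1]:
        raise ValidationError("rank-deficient design (single treatment arm?)")
    return DesignMatrix(frame)


def fit_probe_model(matrix: IntensityMatrix, design: DesignMatrix) -> pd.DataFrame:
    """OLS per probe; returns one row per probe with the treatment effect.

    Columns: log2fc, se, df_resid, t, p, sigma2, ok. Probes with no residual
    degrees of freedom are flagged ok=False and excluded from testing.
    """
    X = design.frame.to_numpy(dtype=float)
    samples = [s for s in design.sample_ids if s in matrix.sample_ids]
    if len(samples) != len(design.sample_ids):
        missing = set(design.sample_ids) - set(samples)
        raise ValidationError(f"design samples missing from matrix: {sorted(missing)}")
    Y = matrix.values[list(design.sample_ids)].to_numpy(dtype=float)

    n, p = X.shape
    df_resid = n - p
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ (xtx_inv @ X.T).T  # probes x p
    resid = Y - beta @ X.T
    j = design.frame.columns.get_loc(design.treatment_column)
    vj = xtx_inv[j, j]

    if df_resid > 0:
        sigma2 = (resid ** 2).sum(axis=1) / df_resid
        se = np.sqrt(sigma2 * vj)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta[:, j] / se, np.inf * np.sign(beta[:, j]))
        pval = 2.0 * stats.t.sf(np.abs(t), df_resid)
        pval = np.clip(pval, np.finfo(float).tiny, 1.0)
        ok = np.ones(Y.shape[0], dtype=bool)
    else:
        sigma2 = np.full(Y.shape[0], np.nan)
        se = np.full(Y.shape[0], np.nan)
        t = np.full(Y.shape[0], np.nan)
        pval = np.full(Y.shape[0], np.nan)
        ok = np.zeros(Y.shape[0], dtype=bool)

    return pd.DataFrame(
        {
            "log2fc": beta[:, j],
            "se": se,
            "df_resid": df_resid,
            "t": t,
            "p": pval,
            "sigma2": sigma2,
            "v_treatment": vj,
            "ok": ok,
        },
        index=matrix.probe_ids,
    )


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # good starting point for all x > 0
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if np.all(np.abs(dif) < 1e-10 * y):
            break
    return y


def estimate_variance_prior(sigma2: np.ndarray, df: np.ndarray):
    """Moment-match (d0, s0^2) from log sample variances.

    Under the scaled-F model, e_g = log s_g^2 - digamma(d_g/2) + log(d_g/2)
    has mean log s0^2 + digamma(d0/2) - log(d0/2) and variance
    trigamma(d0/2) + trigamma(d_g/2); d0 comes from inverting the trigamma,
    s0^2 from the mean. Returns (d0, s0sq); d0 = inf when the observed
    variances are no more dispersed than sampling alone explains.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), sigma2.shape)
    keep = np.isfinite(sigma2) & (sigma2 > -1e-15) & (df > 0)
    if keep.sum() < 2:
        raise ValidationError("not enough positive residual variances to moderate")
    s2, d = np.maximum(sigma2[keep], 0.0), df[keep]
    m = np.median(s2)
    if m == 0:
        raise ValidationError("more than half of residual variances are zero")
    # zero variances (e.g. probes pinned to constant values by rank-preserving
    # normalization) are offset away from zero rather than dropped, so they
    # still widen the prior instead of silently vanishing
    s2 = np.maximum(s2, 1e-5 * m)
    e = np.log(s2) - digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = e.mean()
    excess = e.var(ddof=1) - polygamma(1, d / 2.0).mean()
    if excess <= 0:
        # variances no more dispersed than sampling alone explains: the
        # prior is a point mass at the pooled variance
        return np.inf, float(np.mean(s2))
    d0 = float(2.0 * _trigamma_inverse(np.array([excess]))[0])
    s0sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0sq


def moderate_variances(fits: pd.DataFrame, d0: float | None = None,
                       s0sq: float | None = None) -> pd.DataFrame:
    """Add empirical-Bayes moderated t and p columns to a fit table.

    Hyper-parameters are estimated from the fits unless supplied; d0 = 0
    reproduces the ordinary statistics exactly, d0 = inf pins every variance
    at s0^2.
    """
    out = fits.copy()
    ok = out["ok"].to_numpy(dtype=bool)
    sigma2 = out["sigma2"].to_numpy(dtype=float)
    df = out["df_resid"].to_numpy(dtype=float)
    if d0 is None or s0sq is None:
        est_d0, est_s0 = estimate_variance_prior(sigma2[ok], df[ok])
        d0 = est_d0 if d0 is None else d0
        s0sq = est_s0 if s0sq is None else s0sq

    if np.isinf(d0):
        s2_mod = np.full_like(sigma2, s0sq)
        df_mod = np.full_like(df, np.inf)
    elif d0 == 0:
        s2_mod = sigma2
        df_mod = df
    else:
        s2_mod = (d0 * s0sq + df * sigma2) / (d0 + df)
        df_mod = d0 + df

    v = out["v_treatment"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = out["log2fc"].to_numpy() / np.sqrt(s2_mod * v)
    finite_df = np.where(np.isinf(df_mod), 1e9, df_mod)  # t -> normal limit
    p_mod = 2.0 * stats.t.sf(np.abs(t_mod), finite_df)
    p_mod = np.clip(p_mod, np.finfo(float).tiny, 1.0)

    out["t_moderated"] = np.where(ok, t_mod, np.nan)
    out["p_moderated"] = np.where(ok, p_mod, np.nan)
    out["d0"] = d0
    out["s0sq"] = s0sq
    return out


def call_hits(
    fits: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    fc_cut: float = 0.58,
    p_cut: float = 0.01,
    direction: str = "both",
    use_moderated: bool = True,
    add_bh_fdr: bool = True,
) -> HitTable:
    """Threshold fitted probes into a HitTable (boundaries inclusive).

    Depleted: log2fc <= -fc_cut; enriched: log2fc >= +fc_cut; in both cases
    p <= p_cut. No multiple-testing correction is applied to the calls,
    mirroring the screen's raw p-value rule; a BH-FDR column is attached for
    reference only.
    """
    if direction not in ("both", "depleted", "enriched"):
        raise ValidationError(f"unknown direction {direction!r}")
    work = fits.copy()
    if "ok" in work.columns:
        work = work[work["ok"].astype(bool)]
    pcol = "p_moderated" if (use_moderated and "p_moderated" in work.columns) else "p"
    p = work[pcol].to_numpy(dtype=float)
    fc = work["log2fc"].to_numpy(dtype=float)

    if add_bh_fdr and len(p):
        order = np.argsort(p, kind="stable")
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        fdr = np.empty_like(p)
        fdr[order] = np.minimum(ranked, 1.0)
        work = work.assign(bh_fdr=fdr)

    depleted = (fc <= -fc_cut) & (p <= p_cut)
    enriched = (fc >= fc_cut) & (p <= p_cut)
    if direction == "depleted":
        selected = depleted
    elif direction == "enriched":
        selected = enriched
    else:
        selected = depleted | enriched

    hits = work[selected].copy()
    hits["p"] = p[selected]
    hits["direction"] = np.where(depleted[selected], "depleted", "enriched")
    hits = hits.reset_index().rename(columns={hits.index.name or "index": "probe_id"})

    if annotation is not None:
        gene_map = annotation.set_index("probe_id")["target_gene"]
        hits["target_gene"] = hits["probe_id"].map(gene_map).fillna("")
    elif "target_gene" not in hits.columns:
        hits["target_gene"] = ""

    gene_summary = _summarize_genes(hits)
    return HitTable(
        probe_hits=hits,
        gene_summary=gene_summary,
        fc_cut=fc_cut,
        p_cut=p_cut,
        direction=direction,
        universe=tuple(work.index.astype(str)),
    )


def _summarize_genes(hits: pd.DataFrame) -> pd.DataFrame:
    mapped = hits[hits["target_gene"] != ""]
    if mapped.empty:
        return pd.DataFrame(
            columns=["target_gene", "probes_scored", "log2fc_values", "p_values"]
        )
    rows = []
    for gene, grp in mapped.groupby("target_gene", sort=True):
        rows.append(
            {
                "target_gene": gene,
                "probes_scored": len(grp),
                "log2fc_values": " ".join(f"{v:g}" for v in grp["log2fc"]),
                "p_values": " ".join(f"{v:g}" for v in grp["p"]),
            }
        )
    return pd.DataFrame(rows)


def aggregate_genes(hits: HitTable, annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-gene summary of a hit set: probes_scored and per-probe values.

    Probes without a gene mapping are warned about and excluded.
    """
    probe_hits = hits.probe_hits.copy()
    if annotation is not None:
        gene_map = annotation.set_index("probe_id")["target_gene"]
        probe_hits["target_gene"] = probe_hits["probe_id"].map(gene_map).fillna("")
    unmapped = probe_hits.loc[probe_hits["target_gene"] == "", "probe_id"]
    if len(unmapped):
        import warnings

        warnings.warn(f"probes with no gene mapping excluded: {unmapped.tolist()}")
    return _summarize_genes(probe_hits)


def cross_line_specificity(hits_primary: HitTable, hits_control: HitTable):
    """Split the primary hit set into line-specific and shared probes.

    A probe hit in both screens with the same direction is flagged
    non-specific; a probe moving the opposite way in the control line is
    retained. Both HitTables must come from the same probe universe.
    """
    if set(hits_primary.universe) != set(hits_control.universe):
        raise ValidationError("hit tables come from different probe universes")
    control_dir = dict(
        zip(hits_control.probe_hits["probe_id"], hits_control.probe_hits["direction"])
    )
    primary = hits_primary.probe_hits
    shared_mask = primary.apply(
        lambda row: control_dir.get(row["probe_id"]) == row["direction"], axis=1
    ) if len(primary) else pd.Series([], dtype=bool)
    flagged = primary[shared_mask].copy() if len(primary) else primary.copy()
    unique = primary[~shared_mask].copy() if len(primary) else primary.copy()
    unique_table = HitTable(
        probe_hits=unique,
        gene_summary=_summarize_genes(unique),
        fc_cut=hits_primary.fc_cut,
        p_cut=hits_primary.p_cut,
        direction=hits_primary.direction,
        universe=hits_primary.universe,
    )
    return unique_table, flagged


# ---------------------------------------------------------------------------
# vehicle-arm time drift
# ---------------------------------------------------------------------------


def _f_stats(Y: np.ndarray, X_full: np.ndarray, X_null: np.ndarray) -> np.ndarray:
    """Nested-model F per probe row; 0/0 (constant probe) defined as 0."""

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
        resid = Y.T - X @ beta
        return (resid ** 2).sum(axis=0)

    rss_full = rss(X_full)
    rss_null = rss(X_null)
    df_num = np.linalg.matrix_rank(X_full) - np.linalg.matrix_rank(X_null)
    df_den = Y.shape[1] - np.linalg.matrix_rank(X_full)
    if df_num <= 0 or df_den <= 0:
        raise ValidationError("drift test needs a nested design with residual df")
    # residual sums at rounding-noise level count as exact fits
    tiny = 1e-12 * ((Y ** 2).sum(axis=1) + 1.0)
    num = np.maximum(rss_null - rss_full, 0.0) / df_num
    with np.errstate(divide="ignore", invalid="ignore"):
        f = num / (rss_full / df_den)
    return np.where(
        rss_full > tiny, f, np.where(num > tiny, np.inf, 0.0)
    )


def timecourse_drift_test(
    matrix: IntensityMatrix,
    sheet: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation F-test for hairpins drifting over time in vehicle alone.

    Compares intercept+replicate+timepoint against intercept+replicate on
    the vehicle post-selection samples. Timepoint labels are shuffled within
    each replicate block; since the F statistic depends only on which samples
    share a level, shuffles that reproduce the observed sample partition are
    redrawn. n_perm such permutations contribute to
    p = (1 + #{F_perm >= F_obs}) / (n_perm + 1), so the smallest attainable
    p is 1/(n_perm+1).
    """
    veh = sheet[
        (sheet["arm"] == "vehicle")
        & ~sheet["is_preselection"].astype(bool)
        & sheet["sample_id"].isin(matrix.sample_ids)
    ]
    timepoints = sorted(veh["timepoint"].unique())
    if len(timepoints) < 2:
        raise ValidationError("drift test needs >= 2 post-selection timepoints")
    veh = veh.sort_values(["replicate", "timepoint"])
    sample_ids = veh["sample_id"].tolist()
    Y = matrix.values[sample_ids].to_numpy(dtype=float)

    replicates = sorted(veh["replicate"].unique())
    rep_arr = veh["replicate"].to_numpy()
    tp_arr = veh["timepoint"].to_numpy()

    def design_for(tp_labels: np.ndarray) -> np.ndarray:
        cols = [np.ones(len(veh))]
        for r in replicates[1:]:
            cols.append((rep_arr == r).astype(float))
        null_width = len(cols)
        for t in timepoints[1:]:
            cols.append((tp_labels == t).astype(float))
        X = np.column_stack(cols)
        return X, X[:, :null_width]

    X_full, X_null = design_for(tp_arr)
    f_obs = _f_stats(Y, X_full, X_null)

    rng = np.random.default_rng(seed)
    rep_indices = {r: np.where(rep_arr == r)[0] for r in replicates}

    def partition(labels: np.ndarray) -> frozenset:
        return frozenset(
            frozenset(np.flatnonzero(labels == t).tolist()) for t in timepoints
        )

    observed_partition = partition(tp_arr)
    count_ge = np.zeros(Y.shape[0])
    for _ in range(n_perm):
        while True:  # redraw shuffles equivalent to the observed grouping
            perm_tp = tp_arr.copy()
            for idx in rep_indices.values():
                perm_tp[idx] = perm_tp[idx[rng.permutation(len(idx))]]
            if partition(perm_tp) != observed_partition:
                break
        X_p, _ = design_for(perm_tp)
        count_ge += _f_stats(Y, X_p, X_null) >= f_obs
    p = (1.0 + count_ge) / (n_perm + 1.0)
    return pd.DataFrame({"F": f_obs, "p": p}, index=matrix.probe_ids)


# ---------------------------------------------------------------------------
# clustering for heatmaps
# ---------------------------------------------------------------------------


def treated_vs_vehicle_matrix(matrix: IntensityMatrix, sheet: pd.DataFrame) -> pd.DataFrame:
    """Per treated sample: log2 value minus the mean of matched vehicle
    samples (same timepoint and replicate) — the heatmap quantity."""
    post = sheet[~sheet["is_preselection"].astype(bool)]
    post = post[post["sample_id"].isin(matrix.sample_ids)]
    veh = post[post["arm"] == "vehicle"]
    trt = post[post["arm"] == "treated"]
    cols = {}
    for _, row in trt.iterrows():
        match = veh[
            (veh["timepoint"] == row["timepoint"]) & (veh["replicate"] == row["replicate"])
        ]["sample_id"].tolist()
        if not match:
            continue
        cols[row["sample_id"]] = (
            matrix.values[row["sample_id"]] - matrix.values[match].mean(axis=1)
        )
    if not cols:
        raise ValidationError("no treated/vehicle pairs to contrast")
    return pd.DataFrame(cols)


def cluster_hits(heatmap: pd.DataFrame, method: str = "average", metric: str = "euclidean"):
    """Agglomerative clustering of hit probes (rows) and samples (columns).

    Returns a dict with deterministic row/column orders, the two linkage
    matrices, and the reordered heatmap. Fewer than 2 rows gives the trivial
    ordering with no linkage.
    """
    if heatmap.shape[0] < 2:
        return {
            "row_order": list(heatmap.index),
            "col_order": list(heatmap.columns),
            "row_linkage": None,
            "col_linkage": None,
            "matrix": heatmap.copy(),
        }
    row_link = hierarchy.linkage(heatmap.to_numpy(), method=method, metric=metric)
    row_order = hierarchy.leaves_list(row_link)
    if heatmap.shape[1] >= 2:
        col_link = hierarchy.linkage(heatmap.to_numpy().T, method=method, metric=metric)
        col_order = hierarchy.leaves_list(col_link)
    else:
        col_link, col_order = None, np.arange(heatmap.shape[1])
    ordered = heatmap.iloc[row_order, col_order]
    return {
        "row_order": list(ordered.index),
        "col_order": list(ordered.columns),
        "row_linkage": row_link,
        "col_linkage": col_link,
        "matrix": ordered,
    }
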