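"""Tumor-cohort stage: expression classification and time to recurrence.

Tumors are classified against normal tissue by z-score,
z = (x - mean_normal) / sd_normal, with over-expression at z >= 2 and
reduced expression at z <= -2 (both boundaries inclusive). Alteration
summaries count the union of samples altered in any category. Survival is
summarized with the Kaplan-Meier estimator and compared between groups with
the two-sample log-rank test,

    chi2 = (sum_t (O1_t - E1_t))^2 / sum_t V_t ,

with the hypergeometric variance V_t = n1 n2 d (n - d) / (n^2 (n - 1)) at
each distinct event time; censored subjects leave the risk set without
contributing a step. Kaplan-Meier and log-rank computations are delegated
to lifelines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .screenio import ValidationError


def zscore_classify(
    expression: pd.DataFrame,
    sample_class: pd.Series,
    gene: str,
    hi: float = 2.0,
    lo: float = -2.0,
) -> pd.DataFrame:
    """Classify tumors as over / reduced / normal on one gene's z-score.

    ``expression`` is gene x sample; ``sample_class`` labels each sample
    'tumor' or 'normal'. The z reference is the normal samples' mean and SD
    (ddof=1). Returns one row per tumor with z and class.
    """
    if gene not in expression.index:
        raise ValidationError(f"gene {gene!r} not in expression table")
    normals = sample_class[sample_class == "normal"].index
    tumors = sample_class[sample_class == "tumor"].index
    if len(normals) < 2:
        raise ValidationError("need >= 2 normal samples to define the z-score SD")
    ref = expression.loc[gene, normals]
    mu, sd = float(ref.mean()), float(ref.std(ddof=1))
    if sd == 0:
        raise ValidationError("normal-sample SD is zero; z-score undefined")
    z = (expression.loc[gene, tumors] - mu) / sd
    cls = np.where(z >= hi, "over", np.where(z <= lo, "reduced", "normal"))
    return pd.DataFrame({"sample_id": tumors, "z": z.to_numpy(), "class": cls})


def alteration_table(alterations: dict, n_samples: int) -> pd.DataFrame:
    """Per-gene alteration counts and percent altered.

    ``alterations`` maps gene -> dict of category -> set of sample ids, with
    categories among mrna_up, mrna_down, amplified, deleted. Percent altered
    is the size of the union of all categories over n_samples, so a sample
    altered in several ways is counted once.
    """
    if n_samples <= 0:
        raise ValidationError("n_samples must be positive")
    rows = []
    for gene, cats in alterations.items():
        union = set()
        counts = {}
        for cat in ("mrna_up", "mrna_down", "amplified", "deleted"):
            ids = set(cats.get(cat, ()))
            counts[cat] = len(ids)
            union |= ids
        rows.append(
            {
                "gene": gene,
                "pct_altered": round(100.0 * len(union) / n_samples, 1),
                "n_altered": len(union),
                "mrna_up": counts["mrna_up"],
                "mrna_down": counts["mrna_down"],
                "amplified": counts["amplified"],
                "deleted": counts["deleted"],
            }
        )
    return pd.DataFrame(rows)


def alterations_from_calls(
    classification: pd.DataFrame, copy_number: pd.Series | None = None
) -> dict:
    """Build the per-category sample-id sets for one gene from a
    zscore_classify table and optional per-sample copy-number calls
    ('amplified' | 'deleted' | 'neutral')."""
    up = set(classification.loc[classification["class"] == "over", "sample_id"])
    down = set(classification.loc[classification["class"] == "reduced", "sample_id"])
    amp, dele = set(), set()
    if copy_number is not None:
        amp = set(copy_number[copy_number == "amplified"].index)
        dele = set(copy_number[copy_number == "deleted"].index)
    return {"mrna_up": up, "mrna_down": down, "amplified": amp, "deleted": dele}


def km_estimate(survival: pd.DataFrame, group_col: str | None = None) -> pd.DataFrame:
    """Kaplan-Meier survival curve(s): S(t) = prod_{t_i <= t} (1 - d_i/n_i).

    ``survival`` needs time_months and event columns; with ``group_col`` one
    curve per group. Returns rows (group, time, survival, n_at_risk,
    n_events) stepping only at event times.
    """
    if survival.empty:
        raise ValidationError("empty survival cohort")
    if (survival["time_months"] <= 0).any():
        raise ValidationError("survival times must be positive")
    groups = survival.groupby(group_col) if group_col else [("all", survival)]
    frames = []
    for name, grp in groups:
        if grp.empty:
            raise ValidationError(f"empty group {name!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(grp["time_months"], event_observed=grp["event"].astype(bool))
        table = kmf.event_table
        at_event = table[table["observed"] > 0]
        surv = kmf.survival_function_at_times(at_event.index).to_numpy()
        frames.append(
            pd.DataFrame(
                {
                    "group": name,
                    "time": at_event.index.to_numpy(dtype=float),
                    "survival": surv,
                    "n_at_risk": at_event["at_risk"].to_numpy(),
                    "n_events": at_event["observed"].to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def logrank_test(survival: pd.DataFrame, group_col: str = "group") -> dict:
    """Two-sample log-rank test; returns chi-square statistic (1 df) and p."""
    groups = survival[group_col].unique()
    if len(groups) != 2:
        raise ValidationError(f"log-rank needs exactly 2 groups, got {len(groups)}")
    a = survival[survival[group_col] == groups[0]]
    b = survival[survival[group_col] == groups[1]]
    if a.empty or b.empty:
        raise ValidationError("a group is empty")
    if not survival["event"].astype(bool).any():
        raise ValidationError("log-rank needs at least one event")
    res = _ll_logrank(
        a["time_months"], b["time_months"],
        event_observed_A=a["event"].astype(bool),
        event_observed_B=b["event"].astype(bool),
    )
    return {
        "statistic": float(res.test_statistic),
        "p": float(res.p_value),
        "groups": {str(groups[0]): int(len(a)), str(groups[1]): int(len(b))},
    }


def recurrence_analysis(
    expression: pd.DataFrame,
    sample_class: pd.Series,
    survival: pd.DataFrame,
    gene: str,
    hi: float = 2.0,
    lo: float = -2.0,
) -> dict:
    """Full downstream pipeline for one gene.

    z-classify tumors against normals, split into over vs not-over, then
    Kaplan-Meier curves and the log-rank p for biochemical recurrence.
    Survival and expression tables are joined on sample_id.
    """
    classification = zscore_classify(expression, sample_class, gene, hi=hi, lo=lo)
    merged = survival.merge(classification[["sample_id", "class"]], on="sample_id")
    if merged.empty:
        raise ValidationError("no shared samples between expression and survival tables")
    merged["group"] = np.where(merged["class"] == "over", f"{gene}-high", f"{gene}-not-over")
    sizes = merged["group"].value_counts().to_dict()
    if len(sizes) < 2:
        raise ValidationError(f"a group is empty: {sizes}")
    curves = km_estimate(merged, group_col="group")
    test = logrank_test(merged, group_col="group")
    return {
        "classification": classification,
        "groups": sizes,
        "km_curves": curves,
        "logrank": test,
    }
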