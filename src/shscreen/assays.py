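"""Normalization arithmetic for the validation assays.

Three small, exactly specified computations: viability as percent of a
control condition with SEM propagated from the numerator replicates,
caspase activity normalized to matched day-3 viability and expressed
relative to control, and 2^-ddCt relative expression against a reference
gene and a control condition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .screenio import ValidationError


def _check_readings(readings: pd.DataFrame) -> None:
    if (readings["value"] <= 0).any():
        raise ValidationError("luminescence values must be positive")


def viability_percent(readings: pd.DataFrame, control_condition: str) -> pd.DataFrame:
    """Mean percent-of-control viability per condition with SEM.

    value = 100 * mean(condition) / mean(control); SEM is the replicate
    standard error of the numerator divided by the control mean, so the
    control row reads exactly 100 with the spread of its own replicates.
    """
    _check_readings(readings)
    grouped = readings.groupby("condition")["value"]
    means = grouped.mean()
    if control_condition not in means.index:
        raise ValidationError(f"control condition {control_condition!r} missing")
    control_mean = means[control_condition]
    sems = grouped.apply(lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0)
    out = pd.DataFrame(
        {
            "condition": means.index,
            "percent_of_control": 100.0 * means.to_numpy() / control_mean,
            "sem": 100.0 * sems.to_numpy() / control_mean,
            "n_replicates": grouped.size().to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def apoptosis_ratio(
    caspase: pd.DataFrame, viability_day3: pd.DataFrame, control_condition: str
) -> pd.DataFrame:
    """Caspase activity / matched day-3 viability, relative to control.

    Both tables need condition and value columns over the same condition
    set; the per-condition ratio of means is divided by the control's ratio
    so the control condition maps to exactly 1.
    """
    _check_readings(caspase)
    _check_readings(viability_day3)
    casp = caspase.groupby("condition")["value"].mean()
    viab = viability_day3.groupby("condition")["value"].mean()
    if set(casp.index) != set(viab.index):
        raise ValidationError(
            "caspase and viability condition sets differ: "
            f"{sorted(set(casp.index) ^ set(viab.index))}"
        )
    if control_condition not in casp.index:
        raise ValidationError(f"control condition {control_condition!r} missing")
    ratio = casp / viab.reindex(casp.index)
    relative = ratio / ratio[control_condition]
    return pd.DataFrame(
        {
            "condition": ratio.index,
            "caspase_per_viability": ratio.to_numpy(),
            "relative_to_control": relative.to_numpy(),
        }
    ).reset_index(drop=True)


def relative_expression_ddct(
    records: pd.DataFrame, reference_gene: str, control_condition: str
) -> pd.DataFrame:
    """2^-ddCt fold change per (gene, condition) with an SEM envelope.

    dCt = Ct_target - Ct_reference is formed per replicate (matched by the
    replicate column within each condition); ddCt subtracts the control
    condition's mean dCt. The SEM band is the asymmetric envelope
    2^-(ddCt +/- SEM(dCt)), since fold changes are log-scale quantities.
    Fold changes are invariant to adding a constant to every Ct.
    """
    needed = {"target_gene", "condition", "replicate", "ct"}
    missing = needed - set(records.columns)
    if missing:
        raise ValidationError(f"qPCR records missing columns: {sorted(missing)}")
    ref = records[records["target_gene"] == reference_gene]
    if ref.empty:
        raise ValidationError(f"no reactions for reference gene {reference_gene!r}")
    ref_ct = ref.set_index(["condition", "replicate"])["ct"]

    rows = []
    targets = records[records["target_gene"] != reference_gene]
    for (gene, cond), grp in targets.groupby(["target_gene", "condition"]):
        key = pd.MultiIndex.from_arrays([grp["condition"], grp["replicate"]])
        try:
            matched_ref = ref_ct.loc[key]
        except KeyError as exc:
            raise ValidationError(
                f"missing reference reactions for {gene!r} in {cond!r}"
            ) from exc
        dct = grp["ct"].to_numpy() - matched_ref.to_numpy()
        rows.append({"target_gene": gene, "condition": cond,
                     "dct_mean": dct.mean(),
                     "dct_sem": dct.std(ddof=1) / np.sqrt(len(dct)) if len(dct) > 1 else 0.0})
    dct_table = pd.DataFrame(rows)

    out_rows = []
    for gene, grp in dct_table.groupby("target_gene"):
        ctrl = grp[grp["condition"] == control_condition]
        if ctrl.empty:
            raise ValidationError(
                f"control condition {control_condition!r} missing for {gene!r}"
            )
        dct_control = float(ctrl["dct_mean"].iloc[0])
        for _, row in grp.iterrows():
            ddct = row["dct_mean"] - dct_control
            sem = row["dct_sem"]
            out_rows.append(
                {
                    "target_gene": gene,
                    "condition": row["condition"],
                    "ddct": ddct,
                    "fold_change": 2.0 ** -ddct,
                    "fold_low": 2.0 ** -(ddct + sem),
                    "fold_high": 2.0 ** -(ddct - sem),
                }
            )
    return pd.DataFrame(out_rows)
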