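"""Synthetic pooled-screen and clinical-cohort generators.

The screen generator emulates the study design the analysis pipeline
expects: ~6,000 barcoded hairpins infected in triplicate, two drug doses
pooled against vehicle, pre-selection (T0) harvests plus two post-selection
timepoints, negative-control probes sitting at hybridization background,
and log-scale array noise. Per-hairpin log2 abundance evolves linearly in
the sampled-timepoint index t:

    a_h(t) = baseline_h + beta_h * t + treated * gamma_h * t

Abundances are renormalized to proportions per specimen, multinomially
sampled at the infection depth, and mapped to intensity as
log2(count + 0.5) + affinity_h + noise, where affinity_h is a per-probe
hybridization-efficiency term that gives the array its wide dynamic range.
Truth labels travel alongside so that hit-caller sensitivity and
false-discovery rate are measurable.

The cohort generator emulates the downstream tumor analysis: normals drawn
from a per-gene reference Gaussian, a planted over-expressing tumor class
shifted upward on the index gene, and exponential times to biochemical
recurrence with an elevated hazard in the high class, under administrative
censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd

from .screenio import (
    IntensityMatrix,
    ValidationError,
    validate_probe_annotation,
    validate_sample_sheet,
)

# effect-class labels in SimTruth
NEUTRAL = "neutral"
DEPLETED = "depleted_under_drug"
ENRICHED = "enriched_under_drug"
DROPOUT = "fitness_dropout"


@dataclass
class SimScreenConfig:
    """Study conditions for the synthetic screen.

    gamma is the drug-interaction log2-abundance change per sampled
    timepoint for planted hairpins; the default -2/3 yields an average
    treated-vs-vehicle log2 fold change of -1 across the two post-selection
    timepoints (t = 1, 2), matching the planted-effect scale the recovery
    benchmark assumes. beta_sd spreads drug-independent fitness drift across
    all hairpins; noise_sd is additive Gaussian noise on log2 intensity.
    depth is the number of cells sampled per specimen (6 million infected
    cells per replicate in the emulated screen).
    """

    n_hairpins: int = 6000
    n_genes: int = 2000
    n_neg_controls: int = 300
    replicates: int = 3
    doses: tuple = (0.4, 1.0)
    timepoints: tuple = (("T0", 0), ("T1", 8), ("T2", 21))
    frac_depleted: float = 100 / 6000
    frac_enriched: float = 0.0
    frac_dropout: float = 0.0
    gamma: float = -2.0 / 3.0
    gamma_enriched: float = 2.0 / 3.0
    beta_dropout: float = -1.0
    beta_sd: float = 0.05
    baseline_sd: float = 1.0
    affinity_sd: float = 5.0
    noise_sd: float = 0.3
    neg_control_sd: float = 0.25
    intensity_offset: float = 4.0  # scanner gain: keeps raw signal well above 1
    depth: int = 6_000_000
    cell_line: str = "LNCaP"
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_hairpins", "n_genes", "n_neg_controls", "replicates", "depth"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("frac_depleted", "frac_enriched", "frac_dropout"):
            frac = getattr(self, name)
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.frac_depleted + self.frac_enriched + self.frac_dropout > 1.0:
            raise ValidationError("effect-class fractions exceed 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.gamma != 0 and 0 < self.frac_depleted * self.n_hairpins < 1:
            raise ValidationError(
                "frac_depleted too small to plant a single hairpin at gamma != 0"
            )


@dataclass
class SimTruth:
    """Planted per-hairpin effect labels for recovery testing."""

    labels: pd.DataFrame  # probe_id, effect_class, gamma, beta

    def probes_in_class(self, effect_class: str) -> list:
        mask = self.labels["effect_class"] == effect_class
        return self.labels.loc[mask, "probe_id"].tolist()


@dataclass
class SimCohortConfig:
    """Study conditions for the synthetic tumor cohort.

    Defaults mirror the emulated cohort: 131 tumors with ~15% planted in the
    over-expressed class (shifted +3 SD on the index gene), a 3-fold hazard
    of biochemical recurrence in that class, exponential event times with a
    36-month median in the reference class, and ~30% administrative
    censoring.
    """

    n_tumors: int = 131
    n_normals: int = 29
    frac_high: float = 20 / 131
    shift_sd: float = 3.0
    hazard_ratio: float = 3.0
    median_months: float = 36.0
    censor_rate: float = 0.3
    index_gene: str = "TTK"
    n_extra_genes: int = 4
    normal_mean: float = 8.0
    normal_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_tumors <= 0 or self.n_normals < 2:
            raise ValidationError("need n_tumors > 0 and >= 2 normals")
        if not 0.0 <= self.frac_high <= 1.0:
            raise ValidationError("frac_high must be in [0, 1]")
        if self.hazard_ratio <= 0:
            raise ValidationError("hazard_ratio must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValidationError("censor_rate must be in [0, 1)")
        if self.hazard_ratio != 1 and 0 < self.frac_high * self.n_tumors < 1:
            raise ValidationError(
                "frac_high too small to plant a single high tumor at hazard_ratio != 1"
            )


# ---------------------------------------------------------------------------
# screen simulation
# ---------------------------------------------------------------------------


def _make_annotation(config: SimScreenConfig) -> pd.DataFrame:
    genes = [f"GENE{i + 1:05d}" for i in range(config.n_genes)]
    rows = []
    for h in range(config.n_hairpins):
        rows.append(
            {
                "probe_id": f"HP{h + 1:06d}",
                "target_gene": genes[h % config.n_genes],
                "is_negative_control": False,
                "description": "library hairpin",
            }
        )
    for c in range(config.n_neg_controls):
        rows.append(
            {
                "probe_id": f"NC{c + 1:05d}",
                "target_gene": "",
                "is_negative_control": True,
                "description": "hairpin absent from library",
            }
        )
    return validate_probe_annotation(pd.DataFrame(rows))


def _make_sheet(config: SimScreenConfig) -> pd.DataFrame:
    """One specimen per (arm x replicate x timepoint); T0 is pre-selection,
    harvested per replicate before the arms split."""
    rows = []
    base_date = pd.Timestamp("2010-01-01")
    tp_days = dict(config.timepoints)
    for rep in range(1, config.replicates + 1):
        rows.append(
            {
                "sample_id": f"{config.cell_line}_T0_rep{rep}",
                "cell_line": config.cell_line,
                "arm": "vehicle",
                "dose": 0.0,
                "timepoint": "T0",
                "replicate": rep,
                "acquisition_date": (base_date + pd.Timedelta(days=tp_days["T0"])).date().isoformat(),
                "is_preselection": True,
            }
        )
    arms = [("vehicle", 0.0)] + [("treated", d) for d in config.doses]
    for tp in ("T1", "T2"):
        for arm, dose in arms:
            for rep in range(1, config.replicates + 1):
                label = "veh" if arm == "vehicle" else f"bic{dose}"
                rows.append(
                    {
                        "sample_id": f"{config.cell_line}_{tp}_{label}_rep{rep}",
                        "cell_line": config.cell_line,
                        "arm": arm,
                        "dose": dose,
                        "timepoint": tp,
                        "replicate": rep,
                        "acquisition_date": (base_date + pd.Timedelta(days=tp_days[tp])).date().isoformat(),
                        "is_preselection": False,
                    }
                )
    return validate_sample_sheet(pd.DataFrame(rows))


def _assign_truth(config: SimScreenConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_hairpins
    n_dep = int(round(config.frac_depleted * n))
    n_enr = int(round(config.frac_enriched * n))
    n_drop = int(round(config.frac_dropout * n))
    ids = np.array([f"HP{h + 1:06d}" for h in range(n)])
    perm = rng.permutation(n)
    classes = np.full(n, NEUTRAL, dtype=object)
    classes[perm[:n_dep]] = DEPLETED
    classes[perm[n_dep:n_dep + n_enr]] = ENRICHED
    classes[perm[n_dep + n_enr:n_dep + n_enr + n_drop]] = DROPOUT

    beta = rng.normal(0.0, config.beta_sd, size=n)
    beta[classes == DROPOUT] += config.beta_dropout
    gamma = np.zeros(n)
    gamma[classes == DEPLETED] = config.gamma
    gamma[classes == ENRICHED] = config.gamma_enriched
    return pd.DataFrame(
        {"probe_id": ids, "effect_class": classes, "gamma": gamma, "beta": beta}
    )


def simulate_screen(config: SimScreenConfig):
    """Generate (IntensityMatrix, SampleSheet, ProbeAnnotation, SimTruth).

    Returns raw-scale intensities (2**log2 signal) so the matrix enters the
    pipeline at its natural starting point.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    annotation = _make_annotation(config)
    sheet = _make_sheet(config)
    truth_df = _assign_truth(config, rng)

    baseline = rng.normal(0.0, config.baseline_sd, size=config.n_hairpins)
    # per-probe hybridization efficiency: constant across samples, so it is
    # absorbed by each probe's model intercept; it carries the wide dynamic
    # range real barcode arrays show (and that the IQR sample-QC rule assumes)
    affinity = rng.normal(0.0, config.affinity_sd, size=config.n_hairpins)
    beta = truth_df["beta"].to_numpy()
    gamma = truth_df["gamma"].to_numpy()
    tp_index = {"T0": 0, "T1": 1, "T2": 2}

    hairpin_ids = truth_df["probe_id"].tolist()
    nc_ids = annotation.loc[annotation["is_negative_control"], "probe_id"].tolist()

    log2_cols = {}
    for _, sample in sheet.iterrows():
        t = tp_index[sample["timepoint"]]
        treated = 1.0 if sample["arm"] == "treated" else 0.0
        log_abund = baseline + beta * t + treated * gamma * t
        rel = np.exp2(log_abund)
        rel /= rel.sum()
        counts = rng.multinomial(config.depth, rel)
        signal = np.log2(counts + 0.5) + affinity + config.intensity_offset
        signal += rng.normal(0.0, config.noise_sd, size=config.n_hairpins)
        log2_cols[sample["sample_id"]] = signal

    # negative controls: fixed background Gaussian, independent of arm,
    # centered at the 5th percentile of real-probe intensity so the
    # detection filter has a meaningful floor to work against
    pooled = np.concatenate(list(log2_cols.values()))
    background_center = float(np.quantile(pooled, 0.05))
    for sid in list(log2_cols):
        nc = rng.normal(background_center, config.neg_control_sd, size=config.n_neg_controls)
        log2_cols[sid] = np.concatenate([log2_cols[sid], nc])

    values = pd.DataFrame(log2_cols, index=hairpin_ids + nc_ids)
    values = values[sheet["sample_id"].tolist()]
    raw = np.exp2(values)  # pipeline starts from raw-scale intensities
    matrix = IntensityMatrix(raw, scale="raw")
    return matrix, sheet, annotation, SimTruth(truth_df)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimCohortConfig):
    """Generate (expression DataFrame, survival DataFrame, SimTruth).

    Expression is gene x sample with a ``sample_class`` row convention left
    to the caller: tumors are ``TUM####``, normals ``NORM####``. Survival has
    one row per tumor: time_months, event, plus the planted class for truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_high = int(round(config.frac_high * config.n_tumors))
    tumor_ids = [f"TUM{i + 1:04d}" for i in range(config.n_tumors)]
    normal_ids = [f"NORM{i + 1:04d}" for i in range(config.n_normals)]
    high_idx = rng.permutation(config.n_tumors)[:n_high]
    is_high = np.zeros(config.n_tumors, dtype=bool)
    is_high[high_idx] = True

    genes = [config.index_gene] + [f"BG{i + 1:03d}" for i in range(config.n_extra_genes)]
    expr = pd.DataFrame(
        rng.normal(config.normal_mean, config.normal_sd,
                   size=(len(genes), config.n_tumors + config.n_normals)),
        index=genes,
        columns=tumor_ids + normal_ids,
    )
    expr.loc[config.index_gene, np.array(tumor_ids)[is_high]] += (
        config.shift_sd * config.normal_sd
    )
    sample_class = pd.Series(
        ["tumor"] * config.n_tumors + ["normal"] * config.n_normals,
        index=tumor_ids + normal_ids,
        name="sample_class",
    )

    base_hazard = np.log(2.0) / config.median_months
    hazard = np.where(is_high, base_hazard * config.hazard_ratio, base_hazard)
    event_times = rng.exponential(1.0 / hazard)

    # administrative censoring: study closes at the (1 - censor_rate)
    # quantile of the drawn event times
    if config.censor_rate > 0:
        close = np.quantile(event_times, 1.0 - config.censor_rate)
        event = event_times <= close
        times = np.minimum(event_times, close)
    else:
        event = np.ones(config.n_tumors, dtype=bool)
        times = event_times
    times = np.maximum(times, 1e-9)  # survival times must be positive

    surv = pd.DataFrame(
        {
            "sample_id": tumor_ids,
            "time_months": times,
            "event": event,
            "true_class": np.where(is_high, "high", "normal_low"),
        }
    )
    truth = SimTruth(
        pd.DataFrame(
            {
                "probe_id": tumor_ids,
                "effect_class": np.where(is_high, "high", NEUTRAL),
                "gamma": np.where(is_high, np.log(config.hazard_ratio), 0.0),
                "beta": 0.0,
            }
        )
    )
    expr_cohort = {"expression": expr, "sample_class": sample_class}
    return expr_cohort, surv, truth


# ---------------------------------------------------------------------------
# packaged worked-example fixture
# ---------------------------------------------------------------------------

# Per-probe depletion effects and p-values for a reference screen hit
# list: 23 probes over 15 genes, log2 treated/vehicle and the treatment-term
# p-value for each probe.
_REFERENCE_HITS = """\
target_gene\tdescription\tlog2fc\tp
STRN3\tStriatin, calmodulin binding protein 3, cell cycle protein\t-1.527\t0.0037
STRN3\tStriatin, calmodulin binding protein 3, cell cycle protein\t-1.008\t0.0073
STRADA\tSTE20-related kinase adaptor alpha\t-1.197\t0.0003
TTK\tSer/Thr/Tyr kinase, cell cycle regulated\t-1.014\t0.0039
TTK\tSer/Thr/Tyr kinase, cell cycle regulated\t-1.018\t0.0040
TTK\tSer/Thr/Tyr kinase, cell cycle regulated\t-0.991\t0.0073
MAST3\tMicrotubule associated Ser/Thr kinase 3\t-0.901\t0.0009
PSMC1\tProteasome 26S subunit ATPase 1\t-0.900\t0.0048
PSMC1\tProteasome 26S subunit ATPase 1\t-0.880\t0.0060
CIT\tCitron, Rho-interacting, Ser/Thr kinase 21\t-0.802\t9.12e-05
CIT\tCitron, Rho-interacting, Ser/Thr kinase 21\t-0.815\t0.0001
RABGAP1\tGTPase-activating protein of RAB6A, microtubule/centrosome function\t-0.791\t0.0035
PRKACG\tGamma form of Protein Kinase A catalytic subunit\t-0.758\t0.0043
IGF1R\tInsulin-like growth factor 1 receptor\t-0.716\t0.0047
IGF1R\tInsulin-like growth factor 1 receptor\t-0.681\t0.0091
TSSK2\tTestes-specific serine kinase 2\t-0.666\t0.0045
VEGFB\tVascular endothelial growth factor beta\t-0.660\t0.0015
VEGFB\tVascular endothelial growth factor beta\t-0.594\t0.0026
MAPKAPK5\tMitogen-activated protein kinase-activated protein kinase 5\t-0.645\t0.0095
ABL2\tV-abl Abelson murine leukemia viral oncogene homolog 2, tyrosine kinase\t-0.621\t0.0047
PLK2\tPolo-like kinase 2, Ser/Thr kinase\t-0.598\t0.0045
PLK2\tPolo-like kinase 2, Ser/Thr kinase\t-0.584\t0.0085
AKT1\tSer/Thr kinase\t-0.594\t0.0041
"""


def make_reference_hit_fixture() -> pd.DataFrame:
    """The reference per-probe depletion hit list as fit-result-style rows.

    Returns one row per probe with probe_id, target_gene, log2fc and p,
    ready for the hit caller and gene aggregation.
    """
    df = pd.read_csv(StringIO(_REFERENCE_HITS), sep="\t")
    df.insert(0, "probe_id", [f"T1P{i + 1:02d}" for i in range(len(df))])
    return df
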