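"""Synthetic cohort generator.

Emulates the statistical structure the analysis assumes: paired
tumor/normal log2 miRNA intensities for a cohort of non-smoking lung
cancer patients, a mostly-downregulated cancer effect on a planted
cancer-related subset, exposure-linked miRNA subsets whose alteration is
amplified in exposed patients' tumors, histotype-linked miRNAs, and
benzo(a)pyrene adduct levels tied linearly to exposure covariates.

Defaults mirror the cohort the pipeline targets: 2549 miRNAs, 50 paired
patients (38 with complete questionnaires), 273 cancer-related miRNAs of
which 222 are down-regulated, planted exposure-signature sizes
8/1/53/21/19, and home-to-volcano distances uniform on 13-152 km.
Categorical covariates are assigned with fixed margins (exactly
round(prevalence x n) patients exposed) so every generated cohort has the
cohort composition the defaults state rather than a binomial draw of it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    AdductMeasurement,
    ExposureProfile,
    ExpressionMatrix,
    Histotype,
    SampleAnnotation,
    Scale,
    Tissue,
    ValidationError,
)

EXPOSURES = (
    "passive_smoke_home",
    "passive_smoke_work",
    "vehicle_traffic_home",
    "distance_etna_km",
    "radon_risk",
)


@dataclass
class CohortConfig:
    """Generator parameters; defaults are the target-cohort conditions."""

    n_patients: int = 50
    n_mirnas: int = 2549
    n_cancer_related: int = 273
    down_fraction: float = 222 / 273
    cancer_effect_range: tuple[float, float] = (1.0, 3.0)  # |log2fc| ~ Uniform
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    residual_sd: float = 0.5
    # per-patient multiplicative heterogeneity of the cancer effect:
    # each (miRNA, patient) effect is scaled by Uniform(1-h, 1+h)
    effect_heterogeneity: float = 0.5
    # exposure prevalences (fraction of patients exposed)
    prevalences: dict = field(
        default_factory=lambda: {
            "passive_smoke_home": 0.3,
            "passive_smoke_work": 0.2,
            "vehicle_traffic_home": 0.5,
            "radon_risk": 0.25,
        }
    )
    distance_range_km: tuple[float, float] = (13.0, 152.0)
    # planted exposure-signature sizes and the log2 effect added (in the
    # direction of each member's cancer effect) to exposed patients' tumors
    signature_sizes: dict = field(
        default_factory=lambda: {
            "passive_smoke_home": 8,
            "passive_smoke_work": 1,
            "vehicle_traffic_home": 53,
            "distance_etna_km": 21,
            "radon_risk": 19,
        }
    )
    exposure_effect: float = 1.5
    # histotype structure
    sclc_fraction: float = 0.2
    n_histotype_linked: int = 26
    histotype_up_fraction: float = 25 / 26  # up in NSCLC
    histotype_effect: float = 1.5
    # questionnaire completeness and smoking history
    complete_fraction: float = 38 / 50
    never_smoker_fraction: float = 0.3
    cessation_range_years: tuple[float, float] = (5.0, 30.0)
    # adduct model: total = b0 + b_smoke*home + b_dist*dist + b_cess*years + N(0, sd)
    adduct_intercept: float = 12.0
    adduct_beta_smoke: float = 3.0
    adduct_beta_distance: float = -0.04
    adduct_beta_cessation: float = -0.12
    adduct_sd: float = 1.5
    adduct_floor: float = 0.1
    never_smoker_effective_years: float = 30.0
    tetrol_I1_fraction: float = 0.6
    # heavy-tailed noise option (Student t, 3 df) for non-parametric paths
    heavy_tail_noise: bool = False
    replicate_spots: int = 1
    spot_sd: float = 0.1
    emit_scale: str = "log2"  # or "raw_linear"
    n_literature: int = 3
    seed: int = 0

    def validate(self) -> None:
        planted = sum(self.signature_sizes.values()) + self.n_histotype_linked
        if planted > self.n_cancer_related:
            raise ValidationError(
                f"planted subsets ({planted}) exceed n_cancer_related "
                f"({self.n_cancer_related})"
            )
        if self.n_cancer_related > self.n_mirnas:
            raise ValidationError("n_cancer_related exceeds n_mirnas")
        if self.residual_sd <= 0 or self.adduct_sd <= 0:
            raise ValidationError("noise scales must be positive")
        if self.replicate_spots < 1:
            raise ValidationError("replicate_spots must be >= 1")


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    cancer_members: dict[str, str]  # mirna -> "up"|"down" (in tumor)
    exposure_signatures: dict[str, list[str]]
    histotype_members: dict[str, str]  # mirna -> "up"|"down" (in NSCLC)
    exposure_labels: dict[str, dict[str, bool]]  # exposure -> patient -> exposed
    planted_ranking: list[str]
    adduct_coefficients: dict[str, float]
    etna_median_km: float

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def _fixed_margin_bools(rng: np.random.Generator, n: int, prevalence: float) -> np.ndarray:
    k = int(round(prevalence * n))
    flags = np.zeros(n, dtype=bool)
    flags[rng.permutation(n)[:k]] = True
    return flags


def generate_cohort(
    config: CohortConfig | None = None, seed: int | None = None
) -> tuple[
    ExpressionMatrix,
    list[SampleAnnotation],
    list[ExposureProfile],
    list[AdductMeasurement],
    GroundTruth,
]:
    """Generate a paired tumor/normal cohort with planted structure.

    Deterministic given the seed (``seed`` overrides ``config.seed``).
    The returned matrix holds tumor and normal columns for every patient;
    exposure and histotype effects act on tumor columns only, pushing each
    planted miRNA further in the direction of its cancer effect.
    """
    cfg = config or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_patients
    patients = [f"P{i + 1:03d}" for i in range(n)]
    mirnas = [f"miR-{i + 1:04d}" for i in range(cfg.n_mirnas)]

    # --- planted sets ------------------------------------------------------
    cancer_idx = rng.choice(cfg.n_mirnas, size=cfg.n_cancer_related, replace=False)
    n_down = int(round(cfg.down_fraction * cfg.n_cancer_related))
    signs = np.ones(cfg.n_cancer_related)
    signs[:n_down] = -1.0
    rng.shuffle(signs)
    lo, hi = cfg.cancer_effect_range
    magnitudes = rng.uniform(lo, hi, size=cfg.n_cancer_related)
    cancer_effect = np.zeros(cfg.n_mirnas)
    cancer_effect[cancer_idx] = signs * magnitudes

    # exposure and histotype subsets: disjoint slices of the cancer set
    pool = rng.permutation(cancer_idx)
    cursor = 0
    exposure_sig_idx: dict[str, np.ndarray] = {}
    for key in EXPOSURES:
        k = cfg.signature_sizes.get(key, 0)
        exposure_sig_idx[key] = pool[cursor : cursor + k]
        cursor += k
    histotype_idx = pool[cursor : cursor + cfg.n_histotype_linked]

    # --- covariates --------------------------------------------------------
    exposure_labels: dict[str, dict[str, bool]] = {}
    flags: dict[str, np.ndarray] = {}
    for key, prev in cfg.prevalences.items():
        flags[key] = _fixed_margin_bools(rng, n, prev)
        exposure_labels[key] = {p: bool(f) for p, f in zip(patients, flags[key])}
    d_lo, d_hi = cfg.distance_range_km
    distances = rng.uniform(d_lo, d_hi, size=n)
    etna_median = float(np.median(distances))
    flags["distance_etna_km"] = distances <= etna_median
    exposure_labels["distance_etna_km"] = {
        p: bool(f) for p, f in zip(patients, flags["distance_etna_km"])
    }

    sclc = _fixed_margin_bools(rng, n, cfg.sclc_fraction)
    complete = _fixed_margin_bools(rng, n, cfg.complete_fraction)
    never = _fixed_margin_bools(rng, n, cfg.never_smoker_fraction)
    c_lo, c_hi = cfg.cessation_range_years
    years = rng.uniform(c_lo, c_hi, size=n)

    # --- expression matrix -------------------------------------------------
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_mirnas)

    def noise(shape):
        if cfg.heavy_tail_noise:
            return rng.standard_t(3, size=shape) * cfg.residual_sd
        return rng.normal(0.0, cfg.residual_sd, size=shape)

    normal_vals = baseline[:, None] + noise((cfg.n_mirnas, n))
    h = cfg.effect_heterogeneity
    hetero = rng.uniform(1.0 - h, 1.0 + h, size=(cfg.n_mirnas, n)) if h > 0 else 1.0
    tumor_mean = baseline[:, None] + cancer_effect[:, None] * hetero
    # exposure effects amplify the cancer alteration in exposed tumors
    direction = np.sign(cancer_effect)
    for key in EXPOSURES:
        idx = exposure_sig_idx[key]
        if len(idx) == 0:
            continue
        exposed_cols = np.where(flags[key])[0]
        for i in idx:
            tumor_mean[i, exposed_cols] += cfg.exposure_effect * direction[i]
    # histotype effect on histotype-linked members: a centered NSCLC-vs-SCLC
    # contrast of size histotype_effect, weighted so the patient-averaged
    # tumor mean is unchanged (these miRNAs stay nested in the cancer set)
    n_hist_up = int(round(cfg.histotype_up_fraction * cfg.n_histotype_linked))
    hist_dirs = np.array([1.0] * n_hist_up + [-1.0] * (cfg.n_histotype_linked - n_hist_up))
    nsclc_cols = np.where(~sclc)[0]
    sclc_cols = np.where(sclc)[0]
    f_sclc = len(sclc_cols) / n
    for i, d in zip(histotype_idx, hist_dirs):
        tumor_mean[i, nsclc_cols] += cfg.histotype_effect * d * f_sclc
        tumor_mean[i, sclc_cols] -= cfg.histotype_effect * d * (1.0 - f_sclc)
    tumor_vals = tumor_mean + noise((cfg.n_mirnas, n))

    sample_ids: list[str] = []
    columns = []
    annotations: list[SampleAnnotation] = []
    for j, p in enumerate(patients):
        hist = Histotype.SCLC if sclc[j] else Histotype.NSCLC
        sample_ids.append(f"{p}_T")
        columns.append(tumor_vals[:, j])
        annotations.append(SampleAnnotation(f"{p}_T", p, Tissue.TUMOR, hist))
        sample_ids.append(f"{p}_N")
        columns.append(normal_vals[:, j])
        annotations.append(SampleAnnotation(f"{p}_N", p, Tissue.NORMAL, hist))
    values = np.column_stack(columns)

    out_mirnas = mirnas
    if cfg.replicate_spots > 1:
        rep_ids, rep_rows = [], []
        for i, m in enumerate(mirnas):
            for _ in range(cfg.replicate_spots):
                rep_ids.append(m)
                rep_rows.append(values[i] + rng.normal(0.0, cfg.spot_sd, size=values.shape[1]))
        out_mirnas = rep_ids
        values = np.vstack(rep_rows)
    if cfg.emit_scale == "raw_linear":
        matrix = ExpressionMatrix(out_mirnas, sample_ids, np.exp2(values), Scale.RAW_LINEAR)
    else:
        matrix = ExpressionMatrix(out_mirnas, sample_ids, values, Scale.LOG2)

    # --- questionnaire profiles -------------------------------------------
    profiles = [
        ExposureProfile(
            patient_id=p,
            passive_smoke_home=bool(flags["passive_smoke_home"][j]),
            passive_smoke_work=bool(flags["passive_smoke_work"][j]),
            vehicle_traffic_home=bool(flags["vehicle_traffic_home"][j]),
            distance_etna_km=float(distances[j]),
            radon_risk=bool(flags["radon_risk"][j]),
            years_since_cessation=None if never[j] else float(years[j]),
            never_smoker=bool(never[j]),
            complete=bool(complete[j]),
        )
        for j, p in enumerate(patients)
    ]

    # --- adducts -----------------------------------------------------------
    eff_years = np.where(never, cfg.never_smoker_effective_years, years)
    totals = (
        cfg.adduct_intercept
        + cfg.adduct_beta_smoke * flags["passive_smoke_home"].astype(float)
        + cfg.adduct_beta_distance * distances
        + cfg.adduct_beta_cessation * eff_years
        + rng.normal(0.0, cfg.adduct_sd, size=n)
    )
    totals = np.maximum(totals, cfg.adduct_floor)
    i1_frac = np.clip(rng.normal(cfg.tetrol_I1_fraction, 0.05, size=n), 0.05, 0.95)
    adducts = []
    for j, p in enumerate(patients):
        i1 = float(totals[j] * i1_frac[j])
        ii2 = float(totals[j] - i1)
        adducts.append(
            AdductMeasurement(
                patient_id=p,
                tetrol_I1=i1,
                tetrol_II2=ii2,
                total=float(totals[j]),
                below_mdl_I1=i1 <= 2.0,
                below_mdl_II2=ii2 <= 3.1,
            )
        )

    truth = GroundTruth(
        cancer_members={
            mirnas[i]: ("up" if cancer_effect[i] > 0 else "down") for i in sorted(cancer_idx)
        },
        exposure_signatures={
            key: sorted(mirnas[i] for i in exposure_sig_idx[key]) for key in EXPOSURES
        },
        histotype_members={
            mirnas[i]: ("up" if d > 0 else "down")
            for i, d in zip(histotype_idx, hist_dirs)
        },
        exposure_labels=exposure_labels,
        planted_ranking=sorted(
            (k for k in EXPOSURES if cfg.signature_sizes.get(k, 0) > 0),
            key=lambda k: (-cfg.signature_sizes[k], k),
        ),
        adduct_coefficients={
            "intercept": cfg.adduct_intercept,
            "beta_smoke": cfg.adduct_beta_smoke,
            "beta_distance": cfg.adduct_beta_distance,
            "beta_cessation": cfg.adduct_beta_cessation,
            "sd": cfg.adduct_sd,
        },
        etna_median_km=etna_median,
    )
    return matrix, annotations, profiles, adducts, truth


def emit_fixture(config: CohortConfig, out_dir: str | Path, seed: int | None = None) -> dict[str, Path]:
    """Write a full on-disk cohort readable by :mod:`envsig.io`.

    Emits the expression TSV, sample/exposure/adduct CSVs, ground-truth
    JSON and one literature miRNA list per exposure (cancer-related
    members outside the planted signature, to exercise signature merging).
    """
    from .io import NEVER_SMOKER, write_expression

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, annotations, profiles, adducts, truth = generate_cohort(config, seed=seed)
    paths = {
        "expression": out / "expression.tsv",
        "samples": out / "samples.csv",
        "exposures": out / "exposures.csv",
        "adducts": out / "adducts.csv",
        "ground_truth": out / "ground_truth.json",
    }
    write_expression(matrix, paths["expression"])
    with open(paths["samples"], "w") as fh:
        fh.write("sample_id,patient_id,tissue,histotype\n")
        for a in annotations:
            fh.write(f"{a.sample_id},{a.patient_id},{a.tissue.value},{a.histotype.value}\n")
    with open(paths["exposures"], "w") as fh:
        fh.write(
            "patient_id,passive_smoke_home,passive_smoke_work,vehicle_traffic_home,"
            "distance_etna_km,radon_risk,years_since_cessation\n"
        )
        for p in profiles:
            if p.complete:
                ysc = NEVER_SMOKER if p.never_smoker else (
                    "" if p.years_since_cessation is None else f"{p.years_since_cessation:.2f}"
                )
                fh.write(
                    f"{p.patient_id},{int(p.passive_smoke_home)},{int(p.passive_smoke_work)},"
                    f"{int(p.vehicle_traffic_home)},{p.distance_etna_km:.3f},"
                    f"{int(p.radon_risk)},{ysc}\n"
                )
            else:
                fh.write(f"{p.patient_id},,,,,,\n")
    with open(paths["adducts"], "w") as fh:
        fh.write("patient_id,tetrol_I1,tetrol_II2,total\n")
        for a in adducts:
            # keep total exactly the sum of the printed components
            i1, ii2 = round(a.tetrol_I1, 6), round(a.tetrol_II2, 6)
            fh.write(f"{a.patient_id},{i1:.6f},{ii2:.6f},{i1 + ii2:.6f}\n")
    paths["ground_truth"].write_text(truth.to_json())

    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    cancer_list = sorted(truth.cancer_members)
    for key in EXPOSURES:
        outside = [m for m in cancer_list if m not in set(truth.exposure_signatures[key])]
        picks = sorted(
            rng.choice(outside, size=min(config.n_literature, len(outside)), replace=False)
        )
        lit_path = out / f"literature_{key}.txt"
        lit_path.write_text(
            f"# literature miRNAs for {key} (synthetic stand-in list)\n"
            + "\n".join(picks)
            + "\n"
        )
        paths[f"literature_{key}"] = lit_path
    return paths
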