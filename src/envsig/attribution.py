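"""Environmental-exposure signature derivation and per-patient attribution.

This is the pipeline's core procedure.  For each environmental exposure the
cohort is split into exposed and unexposed patients; a volcano contrast of
exposed vs. unexposed tumors, restricted to the cancer-related miRNA
universe, yields that exposure's miRNA signature (optionally merged with a
literature-supplied list).  Each patient's tumor is then compared with
their matched normal tissue: the number of signature miRNAs whose
per-patient fold change reaches the FC threshold is the patient's
alteration count for that exposure.  A patient whose count strictly
exceeds the cohort median for an exposure is attributed to it, and
exposures are ranked by how many patients they are attributed to.

A per-patient "volcano t-test" is not definable with one tumor and one
normal sample, so the per-patient criterion is the fold-change axis of the
volcano alone: |log2 T(i,m) - log2 N(i,m)| >= log2(FC), inclusive.
"""

from __future__ import annotations

from collections.abc import Callable, Mapping, Sequence

import numpy as np

from .differential import DEFAULT_FC, DEFAULT_P, table_to_signature, volcano_contrast
from .io import (
    AttributionReport,
    ExposureProfile,
    ExpressionMatrix,
    Signature,
    ValidationError,
)
from .stats import TestResult, choose_correlation

EXPOSURE_KEYS = (
    "passive_smoke_home",
    "passive_smoke_work",
    "vehicle_traffic_home",
    "distance_etna_km",
    "radon_risk",
)


def dichotomize_exposure(
    profiles: Sequence[ExposureProfile],
    exposure_key: str,
    rule: str | Callable[[ExposureProfile], bool] = "default",
) -> tuple[list[str], list[str], str]:
    """Split complete-profile patients into exposed / unexposed sets.

    Boolean exposures pass through; the continuous Etna distance is
    dichotomized at the cohort median with *nearer than the median*
    counting as exposed (volcanic exposure decays with distance).  Returns
    ``(exposed_ids, unexposed_ids, rule_description)``.
    """
    usable = [p for p in profiles if p.complete]
    if callable(rule):
        flags = {p.patient_id: bool(rule(p)) for p in usable}
        desc = getattr(rule, "__name__", "custom_rule")
    elif exposure_key == "distance_etna_km":
        dists = np.array([p.distance_etna_km for p in usable])
        cut = float(np.median(dists))
        flags = {p.patient_id: p.distance_etna_km <= cut for p in usable}
        desc = f"distance <= cohort median ({cut:g} km)"
    elif exposure_key in EXPOSURE_KEYS:
        flags = {p.patient_id: bool(getattr(p, exposure_key)) for p in usable}
        desc = "boolean passthrough"
    else:
        raise ValidationError(f"unknown exposure key {exposure_key!r}")
    exposed = sorted(pid for pid, f in flags.items() if f)
    unexposed = sorted(pid for pid, f in flags.items() if not f)
    if len(exposed) < 2 or len(unexposed) < 2:
        raise ValidationError(
            f"exposure {exposure_key}: a side has <2 patients "
            f"({len(exposed)} exposed / {len(unexposed)} unexposed)"
        )
    return exposed, unexposed, desc


def derive_env_signature(
    tumor: ExpressionMatrix,
    patient_order: Sequence[str],
    exposed: Sequence[str],
    unexposed: Sequence[str],
    cancer_signature: Signature,
    literature_mirnas: Sequence[str] = (),
    name: str | None = None,
    exposure_key: str = "",
    fc_threshold: float = DEFAULT_FC,
    p_threshold: float = DEFAULT_P,
) -> Signature:
    """Volcano contrast of exposed vs. unexposed tumors within the
    cancer-related universe, merged with a literature list if given.

    ``tumor`` columns are addressed through ``patient_order`` (column j of
    the tumor matrix belongs to patient_order[j], as produced by
    ``split_by_tissue``).  Literature miRNAs join with direction taken from
    the contrast ("up" when not measured or tied), and the signature's
    provenance becomes "merged".
    """
    universe = sorted(cancer_signature.mirna_ids)
    if not universe:
        raise ValidationError("empty cancer-related universe")
    col_of = {p: j for j, p in enumerate(patient_order)}
    missing = [p for p in (*exposed, *unexposed) if p not in col_of]
    if missing:
        raise ValidationError(f"patients without tumor columns: {missing[:5]}")
    restricted = tumor.subset_mirnas(universe)
    sub_exposed = ExpressionMatrix(
        restricted.mirna_ids,
        list(exposed),
        restricted.values[:, [col_of[p] for p in exposed]],
        restricted.scale,
    )
    sub_unexposed = ExpressionMatrix(
        restricted.mirna_ids,
        list(unexposed),
        restricted.values[:, [col_of[p] for p in unexposed]],
        restricted.scale,
    )
    table = volcano_contrast(
        sub_exposed, sub_unexposed, fc_threshold, p_threshold, contrast="exposed_vs_unexposed"
    )
    sig = table_to_signature(table, name or exposure_key or "env_signature", exposure_key)
    if literature_mirnas:
        direction_of = {r.mirna_id: r.direction for r in table.records}
        extra = {
            (m, direction_of.get(m, "up"))
            for m in literature_mirnas
            if m not in sig.mirna_ids
        }
        sig = Signature(
            name=sig.name,
            exposure_key=sig.exposure_key,
            members=sig.members | extra,
            provenance="merged",
        )
    return sig


def patient_alteration_counts(
    tumor: ExpressionMatrix,
    normal: ExpressionMatrix,
    patient_order: Sequence[str],
    signatures: Mapping[str, Signature],
    fc_threshold: float = DEFAULT_FC,
    patients: Sequence[str] | None = None,
) -> tuple[list[str], list[str], np.ndarray]:
    """Count, per patient and signature, the members altered beyond the
    per-patient FC threshold (inclusive).

    Returns ``(patient_ids, exposure_keys, counts)`` with counts shaped
    (patients x signatures).  ``patients`` restricts to a subset (e.g. the
    questionnaire-complete cohort); others are excluded.
    """
    if not signatures:
        raise ValidationError("at least one signature required")
    if tumor.mirna_ids != normal.mirna_ids:
        raise ValidationError("tumor/normal matrices must share miRNA rows")
    col_of = {p: j for j, p in enumerate(patient_order)}
    if patients is None:
        patients = list(patient_order)
    else:
        patients = [p for p in patients if p in col_of]
    cols = [col_of[p] for p in patients]
    delta = np.abs(tumor.values[:, cols] - normal.values[:, cols])  # miRNA x patient
    altered = delta >= np.log2(fc_threshold)
    row_of = {m: i for i, m in enumerate(tumor.mirna_ids)}
    keys = list(signatures)
    counts = np.zeros((len(patients), len(keys)), dtype=int)
    for s, key in enumerate(keys):
        rows = [row_of[m] for m in signatures[key].mirna_ids if m in row_of]
        if rows:
            counts[:, s] = altered[rows, :].sum(axis=0)
    return list(patients), keys, counts


def median_attribution(
    patient_ids: Sequence[str],
    exposures: Sequence[str],
    counts: np.ndarray,
    signature_sizes: Mapping[str, int] | None = None,
    tiebreak: str = "signature_size",
) -> AttributionReport:
    """Median-threshold attribution and exposure ranking.

    Per exposure, the cohort median of alteration counts is computed and a
    patient is attributed to the exposure when their count is strictly
    above it (ties at the median do not attribute).  Exposures are ranked
    by the number of attributed patients, descending.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.shape != (len(patient_ids), len(exposures)):
        raise ValidationError("counts shape mismatch")
    if counts.shape[0] < 1:
        raise ValidationError("need at least one patient")
    medians = np.median(counts, axis=0)
    above = counts > medians[np.newaxis, :]
    n_above = {e: int(above[:, j].sum()) for j, e in enumerate(exposures)}
    sizes = dict(signature_sizes or {})
    ranking = rank_exposures(n_above, sizes, tiebreak)
    return AttributionReport(
        patient_ids=list(patient_ids),
        exposures=list(exposures),
        counts=counts,
        medians=medians,
        above_median=above,
        n_above=n_above,
        ranking=ranking,
        signature_sizes=sizes,
        tiebreak=tiebreak,
    )


def rank_exposures(
    n_above: Mapping[str, int],
    signature_sizes: Mapping[str, int] | None = None,
    tiebreak: str = "signature_size",
) -> list[str]:
    """Order exposures by attributed-patient count, descending.

    Ties are broken by larger signature size (``tiebreak='signature_size'``,
    the default) and then lexicographically; ``tiebreak='lexicographic'``
    skips the size step.
    """
    sizes = dict(signature_sizes or {})
    if tiebreak == "signature_size":
        key = lambda e: (-n_above[e], -sizes.get(e, 0), e)
    elif tiebreak == "lexicographic":
        key = lambda e: (-n_above[e], e)
    else:
        raise ValueError(f"unknown tiebreak {tiebreak!r}")
    return sorted(n_above, key=key)


def signature_adduct_correlation(
    patient_ids: Sequence[str],
    exposures: Sequence[str],
    counts: np.ndarray,
    adduct_totals: Mapping[str, float],
    alpha_normality: float = 0.05,
) -> dict[str, TestResult]:
    """Correlate each exposure's alteration counts with total B(a)P-DNA
    adducts over patients having both, choosing Pearson or Spearman by a
    Shapiro-Wilk normality gate."""
    idx = [i for i, p in enumerate(patient_ids) if p in adduct_totals]
    if len(idx) < 3:
        raise ValidationError("need >=3 patients with both counts and adducts")
    totals = np.array([adduct_totals[patient_ids[i]] for i in idx])
    out: dict[str, TestResult] = {}
    for j, e in enumerate(exposures):
        col = counts[idx, j].astype(float)
        if np.ptp(col) == 0 or np.ptp(totals) == 0:
            # constant burden column: correlation undefined, recorded as null
            out[e] = TestResult(0.0, 1.0, float(len(col) - 2), "pearson", degenerate=True)
            continue
        out[e] = choose_correlation(col, totals, alpha_normality)
    return out
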