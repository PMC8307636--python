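"""Volcano-style differential selection.

A miRNA is selected when the magnitude of its fold change between group
means reaches the FC threshold (default 2, i.e. |log2fc| >= 1) and its
unpaired Student t p-value is at or below the p threshold (default 0.05).
Both thresholds are inclusive and no multiple-testing correction is applied.
Rows with degenerate (zero pooled) variance fall back to the fold-change
criterion alone and are flagged.
"""

from __future__ import annotations

import warnings

import numpy as np

from .io import (
    DifferentialRecord,
    DifferentialTable,
    ExpressionMatrix,
    Histotype,
    SampleAnnotation,
    Scale,
    Signature,
    Tissue,
    ValidationError,
)
from .stats import row_t_tests

DEFAULT_FC = 2.0
DEFAULT_P = 0.05


def volcano_contrast(
    group_a: ExpressionMatrix,
    group_b: ExpressionMatrix,
    fc_threshold: float = DEFAULT_FC,
    p_threshold: float = DEFAULT_P,
    contrast: str = "tumor_vs_normal",
) -> DifferentialTable:
    """Per-miRNA contrast of group A minus group B on the log2 scale.

    log2fc is the difference of group means (a geometric-mean fold change
    on the linear scale); direction "up" means higher in group A.
    """
    if group_a.scale is not Scale.LOG2 or group_b.scale is not Scale.LOG2:
        raise ValidationError("volcano_contrast requires log2-scale matrices")
    if group_a.mirna_ids != group_b.mirna_ids:
        raise ValidationError("groups must share identical miRNA rows")
    if group_a.shape[1] < 2 or group_b.shape[1] < 2:
        raise ValidationError("each group needs at least 2 samples")
    log2fc = group_a.values.mean(axis=1) - group_b.values.mean(axis=1)
    t, p, degenerate = row_t_tests(group_a.values, group_b.values)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} rows with zero pooled variance; "
            "selection decided by fold change only for those rows",
            stacklevel=2,
        )
    cut = np.log2(fc_threshold)
    fc_pass = np.abs(log2fc) >= cut
    selected = np.where(degenerate, fc_pass, fc_pass & (p <= p_threshold))
    records = [
        DifferentialRecord(
            mirna_id=m,
            log2fc=float(log2fc[i]),
            t_stat=float(t[i]),
            p_value=float(p[i]),
            direction="up" if log2fc[i] > 0 else "down",
            selected=bool(selected[i]),
            degenerate=bool(degenerate[i]),
        )
        for i, m in enumerate(group_a.mirna_ids)
    ]
    return DifferentialTable(records, contrast=contrast)


def table_to_signature(table: DifferentialTable, name: str, exposure_key: str) -> Signature:
    return Signature(
        name=name,
        exposure_key=exposure_key,
        members=frozenset((r.mirna_id, r.direction) for r in table.selected_records()),
        provenance="derived",
    )


def cancer_related_set(
    tumor: ExpressionMatrix,
    normal: ExpressionMatrix,
    fc_threshold: float = DEFAULT_FC,
    p_threshold: float = DEFAULT_P,
) -> tuple[Signature, DifferentialTable]:
    """Tumor-vs-normal volcano selection: the cancer-related miRNA set.

    Returns the signature (direction "up" = higher in tumor) together with
    the full differential table it was cut from.
    """
    table = volcano_contrast(tumor, normal, fc_threshold, p_threshold, contrast="tumor_vs_normal")
    return table_to_signature(table, "cancer_related", "cancer_related"), table


def histotype_contrast(
    tumor: ExpressionMatrix,
    annotations: list[SampleAnnotation],
    cancer_signature: Signature,
    fc_threshold: float = DEFAULT_FC,
    p_threshold: float = DEFAULT_P,
) -> DifferentialTable:
    """NSCLC-vs-SCLC contrast restricted to the cancer-related universe."""
    histotype_of = {
        a.sample_id: a.histotype for a in annotations if a.tissue is Tissue.TUMOR
    }
    nsclc = [s for s in tumor.sample_ids if histotype_of.get(s) is Histotype.NSCLC]
    sclc = [s for s in tumor.sample_ids if histotype_of.get(s) is Histotype.SCLC]
    if len(nsclc) < 2 or len(sclc) < 2:
        raise ValidationError(
            f"need >=2 tumors per histotype (NSCLC={len(nsclc)}, SCLC={len(sclc)})"
        )
    universe = sorted(cancer_signature.mirna_ids)
    if not universe:
        raise ValidationError("empty cancer-related universe")
    restricted = tumor.subset_mirnas(universe)
    return volcano_contrast(
        restricted.subset_samples(nsclc),
        restricted.subset_samples(sclc),
        fc_threshold,
        p_threshold,
        contrast="nsclc_vs_sclc",
    )
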