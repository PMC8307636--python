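"""Array preprocessing: log transformation, replicate-spot averaging and
paired tumor/normal views.

The raw arrays carry replicated spots per miRNA; per sample they are log2
transformed and averaged.  No baseline/quantile normalization is applied.
"""

from __future__ import annotations

import numpy as np

from .io import ExpressionMatrix, SampleAnnotation, Scale, Tissue, ValidationError, validate_pairing


def log_transform(matrix: ExpressionMatrix, pseudo_offset: float = 0.0) -> ExpressionMatrix:
    """log2-transform a linear-scale matrix.

    ``pseudo_offset`` (epsilon added before the log) defaults to 0 so that
    non-positive intensities fail loudly instead of being masked.
    """
    if matrix.scale is not Scale.RAW_LINEAR:
        raise ValidationError("log_transform expects a raw_linear matrix")
    shifted = matrix.values + pseudo_offset
    if np.any(shifted <= 0):
        raise ValidationError(
            "non-positive intensities; set pseudo_offset to proceed deliberately"
        )
    return ExpressionMatrix(
        list(matrix.mirna_ids), list(matrix.sample_ids), np.log2(shifted), Scale.LOG2
    )


def average_replicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse replicate spots: rows sharing a miRNA id become their mean.

    Operates on the log2 scale; output row order follows first occurrence.
    Idempotent on matrices without replicates.
    """
    if matrix.scale is not Scale.LOG2:
        raise ValidationError("average_replicates expects a log2 matrix")
    if not matrix.has_replicates:
        return ExpressionMatrix(
            list(matrix.mirna_ids), list(matrix.sample_ids), matrix.values.copy(), Scale.LOG2
        )
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, m in enumerate(matrix.mirna_ids):
        if m not in groups:
            groups[m] = []
            order.append(m)
        groups[m].append(i)
    out = np.empty((len(order), len(matrix.sample_ids)))
    for k, m in enumerate(order):
        out[k] = matrix.values[groups[m], :].mean(axis=0)
    return ExpressionMatrix(order, list(matrix.sample_ids), out, Scale.LOG2)


def split_by_tissue(
    matrix: ExpressionMatrix, annotations: list[SampleAnnotation]
) -> tuple[ExpressionMatrix, ExpressionMatrix, list[str]]:
    """Split into tumor and normal matrices with columns aligned by patient.

    Returns ``(tumor, normal, patient_order)`` where column ``j`` of both
    matrices belongs to ``patient_order[j]``.  Patient order is sorted for
    determinism regardless of input sample order.
    """
    relevant = [a for a in annotations if a.sample_id in set(matrix.sample_ids)]
    validate_pairing(relevant)
    tumor_of: dict[str, str] = {}
    normal_of: dict[str, str] = {}
    for a in relevant:
        (tumor_of if a.tissue is Tissue.TUMOR else normal_of)[a.patient_id] = a.sample_id
    patient_order = sorted(tumor_of)
    tumor = matrix.subset_samples([tumor_of[p] for p in patient_order])
    normal = matrix.subset_samples([normal_of[p] for p in patient_order])
    return tumor, normal, patient_order
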