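"""Volcano selection, the cancer-related set and the histotype contrast."""

import numpy as np
import pytest
from scipy import stats as sps

from envsig.differential import cancer_related_set, histotype_contrast, volcano_contrast
from envsig.io import ExpressionMatrix, Scale, Signature, ValidationError
from envsig.preprocess import split_by_tissue
from envsig.synthetic import CohortConfig, generate_cohort
from tests.conftest import random_matrix, tiny_config


def volcano_oracle(a, b, fc=2.0, alpha=0.05):
    """Naive per-row loop recomputing fold change and pooled t."""
    out = []
    for i in range(a.shape[0]):
        fc_i = a[i].mean() - b[i].mean()
        n1, n2 = a.shape[1], b.shape[1]
        sp2 = ((n1 - 1) * np.var(a[i], ddof=1) + (n2 - 1) * np.var(b[i], ddof=1)) / (
            n1 + n2 - 2
        )
        t = (a[i].mean() - b[i].mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p = 2 * sps.t.sf(abs(t), n1 + n2 - 2)
        out.append((fc_i, t, p, abs(fc_i) >= np.log2(fc) and p <= alpha))
    return out


def _pair(rng, n_mirnas=50, n1=10, n2=10):
    a = random_matrix(rng, n_mirnas, [f"a{j}" for j in range(n1)])
    b = ExpressionMatrix(
        a.mirna_ids, [f"b{j}" for j in range(n2)],
        rng.normal(8, 1, size=(n_mirnas, n2)), Scale.LOG2,
    )
    return a, b


class TestVolcanoContrast:
    def test_identical_groups_select_nothing(self, rng):
        a = random_matrix(rng, 20, [f"a{j}" for j in range(4)])
        b = ExpressionMatrix(a.mirna_ids, [f"b{j}" for j in range(4)], a.values.copy(), Scale.LOG2)
        table = volcano_contrast(a, b)
        assert table.n_selected == 0

    def test_rowwise_agreement_with_loop_oracle(self, rng):
        a, b = _pair(rng)
        table = volcano_contrast(a, b)
        oracle = volcano_oracle(a.values, b.values)
        for rec, (fc, t, p, sel) in zip(table.records, oracle):
            assert rec.log2fc == pytest.approx(fc, abs=1e-10)
            assert rec.t_stat == pytest.approx(t, abs=1e-10)
            assert rec.p_value == pytest.approx(p, abs=1e-10)
            assert rec.selected == sel

    def test_planted_signal_recovered(self):
        rng = np.random.default_rng(77)
        n, planted = 100, 10
        base = rng.normal(8, 1, size=(n, 1))
        a_vals = base + rng.normal(0, 0.3, size=(n, 10))
        b_vals = base + rng.normal(0, 0.3, size=(n, 10))
        a_vals[:planted] += 2.0  # log2fc = 2 on the first ten rows
        a = ExpressionMatrix([f"m{i}" for i in range(n)], [f"a{j}" for j in range(10)], a_vals, Scale.LOG2)
        b = ExpressionMatrix(a.mirna_ids, [f"b{j}" for j in range(10)], b_vals, Scale.LOG2)
        table = volcano_contrast(a, b)
        flags = [r.selected for r in table.records]
        assert all(flags[:planted])
        assert sum(flags[planted:]) <= 5  # false positives bounded well below alpha*n

    def test_inclusive_thresholds_at_boundary(self):
        # one row with |log2fc| exactly 1; the +-2^-30 offsets are exactly
        # representable and cancel in the mean, leaving tiny variance for p
        eps = 2.0**-30
        a_vals = np.array([[9.0 + eps, 9.0 - eps, 9.0, 9.0]])
        b_vals = np.array([[8.0 + eps, 8.0 - eps, 8.0, 8.0]])
        a = ExpressionMatrix(["m"], list("abcd"), a_vals, Scale.LOG2)
        b = ExpressionMatrix(["m"], list("efgh"), b_vals, Scale.LOG2)
        table = volcano_contrast(a, b, fc_threshold=2.0, p_threshold=0.05)
        rec = table.records[0]
        assert rec.log2fc == pytest.approx(1.0, abs=1e-12)
        assert rec.selected

    def test_antisymmetry_under_group_swap(self, rng):
        a, b = _pair(rng, n_mirnas=30)
        t1 = volcano_contrast(a, b)
        t2 = volcano_contrast(b, a)
        for r1, r2 in zip(t1.records, t2.records):
            assert r1.log2fc == pytest.approx(-r2.log2fc, abs=1e-12)
            assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)
            assert r1.selected == r2.selected

    def test_selection_monotone_in_thresholds(self, rng):
        a, b = _pair(rng, n_mirnas=40)
        tight = volcano_contrast(a, b, fc_threshold=2.5, p_threshold=0.01)
        loose = volcano_contrast(a, b, fc_threshold=2.0, p_threshold=0.10)
        tight_sel = {r.mirna_id for r in tight.selected_records()}
        loose_sel = {r.mirna_id for r in loose.selected_records()}
        assert tight_sel <= loose_sel

    def test_degenerate_rows_fall_back_to_fc(self):
        a = ExpressionMatrix(["m1", "m2"], list("ab"), [[9.0, 9.0], [8.1, 8.1]], Scale.LOG2)
        b = ExpressionMatrix(["m1", "m2"], list("cd"), [[7.0, 7.0], [8.0, 8.0]], Scale.LOG2)
        with pytest.warns(UserWarning, match="zero pooled variance"):
            table = volcano_contrast(a, b)
        assert table.records[0].degenerate and table.records[0].selected
        assert table.records[1].degenerate and not table.records[1].selected

    def test_scale_mismatch_rejected(self, rng):
        a = random_matrix(rng, 5, ["a1", "a2"])
        b = ExpressionMatrix(a.mirna_ids, ["b1", "b2"], np.ones((5, 2)), Scale.RAW_LINEAR)
        with pytest.raises(ValidationError):
            volcano_contrast(a, b)


class TestCancerRelatedSet:
    def test_recovers_planted_members_with_directions(self, default_cohort):
        matrix, annotations, _, _, truth = default_cohort
        tumor, normal, _ = split_by_tissue(matrix, annotations)
        sig, table = cancer_related_set(tumor, normal)
        planted = truth.cancer_members
        recovered = {m: d for m, d in sig.members if m in planted}
        assert len(recovered) / len(planted) >= 0.95
        # directions follow the planted sign
        agree = sum(planted[m] == d for m, d in recovered.items())
        assert agree == len(recovered)
        assert table.n_down > table.n_up  # mostly-downregulated cancer effect

    def test_null_cohort_selects_almost_nothing(self):
        cfg = tiny_config(
            n_patients=10, n_mirnas=300, n_cancer_related=0,
            signature_sizes={}, n_histotype_linked=0,
        )
        matrix, annotations, _, _, _ = generate_cohort(cfg, seed=3)
        tumor, normal, _ = split_by_tissue(matrix, annotations)
        _, table = cancer_related_set(tumor, normal)
        # joint |fc|>=1 AND p<=0.05 rule: p-only false positives bound the size
        assert table.n_selected <= sum(r.p_value <= 0.05 for r in table.records)
        assert table.n_selected <= 0.05 * 300


class TestHistotypeContrast:
    def test_recovers_planted_histotype_subset(self, default_cohort):
        matrix, annotations, _, _, truth = default_cohort
        tumor, normal, _ = split_by_tissue(matrix, annotations)
        sig, _ = cancer_related_set(tumor, normal)
        table = histotype_contrast(tumor, annotations, sig)
        selected = {r.mirna_id: r.direction for r in table.selected_records()}
        planted = truth.histotype_members
        hits = {m for m in selected if m in planted}
        assert len(hits) / len(planted) >= 0.8
        assert all(selected[m] == planted[m] for m in hits)
        assert table.n_up > table.n_down  # mostly up-regulated in NSCLC

    def test_universe_restriction(self, default_cohort):
        matrix, annotations, _, _, _ = default_cohort
        tumor, normal, _ = split_by_tissue(matrix, annotations)
        sig, _ = cancer_related_set(tumor, normal)
        table = histotype_contrast(tumor, annotations, sig)
        assert {r.mirna_id for r in table.records} <= sig.mirna_ids

    def test_shuffled_labels_near_null(self, default_cohort, rng):
        matrix, annotations, _, _, _ = default_cohort
        tumor, normal, _ = split_by_tissue(matrix, annotations)
        sig, _ = cancer_related_set(tumor, normal)
        # rebuild annotations with histotype labels randomly reassigned
        import dataclasses

        from envsig.io import Histotype, Tissue

        tumor_anns = [a for a in annotations if a.tissue is Tissue.TUMOR]
        labels = [Histotype.SCLC] * 10 + [Histotype.NSCLC] * (len(tumor_anns) - 10)
        perm = rng.permutation(len(labels))
        shuffled = [
            dataclasses.replace(a, histotype=labels[j])
            for a, j in zip(tumor_anns, perm)
        ]
        table = histotype_contrast(tumor, shuffled, sig)
        assert table.n_selected <= 0.05 * sig.n + 3

    def test_too_few_histotype_samples_rejected(self, tiny_cohort):
        matrix, annotations, _, _, _ = tiny_cohort
        tumor, normal, _ = split_by_tissue(matrix, annotations)
        sig = Signature("s", "cancer_related", frozenset({(matrix.mirna_ids[0], "up")}))
        import dataclasses

        from envsig.io import Histotype

        all_nsclc = [dataclasses.replace(a, histotype=Histotype.NSCLC) for a in annotations]
        with pytest.raises(ValidationError, match="histotype"):
            histotype_contrast(tumor, all_nsclc, sig)
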