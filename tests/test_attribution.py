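"""Exposure dichotomization, signature derivation, per-patient counts,
median attribution and exposure ranking."""

import numpy as np
import pytest

from envsig.attribution import (
    derive_env_signature,
    dichotomize_exposure,
    median_attribution,
    patient_alteration_counts,
    rank_exposures,
    signature_adduct_correlation,
)
from envsig.differential import cancer_related_set
from envsig.io import ExposureProfile, ExpressionMatrix, Scale, Signature, ValidationError
from envsig.preprocess import split_by_tissue
from envsig.synthetic import generate_cohort
from tests.conftest import tiny_config


def _profiles(n=10, smoke_flags=None, distances=None):
    out = []
    for i in range(n):
        out.append(
            ExposureProfile(
                patient_id=f"P{i + 1:02d}",
                passive_smoke_home=bool(smoke_flags[i]) if smoke_flags else (i % 2 == 0),
                passive_smoke_work=False,
                vehicle_traffic_home=i < n // 2,
                distance_etna_km=float(distances[i]) if distances is not None else 20.0 + i,
                radon_risk=i % 3 == 0,
                years_since_cessation=None,
                never_smoker=True,
                complete=True,
            )
        )
    return out


class TestDichotomize:
    def test_boolean_passthrough(self):
        profiles = _profiles(8)
        exposed, unexposed, rule = dichotomize_exposure(profiles, "passive_smoke_home")
        assert rule == "boolean passthrough"
        assert set(exposed) == {p.patient_id for p in profiles if p.passive_smoke_home}
        assert set(exposed).isdisjoint(unexposed)
        assert len(exposed) + len(unexposed) == 8

    @pytest.mark.parametrize("n", [8, 9])
    def test_distance_median_split_sizes(self, n):
        rng = np.random.default_rng(1)
        distances = rng.uniform(13, 152, size=n)
        profiles = _profiles(n, distances=distances)
        exposed, unexposed, rule = dichotomize_exposure(profiles, "distance_etna_km")
        # sort-based oracle: near half (including the median patient) is exposed
        order = np.argsort(distances)
        near = {profiles[i].patient_id for i in order[: int(np.ceil(n / 2))]}
        assert set(exposed) == near
        assert len(exposed) == int(np.ceil(n / 2))
        assert len(unexposed) == n // 2

    def test_incomplete_profiles_excluded(self):
        profiles = _profiles(8)
        import dataclasses

        profiles[0] = dataclasses.replace(profiles[0], complete=False)
        exposed, unexposed, _ = dichotomize_exposure(profiles, "radon_risk")
        assert profiles[0].patient_id not in exposed + unexposed

    def test_one_sided_partition_rejected(self):
        profiles = _profiles(6, smoke_flags=[True] * 6)
        with pytest.raises(ValidationError, match="<2"):
            dichotomize_exposure(profiles, "passive_smoke_home")

    def test_unknown_key_rejected(self):
        with pytest.raises(ValidationError):
            dichotomize_exposure(_profiles(4), "phase_of_moon")


class TestDeriveSignature:
    def test_planted_subset_recovered(self, default_cohort):
        matrix, annotations, profiles, _, truth = default_cohort
        tumor, normal, order = split_by_tissue(matrix, annotations)
        csig, _ = cancer_related_set(tumor, normal)
        exposed, unexposed, _ = dichotomize_exposure(profiles, "vehicle_traffic_home")
        sig = derive_env_signature(
            tumor, order, exposed, unexposed, csig, exposure_key="vehicle_traffic_home"
        )
        planted = set(truth.exposure_signatures["vehicle_traffic_home"])
        assert len(planted & sig.mirna_ids) >= 0.9 * len(planted)
        assert sig.provenance == "derived"
        assert sig.mirna_ids <= csig.mirna_ids  # universe restriction

    def test_null_exposure_yields_tiny_signature(self, rng):
        cfg = tiny_config(signature_sizes={k: 0 for k in tiny_config().signature_sizes})
        matrix, annotations, profiles, _, _ = generate_cohort(cfg, seed=9)
        tumor, normal, order = split_by_tissue(matrix, annotations)
        csig, table = cancer_related_set(tumor, normal)
        exposed, unexposed, _ = dichotomize_exposure(profiles, "vehicle_traffic_home")
        sig = derive_env_signature(
            tumor, order, exposed, unexposed, csig, exposure_key="vehicle_traffic_home"
        )
        # no planted exposure effect: bounded by the p-only false positives
        assert sig.n <= max(3, 0.05 * csig.n + 3)

    def test_literature_merge_adds_members_and_marks_provenance(self, tiny_cohort):
        matrix, annotations, profiles, _, truth = tiny_cohort
        tumor, normal, order = split_by_tissue(matrix, annotations)
        csig, _ = cancer_related_set(tumor, normal)
        exposed, unexposed, _ = dichotomize_exposure(profiles, "passive_smoke_home")
        base = derive_env_signature(
            tumor, order, exposed, unexposed, csig, exposure_key="passive_smoke_home"
        )
        extra = sorted(csig.mirna_ids - base.mirna_ids)[:2]
        merged = derive_env_signature(
            tumor, order, exposed, unexposed, csig,
            literature_mirnas=extra, exposure_key="passive_smoke_home",
        )
        assert merged.provenance == "merged"
        assert merged.mirna_ids == base.mirna_ids | set(extra)

    def test_empty_universe_rejected(self, tiny_cohort):
        matrix, annotations, profiles, _, _ = tiny_cohort
        tumor, normal, order = split_by_tissue(matrix, annotations)
        empty = Signature("none", "cancer_related", frozenset())
        with pytest.raises(ValidationError, match="universe"):
            derive_env_signature(tumor, order, order[:3], order[3:], empty)


class TestAlterationCounts:
    def _paired(self, rng, n_mirnas=12, n_patients=5):
        patients = [f"P{i}" for i in range(n_patients)]
        normal = rng.normal(8, 1, size=(n_mirnas, n_patients))
        tumor = normal + rng.normal(0, 1.2, size=(n_mirnas, n_patients))
        ids = [f"m{i}" for i in range(n_mirnas)]
        t = ExpressionMatrix(ids, [f"{p}_T" for p in patients], tumor, Scale.LOG2)
        n = ExpressionMatrix(ids, [f"{p}_N" for p in patients], normal, Scale.LOG2)
        return t, n, patients

    def test_equal_tumor_normal_counts_zero(self, rng):
        t, n, patients = self._paired(rng)
        t2 = ExpressionMatrix(t.mirna_ids, t.sample_ids, n.values.copy(), Scale.LOG2)
        sig = Signature("s", "x", frozenset((m, "up") for m in t.mirna_ids))
        _, _, counts = patient_alteration_counts(t2, n, patients, {"x": sig})
        assert np.all(counts == 0)

    def test_boundary_fold_change_is_inclusive(self):
        t = ExpressionMatrix(["m"], ["P1_T", "P2_T"], [[9.0, 8.5]], Scale.LOG2)
        n = ExpressionMatrix(["m"], ["P1_N", "P2_N"], [[8.0, 8.0]], Scale.LOG2)
        sig = Signature("s", "x", frozenset({("m", "up")}))
        _, _, counts = patient_alteration_counts(t, n, ["P1", "P2"], {"x": sig})
        assert counts[0, 0] == 1  # |delta| exactly 1 counts
        assert counts[1, 0] == 0

    def test_matches_double_loop_oracle(self, rng):
        t, n, patients = self._paired(rng, n_mirnas=20, n_patients=8)
        members = rng.choice(t.mirna_ids, size=7, replace=False)
        sigs = {
            "a": Signature("a", "a", frozenset((m, "up") for m in members[:4])),
            "b": Signature("b", "b", frozenset((m, "up") for m in members)),
        }
        pids, keys, counts = patient_alteration_counts(t, n, patients, sigs)
        row = {m: i for i, m in enumerate(t.mirna_ids)}
        for i, p in enumerate(pids):
            for s, key in enumerate(keys):
                expected = 0
                for m in sigs[key].mirna_ids:
                    d = t.values[row[m], patients.index(p)] - n.values[row[m], patients.index(p)]
                    if abs(d) >= 1.0:
                        expected += 1
                assert counts[i, s] == expected

    def test_enlarging_signature_never_decreases_counts(self, rng):
        t, n, patients = self._paired(rng)
        small = Signature("s", "x", frozenset((m, "up") for m in t.mirna_ids[:4]))
        big = Signature("s", "x", frozenset((m, "up") for m in t.mirna_ids[:9]))
        _, _, c_small = patient_alteration_counts(t, n, patients, {"x": small})
        _, _, c_big = patient_alteration_counts(t, n, patients, {"x": big})
        assert np.all(c_big >= c_small)

    def test_patient_permutation_equivariance(self, rng):
        t, n, patients = self._paired(rng)
        sig = {"x": Signature("s", "x", frozenset((m, "up") for m in t.mirna_ids[:6]))}
        pids1, _, c1 = patient_alteration_counts(t, n, patients, sig)
        perm = list(reversed(patients))
        pids2, _, c2 = patient_alteration_counts(t, n, patients, sig, patients=perm)
        lookup = {p: c1[i] for i, p in enumerate(pids1)}
        for i, p in enumerate(pids2):
            np.testing.assert_array_equal(c2[i], lookup[p])

    def test_restriction_to_subset(self, rng):
        t, n, patients = self._paired(rng)
        sig = {"x": Signature("s", "x", frozenset((m, "up") for m in t.mirna_ids))}
        pids, _, counts = patient_alteration_counts(
            t, n, patients, sig, patients=patients[:3]
        )
        assert pids == patients[:3] and counts.shape == (3, 1)


class TestMedianAttribution:
    def test_hand_computed_toy(self):
        # single exposure, counts 5,1,3,4 -> median 3.5, strictly above: 5 and 4
        report = median_attribution(["P1", "P2", "P3", "P4"], ["smoke"],
                                    np.array([[5], [1], [3], [4]]))
        assert report.medians[0] == pytest.approx(3.5)
        assert report.n_above == {"smoke": 2}
        assert list(report.above_median[:, 0]) == [True, False, False, True]

    def test_all_equal_counts_attribute_nobody(self):
        report = median_attribution(["P1", "P2", "P3"], ["x"], np.array([[4], [4], [4]]))
        assert report.n_above == {"x": 0}

    def test_paper_scale_worked_example(self):
        """Attributed-patient counts with the tie broken by signature size
        reproduce the published decreasing order: traffic, passive smoke,
        volcano distance, radon."""
        n_above = {"passive_smoke": 38, "vehicle_traffic": 38, "etna_distance": 21, "radon": 13}
        sizes = {"passive_smoke": 8, "vehicle_traffic": 53, "etna_distance": 21, "radon": 19}
        ranking = rank_exposures(n_above, sizes)
        assert ranking == ["vehicle_traffic", "passive_smoke", "etna_distance", "radon"]

    def test_full_tie_falls_back_to_lexicographic(self):
        ranking = rank_exposures({"b": 5, "a": 5, "c": 5}, {"a": 2, "b": 2, "c": 2})
        assert ranking == ["a", "b", "c"]

    def test_single_exposure_ranks_itself(self):
        assert rank_exposures({"only": 7}, {"only": 3}) == ["only"]

    def test_lexicographic_tiebreak_mode(self):
        ranking = rank_exposures({"b": 5, "a": 5}, {"a": 1, "b": 9}, tiebreak="lexicographic")
        assert ranking == ["a", "b"]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            median_attribution(["P1"], ["a", "b"], np.array([[1]]))


class TestAdductCorrelation:
    def test_proportional_counts_give_r_one(self):
        counts = np.array([[1], [2], [3], [4], [5], [6]])
        totals = {f"P{i}": 2.0 * (i + 1) + 1 for i in range(6)}
        res = signature_adduct_correlation(
            [f"P{i}" for i in range(6)], ["x"], counts, totals
        )
        assert res["x"].statistic == pytest.approx(1.0)

    def test_independent_data_rarely_significant(self, rng):
        hits = 0
        reps = 100
        for _ in range(reps):
            counts = rng.integers(0, 20, size=(12, 1))
            totals = {f"P{i}": float(rng.normal(10, 2)) for i in range(12)}
            res = signature_adduct_correlation(
                [f"P{i}" for i in range(12)], ["x"], counts, totals
            )
            hits += res["x"].p_value <= 0.05
        assert hits <= 0.05 * reps + 3 * np.sqrt(reps * 0.05 * 0.95)

    def test_too_few_overlapping_patients_rejected(self):
        with pytest.raises(ValidationError):
            signature_adduct_correlation(["P1", "P2"], ["x"], np.array([[1], [2]]), {"P1": 1.0})
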