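"""End-to-end orchestration of the attribution workflow.

``run_all`` executes the stage sequence — read/simulate, preprocess,
cancer-related selection, histotype contrast, exploratory structure
checks, per-exposure signatures, median attribution, classification, and
adduct statistics — writing every report plus a run manifest into one
output directory.  Each stage failure aborts with the stage name.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import attribution, classification, differential, exploratory, preprocess, stats
from .io import (
    ExpressionMatrix,
    Scale,
    Tissue,
    read_expression,
    read_literature_list,
    read_metadata,
    write_report,
)
from .synthetic import EXPOSURES, CohortConfig, generate_cohort

log = logging.getLogger("envsig")

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "fc_threshold": 2.0,
    "p_threshold": 0.05,
    "alpha_normality": 0.05,
    "tiebreak": "signature_size",
    "cv_folds": 5,
    "classify": True,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # surface the failing stage
                raise StageError(name, exc) from exc
            log.info("stage %-12s %6.2fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return {**DEFAULTS, **cfg}


def _load_inputs(cfg: dict):
    if "simulate" in cfg:
        sim = dict(cfg.get("simulate") or {})
        sizes = sim.pop("signature_sizes", None)
        prevalences = sim.pop("prevalences", None)
        ccfg = CohortConfig(**sim)
        if sizes:
            ccfg.signature_sizes = dict(sizes)
        if prevalences:
            ccfg.prevalences = dict(prevalences)
        matrix, annotations, profiles, adducts, truth = generate_cohort(ccfg, seed=cfg["seed"])
        literature: dict[str, list[str]] = {}
        return matrix, annotations, profiles, adducts, literature, truth
    inputs = cfg["inputs"]
    scale = Scale(inputs.get("scale", "log2"))
    matrix = read_expression(inputs["expression"], scale)
    annotations, profiles, adducts = read_metadata(
        inputs["samples"], inputs["exposures"], inputs.get("adducts")
    )
    literature = {}
    for key in EXPOSURES:
        p = inputs.get(f"literature_{key}")
        if p:
            literature[key] = read_literature_list(p)
    return matrix, annotations, profiles, adducts, literature, None


def run_all(cfg: dict, out_dir: str | Path) -> dict:
    """Run the full workflow; returns the in-memory result bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fc, pthr = float(cfg["fc_threshold"]), float(cfg["p_threshold"])
    seed = int(cfg["seed"])
    results: dict[str, Any] = {}

    matrix, annotations, profiles, adducts, literature, truth = _stage("read")(_load_inputs)(cfg)

    @_stage("preprocess")
    def _preprocess(matrix: ExpressionMatrix) -> ExpressionMatrix:
        if matrix.scale is Scale.RAW_LINEAR:
            matrix = preprocess.log_transform(matrix)
        return preprocess.average_replicates(matrix)

    matrix = _preprocess(matrix)
    tumor, normal, patient_order = _stage("split")(preprocess.split_by_tissue)(matrix, annotations)

    @_stage("cancer_set")
    def _cancer():
        sig, table = differential.cancer_related_set(tumor, normal, fc, pthr)
        write_report(table, out / "cancer_related_table.tsv")
        write_report(sig, out / "cancer_related_signature.json")
        return sig, table

    cancer_sig, cancer_table = _cancer()
    results["cancer_signature"] = cancer_sig
    results["cancer_table"] = cancer_table

    @_stage("histotype")
    def _histotype():
        hist_of = {a.patient_id: a.histotype.value for a in annotations if a.tissue is Tissue.TUMOR}
        n_sclc = sum(1 for v in hist_of.values() if v == "SCLC")
        n_nsclc = sum(1 for v in hist_of.values() if v == "NSCLC")
        if min(n_sclc, n_nsclc) < 2 or cancer_sig.n == 0:
            log.info("histotype contrast skipped (SCLC=%d, NSCLC=%d)", n_sclc, n_nsclc)
            return None
        table = differential.histotype_contrast(tumor, annotations, cancer_sig, fc, pthr)
        write_report(table, out / "histotype_table.tsv")
        return table

    results["histotype_table"] = _histotype()

    @_stage("explore")
    def _explore():
        if cancer_sig.n < 2:
            return None
        restricted = matrix.subset_mirnas(sorted(cancer_sig.mirna_ids))
        dendro = exploratory.hierarchical_cluster(restricted)
        (out / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
        scores = exploratory.pca_scores(restricted)
        pd.DataFrame(
            scores.scores,
            index=scores.sample_ids,
            columns=[f"PC{i + 1}" for i in range(scores.scores.shape[1])],
        ).to_csv(out / "pca_scores.tsv", sep="\t", index_label="sample_id")
        tissue_of = {a.sample_id: a.tissue.value for a in annotations}
        labels = [tissue_of[s] for s in restricted.sample_ids]
        purity = exploratory.cluster_purity(labels, dendro.cut(2))
        return {"purity": purity, "explained_variance": scores.explained_variance_ratio.tolist()}

    results["exploratory"] = _explore()

    @_stage("signatures")
    def _signatures():
        sigs: dict[str, Any] = {}
        partitions: dict[str, tuple[list[str], list[str]]] = {}
        for key in EXPOSURES:
            try:
                exposed, unexposed, rule = attribution.dichotomize_exposure(profiles, key)
            except Exception as exc:
                log.warning("exposure %s skipped: %s", key, exc)
                continue
            sig = attribution.derive_env_signature(
                tumor,
                patient_order,
                exposed,
                unexposed,
                cancer_sig,
                literature_mirnas=literature.get(key, ()),
                name=key,
                exposure_key=key,
                fc_threshold=fc,
                p_threshold=pthr,
            )
            write_report(sig, out / f"signature_{key}.json")
            sigs[key] = sig
            partitions[key] = (exposed, unexposed)
            log.info("signature %-22s n=%-3d (%s)", key, sig.n, rule)
        return sigs, partitions

    signatures, partitions = _signatures()
    results["signatures"] = signatures

    @_stage("attribute")
    def _attribute():
        if not signatures:
            return None
        complete = [p.patient_id for p in profiles if p.complete]
        pids, keys, counts = attribution.patient_alteration_counts(
            tumor, normal, patient_order, signatures, fc_threshold=fc, patients=complete
        )
        report = attribution.median_attribution(
            pids, keys, counts,
            signature_sizes={k: signatures[k].n for k in keys},
            tiebreak=cfg["tiebreak"],
        )
        write_report(report, out / "attribution.json")
        write_report(report, out / "attribution_counts.tsv")
        return report

    report = _attribute()
    results["attribution"] = report

    @_stage("classify")
    def _classify():
        if not cfg.get("classify", True) or not signatures:
            return None
        col_of = {p: j for j, p in enumerate(patient_order)}
        rows = []
        for key, sig in signatures.items():
            if sig.n == 0:
                continue
            exposed, unexposed = partitions[key]
            pts = sorted(exposed + unexposed)
            sub = ExpressionMatrix(
                tumor.mirna_ids,
                pts,
                tumor.values[:, [col_of[p] for p in pts]],
                tumor.scale,
            )
            labels = [p in set(exposed) for p in pts]
            if min(sum(labels), len(labels) - sum(labels)) < 2:
                continue
            base = classification.train_predict_nn(
                sub, labels, panel=None, cv_folds=cfg["cv_folds"], seed=seed, panel_name="all_mirnas"
            )
            panel = classification.train_predict_nn(
                sub, labels, panel=sorted(sig.mirna_ids), cv_folds=cfg["cv_folds"],
                seed=seed, panel_name=key,
            )
            rows.append((base, panel))
        if not rows:
            return None
        # each panel has its own baseline label set, so build the table row-wise
        table = pd.concat(
            [classification.accuracy_delta_table(b, [p]) for b, p in rows], ignore_index=True
        ).sort_values("delta", ascending=False, kind="mergesort").reset_index(drop=True)
        write_report(table, out / "classification.tsv")
        return table

    results["classification"] = _classify()

    @_stage("adducts")
    def _adducts():
        if not adducts:
            return None
        totals = {a.patient_id: a.total for a in adducts}
        prof_of = {p.patient_id: p for p in profiles}
        res: dict[str, Any] = {}
        # group contrasts of adduct totals across boolean exposures
        for key in ("passive_smoke_home", "passive_smoke_work", "vehicle_traffic_home", "radon_risk"):
            groups = {True: [], False: []}
            for pid, tot in totals.items():
                pr = prof_of.get(pid)
                if pr is not None and pr.complete:
                    groups[bool(getattr(pr, key))].append(tot)
            if min(len(groups[True]), len(groups[False])) >= 2:
                an = stats.anova_oneway([groups[True], groups[False]])
                tt = stats.t_test_unpaired(groups[True], groups[False])
                res[f"anova_{key}"] = {"F": an.statistic, "p": an.p_value}
                res[f"ttest_{key}"] = {"t": tt.statistic, "p": tt.p_value}
        # dose-response regressions
        xs, ys = [], []
        for pid, tot in totals.items():
            pr = prof_of.get(pid)
            if pr is not None:
                xs.append(pr.distance_etna_km)
                ys.append(tot)
        if len(xs) >= 3 and np.ptp(xs) > 0:
            fit = stats.ols_regression(xs, ys)
            res["ols_distance"] = dataclasses.asdict(fit)
        xs, ys = [], []
        for pid, tot in totals.items():
            pr = prof_of.get(pid)
            if pr is not None and pr.years_since_cessation is not None:
                xs.append(pr.years_since_cessation)
                ys.append(tot)
        if len(xs) >= 3 and np.ptp(xs) > 0:
            fit = stats.ols_regression(xs, ys)
            res["ols_cessation"] = dataclasses.asdict(fit)
        # signature-burden vs adduct correlations
        if report is not None:
            corr = attribution.signature_adduct_correlation(
                report.patient_ids, report.exposures, report.counts, totals,
                alpha_normality=cfg["alpha_normality"],
            )
            res["signature_correlations"] = {
                k: {"r": v.statistic, "p": v.p_value, "method": v.method}
                for k, v in corr.items()
            }
        (out / "adduct_stats.json").write_text(json.dumps(res, indent=1, sort_keys=True))
        return res

    results["adduct_stats"] = _adducts()

    manifest = {
        "seed": seed,
        "fc_threshold": fc,
        "p_threshold": pthr,
        "alpha_normality": cfg["alpha_normality"],
        "tiebreak": cfg["tiebreak"],
        "cv_folds": cfg["cv_folds"],
        "simulate": cfg.get("simulate"),
        "inputs": cfg.get("inputs"),
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    results["manifest"] = manifest
    results["ground_truth"] = truth
    return results


def _versions() -> dict[str, str]:
    import numpy
    import pandas
    import scipy
    import sklearn

    from . import __version__

    return {
        "envsig": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
        "python": sys.version.split()[0],
    }
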