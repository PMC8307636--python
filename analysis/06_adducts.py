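#!/usr/bin/env python
"""B(a)P-DNA adduct statistics: group contrasts across boolean exposures,
dose-response regressions on Etna distance and years since smoking
cessation, and correlation of each signature's alteration burden with
total adduct levels (Pearson or Spearman by a normality gate).
"""

import argparse
import dataclasses
import json
from pathlib import Path

import numpy as np

from envsig import stats
from envsig.attribution import (
    derive_env_signature,
    dichotomize_exposure,
    patient_alteration_counts,
    signature_adduct_correlation,
)
from envsig.differential import cancer_related_set
from envsig.io import read_expression, read_metadata
from envsig.preprocess import split_by_tissue
from envsig.synthetic import EXPOSURES

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    matrix = read_expression(args.cohort / "expression.tsv")
    annotations, profiles, adducts = read_metadata(
        args.cohort / "samples.csv", args.cohort / "exposures.csv",
        args.cohort / "adducts.csv",
    )
    totals = {a.patient_id: a.total for a in adducts}
    res = {}

    for key in ("passive_smoke_home", "passive_smoke_work", "vehicle_traffic_home",
                "radon_risk"):
        exposed = [totals[p.patient_id] for p in profiles
                   if p.complete and getattr(p, key)]
        unexposed = [totals[p.patient_id] for p in profiles
                     if p.complete and not getattr(p, key)]
        an = stats.anova_oneway([exposed, unexposed])
        res[f"anova_{key}"] = {"F": an.statistic, "p": an.p_value}
        print(f"adducts by {key:24s} ANOVA F={an.statistic:6.2f} p={an.p_value:.3f}")

    fit = stats.ols_regression([p.distance_etna_km for p in profiles],
                               [totals[p.patient_id] for p in profiles])
    res["ols_distance"] = dataclasses.asdict(fit)
    print(f"adducts ~ Etna distance: slope {fit.slope:+.4f} pg/ug/km, "
          f"p={fit.p_slope:.2g} (inverse relation)" )
    former = [(p.years_since_cessation, totals[p.patient_id])
              for p in profiles if p.years_since_cessation is not None]
    fit2 = stats.ols_regression([x for x, _ in former], [y for _, y in former])
    res["ols_cessation"] = dataclasses.asdict(fit2)
    print(f"adducts ~ years since cessation (former smokers, n={len(former)}): "
          f"slope {fit2.slope:+.4f}, p={fit2.p_slope:.2g}")

    tumor, normal, order = split_by_tissue(matrix, annotations)
    csig, _ = cancer_related_set(tumor, normal)
    sigs = {}
    for key in EXPOSURES:
        exposed, unexposed, _ = dichotomize_exposure(profiles, key)
        sigs[key] = derive_env_signature(tumor, order, exposed, unexposed, csig,
                                         exposure_key=key, name=key)
    complete = [p.patient_id for p in profiles if p.complete]
    pids, keys, counts = patient_alteration_counts(tumor, normal, order, sigs,
                                                   patients=complete)
    corr = signature_adduct_correlation(pids, keys, counts, totals)
    res["signature_correlations"] = {}
    for key, r in corr.items():
        res["signature_correlations"][key] = {
            "r": r.statistic, "p": r.p_value, "method": r.method,
        }
        print(f"adducts vs {key:24s} burden: {r.method} r={r.statistic:+.2f} "
              f"p={r.p_value:.3f}")
    (args.out / "adduct_stats.json").write_text(json.dumps(res, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
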