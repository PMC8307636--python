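#!/usr/bin/env python
"""Signature-panel validation by neural-network class prediction.

For each exposure, a one-hidden-layer MLP predicts the exposed/unexposed
label from tumor profiles under stratified 5-fold cross-validation, once
from all miRNAs (baseline) and once from the exposure's derived signature
panel.  The table reports the accuracy gain of each panel.
"""

import argparse
from pathlib import Path

import pandas as pd

from envsig.attribution import derive_env_signature, dichotomize_exposure
from envsig.classification import accuracy_delta_table, train_predict_nn
from envsig.differential import cancer_related_set
from envsig.io import ExpressionMatrix, read_expression, read_metadata, write_report
from envsig.preprocess import split_by_tissue
from envsig.synthetic import EXPOSURES

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    matrix = read_expression(args.cohort / "expression.tsv")
    annotations, profiles, _ = read_metadata(
        args.cohort / "samples.csv", args.cohort / "exposures.csv"
    )
    tumor, normal, order = split_by_tissue(matrix, annotations)
    csig, _ = cancer_related_set(tumor, normal)
    col_of = {p: j for j, p in enumerate(order)}

    rows = []
    for key in EXPOSURES:
        exposed, unexposed, _ = dichotomize_exposure(profiles, key)
        sig = derive_env_signature(tumor, order, exposed, unexposed, csig,
                                   exposure_key=key, name=key)
        if sig.n == 0:
            print(f"{key}: empty signature, skipped")
            continue
        pts = sorted(exposed + unexposed)
        sub = ExpressionMatrix(
            tumor.mirna_ids, pts, tumor.values[:, [col_of[p] for p in pts]], tumor.scale
        )
        labels = [p in set(exposed) for p in pts]
        base = train_predict_nn(sub, labels, None, 5, args.seed, panel_name="all_mirnas")
        panel = train_predict_nn(sub, labels, sorted(sig.mirna_ids), 5, args.seed,
                                 panel_name=key)
        rows.append(accuracy_delta_table(base, [panel]))
        print(f"{key:24s} n={sig.n:3d}  baseline {base.overall_accuracy:.2f}  "
              f"panel {panel.overall_accuracy:.2f}  "
              f"delta {panel.overall_accuracy - base.overall_accuracy:+.2f}")
    table = pd.concat(rows, ignore_index=True).sort_values(
        "delta", ascending=False, kind="mergesort"
    )
    write_report(table, args.out / "classification.tsv")


if __name__ == "__main__":
    main()
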