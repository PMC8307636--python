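#!/usr/bin/env python
"""Tumor-vs-normal volcano selection and the histotype contrast.

Reads the cohort from results/cohort/, selects the cancer-related miRNA
set (fold change >= 2, p <= 0.05, unpaired Student t, no multiple-testing
correction) and contrasts NSCLC vs SCLC tumors within that set.  Reports
how much of the planted structure was recovered.
"""

import argparse
import json
from pathlib import Path

from envsig.differential import cancer_related_set, histotype_contrast
from envsig.io import read_expression, read_metadata, write_report
from envsig.preprocess import split_by_tissue
from envsig.synthetic import GroundTruth

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    matrix = read_expression(args.cohort / "expression.tsv")
    annotations, _, _ = read_metadata(
        args.cohort / "samples.csv", args.cohort / "exposures.csv"
    )
    truth = GroundTruth(**json.loads((args.cohort / "ground_truth.json").read_text()))

    tumor, normal, _ = split_by_tissue(matrix, annotations)
    sig, table = cancer_related_set(tumor, normal)
    write_report(table, args.out / "cancer_related_table.tsv")
    write_report(sig, args.out / "cancer_related_signature.json")
    planted = set(truth.cancer_members)
    rec = len(planted & sig.mirna_ids) / len(planted)
    print(f"cancer-related set: {table.n_selected} selected "
          f"({table.n_down} down, {table.n_up} up); "
          f"recovered {rec:.1%} of the {len(planted)} planted members")

    hist = histotype_contrast(tumor, annotations, sig)
    write_report(hist, args.out / "histotype_table.tsv")
    print(f"histotype contrast (NSCLC vs SCLC, within the cancer set): "
          f"{hist.n_selected} selected ({hist.n_up} up in NSCLC, {hist.n_down} down)")


if __name__ == "__main__":
    main()
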