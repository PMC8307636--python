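#!/usr/bin/env python
"""Structure checks over the cancer-related signature: hierarchical
clustering of all samples (1 - Pearson correlation, average linkage) and
3-D principal-component scores, with tumor/normal separation purity.
"""

import argparse
from pathlib import Path

import pandas as pd

from envsig.differential import cancer_related_set
from envsig.exploratory import cluster_purity, hierarchical_cluster, pca_scores
from envsig.io import read_expression, read_metadata
from envsig.preprocess import split_by_tissue

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
    tumor, normal, _ = split_by_tissue(matrix, annotations)
    sig, _ = cancer_related_set(tumor, normal)
    restricted = matrix.subset_mirnas(sorted(sig.mirna_ids))

    dendro = hierarchical_cluster(restricted)
    (args.out / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
    tissue_of = {a.sample_id: a.tissue.value for a in annotations}
    labels = [tissue_of[s] for s in restricted.sample_ids]
    purity = cluster_purity(labels, dendro.cut(2))
    print(f"two-cluster cut of the dendrogram: tumor/normal purity {purity:.3f}")

    scores = pca_scores(restricted)
    pd.DataFrame(
        scores.scores, index=scores.sample_ids,
        columns=[f"PC{i + 1}" for i in range(scores.scores.shape[1])],
    ).to_csv(args.out / "pca_scores.tsv", sep="\t", index_label="sample_id")
    evr = scores.explained_variance_ratio
    print("PCA explained variance: " + ", ".join(f"PC{i + 1} {v:.1%}" for i, v in enumerate(evr)))


if __name__ == "__main__":
    main()
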