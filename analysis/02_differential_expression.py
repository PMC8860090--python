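#!/usr/bin/env python
"""Differential expression over the three conditions.

Per-gene one-way ANOVA with BH FDR plus pairwise t contrasts; genes passing
q < 0.01 and >= 2-fold change are clustered into four expression patterns;
sample PCA summarizes the separation of the treatment groups. Reads
results/synthetic/, writes results/de/.
"""

from pathlib import Path

import regdiffnet as rd
from regdiffnet.de import DEConfig, assign_clusters, build_deg_table

ROOT = Path(__file__).resolve().parents[1]


def main():
    indir = ROOT / "results" / "synthetic"
    outdir = ROOT / "results" / "de"
    outdir.mkdir(parents=True, exist_ok=True)
    expr = rd.ExpressionMatrix.from_tsv(
        indir / "expression.tsv", indir / "conditions.tsv"
    )
    config = DEConfig()  # FC 2.0, q 0.01, 4 clusters
    deg = build_deg_table(expr, config)
    passing = rd.filter_degs(deg, config)
    deg.rename_axis("gene").to_csv(outdir / "deg_table.tsv", sep="\t")
    passing.rename_axis("gene").to_csv(outdir / "deg_passing.tsv", sep="\t")
    print(
        f"{len(passing)} of {len(deg)} genes pass "
        f"FC >= {config.fold_change_threshold} and q < {config.q_threshold}"
    )
    if len(passing) >= config.n_clusters:
        clusters = assign_clusters(list(passing.index), expr, config.n_clusters)
        clusters.rename_axis("gene").to_csv(outdir / "deg_clusters.tsv", sep="\t")
        sizes = clusters["cluster"].value_counts().sort_index()
        print("cluster sizes:", {int(k): int(v) for k, v in sizes.items()})
    scores, frac = rd.pca_samples(expr)
    scores.rename_axis("sample").to_csv(outdir / "pca_scores.tsv", sep="\t")
    frac.rename_axis("component").to_csv(
        outdir / "pca_explained_variance.tsv", sep="\t"
    )
    print(
        f"PC1 explains {frac.iloc[0]:.1%} of variance, "
        f"PC2 {frac.iloc[1]:.1%}"
    )


if __name__ == "__main__":
    main()
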