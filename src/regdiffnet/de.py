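"""Differential-expression stage for a multi-condition log2 expression matrix.

Per-gene one-way ANOVA and pairwise equal-variance t statistics with
Benjamini-Hochberg FDR, a fold-change + q filter, hierarchical four-cluster
pattern assignment, row z-scoring for heatmap display, sample PCA, and a
generic hypergeometric over-representation test.

Conventions (stated where they matter so tests are unambiguous):
  * t statistics use the sample (n-1) pooled variance; row z-scores and PCA
    standardization use the population (n) SD.
  * log2 fold change for contrast (A, B) is mean(A) - mean(B) on the log2
    scale.
  * Genes with zero variance everywhere are flagged degenerate with p = 1
    rather than raising, so genome-scale runs never abort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


class DEInputError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Log2 intensities, genes x samples, with a condition per sample."""

    values: pd.DataFrame
    condition_of: dict[str, str]

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise DEInputError("duplicate gene ids")
        if self.values.columns.duplicated().any():
            raise DEInputError("duplicate sample ids")
        missing = [s for s in self.values.columns if s not in self.condition_of]
        if missing:
            raise DEInputError(f"samples without a condition: {missing}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise DEInputError("expression values must all be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        seen = []
        for s in self.values.columns:
            c = self.condition_of[s]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        out = [s for s in self.values.columns if self.condition_of[s] == condition]
        if not out:
            raise DEInputError(f"unknown condition {condition!r}")
        return out

    def condition_values(self, condition: str) -> np.ndarray:
        return self.values[self.samples_of(condition)].to_numpy(dtype=float)

    @classmethod
    def from_tsv(cls, expr_path, conditions_path) -> "ExpressionMatrix":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        cond = pd.read_csv(conditions_path, sep="\t", index_col=0)
        return cls(values, cond.iloc[:, 0].to_dict())


@dataclass(frozen=True)
class DEConfig:
    fold_change_threshold: float = 2.0  # linear-scale ratio
    q_threshold: float = 0.01
    n_clusters: int = 4
    contrast_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.fold_change_threshold <= 1:
            raise DEInputError("fold_change_threshold must exceed 1")
        if not 0 < self.q_threshold < 1:
            raise DEInputError("q_threshold must lie in (0, 1)")
        if self.n_clusters < 1:
            raise DEInputError("n_clusters must be positive")


def default_contrasts(conditions: list[str]) -> tuple[tuple[str, str], ...]:
    """Every non-reference condition vs the first, then later vs earlier."""
    pairs = []
    for i, a in enumerate(conditions):
        for b in conditions[:i]:
            pairs.append((a, b))
    return tuple(pairs)


def contrast_name(pair: tuple[str, str]) -> str:
    return f"{pair[0]}_vs_{pair[1]}"


# ---------------------------------------------------------------------------
# per-gene statistics


def one_way_anova(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Fixed-effects one-way F per gene, df (k-1, N-k).

    Genes with zero between- and within-group variance are flagged degenerate
    with F = NaN, p = 1.
    """
    conditions = matrix.conditions
    if len(conditions) < 2:
        raise DEInputError("ANOVA needs at least 2 conditions")
    groups = []
    for c in conditions:
        g = matrix.condition_values(c)
        if g.shape[1] < 2:
            raise DEInputError(f"condition {c!r} has fewer than 2 samples")
        groups.append(g)
    k = len(groups)
    ns = np.array([g.shape[1] for g in groups])
    N = int(ns.sum())
    grand = np.hstack(groups).mean(axis=1)
    means = np.column_stack([g.mean(axis=1) for g in groups])
    ssb = (ns[None, :] * (means - grand[:, None]) ** 2).sum(axis=1)
    ssw = np.zeros_like(ssb)
    for g, m in zip(groups, means.T):
        ssw += ((g - m[:, None]) ** 2).sum(axis=1)
    df_b, df_w = k - 1, N - k
    degenerate = (ssb <= 0) & (ssw <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df_b) / (ssw / df_w)
    p = np.where(
        np.isfinite(F), stats.f.sf(np.where(np.isfinite(F), F, 0), df_b, df_w), 0.0
    )
    F = np.where(degenerate, np.nan, F)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {"F": F, "anova_p": p, "anova_degenerate": degenerate},
        index=matrix.values.index,
    )


def pairwise_t(
    matrix: ExpressionMatrix, contrast_pairs: tuple[tuple[str, str], ...]
) -> pd.DataFrame:
    """Two-sided unpaired equal-variance t per gene and contrast.

    log2FC = mean(A) - mean(B). Zero-pooled-variance genes are flagged with
    p = 1 (t = NaN) unless the means also differ exactly, in which case the
    flag is still set (the statistic is undefined either way).
    """
    out = {}
    for pair in contrast_pairs:
        a, b = pair
        ga, gb = matrix.condition_values(a), matrix.condition_values(b)
        na, nb = ga.shape[1], gb.shape[1]
        if na < 2 or nb < 2:
            raise DEInputError(f"contrast {pair}: each side needs >= 2 samples")
        ma, mb = ga.mean(axis=1), gb.mean(axis=1)
        va = ga.var(axis=1, ddof=1)
        vb = gb.var(axis=1, ddof=1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        degenerate = se == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (ma - mb) / se
        df = na + nb - 2
        p = np.where(degenerate, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
        t = np.where(degenerate, np.nan, t)
        name = contrast_name(pair)
        out[f"log2fc_{name}"] = ma - mb
        out[f"t_{name}"] = t
        out[f"p_{name}"] = p
        out[f"degenerate_{name}"] = degenerate
    return pd.DataFrame(out, index=matrix.values.index)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * n / j over the ascending p order, capped at
    1; output is order-preserving with the input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise DEInputError("p_values must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DEInputError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# DEG table assembly and filtering


def build_deg_table(
    matrix: ExpressionMatrix, config: DEConfig
) -> pd.DataFrame:
    """Per-gene ANOVA (with BH q), per-contrast t statistics (with BH q)."""
    pairs = config.contrast_pairs or default_contrasts(matrix.conditions)
    anova = one_way_anova(matrix)
    tstats = pairwise_t(matrix, pairs)
    deg = pd.concat([anova, tstats], axis=1)
    deg["anova_q"] = bh_fdr(deg["anova_p"].to_numpy())
    for pair in pairs:
        name = contrast_name(pair)
        deg[f"q_{name}"] = bh_fdr(deg[f"p_{name}"].to_numpy())
    fc_cols = [c for c in deg.columns if c.startswith("log2fc_")]
    deg["max_abs_log2fc"] = deg[fc_cols].abs().max(axis=1)
    return deg


def filter_degs(deg: pd.DataFrame, config: DEConfig) -> pd.DataFrame:
    """Keep genes with ANOVA q < threshold and max |log2FC| >= log2(FC)."""
    cut = np.log2(config.fold_change_threshold)
    keep = (deg["anova_q"] < config.q_threshold) & (deg["max_abs_log2fc"] >= cut)
    out = deg.copy()
    out["passed"] = keep
    return out[keep]


def zscore_rows(values: pd.DataFrame):
    """Row z-scores with the population SD, for heatmap display.

    Returns (z, degenerate_flags, saturated_mask); zero-variance rows become
    all-zero and flagged. Values are not clipped — the |z| >= 2 saturation
    mask is display metadata.
    """
    x = values.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise DEInputError("row z-scores need at least 2 samples")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    degenerate = sd[:, 0] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    z[degenerate] = 0.0
    zdf = pd.DataFrame(z, index=values.index, columns=values.columns)
    flags = pd.Series(degenerate, index=values.index, name="zero_variance")
    saturated = zdf.abs() >= 2
    return zdf, flags, saturated


def condition_means(matrix: ExpressionMatrix) -> pd.DataFrame:
    return pd.DataFrame(
        {c: matrix.condition_values(c).mean(axis=1) for c in matrix.conditions},
        index=matrix.values.index,
    )


def assign_clusters(
    filtered_genes: list[str],
    matrix: ExpressionMatrix,
    n_clusters: int = 4,
    reference: str | None = None,
) -> pd.DataFrame:
    """Average-linkage hierarchical clustering of per-gene z-scored condition
    means, cut at ``n_clusters``, with a post-hoc up/down pattern label per
    cluster relative to the reference (first) condition."""
    if len(filtered_genes) < n_clusters:
        raise DEInputError(
            f"{len(filtered_genes)} passing genes cannot form {n_clusters} clusters"
        )
    means = condition_means(matrix).loc[filtered_genes]
    z, _, _ = zscore_rows(means)
    order = z.index.argsort(kind="mergesort")  # label order: deterministic,
    zs = z.iloc[order]                         # invariant to input row order
    link = hierarchy.linkage(pdist(zs.to_numpy()), method="average")
    labels = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
    cluster = pd.Series(labels, index=zs.index, name="cluster").loc[filtered_genes]
    ref = reference or matrix.conditions[0]
    others = [c for c in matrix.conditions if c != ref]
    patterns = {}
    for cid in sorted(set(cluster)):
        sub = means.loc[cluster[cluster == cid].index]
        delta = sub[others].mean(axis=0) - sub[ref].mean()
        patterns[cid] = "/".join(
            f"{c}:{'up' if d > 0 else 'down'}" for c, d in delta.items()
        )
    return pd.DataFrame(
        {
            "cluster": cluster,
            "pattern": cluster.map(patterns),
        }
    )


# ---------------------------------------------------------------------------
# sample PCA


def pca_samples(matrix: ExpressionMatrix):
    """SVD-based PCA of samples after standardizing each gene to mean 0,
    population SD 1 across samples.

    Returns (scores, explained_variance_fraction); components ordered by
    decreasing variance, fractions summing to 1. Component signs are fixed by
    making the largest-magnitude sample score of each component positive.
    """
    if matrix.values.shape[1] < 3:
        raise DEInputError("sample PCA needs at least 3 samples")
    x = matrix.values.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    keep = sd > 0
    if keep.sum() < 2:
        raise DEInputError("fewer than 2 non-degenerate genes")
    z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    X = z.T  # samples x genes, columns centered
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    scores = U * S
    for j in range(scores.shape[1]):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    var = S**2
    frac = var / var.sum() if var.sum() > 0 else var
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=matrix.values.columns, columns=cols),
        pd.Series(frac, index=cols, name="explained_variance_fraction"),
    )


# ---------------------------------------------------------------------------
# over-representation


def overrepresentation_test(
    query_set: set,
    annotation_sets: dict[str, set],
    universe: set,
    min_overlap: int = 3,
    p_report: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric upper-tail enrichment per annotation set.

    BH correction is applied across all tested sets; the ``reported`` flag
    marks sets with overlap count > 2 and p < 0.05 (the conventional
    "p < 0.05 and gene count > 2" reporting rule).
    """
    if not universe:
        raise DEInputError("empty universe")
    query = set(query_set)
    if not query <= set(universe):
        raise DEInputError("query_set must be a subset of the universe")
    M, N = len(universe), len(query)
    rows = []
    for name, genes in annotation_sets.items():
        ann = set(genes) & set(universe)
        k = len(ann & query)
        n = len(ann)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        expected = N * n / M if M else 0.0
        fold = k / expected if expected > 0 else np.nan
        rows.append((name, k, n, fold, p))
    table = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "fold_enrichment", "p"]
    ).set_index("set")
    table["q"] = bh_fdr(table["p"].to_numpy()) if len(table) else []
    table["reported"] = (table["overlap"] >= min_overlap) & (table["p"] < p_report)
    return table
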