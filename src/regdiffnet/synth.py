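"""Synthetic regulon benchmark generator.

Emulates a three-condition microarray design (e.g., DMSO / SykI / rapamycin,
four replicates each): a set of TF binding motifs, promoter sequences with
binding sites planted for every planted regulatory edge, and a log2
expression matrix driven by a linear TF-activity model in which exactly one
TF gains activity in one condition. The generator records the full ground
truth (planted prior, sites, differential TF and its edges) so every
downstream stage is testable without external data.

Expression model for gene g, sample j in condition c:

    x[g, j] = effect * sum_t prior[t, g] * a~(t, c, j) + eps
    a~(t, c, j) = a(t, c) * (1 + activity_cv * z1[t, j])
                  + induced_activity_cv * (a(t, c) - baseline) * z2[t, j]
    z1, z2 ~ N(0, 1),  eps ~ N(0, noise_sd)

where a(t, c) = baseline_activity for every TF except the differential TF,
which gains ``activity_shift`` in the differential condition. TF activity
thus has two per-replicate noise components: a modest constant-CV
fluctuation of the basal activity shared by every TF (activity_cv), and a
larger fluctuation of the signaling-induced activity gain
(induced_activity_cv), reflecting that stimulus-induced responses vary more
between replicates than basal states. The induced component gives the
differential TF's regulon a strong shared expression component only in the
shifted condition, so condition-specific coexpression — the structure the
network-inference stage detects — is planted alongside the mean shift that
drives differential expression. With noise_sd, activity_cv and
induced_activity_cv all 0 the model is fully deterministic and replicate
columns are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .motifs import (
    BASES,
    PositionWeightMatrix,
    Promoter,
    report_coord,
    write_fasta,
    write_meme,
)


class ConfigError(ValueError):
    """Invalid synthetic configuration; names the offending field."""


class GenerationError(RuntimeError):
    """The requested dataset cannot be constructed (e.g., promoter too short)."""


# rng substream tags, so each generator is independently reproducible
_TAG_PWM, _TAG_PRIOR, _TAG_PROMOTER, _TAG_EXPRESSION = 1, 2, 3, 4


@dataclass(frozen=True)
class SyntheticConfig:
    n_tfs: int = 30
    n_genes: int = 300
    motif_length: int = 8
    regulon_size: int = 10
    conditions: tuple[str, ...] = ("DMSO", "SykI", "rapamycin")
    replicates_per_condition: int = 4
    baseline_activity: float = 1.0
    activity_shift: float = 2.0
    effect_size_per_edge: float = 1.0
    noise_sd: float = 0.5
    activity_cv: float = 0.25
    induced_activity_cv: float = 0.5
    promoter_length: int = 1001
    background_base_frequencies: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    differential_tf: str | None = None  # default: first TF
    differential_condition: str | None = None  # default: second condition
    seed: int = 0

    def __post_init__(self):
        for name in ("n_tfs", "n_genes", "motif_length", "regulon_size",
                     "promoter_length"):
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.motif_length < 4:
            raise ConfigError("motif_length must be at least 4")
        if self.regulon_size > self.n_genes:
            raise ConfigError("regulon_size must not exceed n_genes")
        if len(self.conditions) < 2:
            raise ConfigError("conditions must list at least 2 names")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigError("conditions must be unique")
        if self.replicates_per_condition < 2:
            raise ConfigError("replicates_per_condition must be at least 2")
        for name in ("noise_sd", "activity_cv", "induced_activity_cv"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        bg = self.background_base_frequencies
        if len(bg) != 4 or any(p < 0 for p in bg):
            raise ConfigError(
                "background_base_frequencies must be 4 non-negative values"
            )
        if abs(sum(bg) - 1.0) > 1e-9:
            raise ConfigError("background_base_frequencies must sum to 1")
        if (self.differential_condition is not None
                and self.differential_condition not in self.conditions):
            raise ConfigError("differential_condition must be a listed condition")

    @property
    def tf_ids(self) -> list[str]:
        return [f"TF{i:03d}" for i in range(1, self.n_tfs + 1)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    @property
    def resolved_differential_tf(self) -> str:
        return self.differential_tf or self.tf_ids[0]

    @property
    def resolved_differential_condition(self) -> str:
        return self.differential_condition or self.conditions[1]

    @property
    def reference_condition(self) -> str:
        return self.conditions[0]

    @property
    def promoter_start(self) -> int:
        """Internal offset of the first promoter base (TSS base = 0).

        The default 1001-bp promoter spans -750..+250 around the TSS; other
        lengths keep the same 3:1 upstream:downstream split.
        """
        downstream = self.promoter_length // 4
        return -(self.promoter_length - 1 - downstream)

    def rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, tag]))


@dataclass(frozen=True)
class PlantedSite:
    gene: str
    tf: str
    offset: int  # reported (no-zero) TSS-relative coordinate of site start
    strand: str
    site: str


@dataclass
class GroundTruth:
    prior_truth: pd.DataFrame  # binary TF x gene
    differential_tf: str
    differential_condition: str
    reference_condition: str
    differential_edges: frozenset[tuple[str, str]]
    planted_sites: list[PlantedSite] = field(default_factory=list)


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    pwms: list[PositionWeightMatrix]
    promoters: list[Promoter]
    expression: "ExpressionMatrix"
    truth: GroundTruth


# ---------------------------------------------------------------------------
# generators


def generate_pwms(config: SyntheticConfig) -> list[PositionWeightMatrix]:
    """One informative PWM per TF: every column has a dominant base with
    probability in [0.85, 0.95], the remainder split over the other bases."""
    rng = config.rng(_TAG_PWM)
    pwms = []
    for i, tf in enumerate(config.tf_ids, start=1):
        probs = np.empty((config.motif_length, 4))
        for pos in range(config.motif_length):
            dominant = rng.integers(4)
            p_dom = rng.uniform(0.85, 0.95)
            rest = (1.0 - p_dom) * rng.dirichlet(np.ones(3))
            row = np.empty(4)
            row[dominant] = p_dom
            row[[b for b in range(4) if b != dominant]] = rest
            probs[pos] = row
        pwms.append(PositionWeightMatrix(f"M{i:04d}", tf, probs))
    return pwms


def generate_prior_truth(config: SyntheticConfig) -> pd.DataFrame:
    """Binary TF x gene matrix of planted regulons (regulon_size per TF)."""
    rng = config.rng(_TAG_PRIOR)
    prior = pd.DataFrame(
        0, index=config.tf_ids, columns=config.gene_ids, dtype=int
    )
    for tf in config.tf_ids:
        genes = rng.choice(config.n_genes, size=config.regulon_size, replace=False)
        prior.iloc[prior.index.get_loc(tf), genes] = 1
    return prior


def _sample_site(pwm: PositionWeightMatrix, rng, consensus_only: bool) -> str:
    if consensus_only:
        return pwm.consensus
    bases = [
        BASES[rng.choice(4, p=pwm.probs[pos])] for pos in range(pwm.length)
    ]
    return "".join(bases)


def generate_promoters(
    pwms: list[PositionWeightMatrix],
    prior_truth: pd.DataFrame,
    config: SyntheticConfig,
    consensus_only: bool = False,
) -> tuple[list[Promoter], list[PlantedSite]]:
    """Background promoters with one site planted per planted edge.

    Sites are sampled from the planting TF's PWM (``consensus_only`` forces
    the consensus, the zero-temperature path used for exact tests), placed at
    non-overlapping uniform random offsets on the forward strand. Background
    matches arising by chance are not suppressed. Genes without an edge for a
    TF receive no planted site for that TF.
    """
    if list(prior_truth.index) != [p.tf_name for p in pwms]:
        raise ConfigError("prior_truth rows must match the PWM TF names in order")
    if prior_truth.shape[1] != config.n_genes:
        raise ConfigError("prior_truth columns must match n_genes")
    rng = config.rng(_TAG_PROMOTER)
    bg = np.asarray(config.background_base_frequencies)
    pwm_of = {p.tf_name: p for p in pwms}
    start = config.promoter_start
    promoters: list[Promoter] = []
    sites: list[PlantedSite] = []
    for gene in prior_truth.columns:
        tfs = [tf for tf in prior_truth.index if prior_truth.at[tf, gene] == 1]
        total_needed = sum(pwm_of[tf].length for tf in tfs)
        if total_needed > config.promoter_length:
            raise GenerationError(
                f"gene {gene}: promoter of length {config.promoter_length} "
                f"cannot host {len(tfs)} non-overlapping sites "
                f"({total_needed} bp required)"
            )
        seq = list(rng.choice(list(BASES), size=config.promoter_length, p=bg))
        occupied: list[tuple[int, int]] = []
        for tf in tfs:
            pwm = pwm_of[tf]
            L = pwm.length
            placed = False
            for _ in range(1000):
                pos = int(rng.integers(0, config.promoter_length - L + 1))
                if all(pos + L <= lo or pos >= hi for lo, hi in occupied):
                    placed = True
                    break
            if not placed:
                raise GenerationError(
                    f"gene {gene}: could not place a non-overlapping site "
                    f"for {tf} after 1000 attempts"
                )
            site = _sample_site(pwm, rng, consensus_only)
            seq[pos : pos + L] = list(site)
            occupied.append((pos, pos + L))
            sites.append(
                PlantedSite(
                    gene=gene,
                    tf=tf,
                    offset=report_coord(start + pos),
                    strand="+",
                    site=site,
                )
            )
        promoters.append(
            Promoter(gene_id=gene, sequence="".join(seq), start=start, strand="+")
        )
    return promoters, sites


def activity_matrix(config: SyntheticConfig) -> pd.DataFrame:
    """Deterministic TF x condition activity a(t, c)."""
    a = pd.DataFrame(
        config.baseline_activity,
        index=config.tf_ids,
        columns=list(config.conditions),
        dtype=float,
    )
    a.at[config.resolved_differential_tf, config.resolved_differential_condition] += (
        config.activity_shift
    )
    return a


def generate_expression(
    prior_truth: pd.DataFrame,
    config: SyntheticConfig,
    planted_sites: list[PlantedSite] | None = None,
) -> tuple["ExpressionMatrix", GroundTruth]:
    from .de import ExpressionMatrix  # local import to avoid a cycle

    rng = config.rng(_TAG_EXPRESSION)
    a = activity_matrix(config)
    prior = prior_truth.to_numpy(dtype=float)
    n_rep = config.replicates_per_condition
    columns, blocks, condition_of = [], [], {}
    for cond in config.conditions:
        act = a[cond].to_numpy()[:, None]  # nTF x 1
        z1 = rng.standard_normal((config.n_tfs, n_rep))
        z2 = rng.standard_normal((config.n_tfs, n_rep))
        induced = act - config.baseline_activity
        tilde = (
            act * (1.0 + config.activity_cv * z1)
            + config.induced_activity_cv * induced * z2
        )
        eps = config.noise_sd * rng.standard_normal((config.n_genes, n_rep))
        block = config.effect_size_per_edge * prior.T @ tilde + eps
        blocks.append(block)
        for r in range(1, n_rep + 1):
            sample = f"{cond}_{r}"
            columns.append(sample)
            condition_of[sample] = cond
    values = pd.DataFrame(
        np.hstack(blocks), index=prior_truth.columns, columns=columns
    )
    diff_tf = config.resolved_differential_tf
    edges = frozenset(
        (diff_tf, g) for g in prior_truth.columns if prior_truth.at[diff_tf, g] == 1
    )
    truth = GroundTruth(
        prior_truth=prior_truth,
        differential_tf=diff_tf,
        differential_condition=config.resolved_differential_condition,
        reference_condition=config.reference_condition,
        differential_edges=edges,
        planted_sites=list(planted_sites or []),
    )
    return ExpressionMatrix(values, condition_of), truth


def noiseless_means(prior_truth: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Expected gene x condition means of the expression model (no noise)."""
    a = activity_matrix(config)
    means = config.effect_size_per_edge * (
        prior_truth.to_numpy(dtype=float).T @ a.to_numpy()
    )
    return pd.DataFrame(means, index=prior_truth.columns, columns=a.columns)


def simulate_all(
    config: SyntheticConfig, consensus_only: bool = False
) -> SyntheticDataset:
    """Run all three generators with consistent ground truth."""
    pwms = generate_pwms(config)
    prior_truth = generate_prior_truth(config)
    promoters, sites = generate_promoters(pwms, prior_truth, config, consensus_only)
    expression, truth = generate_expression(prior_truth, config, planted_sites=sites)
    return SyntheticDataset(config, pwms, promoters, expression, truth)


# ---------------------------------------------------------------------------
# consensus promoter-construct helper (ETV2 site logic fixtures)


def make_promoter_construct(
    start: int,
    end: int,
    site_offset: int | None,
    site: str = "CCGGAA",
    seed: int = 0,
) -> Promoter:
    """A TSS-anchored fragment with exactly the planted consensus sites.

    ``start``/``end``/``site_offset`` use the reported no-zero TSS-relative
    convention (e.g., start=-311, end=+75 is a 386-bp fragment). The
    background alternates over A/C only, so neither CCGGAW nor its reverse
    complement can occur by chance; the planted site is the only match.
    """
    from .motifs import internal_coord

    lo = internal_coord(start)
    hi = internal_coord(end)
    length = hi - lo + 1
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(["A", "C"], size=length))
    if site_offset is not None:
        pos = internal_coord(site_offset) - lo
        if pos < 0 or pos + len(site) > length:
            raise GenerationError("site does not fit inside the fragment")
        seq[pos : pos + len(site)] = list(site)
    return Promoter(
        gene_id="construct", sequence="".join(seq), start=lo, strand="+"
    )


# ---------------------------------------------------------------------------
# writers


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write the dataset in plain-text interchange formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "promoters": outdir / "promoters.fa",
        "tss": outdir / "tss.tsv",
        "motifs": outdir / "motifs.meme",
        "expression": outdir / "expression.tsv",
        "conditions": outdir / "conditions.tsv",
        "prior_truth": outdir / "prior_truth_edges.tsv",
        "planted_sites": outdir / "planted_sites.tsv",
    }
    write_fasta(
        {p.gene_id: p.sequence for p in dataset.promoters}, paths["promoters"]
    )
    pd.DataFrame(
        [
            (p.gene_id, p.start, p.start + len(p.sequence), p.strand)
            for p in dataset.promoters
        ],
        columns=["chrom", "start", "end", "strand"],
    ).to_csv(paths["tss"], sep="\t", index=False)
    write_meme(dataset.pwms, paths["motifs"])
    dataset.expression.values.rename_axis("gene").to_csv(
        paths["expression"], sep="\t"
    )
    pd.Series(dataset.expression.condition_of, name="condition").rename_axis(
        "sample"
    ).to_csv(paths["conditions"], sep="\t")
    truth = dataset.truth
    edges = truth.prior_truth.stack()
    edges = edges[edges == 1]
    pd.DataFrame(
        [
            (tf, gene, int((tf, gene) in truth.differential_edges))
            for tf, gene in edges.index
        ],
        columns=["tf", "gene", "differential"],
    ).to_csv(paths["prior_truth"], sep="\t", index=False)
    pd.DataFrame(
        [(s.gene, s.tf, s.offset, s.strand, s.site) for s in truth.planted_sites],
        columns=["gene", "tf", "offset", "strand", "site"],
    ).to_csv(paths["planted_sites"], sep="\t", index=False)
    return paths
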