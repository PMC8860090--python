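"""End-to-end orchestration: simulate -> de -> prior -> network -> diffnet.

A structured (YAML/dict) configuration with one section per stage is
validated up front with an aggregated error report; each stage writes
tab-separated outputs under a run directory together with a manifest
(config echo, per-stage row counts, derived seeds). Reruns with the same
configuration and seed reproduce every numeric output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from . import diffnet as dn
from . import motifs as mo
from . import panda as pa
from . import synth

log = logging.getLogger("regdiffnet.pipeline")

STAGES = ("simulate", "de", "prior", "network", "diffnet")

_SECTION_TYPES = {
    "synthetic": synth.SyntheticConfig,
    "de": de_mod.DEConfig,
    "scan": mo.MotifScanConfig,
    "panda": pa.PandaConfig,
    "diffnet": dn.DiffNetConfig,
}

_TOP_LEVEL = set(_SECTION_TYPES) | {
    "seed",
    "log_level",
    "comparison",
    "inputs",
    "plant_consensus",
}


class ConfigValidationError(ValueError):
    """Aggregated report of every configuration violation."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _coerce(value, typ):
    if typ is tuple or (getattr(typ, "__origin__", None) is tuple):
        if isinstance(value, list):
            return tuple(tuple(v) if isinstance(v, list) else v for v in value)
    return value


def _validate_section(name: str, cls, overrides: dict, violations: list[str]):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = [k for k in overrides if k not in fields]
    for k in unknown:
        violations.append(f"unknown key {name}.{k}")
    known = {
        k: _coerce(v, fields[k].type) for k, v in overrides.items() if k in fields
    }
    # per-field range checks so every violation is reported, not just the first
    bad = set()
    for k, v in known.items():
        try:
            cls(**{k: v})
        except Exception as exc:
            violations.append(f"{name}.{k}: {exc}")
            bad.add(k)
    try:
        return cls(**{k: v for k, v in known.items() if k not in bad})
    except Exception as exc:  # cross-field invariants
        violations.append(f"{name}: {exc}")
        return None


def validate_config(config: dict) -> dict:
    """Type- and range-check every section, fill defaults, reject unknown
    keys; raises :class:`ConfigValidationError` listing all violations."""
    violations: list[str] = []
    for key in config:
        if key not in _TOP_LEVEL:
            violations.append(f"unknown key {key}")
    seed = config.get("seed", 0)
    if not isinstance(seed, (int, np.integer)):
        violations.append("seed: must be an integer")
        seed = 0
    sections = {}
    for name, cls in _SECTION_TYPES.items():
        overrides = dict(config.get(name) or {})
        if name == "synthetic" and "seed" not in overrides:
            overrides["seed"] = int(seed)
        sections[name] = _validate_section(name, cls, overrides, violations)
    inputs = config.get("inputs")
    if inputs is not None:
        required = {"expression", "conditions", "motifs", "promoters"}
        missing = required - set(inputs)
        if missing:
            violations.append(
                "inputs: missing paths " + ", ".join(sorted(missing))
            )
        else:
            for key in required:
                if not Path(inputs[key]).exists():
                    violations.append(f"inputs.{key}: path does not exist")
    comparison = config.get("comparison")
    syn = sections.get("synthetic")
    if comparison is None and syn is not None:
        # mirror the SykI-vs-rapamycin comparison: the two treatments
        conds = syn.conditions
        comparison = (conds[1], conds[2]) if len(conds) >= 3 else (conds[1], conds[0])
    elif comparison is not None:
        comparison = tuple(comparison)
        if len(comparison) != 2:
            violations.append("comparison: must name exactly two conditions")
    if violations:
        raise ConfigValidationError(violations)
    return {
        "seed": int(seed),
        "log_level": str(config.get("log_level", "INFO")),
        "plant_consensus": bool(config.get("plant_consensus", False)),
        "comparison": comparison,
        "inputs": inputs,
        **sections,
    }


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def _stage(manifest: dict, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("START %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            elapsed = time.perf_counter() - self.t0
            status = "completed" if exc is None else "failed"
            log.info("END %s (%.2fs, %s)", name, elapsed, status)
            manifest["stages"][name] = {
                "status": status,
                "elapsed_s": round(elapsed, 3),
            }
            if exc is not None:
                raise StageError(name, exc) from exc
            return False

    return _Ctx()


def run_pipeline(config: dict, outdir) -> Path:
    """Run all five stages, writing TSV outputs and a manifest under
    ``outdir``. Any stage error aborts with the stage name; partial outputs
    are kept alongside a FAILED marker."""
    cfg = validate_config(config) if "synthetic" not in config or not isinstance(
        config.get("synthetic"), synth.SyntheticConfig
    ) else config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg["log_level"], logging.INFO))
    manifest = {
        "seed": cfg["seed"],
        "comparison": list(cfg["comparison"]) if cfg["comparison"] else None,
        "stages": {},
        "row_counts": {},
        "config": _echo_config(cfg),
    }
    try:
        _run_stages(cfg, outdir, manifest)
    except StageError:
        (outdir / "FAILED").write_text(
            json.dumps(manifest["stages"], indent=2) + "\n"
        )
        _write_manifest(manifest, outdir)
        raise
    _write_manifest(manifest, outdir)
    return outdir


def _echo_config(cfg: dict) -> dict:
    echo = {}
    for k, v in cfg.items():
        if dataclasses.is_dataclass(v):
            echo[k] = dataclasses.asdict(v)
        elif isinstance(v, tuple):
            echo[k] = list(v)
        else:
            echo[k] = v
    return echo


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")


def _run_stages(cfg: dict, outdir: Path, manifest: dict) -> None:
    counts = manifest["row_counts"]

    with _stage(manifest, "simulate"):
        if cfg.get("inputs"):
            paths = cfg["inputs"]
            expression = de_mod.ExpressionMatrix.from_tsv(
                paths["expression"], paths["conditions"]
            )
            pwms = mo.read_meme(paths["motifs"])
            seqs = mo.read_fasta(paths["promoters"])
            promoters = [
                mo.Promoter(gene_id=g, sequence=s) for g, s in seqs.items()
            ]
            truth = None
        else:
            dataset = synth.simulate_all(
                cfg["synthetic"], consensus_only=cfg["plant_consensus"]
            )
            synth.write_dataset(dataset, outdir / "synthetic")
            expression, pwms, promoters = (
                dataset.expression,
                dataset.pwms,
                dataset.promoters,
            )
            truth = dataset.truth
        counts["expression_genes"] = int(expression.values.shape[0])
        counts["expression_samples"] = int(expression.values.shape[1])
        counts["motifs"] = len(pwms)
        counts["promoters"] = len(promoters)

    with _stage(manifest, "de"):
        de_cfg = cfg["de"]
        deg = de_mod.build_deg_table(expression, de_cfg)
        passing = de_mod.filter_degs(deg, de_cfg)
        deg.rename_axis("gene").to_csv(outdir / "deg_table.tsv", sep="\t")
        passing.rename_axis("gene").to_csv(outdir / "deg_passing.tsv", sep="\t")
        counts["deg_table"] = len(deg)
        counts["deg_passing"] = len(passing)
        if len(passing) >= de_cfg.n_clusters:
            clusters = de_mod.assign_clusters(
                list(passing.index), expression, de_cfg.n_clusters
            )
            clusters.rename_axis("gene").to_csv(
                outdir / "deg_clusters.tsv", sep="\t"
            )
            counts["deg_clusters"] = len(clusters)
        else:
            log.warning("too few passing genes to cluster; skipping")
            counts["deg_clusters"] = 0
        scores, frac = de_mod.pca_samples(expression)
        scores.rename_axis("sample").to_csv(outdir / "pca_scores.tsv", sep="\t")
        frac.rename_axis("component").to_csv(
            outdir / "pca_explained_variance.tsv", sep="\t"
        )

    with _stage(manifest, "prior"):
        scan_cfg = cfg["scan"]
        hits = mo.scan_promoters(promoters, pwms, scan_cfg)
        prior = mo.build_prior(
            hits, [p.tf_name for p in pwms], [p.gene_id for p in promoters]
        )
        mo.hits_to_frame(hits).to_csv(outdir / "hits.tsv", sep="\t", index=False)
        prior.rename_axis("tf").to_csv(outdir / "prior.tsv", sep="\t")
        counts["hits"] = len(hits)
        counts["prior_edges"] = int(prior.to_numpy().sum())

    with _stage(manifest, "network"):
        networks = pa.infer_condition_networks(expression, prior, cfg["panda"])
        net_meta = {}
        for cond, net in networks.items():
            pa.network_to_tsv(net, outdir / f"network_{cond}.tsv")
            net_meta[cond] = net.meta
        with open(outdir / "network_meta.json", "w") as fh:
            json.dump(net_meta, fh, indent=2)
            fh.write("\n")
        counts["networks"] = len(networks)

    with _stage(manifest, "diffnet"):
        cond_a, cond_b = cfg["comparison"]
        table = dn.edge_differences(networks[cond_a], networks[cond_b])
        s_a, s_b, warns = dn.select_top_k(table, cfg["diffnet"])
        summary = dn.tf_summary(
            s_a, s_b, ratio_decimals=cfg["diffnet"].ratio_decimals
        )
        table.to_csv(outdir / "edge_differences.tsv", sep="\t", index=False)
        s_a.to_csv(outdir / f"selected_{cond_a}.tsv", sep="\t", index=False)
        s_b.to_csv(outdir / f"selected_{cond_b}.tsv", sep="\t", index=False)
        summary.to_csv(outdir / "tf_summary.tsv", sep="\t", index=False)
        counts["edge_differences"] = len(table)
        counts["tf_summary"] = len(summary)
        for w in warns:
            log.warning("%s", w)
        # rank the top-|nDiff| TF's A-side unique targets against DE
        top_tf = summary.loc[summary["nDiff"].abs().idxmax(), "tf"]
        uniq_a, _, _ = dn.unique_targets(s_a, s_b, top_tf)
        contrast = de_mod.contrast_name((cond_a, cond_b))
        if f"log2fc_{contrast}" not in deg.columns:
            contrast = de_mod.contrast_name((cond_b, cond_a))
        candidates = dn.rank_candidates(sorted(uniq_a), deg, contrast)
        candidates.insert(0, "tf", top_tf)
        candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
        counts["candidates"] = len(candidates)
        manifest["top_tf"] = str(top_tf)
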