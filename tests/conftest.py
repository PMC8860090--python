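import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

import regdiffnet as rd
from regdiffnet.diffnet import DiffNetConfig, edge_differences, select_top_k


RECOVERY_CONFIG = dict(
    n_tfs=30,
    n_genes=300,
    regulon_size=30,
    replicates_per_condition=20,
    activity_shift=2.0,
    effect_size_per_edge=1.0,
    noise_sd=0.5,
    seed=11,
)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small end-to-end synthetic dataset shared across tests."""
    cfg = rd.SyntheticConfig(
        n_tfs=5, n_genes=40, regulon_size=4, replicates_per_condition=6, seed=1
    )
    return rd.simulate_all(cfg, consensus_only=True)


@pytest.fixture(scope="session")
def recovery_run():
    """The planted-recovery benchmark: simulate, scan, infer the shifted and
    reference condition networks, and select the top-100 differential edges.

    Shared session-wide because it is the most expensive computation in the
    suite and several recovery properties are checked against it.
    """
    cfg = rd.SyntheticConfig(**RECOVERY_CONFIG)
    dataset = rd.simulate_all(cfg, consensus_only=True)
    hits = rd.scan_promoters(dataset.promoters, dataset.pwms)
    prior = rd.build_prior(
        hits,
        [p.tf_name for p in dataset.pwms],
        [p.gene_id for p in dataset.promoters],
    )
    # the two treatment networks are compared, mirroring the study's
    # headline SykI-vs-rapamycin pair; the differential TF is shifted in the
    # first of them
    cond_a, cond_b = cfg.conditions[1], cfg.conditions[2]
    networks = rd.infer_condition_networks(
        dataset.expression, prior, rd.PandaConfig(), conditions=[cond_a, cond_b]
    )
    table = edge_differences(networks[cond_a], networks[cond_b])
    s_a, s_b, _ = select_top_k(table, DiffNetConfig(k=100))
    return {
        "config": cfg,
        "dataset": dataset,
        "prior": prior,
        "networks": networks,
        "table": table,
        "s_a": s_a,
        "s_b": s_b,
    }
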