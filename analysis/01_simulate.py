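#!/usr/bin/env python
"""Generate the synthetic benchmark dataset.

Emulates the study design this pipeline targets: three conditions (DMSO,
SykI, rapamycin), a panel of TFs with planted regulons encoded both in
promoter motif content and in expression covariance, and one TF (TF001)
whose activity is shifted under SykI only. Writes motifs (MEME), promoters
(FASTA + TSS table), the expression matrix with condition labels, and the
ground truth under results/synthetic/.
"""

from pathlib import Path

import regdiffnet as rd
from regdiffnet.synth import write_dataset

ROOT = Path(__file__).resolve().parents[1]

# benchmark conditions: 30 TFs x 300 genes, regulons of 30, 20 replicates,
# activity shift 2.0 under SykI, gene noise SD 0.5, consensus-planted sites
CONFIG = rd.SyntheticConfig(
    n_tfs=30,
    n_genes=300,
    regulon_size=30,
    replicates_per_condition=20,
    activity_shift=2.0,
    noise_sd=0.5,
    seed=11,
)


def main():
    dataset = rd.simulate_all(CONFIG, consensus_only=True)
    outdir = ROOT / "results" / "synthetic"
    paths = write_dataset(dataset, outdir)
    truth = dataset.truth
    print(f"wrote {len(paths)} files under {outdir}")
    print(
        f"{CONFIG.n_tfs} TFs x {CONFIG.n_genes} genes, "
        f"{int(truth.prior_truth.to_numpy().sum())} planted edges, "
        f"{len(truth.planted_sites)} planted promoter sites"
    )
    print(
        f"differential TF {truth.differential_tf} "
        f"(+{CONFIG.activity_shift} activity in {truth.differential_condition}), "
        f"{len(truth.differential_edges)} differential edges"
    )


if __name__ == "__main__":
    main()
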