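"""Comparison of two condition networks.

Per-edge weight differences, top-K condition-favored edge selections, per-TF
summary statistics (genes per side, their difference and ratio, shared
genes), unique-target extraction, and candidate ranking of one TF's targets
against differential expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .panda import RegulatoryNetwork


class DiffNetError(ValueError):
    pass


@dataclass(frozen=True)
class DiffNetConfig:
    k: int = 10_000
    ratio_decimals: int = 2
    selection: str = "per_direction"  # or "single_pool"

    def __post_init__(self):
        if self.k < 1:
            raise DiffNetError("k must be at least 1")
        if self.selection not in ("per_direction", "single_pool"):
            raise DiffNetError("selection must be per_direction or single_pool")


def round_half_up(x: float, decimals: int = 2) -> float:
    """Reporting-style rounding (0.995 -> 1.00), not banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def edge_differences(
    net_a: RegulatoryNetwork, net_b: RegulatoryNetwork
) -> pd.DataFrame:
    """Full (tf, gene, w_a, w_b, diff = w_a - w_b) table over all pairs."""
    wa, wb = net_a.weights, net_b.weights
    if list(wa.index) != list(wb.index) or list(wa.columns) != list(wb.columns):
        extra_tf = set(wa.index).symmetric_difference(wb.index)
        extra_g = set(wa.columns).symmetric_difference(wb.columns)
        raise DiffNetError(
            f"networks are not aligned (tf mismatches: {sorted(extra_tf)[:5]}, "
            f"gene mismatches: {sorted(extra_g)[:5]})"
        )
    table = pd.DataFrame(
        {
            "w_a": wa.stack(),
            "w_b": wb.stack(),
        }
    ).rename_axis(["tf", "gene"]).reset_index()
    table["diff"] = table["w_a"] - table["w_b"]
    return table


def select_top_k(
    table: pd.DataFrame, config: DiffNetConfig = DiffNetConfig()
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """The K most A-favored (largest signed diff) and K most B-favored
    (smallest signed diff) edges; ties broken by (|diff| desc, tf, gene).

    Returns (S_A, S_B, warnings). With fewer than 2K rows the sides may
    overlap; a warning records it. The ``single_pool`` variant instead takes
    the K largest |diff| edges overall and splits them by sign.
    """
    if len(table) < 1:
        raise DiffNetError("empty edge table")
    recorded: list[str] = []
    t = table.copy()
    t["_absdiff"] = t["diff"].abs()
    if config.selection == "single_pool":
        pool = t.sort_values(
            ["_absdiff", "tf", "gene"], ascending=[False, True, True],
            kind="mergesort",
        ).head(config.k)
        s_a = pool[pool["diff"] > 0]
        s_b = pool[pool["diff"] < 0]
    else:
        by_a = t.sort_values(
            ["diff", "_absdiff", "tf", "gene"],
            ascending=[False, False, True, True],
            kind="mergesort",
        )
        by_b = t.sort_values(
            ["diff", "_absdiff", "tf", "gene"],
            ascending=[True, False, True, True],
            kind="mergesort",
        )
        s_a = by_a.head(config.k)
        s_b = by_b.head(config.k)
        if len(table) < 2 * config.k:
            recorded.append(
                f"table has {len(table)} rows < 2K={2 * config.k}; "
                "selections may overlap"
            )
    shared = len(
        set(map(tuple, s_a[["tf", "gene"]].to_numpy()))
        & set(map(tuple, s_b[["tf", "gene"]].to_numpy()))
    )
    if shared:
        recorded.append(f"{shared} edges appear in both selections")
    keep = ["tf", "gene", "w_a", "w_b", "diff"]
    return (
        s_a[keep].reset_index(drop=True),
        s_b[keep].reset_index(drop=True),
        recorded,
    )


def _genes_per_tf(selection: pd.DataFrame) -> dict[str, set]:
    out: dict[str, set] = {}
    for tf, gene in selection[["tf", "gene"]].itertuples(index=False):
        out.setdefault(tf, set()).add(gene)
    return out


def tf_summary(
    s_a: pd.DataFrame,
    s_b: pd.DataFrame,
    motif_of: dict[str, str] | None = None,
    ratio_decimals: int = 2,
) -> pd.DataFrame:
    """Per-TF counts over the two selections, sorted by nA descending.

    Columns: nA and nB (genes connected by the TF within each side's
    selection), nDiff = nA - nB, nOverlap (genes shared between the sides for
    that TF), and nRatio = nA/nB rounded half-up (NaN with a flag when
    nB = 0). One row per TF appearing in either selection.
    """
    genes_a = _genes_per_tf(s_a)
    genes_b = _genes_per_tf(s_b)
    rows = []
    for tf in sorted(set(genes_a) | set(genes_b)):
        ga = genes_a.get(tf, set())
        gb = genes_b.get(tf, set())
        na, nb = len(ga), len(gb)
        ratio_exact = na / nb if nb else np.nan
        rows.append(
            {
                "tf": tf,
                "motif_id": (motif_of or {}).get(tf, ""),
                "nA": na,
                "nB": nb,
                "nDiff": na - nb,
                "nOverlap": len(ga & gb),
                "nRatio": (
                    round_half_up(ratio_exact, ratio_decimals) if nb else np.nan
                ),
                "nRatio_exact": ratio_exact,
                "ratio_undefined": nb == 0,
            }
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(
        ["nA", "tf"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out.attrs["n_unique_tfs"] = len(out)
    return out


def unique_targets(
    s_a: pd.DataFrame, s_b: pd.DataFrame, tf: str
) -> tuple[set, set, set]:
    """(genes unique to the A side, unique to B, shared) for one TF."""
    genes_a = set(s_a.loc[s_a["tf"] == tf, "gene"])
    genes_b = set(s_b.loc[s_b["tf"] == tf, "gene"])
    if not genes_a and not genes_b:
        warnings.warn(f"TF {tf!r} absent from both selections", stacklevel=2)
    return genes_a - genes_b, genes_b - genes_a, genes_a & genes_b


def rank_candidates(
    target_genes, deg_table: pd.DataFrame, contrast: str
) -> pd.DataFrame:
    """Rank a TF's target genes by |fold change| for one contrast.

    ``contrast`` names a contrast present in the DEG table (columns
    log2fc_<contrast>, p_<contrast>, q_<contrast>). Reported fold change is
    linear-scale with the sign carrying direction (e.g., -1.38 means a
    1.38-fold decrease).
    """
    fc_col = f"log2fc_{contrast}"
    if fc_col not in deg_table.columns:
        raise DiffNetError(f"contrast {contrast!r} not present in the DEG table")
    present = [g for g in target_genes if g in deg_table.index]
    sub = deg_table.loc[present]
    log2fc = sub[fc_col].astype(float)
    linear = np.sign(log2fc) * np.power(2.0, np.abs(log2fc))
    linear = linear.where(log2fc != 0, 1.0)
    out = pd.DataFrame(
        {
            "gene": present,
            "fold_change": linear.to_numpy(),
            "log2fc": log2fc.to_numpy(),
            "p": sub[f"p_{contrast}"].to_numpy(),
            "q": sub[f"q_{contrast}"].to_numpy(),
        }
    )
    out["_abs"] = out["fold_change"].abs()
    out = (
        out.sort_values(["_abs", "gene"], ascending=[False, True], kind="mergesort")
        .drop(columns="_abs")
        .reset_index(drop=True)
    )
    return out
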