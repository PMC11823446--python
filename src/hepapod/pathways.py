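"""Pathway-level potency aggregation and molecular-hazard prioritization.

Gene-level BMCs are mapped onto gene-set collections; each pathway with
enough member hits is scored by the median member BMC (BMCMedian), ranked
across pathways by ascending potency, and prioritized with the FOC/BMC x 100
metric: the maximum fold-over-control response divided by the mean BMCMedian,
times 100. This is potency aggregation, not enrichment testing — no
hypergeometric or GSEA p-values are computed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .injury import SubstanceBMCSet

DEFAULT_MIN_HITS = 3


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0 or not np.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def foc_over_bmc(max_fold_change: float, bmc_median: float) -> float:
    """Prioritization metric: max fold-over-control / BMCMedian x 100.

    Reported to 3 significant figures for intuitive cross-substance
    comparison of effect size per unit potency.
    """
    if bmc_median <= 0:
        raise ValueError("bmc_median must be positive")
    return round_sig(max_fold_change / bmc_median * 100.0, 3)


def map_pathways(
    gene_bmcs: SubstanceBMCSet,
    genesets: dict[str, list[str]],
    min_hits: int = DEFAULT_MIN_HITS,
) -> pd.DataFrame:
    """Score each gene set holding >= min_hits member genes with BMCs.

    One row per qualifying pathway: hit count, BMCMedian (median of member
    BMCs; arithmetic mean of the central pair for even counts), max member
    fold-change, the FOC/BMC x 100 metric, and an up/down/mixed direction
    summary. Rank order is assigned by ``rank_pathways``.
    """
    if not genesets:
        raise ValueError("gene-set collection is empty")
    tbl = gene_bmcs.table.set_index("probe_id")
    rows = []
    for name, members in genesets.items():
        hits = tbl.index.intersection(members)
        if len(hits) < min_hits:
            continue
        sub = tbl.loc[hits]
        dirs = set(sub["direction"])
        rows.append(
            {
                "pathway": name,
                "substance": gene_bmcs.substance,
                "run": gene_bmcs.run,
                "n_genes_with_bmc": len(hits),
                "bmc_median": float(np.median(sub["bmc"])),
                "max_fold_change": float(sub["max_fold_change"].max()),
                "direction": dirs.pop() if len(dirs) == 1 else "mixed",
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "pathway", "substance", "run", "n_genes_with_bmc", "bmc_median",
            "max_fold_change", "direction",
        ],
    )
    if len(out):
        out["foc_over_bmc"] = [
            foc_over_bmc(fc, bm)
            for fc, bm in zip(out["max_fold_change"], out["bmc_median"])
        ]
    else:
        out["foc_over_bmc"] = pd.Series(dtype=float)
    return rank_pathways(out)


def rank_pathways(summaries: pd.DataFrame) -> pd.DataFrame:
    """Assign ascending-BMCMedian rank order (ties share the mean rank)."""
    out = summaries.copy()
    if len(out):
        out["bmc_rank_order"] = stats.rankdata(out["bmc_median"], method="average")
        out = out.sort_values("bmc_rank_order", kind="stable").reset_index(drop=True)
    else:
        out["bmc_rank_order"] = pd.Series(dtype=float)
    return out


def pathway_frequency(
    summaries: pd.DataFrame, pathway: str
) -> tuple[int, int]:
    """(identified, possible) exposure-profile counts for one pathway.

    An exposure profile is one (substance, run) combination present in the
    summaries table; the pathway is identified in a profile when it received
    a summary row there.
    """
    profiles = summaries[["substance", "run"]].drop_duplicates()
    possible = len(profiles)
    hits = summaries[summaries["pathway"] == pathway][
        ["substance", "run"]
    ].drop_duplicates()
    return len(hits), possible


def mean_pathway_summary(summaries: pd.DataFrame) -> pd.DataFrame:
    """Cross-run prioritization table: mean BMCMedian, max FC, FOC/BMC x 100.

    Averages each (substance, pathway) over runs with the arithmetic mean of
    BMCMedian, takes the maximum fold-change across runs, and recomputes the
    prioritization metric from the averaged potency.
    """
    grp = summaries.groupby(["substance", "pathway"], sort=True).agg(
        mean_bmc_median=("bmc_median", "mean"),
        max_fold_change=("max_fold_change", "max"),
        n_runs=("run", "nunique"),
    )
    grp["foc_over_bmc"] = [
        foc_over_bmc(fc, bm)
        for fc, bm in zip(grp["max_fold_change"], grp["mean_bmc_median"])
    ]
    return grp.reset_index().sort_values("mean_bmc_median").reset_index(drop=True)


def apply_geneset_patch(
    genesets: dict[str, list[str]], patch: dict[str, dict[str, list[str]]]
) -> dict[str, list[str]]:
    """Apply configured add/remove edits to a gene-set collection.

    ``patch`` maps set name -> {"add": [...], "remove": [...]}; supports
    documented post hoc curation without hard-coding any edit.
    """
    out = {k: list(v) for k, v in genesets.items()}
    for name, ops in patch.items():
        if name not in out:
            raise KeyError(f"gene set {name!r} not in collection")
        members = [g for g in out[name] if g not in set(ops.get("remove", []))]
        members += [g for g in ops.get("add", []) if g not in members]
        out[name] = members
    return out
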