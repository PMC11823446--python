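"""Normalization and sample-level quality control.

Counts are attenuation-adjusted, depth-normalized to reads-per-million, and
log2-transformed after adding a pseudo-count of 1. Sample QC removes wells
failing sequencing-quality thresholds; replicate QC drops wells whose median
inter-replicate correlation is discordant with their treatment group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import QC_META_COLUMNS, CountMatrix

log = logging.getLogger(__name__)

#: sample-removal thresholds; a sample is removed when a metric falls strictly
#: below its threshold (rates are fractions in [0, 1])
QC_THRESHOLDS = {
    "total_reads": 300_000,
    "total_alignment_rate": 0.40,
    "unique_alignment_rate": 0.30,
    "aligned_reads": 300_000,
    "pct_probes_expressed": 0.50,
}

#: a replicate is dropped when its median inter-replicate correlation differs
#: from the median of its co-replicates' medians by more than this
REPLICATE_CORR_MARGIN = 0.05


@dataclass
class ExprMatrix:
    """Probe x sample log2(RPM + 1) expression with its sample metadata."""

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    attenuation_adjusted: bool = True
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("log2(RPM+1) values must be nonnegative")
        if not self.values.columns.equals(self.sample_meta.index):
            raise ValueError("sample_meta index must match expression columns")


@dataclass
class SampleQCReport:
    """Per-sample QC metrics with pass/fail per criterion and overall verdict.

    ``table`` has one row per sample: the five metrics, one boolean
    ``pass_<metric>`` column each, and ``overall_pass`` (fail iff any
    criterion fails). ``dropped_replicates`` records correlation-outlier
    removals with the margin by which each failed.
    """

    table: pd.DataFrame
    dropped_replicates: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["sample_id", "group", "median_corr", "others_median", "margin"]
        )
    )

    @property
    def removed_samples(self) -> list[str]:
        out = list(self.table.index[~self.table["overall_pass"]])
        out += list(self.dropped_replicates["sample_id"])
        return out


def normalize(counts: CountMatrix) -> ExprMatrix:
    """Attenuation-adjust, normalize to reads-per-million, log2-transform.

    value = log2(adjusted_count / sample_adjusted_total * 1e6 + 1), with
    adjusted_count = raw * attenuation_factor. Samples with zero total counts
    are rejected by name.
    """
    adjusted = counts.counts.to_numpy(dtype=float) * counts.attenuation.to_numpy()[:, None]
    totals = adjusted.sum(axis=0)
    zero = totals == 0
    if zero.any():
        bad = list(counts.counts.columns[zero])
        raise ValueError(f"samples with zero total counts: {bad}")
    rpm = adjusted / totals[None, :] * 1e6
    values = pd.DataFrame(
        np.log2(rpm + 1.0), index=counts.counts.index, columns=counts.counts.columns
    )
    return ExprMatrix(values=values, sample_meta=counts.sample_meta.copy())


def _qc_metrics(counts: CountMatrix) -> pd.DataFrame:
    """Assemble the five QC metrics, computing what the counts determine.

    Aligned reads and the fraction of expressed probes (>=5 reads) are
    computable from the matrix and recomputed when absent from the metadata;
    total reads falls back to the aligned total; alignment rates cannot be
    derived from probe counts and must be provided.
    """
    meta = counts.sample_meta
    missing = [
        c
        for c in ("total_alignment_rate", "unique_alignment_rate")
        if c not in meta.columns
    ]
    if missing:
        raise ValueError(f"sample_meta is missing required QC fields: {missing}")
    arr = counts.counts.to_numpy()
    out = pd.DataFrame(index=meta.index)
    aligned = arr.sum(axis=0)
    out["total_reads"] = meta.get("total_reads", pd.Series(aligned, index=meta.index))
    out["total_alignment_rate"] = meta["total_alignment_rate"]
    out["unique_alignment_rate"] = meta["unique_alignment_rate"]
    out["aligned_reads"] = meta.get("aligned_reads", pd.Series(aligned, index=meta.index))
    out["pct_probes_expressed"] = meta.get(
        "pct_probes_expressed", pd.Series((arr >= 5).mean(axis=0), index=meta.index)
    )
    return out


def qc_filter(counts: CountMatrix) -> tuple[CountMatrix, SampleQCReport]:
    """Remove samples falling strictly below any QC threshold."""
    metrics = _qc_metrics(counts)
    table = metrics.copy()
    ok = pd.Series(True, index=metrics.index)
    for metric, threshold in QC_THRESHOLDS.items():
        passed = metrics[metric] >= threshold
        table[f"pass_{metric}"] = passed
        ok &= passed
    table["overall_pass"] = ok
    keep = list(metrics.index[ok])
    filtered = CountMatrix(
        counts=counts.counts[keep],
        attenuation=counts.attenuation,
        sample_meta=counts.sample_meta.loc[keep],
    )
    return filtered, SampleQCReport(table=table)


def drop_outlier_replicates(
    expr: ExprMatrix, margin: float = REPLICATE_CORR_MARGIN
) -> tuple[ExprMatrix, SampleQCReport]:
    """Drop discordant replicates by median inter-replicate Pearson correlation.

    Within each (substance, concentration, run) group of >= 3 replicates, each
    sample's median correlation with its co-replicates is compared with the
    median of the other replicates' medians; the worst sample exceeding the
    margin is dropped (single pass, at most one removal per group). Groups of
    fewer than 3 replicates are left untouched with a logged warning.
    """
    meta = expr.sample_meta
    dropped_rows = []
    drop: list[str] = []
    for key, grp in meta.groupby(["substance", "concentration", "run"], sort=False):
        samples = list(grp.index)
        if len(samples) < 3:
            log.warning("replicate-outlier rule skipped for group %s (n=%d)",
                        key, len(samples))
            continue
        sub = expr.values[samples].to_numpy()
        corr = np.corrcoef(sub.T)
        med = np.array(
            [np.median(np.delete(corr[i], i)) for i in range(len(samples))]
        )
        margins = np.array(
            [med[i] - np.median(np.delete(med, i)) for i in range(len(samples))]
        )
        worst = int(np.argmax(np.abs(margins)))
        if abs(margins[worst]) > margin:
            drop.append(samples[worst])
            dropped_rows.append(
                {
                    "sample_id": samples[worst],
                    "group": "|".join(map(str, key)),
                    "median_corr": med[worst],
                    "others_median": med[worst] - margins[worst],
                    "margin": margins[worst],
                }
            )
    keep = [s for s in expr.values.columns if s not in drop]
    report = SampleQCReport(
        table=pd.DataFrame(index=pd.Index(drop, name="sample_id")).assign(
            overall_pass=False
        )
        if drop
        else pd.DataFrame(columns=["overall_pass"]),
        dropped_replicates=pd.DataFrame(
            dropped_rows,
            columns=["sample_id", "group", "median_corr", "others_median", "margin"],
        ),
    )
    out = ExprMatrix(
        values=expr.values[keep],
        sample_meta=meta.loc[keep],
        attenuation_adjusted=expr.attenuation_adjusted,
        pseudocount=expr.pseudocount,
    )
    return out, report
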