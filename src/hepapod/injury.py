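"""Liver-injury thresholding from potency-ordered gene-level BMCs.

The injury threshold is the 105th most potent (smallest) surviving gene-level
BMC of a substance (BMC105), an externally qualified index distinguishing
exposures with high potential for human liver injury. A substance is
classified SILI (substance-induced liver injury) when the threshold is
calculable in both independent runs, equivocal when in exactly one, and
non-SILI when in neither.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: potency rank defining the injury threshold (from the qualifying study)
DEFAULT_THRESHOLD_INDEX = 105


@dataclass
class SubstanceBMCSet:
    """Ascending gene-level BMCs for one substance/run with annotations."""

    substance: str
    run: str
    table: pd.DataFrame  # columns: probe_id, bmc, direction, max_fold_change
    unit: str = "uM"

    def __post_init__(self) -> None:
        if (self.table["bmc"] <= 0).any():
            raise ValueError("BMCs must be positive")
        self.table = self.table.sort_values("bmc", kind="stable").reset_index(drop=True)

    @property
    def bmcs(self) -> np.ndarray:
        return self.table["bmc"].to_numpy()


def bmc105(
    bmc_set: SubstanceBMCSet | np.ndarray,
    threshold_index: int = DEFAULT_THRESHOLD_INDEX,
) -> float | None:
    """The threshold_index-th smallest BMC, or None (non-calculable).

    Non-calculable when fewer than ``threshold_index`` BMCs survive
    filtering; ties are resolved by stable ascending sort position.
    """
    values = bmc_set.bmcs if isinstance(bmc_set, SubstanceBMCSet) else np.sort(
        np.asarray(bmc_set, dtype=float), kind="stable"
    )
    if len(values) < threshold_index:
        return None
    return float(values[threshold_index - 1])


def classify(per_run: list[float | None]) -> str:
    """SILI / equivocal / non-SILI from per-run threshold calculability."""
    if not per_run:
        raise ValueError("need at least one run")
    n_calc = sum(v is not None for v in per_run)
    if n_calc == len(per_run):
        return "SILI"
    if n_calc == 0:
        return "non-SILI"
    return "equivocal"


def convert_units(
    value: float,
    from_unit: str,
    to_unit: str,
    mw: float = 300.0,
    density: float = 1.0,
) -> float:
    """Convert between percent (v/v) dilution and micromolar concentration.

    uM = pct * density * 1e7 / mw (density in g/mL, mw in g/mol). The default
    molecular weight of 300 g/mol is the suppositional average used for
    mixtures of unknown composition; density defaults to 1 g/mL.
    """
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    units = {from_unit, to_unit}
    if not units <= {"pct_vv", "uM"}:
        raise ValueError(f"unsupported units {units - {'pct_vv', 'uM'}}")
    if from_unit == to_unit:
        return value
    if from_unit == "pct_vv":
        return value * density * 1e7 / mw
    return value * mw / (density * 1e7)


def accumulation_curve(sets: list[SubstanceBMCSet]) -> pd.DataFrame:
    """Potency-ordered (rank, BMC) pairs per substance for accumulation plots."""
    rows = []
    for s in sets:
        for i, b in enumerate(s.bmcs, start=1):
            rows.append((s.substance, s.run, i, float(b)))
    return pd.DataFrame(rows, columns=["substance", "run", "rank", "bmc"])


def rank_substances(
    sets: list[SubstanceBMCSet],
    threshold_index: int = DEFAULT_THRESHOLD_INDEX,
    mean: str = "arithmetic",
) -> pd.DataFrame:
    """Injury-threshold rankings across runs with SILI classification.

    One row per substance: per-run BMC105 (NaN when non-calculable), the
    cross-run mean over calculable runs (arithmetic by default, geometric
    optionally) and the classification.
    """
    per_sub: dict[str, dict[str, float | None]] = {}
    runs: list[str] = []
    for s in sets:
        per_sub.setdefault(s.substance, {})[s.run] = bmc105(s, threshold_index)
        if s.run not in runs:
            runs.append(s.run)
    runs.sort()
    rows = []
    for sub, by_run in sorted(per_sub.items()):
        vals = [by_run.get(r) for r in runs]
        calc = [v for v in vals if v is not None]
        if calc:
            m = float(np.mean(calc)) if mean == "arithmetic" else float(
                np.exp(np.mean(np.log(calc)))
            )
        else:
            m = np.nan
        rows.append(
            {
                "substance": sub,
                **{f"bmc105_{r}": (np.nan if v is None else v) for r, v in zip(runs, vals)},
                "mean_bmc105": m,
                "classification": classify(vals),
            }
        )
    return pd.DataFrame(rows).sort_values("mean_bmc105").reset_index(drop=True)
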