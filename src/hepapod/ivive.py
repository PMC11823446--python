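"""In vitro to in vivo extrapolation by fold-ratio potency windows.

In vitro pathway potencies (BMCs in uM) are compared with in vivo plasma
concentrations at the liver-weight LOEL (lowest-observed-effect level).
Anchors may need linear dose-extrapolation of plasma levels (dose-
proportional kinetics) and back-scaling for plasma clearance between the
last exposure and sampling. Concordance is scored by the symmetric fold
ratio max(a,b)/min(a,b) against inclusive 2-fold and 3-fold potency windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

WINDOWS = (2.0, 3.0)


@dataclass(frozen=True)
class InVivoAnchor:
    """One substance's in vivo reference point for a pathway comparison."""

    substance: str
    loel_plasma: float | None = None  # uM, measured at the LOEL dose
    loel_dose: float | None = None  # mg/kg-day
    ref_dose: float | None = None  # mg/kg-day with measured plasma
    plasma_at_ref_dose: float | None = None  # uM
    clearance_fraction_24h: float = 0.0
    mw: float | None = None  # g/mol, for mg/L <-> uM conversion
    source: str = ""

    def __post_init__(self) -> None:
        if self.loel_plasma is not None and self.loel_plasma <= 0:
            raise ValueError("loel_plasma must be positive")
        if not (0.0 <= self.clearance_fraction_24h < 1.0):
            raise ValueError("clearance_fraction_24h must be in [0, 1)")

    def adjusted_plasma(self) -> float:
        """LOEL plasma concentration after extrapolation and clearance."""
        if self.loel_plasma is not None:
            plasma = self.loel_plasma
        elif None not in (self.plasma_at_ref_dose, self.ref_dose, self.loel_dose):
            plasma = extrapolate_loel_plasma(
                self.plasma_at_ref_dose, self.ref_dose, self.loel_dose
            )
        else:
            raise ValueError(
                f"anchor for {self.substance!r} has neither a measured LOEL "
                "plasma level nor the fields for linear extrapolation"
            )
        return adjust_for_clearance(plasma, self.clearance_fraction_24h)


def adjust_for_clearance(measured_plasma: float, cleared_fraction: float) -> float:
    """Back-scale a post-clearance plasma level to the pre-clearance level.

    Linear scaling: a level measured after a fraction f of the substance was
    cleared corresponds to measured / (1 - f) at exposure.
    """
    if cleared_fraction >= 1.0 or cleared_fraction < 0.0:
        raise ValueError("cleared_fraction must be in [0, 1)")
    return measured_plasma / (1.0 - cleared_fraction)


def extrapolate_loel_plasma(
    plasma_at_ref_dose: float, ref_dose: float, loel_dose: float
) -> float:
    """Dose-proportional plasma extrapolation to the LOEL dose."""
    if ref_dose <= 0 or loel_dose <= 0:
        raise ValueError("doses must be positive")
    return plasma_at_ref_dose * loel_dose / ref_dose


def mg_per_l_to_um(value: float, mw: float) -> float:
    """mg/L -> uM via molecular weight (g/mol)."""
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    return value * 1000.0 / mw


def fold_ratio(a: float, b: float) -> float:
    """Symmetric fold difference max(a,b)/min(a,b) >= 1."""
    if a <= 0 or b <= 0:
        raise ValueError("concentrations must be positive")
    return max(a, b) / min(a, b)


def window_verdict(ratio: float, windows: tuple[float, float] = WINDOWS) -> str:
    """Classify a fold ratio against inclusive potency windows."""
    two, three = windows
    if ratio <= two:
        return "within 2-fold"
    if ratio <= three:
        return "within 3-fold"
    return "discordant"


def translate(
    anchors: list[InVivoAnchor],
    pathway_bmcs: pd.DataFrame,
    windows: tuple[float, float] = WINDOWS,
) -> pd.DataFrame:
    """Build the substance x pathway IVIVE concordance table.

    ``pathway_bmcs`` has columns (substance, pathway, bmc) in uM — typically
    PPARa / CAR pathway BMCMedians and the BMC105 injury threshold. One row
    per anchor x available pathway, sorted by fold ratio.
    """
    rows = []
    for anchor in anchors:
        plasma = anchor.adjusted_plasma()
        avail = pathway_bmcs[pathway_bmcs["substance"] == anchor.substance]
        for _, rec in avail.iterrows():
            ratio = fold_ratio(rec["bmc"], plasma)
            rows.append(
                {
                    "substance": anchor.substance,
                    "pathway": rec["pathway"],
                    "in_vitro_bmc": float(rec["bmc"]),
                    "in_vivo_plasma": float(plasma),
                    "fold_ratio": float(ratio),
                    "verdict": window_verdict(ratio, windows),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "substance", "pathway", "in_vitro_bmc", "in_vivo_plasma",
            "fold_ratio", "verdict",
        ],
    )
    return out.sort_values("fold_ratio", kind="stable").reset_index(drop=True)
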