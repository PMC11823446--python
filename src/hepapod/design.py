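"""Exposure design: substances crossed with a half-log concentration series.

The assay layout modeled here is a concentration-response screen: each
substance is tested over a geometric (half-log, ratio ~sqrt(10)) dilution
series with technical replicates, repeated in independent experimental runs,
alongside vehicle-control wells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HALF_LOG = float(np.sqrt(10.0))

#: vehicle-control wells per substance per run (fixture choice; the assay
#: layout needs enough control wells for fold-change and SD baselines)
DEFAULT_VEHICLE_WELLS = 8


@dataclass(frozen=True)
class DoseDesign:
    """Exposure layout: substances x concentration levels x replicates x runs.

    ``levels`` are stored ascending (lowest to highest concentration) and must
    form a strictly increasing geometric series; ``unit`` tags the
    concentration scale ('uM' or 'pct_vv').
    """

    substances: tuple[str, ...]
    levels: tuple[float, ...]
    unit: str = "uM"
    n_replicates: int = 4
    runs: tuple[str, ...] = ("R1", "R2")
    vehicle_label: str = "vehicle"
    n_vehicle_wells: int = DEFAULT_VEHICLE_WELLS

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=float)
        if lv.size < 3:
            raise ValueError("a dose design needs at least 3 concentration levels")
        if np.any(lv <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(lv) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        ratios = lv[1:] / lv[:-1]
        if np.ptp(ratios) > 1e-6 * ratios[0]:
            raise ValueError("concentration levels must be evenly log-spaced")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per level")

    @property
    def top(self) -> float:
        return self.levels[-1]

    @property
    def lowest(self) -> float:
        return self.levels[0]

    def n_exposed_samples(self) -> int:
        """Exposed (non-vehicle) wells across all substances and runs."""
        return (
            len(self.substances)
            * len(self.levels)
            * self.n_replicates
            * len(self.runs)
        )


def make_design(
    n_substances: int = 1,
    top_conc: float = 500.0,
    n_levels: int = 9,
    n_reps: int = 4,
    n_runs: int = 2,
    unit: str = "uM",
    step: float = HALF_LOG,
) -> DoseDesign:
    """Build a half-log serial-dilution design from the top concentration down.

    Levels are generated by successive division by ``step`` (default sqrt(10),
    the half-log step) starting at ``top_conc``, then stored ascending.
    Deterministic given its arguments.
    """
    if top_conc <= 0:
        raise ValueError(f"top_conc must be positive, got {top_conc!r}")
    if n_levels < 3:
        raise ValueError(f"need at least 3 levels, got {n_levels}")
    if n_substances < 1:
        raise ValueError("need at least one substance")
    levels = tuple(sorted(top_conc / step**i for i in range(n_levels)))
    substances = tuple(f"S{i + 1:02d}" for i in range(n_substances))
    runs = tuple(f"R{i + 1}" for i in range(n_runs))
    return DoseDesign(
        substances=substances,
        levels=levels,
        unit=unit,
        n_replicates=n_reps,
        runs=runs,
    )
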