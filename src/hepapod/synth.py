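"""Synthetic assay data with the statistical structure the pipeline assumes.

Emulates a targeted-probe high-throughput transcriptomic readout (~3,368
probes) over a half-log concentration series: a minority of probes respond to
dose with monotone (Hill-shaped), linear or nonmonotone log2-expression
profiles of known potency; the rest are dose-independent. Noise is Gaussian on
the log2 scale with constant variance across doses; counts are obtained by
allocating a lognormally varying library size across probes and Poisson
sampling, with a subset of probes attenuated (under-counted by a known
factor), exercising the attenuation-adjustment path downstream.

Also simulates per-tile morphology "altered" probabilities from a
variable-dispersion beta model, and random gene-set collections for the
pathway stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DoseDesign

QC_META_COLUMNS = (
    "total_reads",
    "total_alignment_rate",
    "unique_alignment_rate",
    "aligned_reads",
    "pct_probes_expressed",
)


@dataclass(frozen=True)
class ResponderSpec:
    """Ground truth for one dose-responsive probe.

    ``true_bmc`` is the concentration at which the mean log2 profile departs
    from baseline by exactly one noise SD (the 1-SD benchmark response), so the
    planted potency is exact by construction for monotone shapes.
    """

    probe_id: str
    model: str = "hill"  # hill | linear | flat | nonmonotone
    true_bmc: float = 10.0
    direction: str = "up"
    max_fold_change: float = 4.0
    noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.model not in ("hill", "linear", "flat", "nonmonotone"):
            raise ValueError(f"unknown responder model {self.model!r}")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if self.max_fold_change < 1:
            raise ValueError("max_fold_change must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.model != "flat" and self.true_bmc <= 0:
            raise ValueError("true_bmc must be positive")


@dataclass
class CountMatrix:
    """Probe x sample integer counts with attenuation factors and metadata.

    ``counts``: DataFrame, probes as rows, samples as columns, raw
    (as-observed) nonnegative integer counts. ``attenuation``: per-probe
    multiplier >= 1 mapping observed counts back to unattenuated equivalents.
    ``sample_meta``: one row per sample with the design cell (substance,
    concentration, replicate, run) and sequencing QC metrics.
    """

    counts: pd.DataFrame
    attenuation: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if (self.attenuation < 1).any():
            raise ValueError("attenuation factors must be >= 1")
        if not self.counts.columns.equals(self.sample_meta.index):
            raise ValueError("sample_meta index must match count columns")
        if not self.counts.index.equals(self.attenuation.index):
            raise ValueError("attenuation index must match count rows")


def _hill_k(true_bmc: float, fc_max: float, noise_sd: float, h: float) -> float:
    """Half-max concentration placing the 1-SD crossing exactly at true_bmc.

    Solves log2(1 + (FC-1) * B^h / (k^h + B^h)) = noise_sd for k.
    Requires FC > 2**noise_sd so the profile actually spans one SD.
    """
    q = 2.0**noise_sd - 1.0
    if fc_max - 1.0 <= q:
        raise ValueError(
            f"max_fold_change {fc_max} too small to cross 1 SD ({noise_sd}) "
        )
    return true_bmc * ((fc_max - 1.0) / q - 1.0) ** (1.0 / h)


def _log2_shift(spec: ResponderSpec, doses: np.ndarray, hill_h: float) -> np.ndarray:
    """Mean log2 departure from baseline at each dose (0 for vehicle)."""
    d = np.asarray(doses, dtype=float)
    if spec.model == "flat":
        delta = np.zeros_like(d)
    elif spec.model == "hill":
        k = _hill_k(spec.true_bmc, spec.max_fold_change, spec.noise_sd, hill_h)
        frac = d**hill_h / (k**hill_h + d**hill_h)
        delta = np.log2(1.0 + (spec.max_fold_change - 1.0) * frac)
    elif spec.model == "linear":
        # slope chosen so the 1-SD crossing sits at true_bmc; the profile
        # saturates at max_fold_change so extreme doses stay physical
        delta = np.minimum(
            (spec.noise_sd / spec.true_bmc) * d, np.log2(spec.max_fold_change)
        )
    else:  # nonmonotone: log-dose Gaussian bump peaking at true_bmc
        amp = np.log2(spec.max_fold_change)
        with np.errstate(divide="ignore"):
            x = np.where(d > 0, np.log10(np.maximum(d, 1e-300)), -np.inf)
        delta = np.where(
            np.isfinite(x),
            amp * np.exp(-((x - np.log10(spec.true_bmc)) ** 2) / (2 * 0.5**2)),
            0.0,
        )
    return delta if spec.direction == "up" else -delta


def _sample_table(design: DoseDesign) -> pd.DataFrame:
    rows = []
    for sub in design.substances:
        for run in design.runs:
            for rep in range(1, design.n_vehicle_wells + 1):
                rows.append((f"{sub}_{run}_veh_{rep:02d}", sub, 0.0, rep, run))
            for li, conc in enumerate(design.levels, start=1):
                for rep in range(1, design.n_replicates + 1):
                    rows.append(
                        (f"{sub}_{run}_L{li}_{rep}", sub, float(conc), rep, run)
                    )
    return pd.DataFrame(
        rows, columns=["sample_id", "substance", "concentration", "replicate", "run"]
    ).set_index("sample_id")


def simulate_counts(
    design: DoseDesign,
    responders: list[ResponderSpec],
    n_null_probes: int = 3000,
    mean_depth: float = 1_000_000.0,
    seed: int = 0,
    null_noise_sd: float = 0.2,
    hill_h: float = 2.0,
    attenuated_fraction: float = 0.10,
    depth_log_sd: float = 0.15,
) -> CountMatrix:
    """Simulate a probe-count matrix with planted dose responders.

    Null probes have dose-independent expected expression; responder probes
    follow their spec'd log2 profile. Per-probe baselines are drawn once (so
    both runs share biology); log2-scale Gaussian noise with constant variance
    is added per sample; library sizes vary lognormally around ``mean_depth``;
    observed counts for attenuated probes are divided by their attenuation
    factor before Poisson sampling.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    ids = [r.probe_id for r in responders]
    if len(set(ids)) != len(ids):
        raise ValueError("responder probe IDs must be unique")
    rng = np.random.default_rng(seed)

    probes = ids + [f"NULL_{i:05d}" for i in range(n_null_probes)]
    n_probes = len(probes)
    meta = _sample_table(design)
    doses = meta["concentration"].to_numpy()
    n_samples = len(meta)

    # per-probe baseline log2 relative abundance
    base = rng.normal(5.0, 2.0, size=n_probes)

    shift = np.zeros((n_probes, n_samples))
    noise_sd = np.full(n_probes, null_noise_sd)
    for i, spec in enumerate(responders):
        shift[i] = _log2_shift(spec, doses, hill_h)
        noise_sd[i] = spec.noise_sd

    log2_expr = (
        base[:, None]
        + shift
        + rng.normal(0.0, 1.0, size=(n_probes, n_samples)) * noise_sd[:, None]
    )
    abundance = np.exp2(log2_expr)
    frac = abundance / abundance.sum(axis=0, keepdims=True)

    lib = mean_depth * np.exp(rng.normal(0.0, depth_log_sd, size=n_samples))

    att = np.ones(n_probes)
    n_att = int(round(attenuated_fraction * n_probes))
    if n_att:
        idx = rng.choice(n_probes, size=n_att, replace=False)
        att[idx] = np.exp(rng.uniform(0.0, np.log(50.0), size=n_att))
    lam = frac * lib[None, :] / att[:, None]
    counts = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=pd.Index(probes, name="probe_id"),
                             columns=meta.index)
    meta = meta.copy()
    meta["total_reads"] = np.round(lib * rng.uniform(1.05, 1.20, n_samples)).astype(int)
    meta["aligned_reads"] = counts.sum(axis=0)
    meta["total_alignment_rate"] = rng.uniform(0.80, 0.95, n_samples)
    meta["unique_alignment_rate"] = rng.uniform(0.60, 0.85, n_samples)
    meta["pct_probes_expressed"] = (counts >= 5).mean(axis=0)
    return CountMatrix(
        counts=counts_df,
        attenuation=pd.Series(att, index=counts_df.index, name="attenuation_factor"),
        sample_meta=meta,
    )


def simulate_tile_scores(
    design: DoseDesign,
    beta_mean_params: tuple[float, float],
    beta_precision_params: tuple[float, float],
    n_tiles_per_well: int = 16,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-tile morphology 'altered' probabilities.

    Scores are drawn from a beta distribution whose mean follows
    inverse-logit(b0 + b1*x) and precision exp(g0 + g1*x), with x =
    log10(concentration) and vehicle wells at a pseudo-dose one decade below
    the lowest tested concentration. Returns a tidy frame (well_id, substance,
    concentration, replicate, run, tile_index, score) with every score
    strictly inside (0, 1).
    """
    if n_tiles_per_well < 1:
        raise ValueError("need at least one tile per well")
    b0, b1 = beta_mean_params
    g0, g1 = beta_precision_params
    rng = np.random.default_rng(seed)
    meta = _sample_table(design)
    x0 = np.log10(design.lowest) - 1.0
    conc = meta["concentration"].to_numpy()
    x = np.where(conc > 0, np.log10(np.maximum(conc, 1e-300)), x0)
    mu = 1.0 / (1.0 + np.exp(-(b0 + b1 * x)))
    phi = np.exp(g0 + g1 * x)
    rows = []
    for j, well in enumerate(meta.index):
        a, b = mu[j] * phi[j], (1.0 - mu[j]) * phi[j]
        scores = np.clip(rng.beta(a, b, size=n_tiles_per_well), 1e-6, 1 - 1e-6)
        for t, s in enumerate(scores):
            rows.append(
                (
                    well,
                    meta["substance"].iloc[j],
                    conc[j],
                    meta["replicate"].iloc[j],
                    meta["run"].iloc[j],
                    t,
                    float(s),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "well_id",
            "substance",
            "concentration",
            "replicate",
            "run",
            "tile_index",
            "score",
        ],
    )


def default_responders(
    design: DoseDesign,
    n_hill: int = 100,
    n_nonmonotone: int = 25,
    n_linear: int = 10,
    seed: int = 0,
    noise_sd: float = 0.2,
) -> list[ResponderSpec]:
    """A realistic planted-responder panel for the default simulation.

    Hill-shaped responders dominate (monotone saturating responses are the
    typical transcriptomic dose-response shape), with a smaller fraction of
    nonmonotone and linear profiles; potencies log-uniform across the tested
    range, fold-changes log-uniform in [4, 32], directions random.
    """
    rng = np.random.default_rng(seed)
    specs: list[ResponderSpec] = []
    kinds = ["hill"] * n_hill + ["nonmonotone"] * n_nonmonotone + ["linear"] * n_linear
    lo, hi = design.lowest * 2.0, design.top / 2.0
    for i, kind in enumerate(kinds):
        specs.append(
            ResponderSpec(
                probe_id=f"RESP_{kind.upper()}_{i:04d}",
                model=kind,
                true_bmc=float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
                direction="up" if rng.random() < 0.5 else "down",
                max_fold_change=float(np.exp2(rng.uniform(2.0, 5.0))),
                noise_sd=noise_sd,
            )
        )
    return specs


def make_genesets(
    n_pathways: int,
    genes_per_set: tuple[int, int],
    universe: list[str],
    seed: int = 0,
    name_prefix: str = "SET",
) -> dict[str, list[str]]:
    """Random overlapping gene sets over a probe universe (GMT-serializable)."""
    if not universe:
        raise ValueError("gene universe must be nonempty")
    lo, hi = genes_per_set
    if lo < 1:
        raise ValueError("gene sets must be nonempty")
    if hi > len(universe):
        raise ValueError(
            f"genes_per_set upper bound {hi} exceeds universe size {len(universe)}"
        )
    rng = np.random.default_rng(seed)
    universe = list(universe)
    sets: dict[str, list[str]] = {}
    for i in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        sets[f"{name_prefix}_{i + 1:04d}"] = [universe[j] for j in sorted(members)]
    return sets
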