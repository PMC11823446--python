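"""Morphology dose-response: variable-dispersion beta regression and EC10.

Deep-learning tile scores (the probability that an image tile shows altered
cell morphology, strictly inside (0,1)) are modeled against the dose
covariate x = log10(concentration) with a double-index beta regression:
logit(mean) = b0 + b1*x and log(precision) = g0 + g1*x, fit by maximum
likelihood. The EC10 is the concentration at which the fitted mean has risen
10% of the way through its dynamic range over the tested interval (a relative
ECx; an absolute mean-probability-0.10 alternative is available), with
confidence intervals from the asymptotic delta method on the log10
concentration scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

TILE_COLUMNS = ("well_id", "substance", "concentration", "tile_index", "score")


@dataclass
class BetaRegFit:
    """Double-index beta regression fit (logit mean link, log precision link)."""

    mean_coef: np.ndarray  # (b0, b1)
    precision_coef: np.ndarray  # (g0, g1)
    cov: np.ndarray  # 4x4 covariance, order (b0, b1, g0, g1)
    loglik: float
    converged: bool
    x_range: tuple[float, float]

    def mean_at(self, x: np.ndarray | float) -> np.ndarray | float:
        b0, b1 = self.mean_coef
        return special.expit(b0 + b1 * np.asarray(x, dtype=float))


@dataclass(frozen=True)
class Ec10Result:
    ec10: float | None
    ci_lower: float | None
    ci_upper: float | None
    calculable: bool
    reason: str = ""


def dose_covariate(conc: np.ndarray, lowest_positive: float | None = None) -> np.ndarray:
    """x = log10(concentration); vehicle wells one decade below the lowest
    positive concentration (a pseudo-dose on the same log axis)."""
    conc = np.asarray(conc, dtype=float)
    positive = conc[conc > 0]
    if positive.size == 0:
        raise ValueError("no positive concentrations")
    lo = lowest_positive if lowest_positive is not None else positive.min()
    return np.where(conc > 0, np.log10(np.maximum(conc, 1e-300)), np.log10(lo) - 1.0)


def squeeze_scores(y: np.ndarray) -> np.ndarray:
    """Standard boundary squeeze (y*(n-1) + 0.5)/n for scores touching 0/1."""
    y = np.asarray(y, dtype=float)
    n = y.size
    return (y * (n - 1) + 0.5) / n


def screen_altered(tiles: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Retain substances with at least one tile scoring above the threshold.

    Substances whose tiles are never 'altered' carry no dose-response signal
    and are excluded from EC10 modeling. Returns a per-substance table with
    ``active`` flags.
    """
    out = (
        tiles.groupby("substance")["score"]
        .max()
        .rename("max_score")
        .reset_index()
    )
    out["active"] = out["max_score"] > threshold
    return out


def fit_beta(tiles: pd.DataFrame) -> BetaRegFit:
    """ML fit of the double-index beta regression for one substance's tiles.

    Scores must be strictly inside (0,1) — boundary values are rejected with
    guidance to apply ``squeeze_scores`` explicitly (no silent modification).
    Covariance comes from the observed information at the optimum.
    """
    from statsmodels.othermod.betareg import BetaModel

    y = tiles["score"].to_numpy(dtype=float)
    if np.any(y <= 0) or np.any(y >= 1):
        raise ValueError(
            "tile scores must lie strictly in (0,1); apply squeeze_scores() "
            "to boundary data explicitly before fitting"
        )
    x = dose_covariate(tiles["concentration"].to_numpy())
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct concentrations")
    X = np.column_stack([np.ones_like(x), x])
    model = BetaModel(y, X, exog_precision=X)  # logit mean link, log precision link
    res = None
    for method in ("lbfgs", "nm"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            candidate = model.fit(method=method, disp=False, maxiter=2000)
        try:
            cov = np.asarray(candidate.cov_params())
        except ValueError:
            continue
        if candidate.mle_retvals.get("converged", True) and np.all(np.isfinite(cov)):
            res = candidate
            break
    if res is None:
        return BetaRegFit(
            mean_coef=np.full(2, np.nan), precision_coef=np.full(2, np.nan),
            cov=np.full((4, 4), np.nan), loglik=np.nan, converged=False,
            x_range=(float(x.min()), float(x.max())),
        )
    params = np.asarray(res.params)  # (b0, b1, g0, g1)
    converged = True
    return BetaRegFit(
        mean_coef=params[:2],
        precision_coef=params[2:],
        cov=cov,
        loglik=float(res.llf),
        converged=converged,
        x_range=(float(x.min()), float(x.max())),
    )


def _ec10_x(b0: float, b1: float, x_lo: float, x_hi: float, frac: float,
            mode: str) -> float:
    """log10-concentration where the fitted mean crosses the ECx level."""
    mu_lo = special.expit(b0 + b1 * x_lo)
    mu_hi = special.expit(b0 + b1 * x_hi)
    target = mu_lo + frac * (mu_hi - mu_lo) if mode == "relative" else frac
    return (special.logit(target) - b0) / b1


def ec10(
    fit: BetaRegFit,
    level: float = 0.95,
    conc_range: tuple[float, float] | None = None,
    frac: float = 0.10,
    mode: str = "relative",
) -> Ec10Result:
    """EC10 with delta-method confidence interval.

    EC10 (mode='relative') is the concentration where the fitted mean reaches
    10% of its span over the tested range; mode='absolute' uses a mean
    probability of ``frac`` directly. The CI is built on the log10
    concentration scale from the gradient of the inversion with respect to
    (b0, b1) and the fitted covariance, then exponentiated. Non-calculable
    when the dose effect is indistinguishable from zero (|Wald z| of b1 < 1).
    """
    if not fit.converged:
        return Ec10Result(None, None, None, False, "fit did not converge")
    b0, b1 = fit.mean_coef
    se_b1 = float(np.sqrt(fit.cov[1, 1]))
    if not np.isfinite(se_b1) or abs(b1) < se_b1:
        return Ec10Result(None, None, None, False, "no resolvable dose effect")
    if conc_range is not None:
        x_lo, x_hi = np.log10(conc_range[0]), np.log10(conc_range[1])
    else:
        x_lo, x_hi = fit.x_range

    x_star = _ec10_x(b0, b1, x_lo, x_hi, frac, mode)

    eps = 1e-6
    grad = np.zeros(2)
    for i, (db0, db1) in enumerate(((eps, 0.0), (0.0, eps))):
        up = _ec10_x(b0 + db0, b1 + db1, x_lo, x_hi, frac, mode)
        dn = _ec10_x(b0 - db0, b1 - db1, x_lo, x_hi, frac, mode)
        grad[i] = (up - dn) / (2 * eps)
    var = float(grad @ fit.cov[:2, :2] @ grad)
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return Ec10Result(
        ec10=float(10.0**x_star),
        ci_lower=float(10.0 ** (x_star - z * se)),
        ci_upper=float(10.0 ** (x_star + z * se)),
        calculable=True,
    )


def ec10_by_substance(
    tiles: pd.DataFrame,
    threshold: float = 0.5,
    level: float = 0.95,
    per_run: bool = True,
    frac: float = 0.10,
    mode: str = "relative",
) -> pd.DataFrame:
    """Screen, fit and invert EC10 for every substance (per run by default)."""
    screen = screen_altered(tiles, threshold=threshold).set_index("substance")
    keys = ["substance", "run"] if per_run and "run" in tiles.columns else ["substance"]
    rows = []
    for key, grp in tiles.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        sub = key[0]
        entry = dict(zip(keys, key))
        if not screen.loc[sub, "active"]:
            rows.append({**entry, "ec10": np.nan, "ci_lower": np.nan,
                         "ci_upper": np.nan, "calculable": False,
                         "reason": "no altered tiles"})
            continue
        try:
            fit = fit_beta(grp)
            res = ec10(fit, level=level, frac=frac, mode=mode)
        except (ValueError, np.linalg.LinAlgError) as exc:
            res = Ec10Result(None, None, None, False, str(exc))
        rows.append(
            {
                **entry,
                "ec10": res.ec10 if res.calculable else np.nan,
                "ci_lower": res.ci_lower if res.calculable else np.nan,
                "ci_upper": res.ci_upper if res.calculable else np.nan,
                "calculable": res.calculable,
                "reason": res.reason,
            }
        )
    return pd.DataFrame(rows)
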