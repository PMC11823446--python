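"""Benchmark-concentration engine: nine dose-response models, BMC and
profile-likelihood bounds, best-model selection and post-fit filters.

Responses are log2 expression values modeled with Gaussian errors of constant
variance. Each candidate mean function is fit by maximum likelihood
(equivalently least squares) with multi-start optimization; the benchmark
concentration (BMC) is the smallest positive dose at which the fitted mean
departs from its control value by a benchmark response of ``bmr_sd`` standard
deviations of the residual SD. Confidence bounds (BMCL/BMCU) come from the
profile likelihood: the extreme BMC values whose constrained maximum
log-likelihood stays within chi2_1(2*level - 1)/2 of the optimum (two
one-sided bounds at ``level``).

Mean functions (d = dose; internally rescaled by the top dose):

    hill    a + v * d^n / (k^n + d^n)          (n >= 1)
    power   a + b * d^p                        (p >= 1)
    linear  a + b*d;  poly2/poly3 add d^2, d^3 terms
    exp2    a * exp(b*d)
    exp3    a * exp(s*(b*d)^p)                 (s = +/-1, p >= 1)
    exp4    a * (c - (c-1)*exp(-b*d))
    exp5    a * (c - (c-1)*exp(-(b*d)^p))      (p >= 1)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

MODELS = (
    "hill",
    "power",
    "linear",
    "poly2",
    "poly3",
    "exp2",
    "exp3",
    "exp4",
    "exp5",
)

#: hill cooperativity and power/exponent restraints (common BMDS-style bounds
#: preventing supra-steep degenerate fits); configurable at fit time
HILL_N_BOUNDS = (1.0, 18.0)
EXPONENT_BOUNDS = (1.0, 8.0)

_BMC_SEARCH_FACTOR = 10.0  # BMC search bracketed at [0, 10 x top dose]
_PROFILE_DROP = 0.90  # two one-sided 95% bounds <=> chi2_1(0.90)/2 drop


# --- mean functions on the scaled dose axis u = d / dose_scale ---------------

def _f_hill(u, p):
    a, v, k, n = p
    un = np.power(np.maximum(u, 0.0), n)
    return a + v * un / (np.power(k, n) + un)


def _f_power(u, p):
    a, b, q = p
    return a + b * np.power(np.maximum(u, 0.0), q)


def _f_linear(u, p):
    return p[0] + p[1] * u


def _f_poly2(u, p):
    return p[0] + p[1] * u + p[2] * u**2


def _f_poly3(u, p):
    return p[0] + p[1] * u + p[2] * u**2 + p[3] * u**3


def _f_exp2(u, p):
    return p[0] * np.exp(np.clip(p[1] * u, -500, 500))


def _f_exp3(u, p):
    a, b, q, s = p
    return a * np.exp(np.clip(s * np.power(np.maximum(b * u, 0.0), q), -500, 500))


def _f_exp4(u, p):
    a, b, c = p
    return a * (c - (c - 1.0) * np.exp(-np.maximum(b * u, 0.0)))


def _f_exp5(u, p):
    a, b, c, q = p
    return a * (c - (c - 1.0) * np.exp(-np.power(np.maximum(b * u, 0.0), q)))


_INF = np.inf
_MODEL_DEFS: dict[str, dict] = {
    "hill": dict(
        f=_f_hill,
        bounds=([-_INF, -_INF, 1e-4, HILL_N_BOUNDS[0]], [_INF, _INF, 1e2, HILL_N_BOUNDS[1]]),
    ),
    "power": dict(
        f=_f_power,
        bounds=([-_INF, -_INF, EXPONENT_BOUNDS[0]], [_INF, _INF, EXPONENT_BOUNDS[1]]),
    ),
    "linear": dict(f=_f_linear, bounds=([-_INF, -_INF], [_INF, _INF])),
    "poly2": dict(f=_f_poly2, bounds=([-_INF] * 3, [_INF] * 3)),
    "poly3": dict(f=_f_poly3, bounds=([-_INF] * 4, [_INF] * 4)),
    "exp2": dict(f=_f_exp2, bounds=([-_INF, -_INF], [_INF, _INF])),
    "exp3": dict(
        f=_f_exp3,
        bounds=([-_INF, 1e-6, EXPONENT_BOUNDS[0]], [_INF, 1e3, EXPONENT_BOUNDS[1]]),
        fixed_sign=True,
    ),
    "exp4": dict(f=_f_exp4, bounds=([-_INF, 1e-6, 1e-6], [_INF, 1e3, 1e3])),
    "exp5": dict(
        f=_f_exp5,
        bounds=(
            [-_INF, 1e-6, 1e-6, EXPONENT_BOUNDS[0]],
            [_INF, 1e3, 1e3, EXPONENT_BOUNDS[1]],
        ),
    ),
}


@dataclass
class ModelFit:
    """One model's maximum-likelihood fit to a probe's dose-response data."""

    model: str
    params: np.ndarray
    dose_scale: float
    sigma2: float
    loglik: float
    aic: float
    fit_p_value: float
    converged: bool
    n_obs: int
    doses: np.ndarray = field(repr=False)
    responses: np.ndarray = field(repr=False)

    @property
    def n_mean_params(self) -> int:
        extra = 1 if _MODEL_DEFS[self.model].get("fixed_sign") else 0
        return len(self.params) - extra

    def predict(self, d: np.ndarray | float) -> np.ndarray | float:
        u = np.asarray(d, dtype=float) / self.dose_scale
        return _MODEL_DEFS[self.model]["f"](u, self.params)


@dataclass(frozen=True)
class ProbeFitResult:
    """Best-model summary for one probe-substance-run combination."""

    probe_id: str
    substance: str
    run: str
    model: str
    bmc: float
    bmcl: float
    bmcu: float
    fit_p_value: float
    max_fold_change: float
    direction: str
    flag: str = ""


def _saturated_sse(doses: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    sse, k = 0.0, 0
    for d in np.unique(doses):
        grp = y[doses == d]
        sse += float(((grp - grp.mean()) ** 2).sum())
        k += 1
    return sse, k


def _starts(model: str, u: np.ndarray, y: np.ndarray, rng) -> list[np.ndarray]:
    y0 = float(y[u == u.min()].mean())
    ytop = float(y[u == u.max()].mean())
    dy = ytop - y0
    span = max(abs(dy), 0.1)
    base: list[list[float]]
    if model == "hill":
        base = [[y0, dy if dy else span, k0, n0] for k0 in (0.05, 0.3) for n0 in (1.5, 4.0)]
    elif model == "power":
        base = [[y0, dy if dy else span, q] for q in (1.0, 2.0, 4.0)]
    elif model == "linear":
        base = [[y0, dy]]
    elif model == "poly2":
        base = [[y0, dy, 0.0], [y0, 0.0, dy]]
    elif model == "poly3":
        base = [[y0, dy, 0.0, 0.0], [y0, 0.0, 0.0, dy]]
    elif model == "exp2":
        a0 = y0 if abs(y0) > 1e-3 else (0.1 if dy >= 0 else -0.1)
        b0 = np.log(max(ytop, 1e-3) / max(y0, 1e-3)) if y0 > 0 and ytop > 0 else dy
        base = [[a0, b0], [a0, -b0 if b0 else 0.5]]
    elif model == "exp3":
        a0 = y0 if abs(y0) > 1e-3 else 0.1
        base = [[a0, b, q] for b in (1.0, 5.0) for q in (1.0, 2.0)]
    elif model == "exp4":
        a0 = y0 if abs(y0) > 1e-3 else 0.1
        c0 = max(ytop / a0, 1e-3) if a0 else 1.0
        base = [[a0, 2.0, c0], [a0, 10.0, c0]]
    else:  # exp5
        a0 = y0 if abs(y0) > 1e-3 else 0.1
        c0 = max(ytop / a0, 1e-3) if a0 else 1.0
        base = [[a0, 2.0, c0, 1.5], [a0, 10.0, c0, 3.0]]
    starts = [np.asarray(b, dtype=float) for b in base]
    jitter = [s * (1 + 0.3 * rng.standard_normal(s.size)) for s in starts[:2]]
    return starts + jitter


def fit_model(
    model: str,
    doses: np.ndarray,
    responses: np.ndarray,
    n_starts_extra: int = 2,
) -> ModelFit:
    """Maximum-likelihood fit of one mean model under constant variance.

    Least-squares (= Gaussian MLE) with bounded multi-start optimization;
    ``fit_p_value`` is a likelihood-ratio lack-of-fit test against the
    saturated dose-group-means model.
    """
    if model not in _MODEL_DEFS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    doses = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    if len(np.unique(doses)) < 4:
        raise ValueError("need at least 4 distinct dose levels")
    scale = doses.max()
    u = doses / scale
    mdef = _MODEL_DEFS[model]
    f = mdef["f"]
    lo, hi = (np.asarray(b, dtype=float) for b in mdef["bounds"])
    rng = np.random.default_rng(0)

    signs = (1.0, -1.0) if mdef.get("fixed_sign") else (None,)
    best = None
    for sign in signs:
        def resid(p):
            pp = np.append(p, sign) if sign is not None else p
            return f(u, pp) - y

        for x0 in _starts(model, u, y, rng):
            x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)
            try:
                sol = optimize.least_squares(
                    resid, x0, bounds=(lo, hi), method="trf", max_nfev=2000
                )
            except Exception:
                continue
            if not np.all(np.isfinite(sol.x)):
                continue
            sse = float(2 * sol.cost)
            if best is None or sse < best[0]:
                p = np.append(sol.x, sign) if sign is not None else sol.x
                best = (sse, p, bool(sol.success))
    n = len(y)
    if best is None:
        return ModelFit(model, np.full(len(lo), np.nan), scale, np.nan, -np.inf,
                        np.inf, np.nan, False, n, doses, y)
    sse, params, success = best
    sigma2 = max(sse / n, 1e-300)
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    k_mean = len(lo)
    aic = 2 * (k_mean + 1) - 2 * loglik
    sse_sat, n_groups = _saturated_sse(doses, y)
    df = n_groups - k_mean
    if df > 0 and sse_sat > 0:
        lr = n * np.log(sse / sse_sat)
        fit_p = float(stats.chi2.sf(max(lr, 0.0), df))
    else:
        fit_p = np.nan
    return ModelFit(model, params, scale, sigma2, loglik, aic, fit_p,
                    success, n, doses, y)


def compute_bmc(
    fit: ModelFit, bmr_sd: float = 1.0, search_factor: float = _BMC_SEARCH_FACTOR
) -> float | None:
    """Smallest positive dose where |f(d) - f(0)| reaches bmr_sd * sigma-hat.

    Root located by a geometric scan over [~0, search_factor x top dose]
    followed by Brent refinement to ~1e-12 relative tolerance. Returns None
    when the fitted curve never departs from control by the benchmark
    response within range.
    """
    if not fit.converged:
        return None
    target = bmr_sd * float(np.sqrt(fit.sigma2))
    if target <= 0:
        return None
    f0 = float(fit.predict(0.0))

    def g(d: float) -> float:
        return abs(float(fit.predict(d)) - f0) - target

    top = fit.doses.max() * search_factor
    grid = np.geomspace(top * 1e-10, top, 600)
    vals = np.array([g(d) for d in grid])
    if vals[0] >= 0:
        lo_d, hi_d = top * 1e-14, grid[0]
    else:
        idx = np.flatnonzero((vals[:-1] < 0) & (vals[1:] >= 0))
        if idx.size == 0:
            return None
        lo_d, hi_d = grid[idx[0]], grid[idx[0] + 1]
    try:
        bmc = optimize.brentq(g, lo_d, hi_d, xtol=1e-300, rtol=1e-13, maxiter=200)
    except ValueError:
        return None
    return float(bmc)


def bmc_direction(fit: ModelFit, bmc: float) -> str:
    return "up" if float(fit.predict(bmc)) >= float(fit.predict(0.0)) else "down"


def _profile_loglik(fit: ModelFit, c: float, bmr_sd: float) -> float:
    """Constrained max log-likelihood given the BMC pinned at c.

    With Gaussian constant-variance errors the BMC constraint determines the
    residual SD from the mean parameters: sigma = |f(c) - f(0)| / bmr_sd, so
    the profile reduces to an unconstrained search over mean parameters.
    """
    mdef = _MODEL_DEFS[fit.model]
    f = mdef["f"]
    lo, hi = (np.asarray(b, dtype=float) for b in mdef["bounds"])
    u = fit.doses / fit.dose_scale
    uc = c / fit.dose_scale
    y = fit.responses
    n = fit.n_obs
    sign = fit.params[-1] if mdef.get("fixed_sign") else None
    k = len(lo)

    def nll(p):
        pp = np.append(p, sign) if sign is not None else p
        delta = abs(float(f(np.asarray([uc]), pp)[0]) - float(f(np.asarray([0.0]), pp)[0]))
        sigma = delta / bmr_sd
        if not np.isfinite(sigma) or sigma <= 1e-12:
            return 1e12
        sse = float(((f(u, pp) - y) ** 2).sum())
        return 0.5 * n * np.log(2 * np.pi * sigma**2) + sse / (2 * sigma**2)

    x0 = fit.params[:k].copy()
    res = optimize.minimize(
        nll, np.clip(x0, lo + 1e-12, hi - 1e-12),
        method="L-BFGS-B",
        bounds=list(zip(lo, hi)),
        options={"maxiter": 200},
    )
    return -float(res.fun)


def profile_ci(
    fit: ModelFit,
    bmc: float,
    level: float = 0.95,
    bmr_sd: float = 1.0,
    search_factor: float = _BMC_SEARCH_FACTOR,
) -> tuple[float, float, str]:
    """Profile-likelihood BMC bounds (two one-sided bounds at ``level``).

    Scans multiplicatively away from the BMC until the profile log-likelihood
    drops by chi2_1(2*level - 1)/2, then bisects. Returns (bmcl, bmcu, flag);
    a bound that never crosses within the search range is reported at the
    range endpoint with a flag.
    """
    drop = stats.chi2.ppf(2 * level - 1, 1) / 2.0
    ll_target = fit.loglik - drop
    flags = []

    def crossing(c_from: float, factor: float, c_limit: float) -> float | None:
        prev_c = c_from
        c = c_from * factor
        for _ in range(80):
            out_of_range = c < c_limit if factor < 1 else c > c_limit
            if out_of_range:
                c = c_limit
            h = _profile_loglik(fit, c, bmr_sd) - ll_target
            if h < 0:
                lo_c, hi_c = (c, prev_c) if factor < 1 else (prev_c, c)
                for _ in range(40):
                    mid = np.sqrt(lo_c * hi_c)
                    hm = _profile_loglik(fit, mid, bmr_sd) - ll_target
                    if factor < 1:
                        if hm < 0:
                            lo_c = mid
                        else:
                            hi_c = mid
                    else:
                        if hm < 0:
                            hi_c = mid
                        else:
                            lo_c = mid
                    if hi_c / lo_c < 1.0 + 1e-6:
                        break
                return float(np.sqrt(lo_c * hi_c))
            if out_of_range:
                return None
            prev_c = c
            c *= factor
        return None

    top = fit.doses.max() * search_factor
    bmcl = crossing(bmc, 1 / 1.5, bmc * 1e-6)
    if bmcl is None:
        bmcl = bmc * 1e-6
        flags.append("bmcl_at_search_bound")
    bmcu = crossing(bmc, 1.5, top)
    if bmcu is None:
        bmcu = top
        flags.append("bmcu_at_search_bound")
    bmcl = min(bmcl, bmc)
    bmcu = max(bmcu, bmc)
    return bmcl, bmcu, ";".join(flags)


def select_best(
    fits: list[ModelFit], bmr_sd: float = 1.0
) -> tuple[ModelFit, float]:
    """Lowest-AIC converged fit with a defined BMC.

    Ties (identical AIC) go to the model with fewer parameters, then to the
    fixed model-name order.
    """
    eligible = []
    for fit in fits:
        if not fit.converged:
            continue
        bmc = compute_bmc(fit, bmr_sd=bmr_sd)
        if bmc is None:
            continue
        eligible.append((fit.aic, fit.n_mean_params, MODELS.index(fit.model), fit, bmc))
    if not eligible:
        raise ValueError("no converged fit with a defined BMC")
    eligible.sort(key=lambda t: (t[0], t[1], t[2]))
    _, _, _, fit, bmc = eligible[0]
    return fit, bmc


def max_fold_change(doses: np.ndarray, responses: np.ndarray) -> tuple[float, str]:
    """Max linear-scale fold-change of any dose group vs control (log2 data)."""
    doses = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    m0 = y[doses == doses.min()].mean()
    best, direction = 0.0, "up"
    for d in np.unique(doses[doses > doses.min()]):
        delta = y[doses == d].mean() - m0
        if abs(delta) > abs(best):
            best = delta
            direction = "up" if delta >= 0 else "down"
    return float(np.exp2(abs(best))), direction


def fit_probe(
    probe_id: str,
    doses: np.ndarray,
    responses: np.ndarray,
    substance: str = "",
    run: str = "",
    models: tuple[str, ...] = MODELS,
    bmr_sd: float = 1.0,
    confidence: float = 0.95,
    with_ci: bool = True,
) -> ProbeFitResult | None:
    """Fit all candidate models for one probe and summarize the best.

    Returns None when no model converges with a defined BMC.
    """
    fits = [fit_model(m, doses, responses) for m in models]
    try:
        best, bmc = select_best(fits, bmr_sd=bmr_sd)
    except ValueError:
        return None
    if with_ci:
        bmcl, bmcu, flag = profile_ci(best, bmc, level=confidence, bmr_sd=bmr_sd)
    else:
        bmcl, bmcu, flag = np.nan, np.nan, "ci_skipped"
    fc, _ = max_fold_change(doses, responses)
    return ProbeFitResult(
        probe_id=probe_id,
        substance=substance,
        run=run,
        model=best.model,
        bmc=bmc,
        bmcl=bmcl,
        bmcu=bmcu,
        fit_p_value=best.fit_p_value,
        max_fold_change=fc,
        direction=bmc_direction(best, bmc),
        flag=flag,
    )


def results_frame(results: list[ProbeFitResult]) -> pd.DataFrame:
    cols = [
        "probe_id", "substance", "run", "model", "bmc", "bmcl", "bmcu",
        "fit_p_value", "max_fold_change", "direction", "flag",
    ]
    return pd.DataFrame([vars(r) for r in results], columns=cols)


def apply_bmdexpress_filters(
    results: pd.DataFrame, lowest_positive_dose: float
) -> pd.DataFrame:
    """Remove implausible or extrapolated fits with tagged reasons.

    Removes rows with fit_p_value < 0.001, BMCU/BMCL > 40, BMC more than
    10-fold below the lowest positive dose, or max fold-change < 2 (strict
    inequalities; boundary values are retained). Adds ``filter_reason``
    (empty for survivors); returns only survivors, with removals available
    via the ``attrs['removed']`` frame.
    """
    required = {"fit_p_value", "bmcl", "bmcu", "bmc", "max_fold_change"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table is missing fields: {sorted(missing)}")
    res = results.copy()
    reasons = []
    ratio = res["bmcu"] / res["bmcl"]
    checks = {
        "fit_p_below_0.001": res["fit_p_value"] < 0.001,
        "bmcu_bmcl_ratio_above_40": ratio > 40.0,
        "bmc_below_tenth_lowest_dose": res["bmc"] < lowest_positive_dose / 10.0,
        "fold_change_below_2": res["max_fold_change"] < 2.0,
    }
    reason_col = pd.Series([""] * len(res), index=res.index)
    for name, mask in checks.items():
        mask = mask.fillna(False)
        reason_col = reason_col.where(~mask, reason_col + name + ";")
    res["filter_reason"] = reason_col.str.rstrip(";")
    survivors = res[res["filter_reason"] == ""].copy()
    survivors.attrs["removed"] = res[res["filter_reason"] != ""].copy()
    return survivors


def clustering_filter(results: pd.DataFrame, top_dose: float) -> pd.DataFrame:
    """Filters ahead of signature clustering: in-range BMC, tight bounds.

    Removes BMCs greater than the highest tested dose and fits with
    BMCU/BMCL > 20 (boundary values retained).
    """
    res = results.copy()
    ratio = res["bmcu"] / res["bmcl"]
    keep = (res["bmc"] <= top_dose) & ~(ratio > 20.0).fillna(False)
    survivors = res[keep].copy()
    survivors.attrs["removed"] = res[~keep].copy()
    return survivors


def run_bmd(
    expr,
    prefilter_table: pd.DataFrame,
    models: tuple[str, ...] = MODELS,
    bmr_sd: float = 1.0,
    confidence: float = 0.95,
    with_ci: bool = True,
) -> pd.DataFrame:
    """Fit every prefilter-passing probe per (substance, run)."""
    results: list[ProbeFitResult] = []
    passing = prefilter_table[prefilter_table["passes"]]
    meta = expr.sample_meta
    for (sub, run), grp in passing.groupby(["substance", "run"], sort=True):
        sel = meta[(meta["substance"] == sub) & (meta["run"] == run)]
        doses = sel["concentration"].to_numpy()
        for probe in grp["probe_id"]:
            y = expr.values.loc[probe, sel.index].to_numpy()
            r = fit_probe(
                probe, doses, y, substance=sub, run=run, models=models,
                bmr_sd=bmr_sd, confidence=confidence, with_ci=with_ci,
            )
            if r is not None:
                results.append(r)
    return results_frame(results)
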