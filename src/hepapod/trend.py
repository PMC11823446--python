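"""Trend-test prefilters for dose-responsive probes.

Mode A is a Williams-type trend test: dose-group means are isotonized
(pool-adjacent-violators) and the amalgamated mean of the top dose is compared
with the control mean on a pooled-SE scale, maximized over the two monotone
directions; significance comes from a seeded permutation of sample labels.
Probes pass with p < alpha and a maximal fold-change over control of at least
the threshold (default 2-fold).

Mode B is a curve-fit prefilter used ahead of signature clustering: a probe
passes when some dose group differs from control by a constant-variance
t-test (p < alpha), the fold-change at the lowest such dose (the LOTEL)
exceeds the threshold, and a fitted curve crosses a 3-SD benchmark response
within the tested concentration range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .qc import ExprMatrix

MIN_PERMUTATIONS = 100


@dataclass(frozen=True)
class TrendResult:
    probe_id: str
    statistic: float
    p_value: float
    max_abs_fold_change: float
    direction: str
    passes: bool


def pava(
    means: np.ndarray,
    weights: np.ndarray | None = None,
    direction: str = "up",
) -> np.ndarray:
    """Weighted least-squares monotone fit by pool-adjacent-violators.

    Returns the isotone (direction='up') or antitone ('down') vector closest
    to ``means`` in weighted squared error; block merging preserves the
    weighted mean.
    """
    y = np.asarray(means, dtype=float)
    if y.size == 0:
        raise ValueError("pava needs at least one group mean")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if direction == "down":
        return -pava(-y, w, "up")
    if direction != "up":
        raise ValueError("direction must be 'up' or 'down'")
    # stack of (value, weight, block length)
    vals: list[float] = []
    wts: list[float] = []
    lens: list[int] = []
    for yi, wi in zip(y, w):
        vals.append(float(yi))
        wts.append(float(wi))
        lens.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v = (vals[-2] * wts[-2] + vals[-1] * wts[-1]) / (wts[-2] + wts[-1])
            wts[-2] += wts[-1]
            lens[-2] += lens[-1]
            vals[-2] = v
            vals.pop(), wts.pop(), lens.pop()
    return np.repeat(vals, lens)


def _group_layout(doses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted unique dose levels (control first) and sample->group index."""
    levels = np.unique(doses)
    if levels[0] != 0:
        raise ValueError("a control group (dose 0) is required")
    gidx = np.searchsorted(levels, doses)
    return levels, gidx


def _batch_stats(
    Y: np.ndarray, A: np.ndarray, sizes: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Group means, pooled within-group SD and both-direction trend stats.

    ``Y`` is probes x samples; ``A`` the samples x groups indicator (group 0 =
    control). The isotonized top-dose mean uses the minimax identity: the
    isotone fit at the last group equals the max (antitone: min) over j of the
    weighted mean of groups j..k.
    """
    n = Y.shape[1]
    k = A.shape[1]
    sums = Y @ A
    means = sums / sizes[None, :]
    ss = (Y * Y) @ A - sums * means  # within-group sum of squares
    df = n - k
    sp = np.sqrt(np.maximum(ss.sum(axis=1), 0.0) / max(df, 1))
    # suffix weighted means over dose groups 1..k-1
    dm = means[:, 1:]
    w = sizes[1:]
    cw = np.cumsum(w[::-1])[::-1]
    cs = np.cumsum((dm * w[None, :])[:, ::-1], axis=1)[:, ::-1]
    suffix = cs / cw[None, :]
    se = sp * np.sqrt(1.0 / sizes[-1] + 1.0 / sizes[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        t_up = (suffix.max(axis=1) - means[:, 0]) / se
        t_dn = (means[:, 0] - suffix.min(axis=1)) / se
    return means, sp, np.stack([t_up, t_dn], axis=1)


def williams_batch(
    Y: np.ndarray,
    doses: np.ndarray,
    n_perm: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Williams trend test for many probes sharing one dose layout.

    Returns per-probe statistic (max over directions), permutation p-value,
    linear-scale max fold-change over control and the better direction.
    Permutations of sample labels are shared across probes.
    """
    if n_perm < MIN_PERMUTATIONS:
        raise ValueError(f"n_perm must be >= {MIN_PERMUTATIONS} for a stable p-value")
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    doses = np.asarray(doses, dtype=float)
    levels, gidx = _group_layout(doses)
    if len(levels) < 3:
        raise ValueError("need a control plus at least 2 dose groups")
    sizes = np.bincount(gidx, minlength=len(levels)).astype(float)
    if (sizes < 2).any():
        raise ValueError("every dose group needs at least 2 samples")
    A = np.zeros((len(doses), len(levels)))
    A[np.arange(len(doses)), gidx] = 1.0

    means, _, t_obs_dir = _batch_stats(Y, A, sizes)
    t_obs = np.nanmax(t_obs_dir, axis=1)
    direction = np.where(t_obs_dir[:, 0] >= t_obs_dir[:, 1], "up", "down")

    delta = np.abs(means[:, 1:] - means[:, [0]])
    max_fc = np.exp2(delta.max(axis=1))

    rng = np.random.default_rng(seed)
    exceed = np.zeros(Y.shape[0])
    n = Y.shape[1]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, _, t_perm = _batch_stats(Y[:, perm], A, sizes)
        exceed += np.nanmax(t_perm, axis=1) >= t_obs
    p = (1.0 + exceed) / (n_perm + 1.0)
    return pd.DataFrame(
        {
            "statistic": t_obs,
            "p_value": p,
            "max_abs_fold_change": max_fc,
            "direction": direction,
        }
    )


def williams_test(
    doses: np.ndarray,
    values: np.ndarray,
    n_perm: int = 2000,
    seed: int = 0,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    probe_id: str = "probe",
) -> TrendResult:
    """Williams trend test for one probe profile (see ``williams_batch``)."""
    res = williams_batch(np.asarray(values)[None, :], doses, n_perm, seed).iloc[0]
    return TrendResult(
        probe_id=probe_id,
        statistic=float(res["statistic"]),
        p_value=float(res["p_value"]),
        max_abs_fold_change=float(res["max_abs_fold_change"]),
        direction=str(res["direction"]),
        passes=bool(
            res["max_abs_fold_change"] >= fc_threshold and res["p_value"] < alpha
        ),
    )


def prefilter_mode_a(
    expr: ExprMatrix,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    n_perm: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Williams-trend prefilter per probe per (substance, run).

    Returns the full per-probe trend table with a ``passes`` column applying
    the fold-change and alpha thresholds.
    """
    frames = []
    for (sub, run), grp in expr.sample_meta.groupby(["substance", "run"], sort=True):
        cols = list(grp.index)
        doses = grp["concentration"].to_numpy()
        Y = expr.values[cols].to_numpy()
        res = williams_batch(Y, doses, n_perm=n_perm, seed=seed)
        res.insert(0, "probe_id", expr.values.index)
        res.insert(1, "substance", sub)
        res.insert(2, "run", run)
        frames.append(res)
    if not frames:
        return pd.DataFrame(
            columns=[
                "probe_id", "substance", "run", "statistic", "p_value",
                "max_abs_fold_change", "direction", "passes",
            ]
        )
    out = pd.concat(frames, ignore_index=True)
    out["passes"] = (out["max_abs_fold_change"] >= fc_threshold) & (
        out["p_value"] < alpha
    )
    return out


def _lotel(
    Y: np.ndarray, A: np.ndarray, sizes: np.ndarray, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """Lowest dose-group index with a significant pooled t-test, and its FC.

    Returns (lotel_group, fc_at_lotel); lotel_group is -1 when no dose group
    differs from control at alpha.
    """
    n, k = A.shape
    means, sp, _ = _batch_stats(Y, A, sizes)
    df = n - k
    se = sp[:, None] * np.sqrt(1.0 / sizes[None, 1:] + 1.0 / sizes[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (means[:, 1:] - means[:, [0]]) / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    sig = p < alpha
    lotel = np.where(sig.any(axis=1), sig.argmax(axis=1), -1)
    fc = np.exp2(np.abs(means[:, 1:] - means[:, [0]]))
    fc_at = np.where(lotel >= 0, fc[np.arange(len(lotel)), np.maximum(lotel, 0)], np.nan)
    return lotel, fc_at


def prefilter_mode_b(
    expr: ExprMatrix,
    bmr_factor: float = 3.0,
    notel_lotel_min_fc: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Curve-fit prefilter: t-test LOTEL, fold-change and a 3-SD crossing.

    A probe passes for a (substance, run) when (i) some dose group differs
    from control (pooled t-test, p < alpha), (ii) the fold-change at the
    lowest such dose exceeds ``notel_lotel_min_fc``, and (iii) the better of a
    linear and a Hill fit crosses ``bmr_factor`` SDs within the tested range.
    """
    from . import bmd  # deferred: bmd is a heavier module

    rows = []
    for (sub, run), grp in expr.sample_meta.groupby(["substance", "run"], sort=True):
        cols = list(grp.index)
        doses = grp["concentration"].to_numpy()
        top = doses.max()
        levels, gidx = _group_layout(doses)
        sizes = np.bincount(gidx, minlength=len(levels)).astype(float)
        A = np.zeros((len(doses), len(levels)))
        A[np.arange(len(doses)), gidx] = 1.0
        Y = expr.values[cols].to_numpy()
        lotel, fc_at = _lotel(Y, A, sizes, alpha)
        for i, probe in enumerate(expr.values.index):
            ok = lotel[i] >= 0 and fc_at[i] >= notel_lotel_min_fc
            if ok:
                ok = False
                for model in ("linear", "hill"):
                    fit = bmd.fit_model(model, doses, Y[i])
                    if not fit.converged:
                        continue
                    bmc = bmd.compute_bmc(fit, bmr_sd=bmr_factor)
                    if bmc is not None and bmc <= top:
                        ok = True
                        break
            rows.append(
                {
                    "probe_id": probe,
                    "substance": sub,
                    "run": run,
                    "lotel_group": int(lotel[i]),
                    "fc_at_lotel": float(fc_at[i]) if lotel[i] >= 0 else np.nan,
                    "passes": bool(ok),
                }
            )
    return pd.DataFrame(rows)
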