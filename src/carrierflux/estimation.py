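"""Least-squares estimation of carrier parameters from uptake datasets.

Two experimental designs are supported:

* **initial-rate**: zero-trans uptake rates measured at one early time point
  over a range of total external concentrations.  The saturation curve
  ``rate = Vapp·A0 / (Tot0 + Kapp)`` is fitted to per-condition mean rates
  by unweighted least squares, giving the apparent Michaelis-Menten pair.

* **time-course**: internal tracer measured on a time grid for several
  external unlabelled concentrations.  A single (h, V) — with K either fixed
  or re-derived from a fixed Kapp at every candidate — is fitted jointly to
  all conditions by minimising the relative normalized squared error

      sum_points ((model - mean) / mean)**2,

  which puts conditions with very different absolute uptake on a common
  footing.  Points with zero experimental mean (notably t = 0, where uptake
  is identically zero) are excluded, since the normalization is undefined
  there.

Both fits use multi-start Nelder-Mead simplex minimisation in
log-parameter space (positivity by construction), with starts drawn from a
seeded Latin hypercube over fixed bounds; the best of the restarts is
returned.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .carrier_model import (
    ApparentMM,
    CompartmentState,
    InversionContext,
    ObligatoryExchangeError,
    TransporterParams,
    invert_apparent,
)
from .simulation import simulate_timecourse

__all__ = [
    "UptakeDataset",
    "TimeCourseDataset",
    "FitResult",
    "FitConvergenceError",
    "fit_michaelis_menten",
    "fit_timecourse",
    "timecourse_objective",
    "profile_objective",
]

#: default optimisation bounds (log-uniform start draws)
V_BOUNDS = (1.0, 1e4)     # µmol l⁻¹ min⁻¹
H_BOUNDS = (1e-3, 10.0)   # dimensionless
N_STARTS = 8

_INITIAL_RATE_COLUMNS = ["A_out0", "B_out0", "rate", "replicate"]
_TIMECOURSE_COLUMNS = ["B_out0", "time_s", "A_in_mean", "A_in_sd", "n"]


class FitConvergenceError(RuntimeError):
    """No restart converged; carries the best candidate seen."""

    def __init__(self, message: str, best: Optional["FitResult"] = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class UptakeDataset:
    """Initial-rate design: replicate uptake rates per external condition.

    ``data`` columns: A_out0 (tracer, µmol l⁻¹), B_out0 (unlabelled,
    µmol l⁻¹), rate (µmol l⁻¹ min⁻¹), replicate (id).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _INITIAL_RATE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"UptakeDataset missing columns: {missing}")
        d = self.data
        if not np.isfinite(d["rate"]).all():
            raise ValueError("rates must be finite")
        if (d[["A_out0", "B_out0"]] < 0).any().any():
            raise ValueError("concentrations must be >= 0")

    def condition_summary(self) -> pd.DataFrame:
        """Mean, SD and replicate count per (A_out0, B_out0) condition."""
        g = self.data.groupby(["A_out0", "B_out0"], as_index=False)["rate"]
        out = g.agg(rate_mean="mean", rate_sd="std", n="count")
        out["rate_sd"] = out["rate_sd"].fillna(0.0)
        return out.sort_values(["A_out0", "B_out0"], ignore_index=True)


@dataclass(frozen=True)
class TimeCourseDataset:
    """Time-course design: per-condition mean ± SD internal tracer series.

    ``A_out0`` is the fixed external tracer concentration shared by all
    conditions; ``data`` columns: B_out0 (external unlabelled, µmol l⁻¹),
    time_s, A_in_mean, A_in_sd (µmol l⁻¹), n (replicates).
    """

    A_out0: float
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.A_out0 < 0:
            raise ValueError("A_out0 must be >= 0")
        missing = [c for c in _TIMECOURSE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"TimeCourseDataset missing columns: {missing}")
        if (self.data["time_s"] < 0).any():
            raise ValueError("times must be >= 0")
        for b, grp in self.data.groupby("B_out0"):
            if grp["time_s"].duplicated().any():
                raise ValueError(f"duplicate time points in condition B_out0={b}")

    @property
    def b_out_levels(self) -> np.ndarray:
        return np.sort(self.data["B_out0"].unique())

    def condition(self, B_out0: float) -> pd.DataFrame:
        sel = self.data[self.data["B_out0"] == B_out0]
        if sel.empty:
            raise KeyError(f"no condition with B_out0={B_out0}")
        return sel.sort_values("time_s")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a least-squares fit.

    ``params`` holds the estimated (and derived) parameters; ``fixed``
    records the assumptions the fit was conditioned on; ``objective`` is the
    minimised criterion (SSE for the initial-rate fit, relative normalized
    SSE for time courses).
    """

    params: dict
    fixed: dict
    objective: float
    n_restarts: int
    n_obs: int
    success: bool
    message: str = ""
    flags: tuple = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "params": dict(self.params),
            "fixed": dict(self.fixed),
            "objective": self.objective,
            "n_restarts": self.n_restarts,
            "n_obs": self.n_obs,
            "success": self.success,
            "message": self.message,
            "flags": list(self.flags),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# initial-rate (Michaelis-Menten) fit
# ---------------------------------------------------------------------------

def _mm_rate(A0, tot0, Vapp, Kapp):
    return Vapp * A0 / (tot0 + Kapp)


def _lhs_starts(bounds_log: np.ndarray, n_starts: int, seed: int) -> np.ndarray:
    sampler = qmc.LatinHypercube(d=bounds_log.shape[0], seed=seed)
    u = sampler.random(n=n_starts)
    return bounds_log[:, 0] + u * (bounds_log[:, 1] - bounds_log[:, 0])


def _multistart_nm(objective, bounds_log: np.ndarray, n_starts: int,
                   seed: int, maxiter: int = 2000):
    """Best-of-restarts Nelder-Mead over log-parameters."""
    starts = _lhs_starts(bounds_log, n_starts, seed)
    best = None
    n_ok = 0
    for x0 in starts:
        with np.errstate(invalid="ignore", over="ignore"):
            res = minimize(objective, x0, method="Nelder-Mead",
                           options={"maxiter": maxiter, "xatol": 1e-7,
                                    "fatol": 1e-12})
        if math.isfinite(res.fun):
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
    return best, n_ok


def fit_michaelis_menten(data: UptakeDataset, n_starts: int = N_STARTS,
                         seed: int = 0, aggregate: bool = True) -> FitResult:
    """Fit the apparent Michaelis-Menten pair to initial-rate data.

    By default the fit targets per-condition mean rates (unweighted SSE);
    with ``aggregate=False`` individual replicate rates are used instead.
    Emits a warning if the design does not straddle the fitted Kapp (the
    half-saturation point is then extrapolated, not interpolated).
    """
    if aggregate:
        summary = data.condition_summary()
        A0 = summary["A_out0"].to_numpy(float)
        B0 = summary["B_out0"].to_numpy(float)
        y = summary["rate_mean"].to_numpy(float)
    else:
        A0 = data.data["A_out0"].to_numpy(float)
        B0 = data.data["B_out0"].to_numpy(float)
        y = data.data["rate"].to_numpy(float)
    tot0 = A0 + B0
    if np.unique(tot0).size < 2:
        raise ValueError("need >= 2 distinct total external concentrations")

    if np.all(y == 0):
        return FitResult(
            params={"Vapp": 0.0, "Kapp": float("nan")},
            fixed={}, objective=0.0, n_restarts=0, n_obs=int(y.size),
            success=True, message="all rates zero",
            flags=("kapp_unidentifiable",),
        )

    r_scale = max(float(np.max(np.abs(y))), 1e-12)
    c_pos = tot0[tot0 > 0]
    c_lo = float(np.min(c_pos)) if c_pos.size else 1.0
    c_hi = float(np.max(tot0)) if np.max(tot0) > 0 else 1.0
    bounds_log = np.log(np.array([
        [r_scale * 1e-2, r_scale * 1e3],   # Vapp
        [c_lo * 1e-2, c_hi * 1e2],         # Kapp
    ]))

    def objective(theta):
        Vapp, Kapp = np.exp(theta)
        resid = _mm_rate(A0, tot0, Vapp, Kapp) - y
        return float(resid @ resid)

    best, n_ok = _multistart_nm(objective, bounds_log, n_starts, seed)
    if best is None:
        raise FitConvergenceError(
            f"Michaelis-Menten fit failed in all {n_starts} restarts")
    Vapp, Kapp = np.exp(best.x)
    flags = []
    if not (tot0.min() < Kapp < tot0.max()):
        warnings.warn(
            "design concentrations do not straddle the fitted Kapp "
            f"({Kapp:.3g} µmol/l); the half-saturation point is extrapolated",
            stacklevel=2)
        flags.append("kapp_extrapolated")
    return FitResult(
        params={"Vapp": float(Vapp), "Kapp": float(Kapp)},
        fixed={}, objective=float(best.fun), n_restarts=n_starts,
        n_obs=int(y.size), success=bool(n_ok > 0),
        message=best.message, flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# time-course fit
# ---------------------------------------------------------------------------

def _resolve_K(h: float, fixed: Mapping) -> float:
    """K for a candidate h: fixed directly, or re-derived from a fixed Kapp."""
    if "K" in fixed:
        return float(fixed["K"])
    apparent = ApparentMM(Vapp=1.0, Kapp=float(fixed["Kapp"]))
    ctx = InversionContext(h=h, B_in0=float(fixed["B_in0"]))
    return invert_apparent(apparent, ctx).K


def _stacked_rhs(t, y, A_out, B_out, V, K, h):
    # all conditions integrated as one system: y = [A_1, B_1, A_2, B_2, ...]
    a = y[0::2]
    b = y[1::2]
    tot_o = A_out + B_out
    tot_i = a + b
    den = 2.0 * tot_o * tot_i + K * (h + 1.0) * (tot_o + tot_i) \
        + 2.0 * h * K * K
    kh = K * h
    out = np.empty_like(y)
    out[0::2] = 2.0 * V * (A_out * (b + kh) - a * (B_out + kh)) / den
    out[1::2] = 2.0 * V * (B_out * (a + kh) - b * (A_out + kh)) / den
    return out


def timecourse_objective(data: TimeCourseDataset, h: float, V: float,
                         K: float, B_in0: float) -> float:
    """Relative normalized SSE of a candidate parameter set.

    Simulates every external condition from (A_in = 0, B_in = B_in0) —
    stacked into a single ODE system so one adaptive integration covers all
    conditions — and sums ((model - mean)/mean)**2 over all points with a
    non-zero experimental mean.
    """
    TransporterParams(V=V, K=K, h=h)  # validate
    if B_in0 < 0:
        raise ValueError("B_in0 must be >= 0")
    levels = data.b_out_levels
    conds = [data.condition(b) for b in levels]
    t_all = np.unique(np.concatenate(
        [[0.0]] + [c["time_s"].to_numpy(float) / 60.0 for c in conds]))
    if t_all.size < 2:
        return 0.0
    from scipy.integrate import solve_ivp
    from .simulation import ATOL, NEG_TOL, RTOL
    y0 = np.ravel([[0.0, B_in0] for _ in levels])
    sol = solve_ivp(_stacked_rhs, (0.0, float(t_all[-1])), y0, method="RK45",
                    t_eval=t_all, rtol=RTOL, atol=ATOL,
                    args=(np.full(len(levels), data.A_out0),
                          np.asarray(levels, dtype=float), V, K, h))
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    if sol.y.min() < -NEG_TOL:
        raise RuntimeError("integration produced negative concentrations")
    total = 0.0
    for i, cond in enumerate(conds):
        t_min = cond["time_s"].to_numpy(float) / 60.0
        mean = cond["A_in_mean"].to_numpy(float)
        model = np.interp(t_min, sol.t, sol.y[2 * i])
        keep = mean != 0
        if keep.any():
            r = (model[keep] - mean[keep]) / mean[keep]
            total += float(r @ r)
    return total


def fit_timecourse(data: TimeCourseDataset, fixed: Mapping,
                   n_starts: int = N_STARTS, seed: int = 0) -> FitResult:
    """Jointly fit (h,) V to all time-course conditions.

    Parameters
    ----------
    data : TimeCourseDataset
    fixed : mapping
        Must contain ``B_in0`` and exactly one of ``K`` or ``Kapp``; may
        contain ``h`` to constrain the mechanism.  When ``Kapp`` is fixed,
        K is re-derived from it at every candidate (h, B_in0) so the fit
        stays consistent with the measured initial-rate saturation.
    n_starts, seed :
        Multi-start policy: seeded Latin-hypercube draws in log space over
        V ∈ [1, 1e4] µmol l⁻¹ min⁻¹ and h ∈ [1e-3, 10].

    Raises
    ------
    ValueError
        If every condition mean is zero (nothing to normalise against), or
        the fixed set is inconsistent.
    FitConvergenceError
        If no restart yields a finite objective.
    """
    fixed = dict(fixed)
    if "B_in0" not in fixed:
        raise ValueError("fixed must specify B_in0")
    if ("K" in fixed) == ("Kapp" in fixed):
        raise ValueError("fixed must specify exactly one of K or Kapp")
    if not (data.data["A_in_mean"] != 0).any():
        raise ValueError("all experimental means are zero; nothing to fit")

    B_in0 = float(fixed["B_in0"])
    h_fixed = fixed.get("h")
    free = ["V"] if h_fixed is not None else ["h", "V"]
    n_obs = int((data.data["A_in_mean"] != 0).sum())

    if h_fixed is not None:
        bounds_log = np.log(np.array([list(V_BOUNDS)]))
    else:
        bounds_log = np.log(np.array([list(H_BOUNDS), list(V_BOUNDS)]))

    def objective(theta):
        vals = np.exp(theta)
        if h_fixed is not None:
            h, V = float(h_fixed), float(vals[0])
        else:
            h, V = float(vals[0]), float(vals[1])
        try:
            K = _resolve_K(h, fixed)
            return timecourse_objective(data, h=h, V=V, K=K, B_in0=B_in0)
        except (ValueError, ObligatoryExchangeError, RuntimeError):
            return float("inf")

    best, n_ok = _multistart_nm(objective, bounds_log, n_starts, seed)
    if best is None or not math.isfinite(best.fun):
        raise FitConvergenceError(
            f"time-course fit failed in all {n_starts} restarts")

    vals = np.exp(best.x)
    if h_fixed is not None:
        h_hat, V_hat = float(h_fixed), float(vals[0])
    else:
        h_hat, V_hat = float(vals[0]), float(vals[1])
    K_hat = _resolve_K(h_hat, fixed)
    return FitResult(
        params={"h": h_hat, "V": V_hat, "K": K_hat},
        fixed=fixed, objective=float(best.fun), n_restarts=n_starts,
        n_obs=n_obs, success=bool(n_ok > 0), message=best.message,
    )


def profile_objective(data: TimeCourseDataset, grid: Mapping[str, Iterable],
                      fixed: Mapping, n_starts: int = N_STARTS,
                      seed: int = 0) -> pd.DataFrame:
    """Re-fit the free parameters at every point of a 1- or 2-axis grid.

    Each grid point fixes the scanned quantity (one or two of ``B_in0``,
    ``K``, ``h``) on top of the base ``fixed`` set and performs a *full*
    multi-start re-fit of whatever remains free — a profile of the
    objective, not a slice through a single fit.  Failed points are recorded
    with status ``"failed"`` rather than aborting the scan.

    Returns a long-format DataFrame with one row per grid point: the axis
    values, the re-fitted parameters, ``objective`` and ``status``.
    """
    axes = {k: np.asarray(list(v), dtype=float) for k, v in grid.items()}
    bad = set(axes) - {"B_in0", "K", "h"}
    if bad:
        raise ValueError(f"unsupported scan axes: {sorted(bad)}")
    if not 1 <= len(axes) <= 2:
        raise ValueError("grid must have one or two axes")

    names = list(axes)
    if len(names) == 1:
        points = [(v,) for v in axes[names[0]]]
    else:
        points = [(u, v) for u in axes[names[0]] for v in axes[names[1]]]

    rows = []
    for pt in points:
        point_fixed = dict(fixed)
        for name, value in zip(names, pt):
            point_fixed[name] = float(value)
            if name == "K":
                point_fixed.pop("Kapp", None)
        row = dict(zip(names, pt))
        try:
            fit = fit_timecourse(data, point_fixed, n_starts=n_starts,
                                 seed=seed)
            row.update({"objective": fit.objective, "h": fit.params["h"],
                        "V": fit.params["V"], "K": fit.params["K"],
                        "status": "ok"})
        except (ValueError, ObligatoryExchangeError, FitConvergenceError,
                RuntimeError) as exc:
            row.update({"objective": float("nan"), "h": float("nan"),
                        "V": float("nan"), "K": float("nan"),
                        "status": f"failed: {exc}"})
        rows.append(row)
    return pd.DataFrame(rows)
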