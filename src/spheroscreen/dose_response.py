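"""Constrained 4PL concentration-response fitting and DSS scoring.

The inhibition curve on x = log10(concentration / nM) is the
four-parameter logistic

    y(x) = d + (a - d) / (1 + 10^(b (c - x)))

with top asymptote ``a``, bottom asymptote ``d`` (both in % inhibition,
0 <= d <= a <= 100), Hill slope ``b`` in [0.2, 10] (positive: inhibition
does not decrease with dose), and midpoint ``c`` = log10 EC50.  Fitting is a
deterministic multi-start bounded least-squares; the constraint d <= a is
enforced by parameterizing d as a fraction of a.

The drug sensitivity score (DSS) summarizes a fitted curve as the
normalized area above an activity threshold t (default 10 %) over the
tested log10 range [x1, x2]:

    DSS = 100 * integral(max(y(x) - t, 0), x1..x2) / ((100 - t) (x2 - x1))

so a flat 100 % curve scores 100 and anything below threshold scores 0.
The integral has a closed form (used here); adaptive quadrature agrees to
1e-5 and serves as the independent cross-check in the tests.  A drug is
called effective when DSS > 8 (strict).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

LN10 = math.log(10.0)

SLOPE_BOUNDS = (0.2, 10.0)
DSS_ACTIVITY_THRESHOLD = 10.0
DSS_HIT_CUTOFF = 8.0
RMSE_QC_LIMIT = 30.0


def fourpl(x, a: float, d: float, b: float, c: float):
    """Evaluate the 4PL curve at log10 concentration x (stable for large
    |b (c - x)|)."""
    x = np.asarray(x, dtype=float)
    z = np.clip(b * (c - x), -300.0, 300.0)
    out = d + (a - d) / (1.0 + np.power(10.0, z))
    return float(out) if out.ndim == 0 else out


@dataclass
class Curve4PL:
    """A fitted 4PL inhibition curve over the tested log10 nM range."""

    a: float  # top asymptote, % inhibition
    d: float  # bottom asymptote, %
    b: float  # Hill slope (> 0)
    c: float  # log10 EC50 (log10 nM)
    rmse: float
    converged: bool
    conc_range: tuple[float, float]  # (log10 Cmin, log10 Cmax)

    def __call__(self, x):
        return fourpl(x, self.a, self.d, self.b, self.c)


def _residuals(theta, x, y):
    a, f, b, c = theta
    return fourpl(x, a, f * a, b, c) - y


def _sigmoid(x, b, c):
    z = np.clip(b * (c - x), -300.0, 300.0)
    return 1.0 / (1.0 + np.power(10.0, z))


def _jac_free(theta, x, y):
    a, f, b, c = theta
    s = _sigmoid(x, b, c)
    core = a * (1.0 - f) * s * (1.0 - s) * LN10
    return np.column_stack([
        f + (1.0 - f) * s,      # d/da
        a * (1.0 - s),          # d/df
        -core * (c - x),        # d/db
        -core * b * np.ones_like(x),  # d/dc
    ])


def _jac_fixed(theta, x, y, db):
    a, b, c = theta
    s = _sigmoid(x, b, c)
    core = (a - db) * s * (1.0 - s) * LN10
    return np.column_stack([
        s,
        -core * (c - x),
        -core * b * np.ones_like(x),
    ])


def fit_4pl(concs_nM, responses, *, fixed_bottom: float | None = None) -> Curve4PL:
    """Deterministic multi-start constrained least-squares 4PL fit.

    ``concs_nM`` are >= 4 distinct positive concentrations; ``responses``
    are percent inhibition.  The start grid places c at the quartiles of the
    log-dose range and b in {0.5, 1, 2}; the lowest-SSR fit wins, ties
    broken toward the lowest slope.  ``fixed_bottom`` pins the bottom
    asymptote (used by the synergy module's directional fits).
    """
    concs = np.asarray(concs_nM, dtype=float)
    y = np.asarray(responses, dtype=float)
    if concs.shape != y.shape:
        raise ValueError("concs and responses must have the same length")
    if np.any(concs <= 0):
        raise ValueError("concentrations must be positive (zero dose is not on the log axis)")
    if np.unique(concs).size < 4:
        raise ValueError("need >= 4 distinct concentrations")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    x = np.log10(concs)
    order = np.argsort(x)
    x, y = x[order], y[order]
    x1, x2 = float(x[0]), float(x[-1])
    c_bounds = (x1 - 1.0, x2 + 1.0)

    a0 = float(np.clip(y.max(), 1.0, 100.0))
    d0 = float(np.clip(y.min(), 0.0, a0))
    c_starts = np.quantile(x, [0.25, 0.5, 0.75])
    b_starts = (0.5, 1.0, 2.0)

    best = None
    if fixed_bottom is None:
        lo = [0.0, 0.0, SLOPE_BOUNDS[0], c_bounds[0]]
        hi = [100.0, 1.0, SLOPE_BOUNDS[1], c_bounds[1]]
        f0 = d0 / a0 if a0 > 0 else 0.0
        starts = [
            np.array([a0, f0, b, np.clip(c, *c_bounds)])
            for b in b_starts
            for c in c_starts
        ]
        resid = lambda th: _residuals(th, x, y)
        jac = lambda th: _jac_free(th, x, y)
    else:
        # bottom pinned: fit (a, b, c) with a in [fixed_bottom, 100]
        db = float(np.clip(fixed_bottom, 0.0, 100.0))
        lo = [db, SLOPE_BOUNDS[0], c_bounds[0]]
        hi = [100.0, SLOPE_BOUNDS[1], c_bounds[1]]
        a0p = float(np.clip(max(y.max(), db + 1e-6), db, 100.0))
        starts = [
            np.array([a0p, b, np.clip(c, *c_bounds)])
            for b in b_starts
            for c in c_starts
        ]
        resid = lambda th: fourpl(x, th[0], db, th[1], th[2]) - y
        jac = lambda th: _jac_fixed(th, x, y, db)

    for theta0 in starts:
        try:
            sol = least_squares(resid, theta0, jac=jac, bounds=(lo, hi),
                                method="trf", xtol=1e-8, ftol=1e-8, gtol=1e-8,
                                max_nfev=200)
        except Exception:
            continue
        ssr = float(np.sum(sol.fun**2))
        b_fit = sol.x[2] if fixed_bottom is None else sol.x[1]
        key = (round(ssr, 9), b_fit)
        # status 0 = iteration cap inside a flat slope valley: the SSR is at
        # its floor and the curve is usable; only a hard failure (status < 0
        # or non-finite result) is a non-converged fit
        ok = sol.status >= 0 and np.isfinite(ssr) and np.all(np.isfinite(sol.x))
        if ok and (best is None or key < best[0]):
            best = (key, sol, ssr)
        if best is not None and best[2] < 1e-10 * y.size:
            break  # essentially perfect fit; later starts cannot improve

    if best is None:
        return Curve4PL(a=float("nan"), d=float("nan"), b=float("nan"),
                        c=float("nan"), rmse=float("nan"), converged=False,
                        conc_range=(x1, x2))
    _, sol, ssr = best
    if fixed_bottom is None:
        a, f, b, c = sol.x
        d = f * a
    else:
        a, b, c = sol.x
        d = float(np.clip(fixed_bottom, 0.0, 100.0))
    rmse = math.sqrt(ssr / y.size)
    return Curve4PL(a=float(a), d=float(d), b=float(b), c=float(c),
                    rmse=rmse, converged=True, conc_range=(x1, x2))


def curve_qc(curve: Curve4PL, responses=None, *, rmse_limit: float = RMSE_QC_LIMIT) -> bool:
    """Minimal curve-level quality rules.

    A curve fails QC when the fit did not converge, the residual RMSE
    exceeds ``rmse_limit`` percentage points, or the observed responses
    clearly *decrease* with dose (the positive-slope constraint then pins
    the dynamic range a - d at ~0 while the data disagree).
    """
    if not curve.converged:
        return False
    if curve.rmse > rmse_limit:
        return False
    if responses is not None:
        y = np.asarray(responses, dtype=float)
        if y.size >= 4:
            trend = y[-2:].mean() - y[:2].mean()
            if trend < -10.0 and (curve.a - curve.d) < 1.0:
                return False
    return True


def _log1p10(z):
    """ln(1 + 10^z), overflow-safe."""
    z = np.asarray(z, dtype=float)
    out = np.where(z > 0, z * LN10 + np.log1p(np.power(10.0, -np.abs(z))),
                   np.log1p(np.power(10.0, -np.abs(z))))
    return out


def _fourpl_antiderivative(x, a, d, b, c):
    """Antiderivative of the 4PL curve in x."""
    return d * x + (a - d) / (b * LN10) * _log1p10(b * (x - c))


def dss(curve: Curve4PL, t: float = DSS_ACTIVITY_THRESHOLD) -> float:
    """Drug sensitivity score of a fitted curve (closed-form integral).

    Returns 0 when the top asymptote does not exceed the activity
    threshold; 100 for complete inhibition over the whole tested range.
    """
    x1, x2 = curve.conc_range
    if not x2 > x1:
        raise ValueError(f"degenerate concentration range {curve.conc_range}")
    a, d, b, c = curve.a, curve.d, curve.b, curve.c
    if not np.isfinite([a, d, b, c]).all():
        return float("nan")
    if a <= t:
        return 0.0
    if d >= t:
        lo = x1
    else:
        # crossing point y(x_t) = t, monotone increasing curve
        ratio = (a - d) / (t - d) - 1.0
        x_t = c - math.log10(ratio) / b
        if x_t >= x2:
            return 0.0
        lo = max(x1, x_t)
    integral = (
        _fourpl_antiderivative(x2, a, d, b, c)
        - _fourpl_antiderivative(lo, a, d, b, c)
        - t * (x2 - lo)
    )
    score = 100.0 * float(integral) / ((100.0 - t) * (x2 - x1))
    return float(max(score, 0.0))


def effective_drug_count(dss_vector, cutoff: float = DSS_HIT_CUTOFF) -> int:
    """Number of DSS entries strictly above the effectiveness cutoff
    (NaN entries skipped)."""
    v = np.asarray(list(dss_vector), dtype=float)
    return int(np.sum(v[~np.isnan(v)] > cutoff))


@dataclass
class DSSResult:
    sample_id: str
    drug_id: str
    parameter: str
    dss: float
    hit: bool
    qc_pass: bool
    curve: Curve4PL | None = None


def screen_dss(
    normalized: pd.DataFrame,
    qc_report: pd.DataFrame | None = None,
    *,
    activity_threshold: float = DSS_ACTIVITY_THRESHOLD,
    hit_cutoff: float = DSS_HIT_CUTOFF,
) -> pd.DataFrame:
    """Fit a 4PL and score DSS for every (sample, drug, parameter) series.

    ``normalized`` is the long-form percent-inhibition table from
    :func:`spheroscreen.qc.normalize_responses`.  Series belonging to a
    (sample, parameter) that failed the Z' gate are reported with
    ``qc_pass=False`` and a missing DSS; curves failing curve-level QC
    likewise.  Returns a long-form frame with fitted parameters.
    """
    gate: dict[tuple[str, str], bool] = {}
    if qc_report is not None:
        for row in qc_report.itertuples(index=False):
            gate[(row.sample_id, row.parameter)] = bool(row.passed)
    rows = []
    keys = ["sample_id", "drug_id", "parameter"]
    has_format = "format" in normalized.columns
    if has_format:
        keys = ["sample_id", "format", "drug_id", "parameter"]
    for group_key, g in normalized.groupby(keys, sort=True):
        if has_format:
            sample, fmt, drug, parameter = group_key
        else:
            (sample, drug, parameter), fmt = group_key, "3D"
        g = g.groupby("conc_nM", as_index=False)["percent_inhibition"].mean()
        concs = g["conc_nM"].to_numpy()
        resp = g["percent_inhibition"].to_numpy()
        sample_pass = gate.get((sample, parameter), True)
        curve = fit_4pl(concs, resp)
        cqc = curve_qc(curve, resp)
        ok = bool(sample_pass and cqc)
        score = dss(curve, activity_threshold) if cqc else float("nan")
        rows.append(
            {
                "sample_id": sample,
                "format": fmt,
                "drug_id": drug,
                "parameter": parameter,
                "dss": score if ok else float("nan"),
                "hit": bool(ok and not math.isnan(score) and score > hit_cutoff),
                "qc_pass": ok,
                "curve_qc": cqc,
                "a": curve.a,
                "d": curve.d,
                "b": curve.b,
                "c": curve.c,
                "rmse": curve.rmse,
                "converged": curve.converged,
            }
        )
    return pd.DataFrame(rows)
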