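"""Logan and Patlak graphical analysis with t* selection and linearity checks.

The Logan plot linearises reversible kinetics: for t beyond equilibration,

    int_0^t C_t / C_t(t)  =  VT * int_0^t C_p / C_t(t)  +  b,

so the asymptotic slope estimates the total distribution volume.  The Patlak
plot linearises irreversible kinetics,

    C_t(t)/C_p(t)  =  Ki * int_0^t C_p / C_p(t)  +  V0,

with slope Ki = K1 k3/(k2 + k3); a reversible tracer instead bends towards a
plateau (negative curvature, slope -> 0), which is exactly the diagnostic
used to argue reversible binding.

Tissue integrals use the trapezoidal TAC primitive; input integrals use the
exact integral of the continuous input-function contract.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TimeActivityCurve, cumulative_integral
from .input_function import InputFunction


@dataclass
class GraphicalResult:
    """A fitted linear segment of a Logan or Patlak plot."""

    method: str               # "logan" | "patlak"
    slope: float              # Logan: VT (ml/cm^3); Patlak: Ki (ml/cm^3/min)
    intercept: float
    tstar: float              # minutes
    n_points_used: int
    r_squared: float
    max_rel_deviation: float
    slope_ci95: tuple[float, float]
    criterion_met: bool
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray

    @property
    def positive_slope(self) -> bool:
        """Slope significantly positive (95% CI excludes zero)."""
        return self.slope_ci95[0] > 0.0

    def to_dict(self) -> dict:
        return {
            "method": self.method, "slope": self.slope, "intercept": self.intercept,
            "tstar": self.tstar, "n_points_used": self.n_points_used,
            "r_squared": self.r_squared, "max_rel_deviation": self.max_rel_deviation,
            "slope_ci95": list(self.slope_ci95), "criterion_met": self.criterion_met,
        }


def logan_transform(tac: TimeActivityCurve, inp: InputFunction):
    """Logan coordinates (x, y, t) for frames with positive tissue activity."""
    t = tac.midpoints
    ct = tac.values
    int_ct = cumulative_integral(tac)
    int_cp = inp.integral(t)
    keep = ct > 0
    if keep.sum() < 3:
        raise ValueError("fewer than 3 usable Logan points (C_t must be > 0)")
    x = int_cp[keep] / ct[keep]
    y = int_ct[keep] / ct[keep]
    return x, y, t[keep]


def patlak_transform(tac: TimeActivityCurve, inp: InputFunction):
    """Patlak coordinates (x, y, t) for frames with positive plasma activity."""
    t = tac.midpoints
    cp = inp.evaluate(t)
    keep = cp > 0
    if keep.sum() < 3:
        raise ValueError("fewer than 3 usable Patlak points (C_p must be > 0)")
    x = inp.integral(t)[keep] / cp[keep]
    y = tac.values[keep] / cp[keep]
    return x, y, t[keep]


def _ols(x, y):
    n = x.size
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    resid = y - yhat
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    # slope standard error and normal-approximation 95% CI
    sxx = float(np.sum((x - x.mean()) ** 2))
    if n > 2 and sxx > 0:
        se = np.sqrt(ss_res / (n - 2) / sxx)
        from scipy.stats import t as tdist
        tcrit = tdist.ppf(0.975, n - 2)
        ci = (slope - tcrit * se, slope + tcrit * se)
    else:
        ci = (-np.inf, np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(resid) / np.abs(yhat)
    rel = rel[np.isfinite(rel)]
    max_rel = float(rel.max()) if rel.size else np.inf
    return slope, intercept, r2, max_rel, ci


def fit_linear_segment(points, method: str = "logan", tstar="auto",
                       max_rel_dev: float = 0.10) -> GraphicalResult:
    """Fit the late linear segment of a graphical plot.

    ``points`` is the (x, y, t) triple from a transform.  With a numeric
    ``tstar`` (minutes) all points at/after it are used.  In ``auto`` mode
    candidate start indices are scanned from late to early; the earliest
    start whose segment keeps every |residual|/|fitted| at or below
    ``max_rel_dev`` wins.  If no start satisfies the criterion the result is
    flagged and the slope comes from the latest 3 points.
    """
    x, y, t = (np.asarray(a, float) for a in points)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    order = np.argsort(t)
    x, y, t = x[order], y[order], t[order]
    n = x.size

    if tstar != "auto":
        sel = t >= float(tstar) - 1e-12
        if sel.sum() < 3:
            raise ValueError("fewer than 3 points at/after tstar")
        slope, intercept, r2, max_rel, ci = _ols(x[sel], y[sel])
        return GraphicalResult(method, float(slope), float(intercept), float(tstar),
                               int(sel.sum()), r2, max_rel, ci,
                               criterion_met=max_rel <= max_rel_dev,
                               times=t[sel], x=x[sel], y=y[sel])

    best_i = None
    for i in range(n - 3, -1, -1):
        slope, intercept, r2, max_rel, ci = _ols(x[i:], y[i:])
        if max_rel <= max_rel_dev:
            best_i = i
        else:
            break
    if best_i is None:
        slope, intercept, r2, max_rel, ci = _ols(x[-3:], y[-3:])
        return GraphicalResult(method, float(slope), float(intercept), float(t[-3]),
                               3, r2, max_rel, ci, criterion_met=False,
                               times=t[-3:], x=x[-3:], y=y[-3:])
    slope, intercept, r2, max_rel, ci = _ols(x[best_i:], y[best_i:])
    return GraphicalResult(method, float(slope), float(intercept), float(t[best_i]),
                           int(n - best_i), r2, max_rel, ci, criterion_met=True,
                           times=t[best_i:], x=x[best_i:], y=y[best_i:])


def logan_vt(tac: TimeActivityCurve, inp: InputFunction, tstar=20.0,
             max_rel_dev: float = 0.10) -> GraphicalResult:
    """Logan analysis; the slope estimates VT for reversible tracers."""
    return fit_linear_segment(logan_transform(tac, inp), "logan", tstar, max_rel_dev)


def patlak_ki(tac: TimeActivityCurve, inp: InputFunction, tstar=20.0,
              max_rel_dev: float = 0.10) -> GraphicalResult:
    """Patlak analysis; the slope estimates Ki for irreversible tracers."""
    return fit_linear_segment(patlak_transform(tac, inp), "patlak", tstar, max_rel_dev)
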