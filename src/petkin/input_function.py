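"""Image-derived input function and its tracer-specific corrections.

The whole-blood curve is segmented from the inferior vena cava, converted to
plasma with a (possibly time-varying) plasma-to-blood ratio, and corrected
for radiometabolites with a parent-fraction model.  The corrected curve is
wrapped as a continuous-time :class:`InputFunction` whose interpolation
contract is fixed so every downstream convolution is well defined:

* linear from (0, 0) to the first sample (bolus starts at zero activity),
* piecewise linear between samples,
* mono-exponential tail fitted to the last three samples for extrapolation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import RoiMask, TimeActivityCurve, VoxelGrid4D


@dataclass(frozen=True)
class PlasmaBloodRatio:
    """Plasma-to-blood conversion factor, constant or sampled in time.

    Sampled mode interpolates linearly between (time, ratio) samples and
    holds the end values constant beyond both ends.
    """

    mode: str = "constant"
    constant_value: float = 1.0
    sample_times: np.ndarray | None = None      # minutes
    sample_ratios: np.ndarray | None = None

    def __post_init__(self):
        if self.mode not in ("constant", "sampled"):
            raise ValueError("mode must be 'constant' or 'sampled'")
        if self.mode == "constant":
            if self.constant_value <= 0:
                raise ValueError("plasma-to-blood ratio must be positive")
        else:
            t = np.asarray(self.sample_times, float)
            r = np.asarray(self.sample_ratios, float)
            object.__setattr__(self, "sample_times", t)
            object.__setattr__(self, "sample_ratios", r)
            if t.size < 2 or t.shape != r.shape:
                raise ValueError("sampled mode needs >= 2 (time, ratio) pairs")
            if np.any(np.diff(t) <= 0):
                raise ValueError("sample times must be strictly increasing")
            if np.any(r <= 0):
                raise ValueError("ratios must be positive")

    def ratio_at(self, t) -> np.ndarray:
        t = np.asarray(t, float)
        if self.mode == "constant":
            return np.full_like(t, self.constant_value)
        return np.interp(t, self.sample_times, self.sample_ratios)


def fet_pbr_table() -> PlasmaBloodRatio:
    """Literature plasma-to-blood series used for FET: ratios 1.1-1.4 over 1-55 min."""
    return PlasmaBloodRatio(
        mode="sampled",
        sample_times=np.array([1.0, 5.0, 15.0, 30.0, 40.0, 55.0]),
        sample_ratios=np.array([1.1, 1.1, 1.1, 1.1, 1.3, 1.4]),
    )


@dataclass(frozen=True)
class ParentFraction:
    """Fraction of plasma activity that is unmetabolised parent tracer.

    Models
    ------
    constant         f(t) = value
    one_exponential  f(t) = (1 - A) + A * exp(-lam * t)
    hill             f(t) = 1 - (1 - floor) * t^n / (t50^n + t^n)
    """

    model: str = "constant"
    parameters: dict = field(default_factory=lambda: {"value": 1.0})

    def __post_init__(self):
        if self.model not in ("constant", "one_exponential", "hill"):
            raise ValueError(f"unknown parent-fraction model {self.model!r}")
        # validate 0 < f <= 1 over the longest scan
        tt = np.linspace(0.0, 90.0, 181)
        f = self.fraction_at(tt)
        if np.any(f <= 0) or np.any(f > 1 + 1e-12):
            raise ValueError("parent fraction must satisfy 0 < f <= 1 on [0, 90] min")

    def fraction_at(self, t) -> np.ndarray:
        t = np.asarray(t, float)
        p = self.parameters
        if self.model == "constant":
            return np.full_like(t, float(p["value"]))
        if self.model == "one_exponential":
            A, lam = float(p["A"]), float(p["lam"])
            return (1.0 - A) + A * np.exp(-lam * t)
        floor, t50, n = float(p["floor"]), float(p["t50"]), float(p["n"])
        tn = np.power(t, n)
        return 1.0 - (1.0 - floor) * tn / (t50 ** n + tn)


class InputFunction:
    """Metabolite- and plasma-corrected parent concentration in plasma.

    A continuous, non-negative function of time (minutes -> kBq/cm^3)
    defined by samples plus the fixed interpolation contract described in
    the module docstring.
    """

    def __init__(self, times, values):
        t = np.asarray(times, float)
        v = np.asarray(values, float)
        if t.ndim != 1 or t.shape != v.shape or t.size < 2:
            raise ValueError("need >= 2 (time, value) samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if t[0] < 0:
            raise ValueError("sample times must be >= 0")
        if np.any(v < 0):
            raise ValueError("input-function values must be non-negative")
        if t[0] > 0:  # anchor the bolus at (0, 0)
            t = np.concatenate([[0.0], t])
            v = np.concatenate([[0.0], v])
        self.times = t
        self.values = v
        self._fit_tail()
        # exact running integral at the knots (trapezoid is exact for
        # piecewise-linear samples)
        self._knot_integral = np.concatenate(
            [[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(t))])

    def _fit_tail(self):
        """Mono-exponential tail A*exp(-lam*(t - t_last)) from the last 3 samples."""
        t3, v3 = self.times[-3:], self.values[-3:]
        if t3.size == 3 and np.all(v3 > 0):
            slope, logc = np.polyfit(t3, np.log(v3), 1)
            lam = -slope
            if lam > 0:
                self._tail_lam = float(lam)
                self._tail_amp = float(np.exp(logc + slope * self.times[-1]))
                return
        # flat or non-positive tail: hold the last value constant
        self._tail_lam = 0.0
        self._tail_amp = float(self.values[-1])

    # -- evaluation ---------------------------------------------------------
    def evaluate(self, t):
        t = np.asarray(t, float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        if np.any(t < 0):
            raise ValueError("input function is defined for t >= 0 only")
        out = np.interp(t, self.times, self.values)
        late = t > self.times[-1]
        if np.any(late):
            out[late] = self._tail_amp * np.exp(-self._tail_lam * (t[late] - self.times[-1]))
        return float(out[0]) if scalar else out

    __call__ = evaluate

    def integral(self, t):
        """Exact integral of the interpolant from 0 to t."""
        t = np.asarray(t, float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        if np.any(t < 0):
            raise ValueError("t must be >= 0")
        tk, vk = self.times, self.values
        idx = np.clip(np.searchsorted(tk, t, side="right") - 1, 0, tk.size - 2)
        t0 = tk[idx]
        u = np.minimum(t, tk[-1]) - t0
        m = (vk[idx + 1] - vk[idx]) / (tk[idx + 1] - tk[idx])
        out = self._knot_integral[idx] + vk[idx] * u + 0.5 * m * u ** 2
        late = t > tk[-1]
        if np.any(late):
            dt = t[late] - tk[-1]
            if self._tail_lam > 0:
                tail = self._tail_amp * (1.0 - np.exp(-self._tail_lam * dt)) / self._tail_lam
            else:
                tail = self._tail_amp * dt
            out[late] = self._knot_integral[-1] + tail
        return float(out[0]) if scalar else out

    def grid(self, t_max: float, tail_spacing: float = 0.5):
        """Knot times/values extended with sampled tail points up to ``t_max``.

        Downstream convolution treats the result as an exact piecewise-linear
        curve; the tail is sampled finely enough that linearising it is
        numerically immaterial for slowly decaying blood tails.
        """
        t, v = self.times, self.values
        if t_max > t[-1] + 1e-12:
            extra = np.arange(t[-1] + tail_spacing, t_max + tail_spacing, tail_spacing)
            t = np.concatenate([t, extra])
            v = np.concatenate([v, self.evaluate(extra)])
        return t, v

    def scaled(self, factor: float) -> "InputFunction":
        return InputFunction(self.times, self.values * factor)


def evaluate_input(inp: InputFunction, t):
    """Evaluate the input function at time(s) t (minutes)."""
    return inp.evaluate(t)


# ---------------------------------------------------------------------------
# Building the corrected input function
# ---------------------------------------------------------------------------

def derive_idif(grid: VoxelGrid4D, cava_mask: RoiMask) -> TimeActivityCurve:
    """Whole-blood TAC as the per-frame mean over the vena-cava mask."""
    if cava_mask.n_voxels == 0:
        raise ValueError("vena cava mask is empty")
    if cava_mask.membership.shape != grid.spatial_shape:
        raise ValueError("mask dims must match grid spatial dims")
    vals = grid.values[cava_mask.membership].mean(axis=0)
    return TimeActivityCurve(grid.schedule, vals, roi_label="vena_cava")


def apply_pbr(blood: TimeActivityCurve, ratio: PlasmaBloodRatio) -> TimeActivityCurve:
    """Convert whole-blood activity to plasma: plasma(t) = blood(t) * r(t)."""
    r = ratio.ratio_at(blood.midpoints)
    return blood.with_values(blood.values * r, roi_label="plasma")


def apply_parent_fraction(plasma: TimeActivityCurve, pf: ParentFraction) -> InputFunction:
    """Metabolite-correct the plasma curve and wrap it as an InputFunction."""
    f = pf.fraction_at(plasma.midpoints)
    return InputFunction(plasma.midpoints, plasma.values * f)


def build_input_function(blood: TimeActivityCurve, ratio: PlasmaBloodRatio,
                         pf: ParentFraction) -> InputFunction:
    """Full correction chain: whole blood -> plasma -> parent-in-plasma."""
    return apply_parent_fraction(apply_pbr(blood, ratio), pf)


# ---------------------------------------------------------------------------
# Synthetic bolus input (Feng form)
# ---------------------------------------------------------------------------

def feng_values(t, A1, A2, A3, lam1, lam2, lam3):
    """Tri-exponential bolus model evaluated at t (minutes).

    C_p(t) = (A1*t - A2 - A3) e^(-lam1 t) + A2 e^(-lam2 t) + A3 e^(-lam3 t)
    """
    t = np.asarray(t, float)
    return ((A1 * t - A2 - A3) * np.exp(-lam1 * t)
            + A2 * np.exp(-lam2 * t) + A3 * np.exp(-lam3 * t))


def feng_input(params: dict, schedule) -> InputFunction:
    """Sample a Feng bolus densely over a schedule and wrap as InputFunction.

    Dense grid: 1-s spacing over the first 5 min (bolus peak), 30-s after.
    """
    A1, A2, A3 = (float(params[k]) for k in ("A1", "A2", "A3"))
    l1, l2, l3 = (float(params[k]) for k in ("lam1", "lam2", "lam3"))
    if not (l1 > l2 > l3 > 0):
        raise ValueError("need lam1 > lam2 > lam3 > 0")
    t_end = schedule.total_duration
    t_fine = np.arange(0.0, min(5.0, t_end), 1.0 / 60.0)
    t_coarse = np.arange(5.0, t_end + 0.5, 0.5)
    t = np.unique(np.concatenate([t_fine, t_coarse]))
    v = feng_values(t, A1, A2, A3, l1, l2, l3)
    if np.any(v < -1e-9):
        raise ValueError("Feng parameters produce negative plasma values")
    return InputFunction(t, np.clip(v, 0.0, None))
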