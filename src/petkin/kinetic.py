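"""Compartment models (1TCM/2TCM with blood-volume term), SRTM, and fitting.

Model definitions
-----------------
1TCM:  C_pet(t) = (1 - vB) * K1 exp(-k2 t) (*) C_p(t) + vB * C_wb(t)

2TCM:  impulse response
       h(t) = K1/(a2 - a1) * [(k3 + k4 - a1) e^(-a1 t) + (a2 - k3 - k4) e^(-a2 t)]
       with a_{1,2} = [(k2+k3+k4) -/+ sqrt((k2+k3+k4)^2 - 4 k2 k4)] / 2,
       C_pet = (1 - vB) * h (*) C_p + vB * C_wb.

SRTM:  C_t(t) = R1 C_r(t) + (k2 - R1 k2a) C_r (*) exp(-k2a t),
       k2a = k2 / (1 + BPND).

All frame values are exact frame-duration averages of the continuous model;
the convolution against the piecewise-linear input is closed form (see
:mod:`petkin.convolve`).  Degenerate eigenvalues use the analytic
t*exp(-a t) kernel; a vanishing efflux rate collapses to a pure integrator.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .convolve import REPEATED_ROOT_TOL, ConvolutionEngine
from .core import FrameSchedule, TimeActivityCurve
from .input_function import InputFunction


@dataclass(frozen=True)
class Params1T:
    """One-tissue model: delivery K1 (ml/cm^3/min), efflux k2 (1/min)."""

    K1: float
    k2: float
    vB: float = 0.0

    def __post_init__(self):
        if self.K1 < 0 or self.k2 < 0:
            raise ValueError("rate constants must be non-negative")
        if not 0 <= self.vB <= 0.2:
            raise ValueError("vB must lie in [0, 0.2]")

    @property
    def VT(self) -> float:
        return self.K1 / self.k2 if self.k2 > 0 else np.inf


@dataclass(frozen=True)
class Params2T:
    """Two-tissue model: K1 (ml/cm^3/min), k2-k4 (1/min), blood volume vB."""

    K1: float
    k2: float
    k3: float
    k4: float
    vB: float = 0.0

    def __post_init__(self):
        if min(self.K1, self.k2, self.k3, self.k4) < 0:
            raise ValueError("rate constants must be non-negative")
        if not 0 <= self.vB <= 0.2:
            raise ValueError("vB must lie in [0, 0.2]")

    @property
    def alphas(self) -> tuple[float, float]:
        s = self.k2 + self.k3 + self.k4
        # stable form of (k2+k3+k4)^2 - 4 k2 k4: always >= 0, no cancellation
        disc = ((self.k2 - self.k4) ** 2 + self.k3 * self.k3
                + 2.0 * self.k3 * (self.k2 + self.k4))
        root = np.sqrt(disc)
        return (s - root) / 2.0, (s + root) / 2.0

    @property
    def VT(self) -> float:
        """Total distribution volume (K1/k2)(1 + k3/k4); infinite if irreversible."""
        if self.k2 <= 0:
            return np.inf
        if self.k4 <= 0:
            return np.inf if self.k3 > 0 else self.K1 / self.k2
        return (self.K1 / self.k2) * (1.0 + self.k3 / self.k4)

    @property
    def Vs(self) -> float:
        if self.k2 <= 0 or self.k4 <= 0:
            return np.inf if self.k3 > 0 else 0.0
        return self.K1 * self.k3 / (self.k2 * self.k4)

    @property
    def Ki(self) -> float:
        """Net influx rate K1 k3 / (k2 + k3) (the irreversible Patlak slope)."""
        denom = self.k2 + self.k3
        return self.K1 * self.k3 / denom if denom > 0 else 0.0

    @classmethod
    def from_vt(cls, K1, k2=None, k3=None, k4=None, VT=None, vB=0.0) -> "Params2T":
        """Complete a parameter set by inverting VT = (K1/k2)(1 + k3/k4).

        Exactly one of k2, k4 may be omitted and is solved from the target VT.
        """
        if VT is None:
            raise ValueError("VT is required")
        if k2 is None:
            k2 = K1 * (1.0 + k3 / k4) / VT
        elif k4 is None:
            ratio = VT * k2 / K1 - 1.0
            if ratio <= 0:
                raise ValueError("VT inconsistent with K1/k2 (needs VT > K1/k2)")
            k4 = k3 / ratio
        return cls(K1=K1, k2=k2, k3=k3, k4=k4, vB=vB)


@dataclass(frozen=True)
class SRTMParams:
    """SRTM: relative delivery R1, reference efflux k2, binding potential BPND."""

    R1: float
    k2: float
    BPND: float

    def __post_init__(self):
        if self.R1 <= 0 or self.k2 <= 0:
            raise ValueError("R1 and k2 must be positive")
        if self.BPND < -1:
            raise ValueError("BPND must be >= -1")

    @property
    def k2a(self) -> float:
        return self.k2 / (1.0 + self.BPND)


DEFAULT_BOUNDS = {"K1": (0.0, 5.0), "k2": (0.0, 10.0), "k3": (0.0, 10.0),
                  "k4": (0.0, 10.0), "vB": (0.0, 0.2)}


@dataclass(frozen=True)
class FitOptions:
    """Controls for weighted multistart nonlinear least squares."""

    weighting: str = "uniform"          # "uniform" | "frame_duration"
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    multistart_count: int = 20
    seed: int = 0
    fit_vB: bool = False
    vB_fixed: float = 0.0

    def __post_init__(self):
        if self.weighting not in ("uniform", "frame_duration"):
            raise ValueError("weighting must be 'uniform' or 'frame_duration'")
        if self.multistart_count < 1:
            raise ValueError("multistart_count must be >= 1")
        for k, (lo, hi) in self.bounds.items():
            if lo >= hi:
                raise ValueError(f"bound for {k} must have lower < upper")

    def weights(self, schedule: FrameSchedule) -> np.ndarray:
        if self.weighting == "uniform":
            return np.ones(schedule.n_frames)
        return schedule.durations / schedule.durations.sum()


@dataclass
class KineticFit:
    """A fitted kinetic model with goodness-of-fit and selection criteria."""

    model: str
    params: dict
    derived: dict
    sswres: float
    n: int
    p: int
    aic: float
    sc: float
    msc: float
    converged: bool
    stderr: dict
    fitted: np.ndarray
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "model": self.model, "params": self.params, "derived": self.derived,
            "sswres": self.sswres, "n": self.n, "p": self.p,
            "aic": self.aic, "sc": self.sc, "msc": self.msc,
            "converged": self.converged, "stderr": self.stderr, "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------

def _tissue_frame_avg_1t(engine: ConvolutionEngine, K1: float, k2: float) -> np.ndarray:
    return K1 * engine.basis_frame_avg(k2)


def _tissue_frame_avg_2t(engine: ConvolutionEngine, p: Params2T) -> np.ndarray:
    if p.k3 == 0.0:
        # exact analytic collapse: h(t) = K1 e^(-k2 t) regardless of k4
        return p.K1 * engine.basis_frame_avg(p.k2)
    a1, a2 = p.alphas
    kb = p.k3 + p.k4
    if a2 - a1 < REPEATED_ROOT_TOL * max(a2, 1.0):
        a = 0.5 * (a1 + a2)
        if a < 1e-12:          # all rates ~ 0: h(t) = K1
            return p.K1 * engine.basis_frame_avg(0.0)
        return p.K1 * (engine.basis_frame_avg(a)
                       + (kb - a) * engine.basis_t_frame_avg(a))
    c1 = p.K1 * (kb - a1) / (a2 - a1)
    c2 = p.K1 * (a2 - kb) / (a2 - a1)
    return c1 * engine.basis_frame_avg(a1) + c2 * engine.basis_frame_avg(a2)


def _blood_term(engine: ConvolutionEngine, whole_blood: TimeActivityCurve | None,
                vB: float) -> np.ndarray:
    if vB == 0.0:
        return 0.0
    if whole_blood is not None:
        return vB * whole_blood.values
    return vB * engine.input_frame_avg()


def model_1t(params: Params1T, inp: InputFunction, schedule: FrameSchedule,
             whole_blood: TimeActivityCurve | None = None,
             engine: ConvolutionEngine | None = None) -> TimeActivityCurve:
    """Frame-averaged 1TCM prediction on a schedule."""
    engine = engine or ConvolutionEngine(inp, schedule)
    vals = ((1.0 - params.vB) * _tissue_frame_avg_1t(engine, params.K1, params.k2)
            + _blood_term(engine, whole_blood, params.vB))
    return TimeActivityCurve(schedule, vals, roi_label="model_1t")


def model_2t(params: Params2T, inp: InputFunction, schedule: FrameSchedule,
             whole_blood: TimeActivityCurve | None = None,
             engine: ConvolutionEngine | None = None) -> TimeActivityCurve:
    """Frame-averaged 2TCM prediction on a schedule."""
    engine = engine or ConvolutionEngine(inp, schedule)
    vals = ((1.0 - params.vB) * _tissue_frame_avg_2t(engine, params)
            + _blood_term(engine, whole_blood, params.vB))
    return TimeActivityCurve(schedule, vals, roi_label="model_2t")


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_PARAM_NAMES = {"1TCM": ["K1", "k2"], "2TCM": ["K1", "k2", "k3", "k4"]}


def _finalize_fit(model, names, theta, result, y, w, schedule, seed) -> KineticFit:
    from . import selection

    params = dict(zip(names, (float(v) for v in theta)))
    fitted = y - result.fun / np.sqrt(w)
    sswres = float(np.sum(result.fun ** 2))
    n, p = y.size, len(theta)
    # standard errors from the residual-variance-scaled Gauss-Newton curvature
    stderr = {}
    try:
        jtj = result.jac.T @ result.jac
        dof = max(n - p, 1)
        cov = np.linalg.pinv(jtj) * (sswres / dof)
        for name, var in zip(names, np.diag(cov)):
            stderr[name] = float(np.sqrt(max(var, 0.0)))
    except Exception:
        stderr = {name: np.nan for name in names}

    derived: dict = {}
    if model == "1TCM":
        p1 = Params1T(params["K1"], params["k2"], params.get("vB", 0.0))
        derived["VT"] = p1.VT
    elif model == "2TCM":
        p2 = Params2T(params["K1"], params["k2"], params["k3"], params["k4"],
                      params.get("vB", 0.0))
        a1, a2 = p2.alphas
        derived.update(VT=p2.VT, Vs=p2.Vs, Ki=p2.Ki, alpha1=a1, alpha2=a2)
    elif model == "SRTM":
        derived["k2a"] = params["k2"] / (1.0 + params["BPND"])

    return KineticFit(
        model=model, params=params, derived=derived, sswres=sswres,
        n=n, p=p,
        aic=selection.aic(n, p, sswres),
        sc=selection.sc(n, p, sswres),
        msc=selection.msc(w, y, fitted, p),
        converged=bool(result.success), stderr=stderr, fitted=fitted, seed=seed,
    )


def _pick_best(candidates):
    """Lowest sswres; ties (within 1e-12) broken by lowest K1, then lowest k3."""
    best_ss = min(c[0] for c in candidates)
    tied = [c for c in candidates if c[0] <= best_ss + 1e-12]
    tied.sort(key=lambda c: (c[1], c[2]))
    return tied[0]


def fit_compartment(tac: TimeActivityCurve, inp: InputFunction,
                    whole_blood: TimeActivityCurve | None = None,
                    model: str = "2TCM",
                    options: FitOptions = FitOptions()) -> KineticFit:
    """Weighted multistart least-squares fit of a compartment model to a TAC."""
    if model not in _PARAM_NAMES:
        raise ValueError(f"unknown model {model!r}")
    names = list(_PARAM_NAMES[model])
    if options.fit_vB:
        names.append("vB")
    schedule = tac.schedule
    y = tac.values
    n = y.size
    if n <= len(names):
        raise ValueError("need more frames than free parameters")

    w = options.weights(schedule)
    sw = np.sqrt(w)
    engine = ConvolutionEngine(inp, schedule)
    wb_vals = None if whole_blood is None else whole_blood.values

    def predict(theta):
        d = dict(zip(names, theta))
        vB = d.get("vB", options.vB_fixed)
        if model == "1TCM":
            tissue = _tissue_frame_avg_1t(engine, d["K1"], d["k2"])
        else:
            tissue = _tissue_frame_avg_2t(
                engine, Params2T(d["K1"], d["k2"], d["k3"], d["k4"]))
        out = (1.0 - vB) * tissue
        if vB > 0:
            out = out + vB * (wb_vals if wb_vals is not None
                              else engine.input_frame_avg())
        return out

    def residual(theta):
        return sw * (y - predict(theta))

    lo = np.array([options.bounds[nm][0] for nm in names])
    hi = np.array([options.bounds[nm][1] for nm in names])

    rng = np.random.default_rng(options.seed)
    starts = [np.array([{"K1": 0.1, "k2": 0.1, "k3": 0.05, "k4": 0.05,
                         "vB": 0.05}[nm] for nm in names])]
    for _ in range(options.multistart_count - 1):
        u = rng.uniform(size=len(names))
        log_lo = np.log(np.maximum(lo, 1e-3))
        log_hi = np.log(hi)
        starts.append(np.exp(log_lo + u * (log_hi - log_lo)))
    starts = [np.clip(s, lo + 1e-12, hi - 1e-12) for s in starts]

    candidates = []
    any_success = False
    for x0 in starts:
        try:
            res = least_squares(residual, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=400)
        except Exception:
            continue
        any_success = any_success or res.success
        ss = float(np.sum(res.fun ** 2))
        d = dict(zip(names, res.x))
        candidates.append((ss, d["K1"], d.get("k3", 0.0), res))
    if not candidates:
        raise RuntimeError("all optimizer starts failed to evaluate")
    ss, _, _, best = _pick_best(candidates)
    fit = _finalize_fit(model, names, best.x, best, y, w, schedule, options.seed)
    fit.converged = any_success and bool(best.success)
    return fit


# ---------------------------------------------------------------------------
# SRTM
# ---------------------------------------------------------------------------

def _reference_engine(reference: TimeActivityCurve) -> ConvolutionEngine:
    vals = np.clip(reference.values, 0.0, None)
    ref_inp = InputFunction(reference.midpoints, vals)
    return ConvolutionEngine(ref_inp, reference.schedule)


def fit_srtm(target: TimeActivityCurve, reference: TimeActivityCurve,
             options: FitOptions = FitOptions()) -> KineticFit:
    """SRTM via basis functions (200 log-spaced k2a in [0.005, 5]/min) + polish.

    For each candidate k2a the model is linear in (R1, theta2); the best basis
    by weighted residual sum of squares seeds a bounded local refinement of
    (R1, k2, BPND).
    """
    if target.schedule != reference.schedule:
        raise ValueError("target and reference must share a schedule")
    if np.all(reference.values <= 0):
        raise ValueError("reference TAC is degenerate (non-positive everywhere)")
    schedule = target.schedule
    y = target.values
    cr = reference.values
    w = options.weights(schedule)
    sw = np.sqrt(w)
    engine = _reference_engine(reference)

    k2a_grid = np.logspace(np.log10(0.005), np.log10(5.0), 200)
    best = None
    for k2a in k2a_grid:
        basis = engine.basis_frame_avg(k2a)
        A = np.column_stack([sw * cr, sw * basis])
        coef, *_ = np.linalg.lstsq(A, sw * y, rcond=None)
        ss = float(np.sum((sw * y - A @ coef) ** 2))
        if best is None or ss < best[0]:
            best = (ss, k2a, coef)
    _, k2a0, (r1_0, th2_0) = best
    k2_0 = th2_0 + r1_0 * k2a0
    bp_0 = k2_0 / k2a0 - 1.0 if k2a0 > 0 else 0.0

    def residual(theta):
        r1, k2, bp = theta
        k2a = k2 / (1.0 + bp)
        basis = engine.basis_frame_avg(k2a)
        pred = r1 * cr + (k2 - r1 * k2a) * basis
        return sw * (y - pred)

    x0 = np.clip([r1_0, max(k2_0, 1e-4), bp_0], [1e-6, 1e-6, -0.999], [20, 20, 100])
    res = least_squares(residual, x0, bounds=([1e-6, 1e-6, -0.999], [20, 20, 100]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=400)
    names = ["R1", "k2", "BPND"]
    fit = _finalize_fit("SRTM", names, res.x, res, y, w, schedule, options.seed)
    return fit


def srtm_assumption_check(target: TimeActivityCurve, reference: TimeActivityCurve,
                          inp: InputFunction,
                          options: FitOptions = FitOptions(),
                          max_vt_ratio: float = 2.0,
                          min_r2: float = 0.95) -> dict:
    """Diagnose whether the SRTM assumptions plausibly hold.

    Both regions should be well described by a 1TCM against the blood input,
    and their total distribution volumes should not be grossly discrepant
    (a VT ratio beyond ``max_vt_ratio`` indicates the shared-nondisplaceable
    -volume assumption is violated, as seen for high-grade tumors).
    """
    out = {}
    for label, tac in (("target", target), ("reference", reference)):
        fit = fit_compartment(tac, inp, model="1TCM", options=options)
        tot = float(np.sum((tac.values - tac.values.mean()) ** 2))
        r2 = 1.0 - fit.sswres / tot if tot > 0 else 0.0
        out[label] = {"VT": fit.derived["VT"], "r_squared": r2,
                      "one_tissue_ok": r2 >= min_r2}
    ratio = out["target"]["VT"] / out["reference"]["VT"]
    out["vt_ratio"] = ratio
    out["assumptions_ok"] = (out["target"]["one_tissue_ok"]
                             and out["reference"]["one_tissue_ok"]
                             and max(ratio, 1.0 / ratio) <= max_vt_ratio)
    return out
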