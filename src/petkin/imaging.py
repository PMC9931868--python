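"""Semi-quantitative and voxelwise outputs: MTV, TBR, parametric maps, ADC."""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import FrameSchedule, RoiMask, TimeActivityCurve, VoxelGrid4D
from .input_function import InputFunction
from .kinetic import FitOptions, fit_compartment


@dataclass
class MtvResult:
    """Metabolically active tumor volume at a relative threshold."""

    mask: RoiMask
    threshold_fraction: float
    threshold_value: float      # kBq/cm^3
    volume_cm3: float
    flagged_empty: bool = False


@dataclass
class ParametricMaps:
    """Voxelwise 2TCM parameter maps with a convergence mask.

    Non-converged or out-of-ROI voxels carry NaN.
    """

    maps: dict                  # name -> 3-D array (K1, k2, k3, k4, VT)
    converged: np.ndarray       # 3-D boolean


@dataclass
class AdcResult:
    """Apparent diffusion coefficient from a log-linear multi-b fit."""

    adc: float                  # mm^2/s
    s0: float
    r_squared: float


def _mean_image(grid: VoxelGrid4D, frame_window) -> np.ndarray:
    """Duration-weighted mean image over frames with midpoints in the window."""
    lo, hi = frame_window
    mids = grid.schedule.midpoints
    sel = (mids >= lo) & (mids <= hi)
    if not np.any(sel):
        raise ValueError("no frame midpoints fall inside the window")
    w = grid.schedule.durations[sel]
    return np.tensordot(grid.values[..., sel], w, axes=([3], [0])) / w.sum()


def segment_mtv(grid: VoxelGrid4D, roi: RoiMask, frame_window,
                threshold_fraction: float) -> MtvResult:
    """Threshold the windowed mean image at a fraction of the ROI maximum.

    Voxels exactly at the threshold are included.  MTV50 uses fraction 0.50
    (FET/fluciclovine); the lower-uptake PSMA tracer uses MTV75.
    """
    if roi.n_voxels == 0:
        raise ValueError("ROI is empty")
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold fraction must be in (0, 1)")
    img = _mean_image(grid, frame_window)
    roi_vals = img[roi.membership]
    thr = threshold_fraction * roi_vals.max()
    mask = roi.membership & (img >= thr)
    n = int(mask.sum())
    return MtvResult(
        mask=RoiMask(mask, label=f"mtv{int(round(threshold_fraction * 100))}"),
        threshold_fraction=threshold_fraction, threshold_value=float(thr),
        volume_cm3=n * grid.voxel_volume_cm3, flagged_empty=(n == 0))


def roi_mean_tac(grid: VoxelGrid4D, mask: RoiMask,
                 label: str = "roi") -> TimeActivityCurve:
    """Per-frame arithmetic mean over the mask."""
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    if mask.membership.shape != grid.spatial_shape:
        raise ValueError("mask dims must match grid spatial dims")
    vals = grid.values[mask.membership].mean(axis=0)
    return TimeActivityCurve(grid.schedule, vals, roi_label=label)


def compute_tbr(tumor: TimeActivityCurve, reference: TimeActivityCurve,
                at: float | None = None):
    """Tumor-to-background ratio against the contralateral reference.

    Returns the full per-frame TBR curve, and when ``at`` (minutes) is given,
    the ratio at the frame whose midpoint is nearest to it.
    """
    if tumor.schedule != reference.schedule:
        raise ValueError("tumor and reference must share a schedule")
    ref = reference.values
    with np.errstate(divide="ignore", invalid="ignore"):
        curve = np.where(ref > 0, tumor.values / ref, np.nan)
    if at is None:
        return tumor.with_values(curve, roi_label="tbr")
    idx = int(np.argmin(np.abs(tumor.midpoints - at)))
    if ref[idx] <= 0:
        raise ValueError("reference activity is non-positive at the queried frame")
    return float(tumor.values[idx] / ref[idx])


def fit_parametric_maps(grid: VoxelGrid4D, inp: InputFunction,
                        whole_blood: TimeActivityCurve | None,
                        roi: RoiMask,
                        options: FitOptions | None = None) -> ParametricMaps:
    """Voxelwise 2TCM fits within the ROI.

    Per-voxel seeds derive from the base seed plus the voxel's linear index,
    so maps are bit-reproducible.  Voxels with no signal are left as NaN with
    converged = False.  The default uses 5 multistarts per voxel (speed over
    the ROI-level default of 20).
    """
    if roi.n_voxels == 0:
        raise ValueError("ROI is empty")
    base = options or FitOptions(multistart_count=5)
    names = ("K1", "k2", "k3", "k4", "VT")
    shape = grid.spatial_shape
    maps = {nm: np.full(shape, np.nan) for nm in names}
    converged = np.zeros(shape, dtype=bool)
    for idx in np.argwhere(roi.membership):
        i, j, k = (int(v) for v in idx)
        vals = grid.values[i, j, k, :]
        if not np.any(vals > 0):
            continue
        vox_seed = base.seed + int(np.ravel_multi_index((i, j, k), shape))
        opts = replace(base, seed=vox_seed)
        tac = TimeActivityCurve(grid.schedule, np.clip(vals, 0.0, None))
        try:
            fit = fit_compartment(tac, inp, whole_blood, model="2TCM", options=opts)
        except Exception:
            continue
        if not fit.converged:
            continue
        for nm in ("K1", "k2", "k3", "k4"):
            maps[nm][i, j, k] = fit.params[nm]
        maps["VT"][i, j, k] = fit.derived["VT"]
        converged[i, j, k] = True
    return ParametricMaps(maps=maps, converged=converged)


def fit_adc(signals, bvalues) -> AdcResult:
    """ADC from the slope of the linear regression of ln(signal) on b.

    adc = -slope (mm^2/s for b in s/mm^2); s0 = exp(intercept).
    """
    s = np.asarray(signals, float)
    b = np.asarray(bvalues, float)
    if s.shape != b.shape or s.ndim != 1:
        raise ValueError("signals and bvalues must be 1-D and equal length")
    if np.unique(b).size < 2:
        raise ValueError("need at least 2 distinct b-values")
    if np.any(s <= 0):
        raise ValueError("signals must be positive for the log-linear fit")
    logs = np.log(s)
    slope, intercept = np.polyfit(b, logs, 1)
    yhat = slope * b + intercept
    ss_res = float(np.sum((logs - yhat) ** 2))
    ss_tot = float(np.sum((logs - logs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return AdcResult(adc=float(-slope), s0=float(np.exp(intercept)),
                     r_squared=max(min(r2, 1.0), 0.0))
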