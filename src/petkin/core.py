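"""Core domain types, TAC table I/O and numerical primitives.

Conventions
-----------
* Internal time unit is **minutes**; all rate constants are per minute.
  TAC tables on disk use **seconds** (scanner convention) and are converted
  at the I/O boundary.
* Activity concentrations are kBq/cm^3 unless converted to SUV.
* TAC values are frame-averaged concentrations, already decay-corrected by
  reconstruction; no decay correction is applied downstream.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

SEC_PER_MIN = 60.0

#: Tracers studied in the GL261-luc2 glioblastoma cohorts.
TRACERS = ("rhPSMA73", "FET", "fluciclovine")


@dataclass(frozen=True)
class FrameSchedule:
    """Dynamic PET frame schedule (contiguous frames, minutes).

    Parameters
    ----------
    starts : array
        Frame start times in minutes, first frame starts at 0.
    durations : array
        Frame durations in minutes, all positive.
    """

    starts: np.ndarray
    durations: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)
        if starts.ndim != 1 or starts.shape != durations.shape:
            raise ValueError("starts and durations must be 1-D and equal length")
        if starts.size == 0:
            raise ValueError("schedule needs at least one frame")
        if abs(starts[0]) > 1e-12:
            raise ValueError("first frame must start at t = 0")
        if np.any(durations <= 0):
            raise ValueError("all frame durations must be positive")
        if not np.allclose(starts[1:], starts[:-1] + durations[:-1], atol=1e-9):
            raise ValueError("frames must be contiguous (start[i+1] = start[i] + duration[i])")

    @classmethod
    def from_seconds(cls, starts_s, durations_s) -> "FrameSchedule":
        return cls(np.asarray(starts_s, float) / SEC_PER_MIN,
                   np.asarray(durations_s, float) / SEC_PER_MIN)

    @classmethod
    def from_durations(cls, durations_min) -> "FrameSchedule":
        d = np.asarray(durations_min, dtype=float)
        starts = np.concatenate([[0.0], np.cumsum(d)[:-1]])
        return cls(starts, d)

    @classmethod
    def paper_schedule(cls, total_min: int) -> "FrameSchedule":
        """The acquisition schedules used in the mouse studies.

        24 x 5 s, 8 x 60 s, then 10 (60 min) or 16 (90 min) x 300 s frames.
        """
        if total_min == 60:
            n300 = 10
        elif total_min == 90:
            n300 = 16
        else:
            raise ValueError("paper schedules are 60 or 90 minutes")
        dur_s = [5.0] * 24 + [60.0] * 8 + [300.0] * n300
        return cls.from_durations(np.asarray(dur_s) / SEC_PER_MIN)

    @property
    def n_frames(self) -> int:
        return self.starts.size

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.durations

    @property
    def midpoints(self) -> np.ndarray:
        return self.starts + self.durations / 2.0

    @property
    def total_duration(self) -> float:
        return float(self.ends[-1])

    def __eq__(self, other) -> bool:
        return (isinstance(other, FrameSchedule)
                and self.n_frames == other.n_frames
                and np.allclose(self.starts, other.starts, atol=1e-9)
                and np.allclose(self.durations, other.durations, atol=1e-9))


def frame_midpoints(schedule: FrameSchedule) -> np.ndarray:
    """Frame midpoint times in minutes: (start + duration/2) / 1."""
    return schedule.midpoints


@dataclass(frozen=True)
class TimeActivityCurve:
    """Activity concentration per frame for one region of interest."""

    schedule: FrameSchedule
    values: np.ndarray          # kBq/cm^3 (or SUV after normalisation)
    roi_label: str = ""
    sd: np.ndarray | None = None

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (self.schedule.n_frames,):
            raise ValueError("values length must equal frame count")
        if not np.all(np.isfinite(values)):
            raise ValueError("TAC values must be finite")
        if self.sd is not None:
            sd = np.asarray(self.sd, dtype=float)
            object.__setattr__(self, "sd", sd)
            if sd.shape != values.shape:
                raise ValueError("sd length must equal frame count")
            if np.any(sd < 0):
                raise ValueError("sd must be non-negative")

    @property
    def midpoints(self) -> np.ndarray:
        return self.schedule.midpoints

    def with_values(self, values, roi_label: str | None = None) -> "TimeActivityCurve":
        return replace(self, values=np.asarray(values, float),
                       roi_label=self.roi_label if roi_label is None else roi_label)


@dataclass(frozen=True)
class StudyMeta:
    """Injection metadata for one animal scan (SUV normalisation)."""

    tracer: str
    injected_dose_kbq: float
    body_weight_g: float
    day_post_inoculation: int = 28
    animal_id: str = ""

    def __post_init__(self):
        if self.tracer not in TRACERS:
            raise ValueError(f"unknown tracer {self.tracer!r}; expected one of {TRACERS}")
        if self.injected_dose_kbq <= 0:
            raise ValueError("injected dose must be positive")
        if self.body_weight_g <= 0:
            raise ValueError("body weight must be positive")


@dataclass(frozen=True)
class VoxelGrid4D:
    """Small 4-D dynamic volume (x, y, z, frame), kBq/cm^3 per voxel."""

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    schedule: FrameSchedule

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 4:
            raise ValueError("VoxelGrid4D values must be 4-D (x, y, z, frames)")
        if values.shape[3] != self.schedule.n_frames:
            raise ValueError("frame axis must match schedule frame count")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    @property
    def voxel_volume_cm3(self) -> float:
        vx, vy, vz = self.voxel_size_mm
        return vx * vy * vz / 1000.0


@dataclass(frozen=True)
class RoiMask:
    """Boolean voxel membership volume, shape-matched to a VoxelGrid4D."""

    membership: np.ndarray
    label: str = ""

    def __post_init__(self):
        m = np.asarray(self.membership, dtype=bool)
        object.__setattr__(self, "membership", m)
        if m.ndim != 3:
            raise ValueError("RoiMask must be 3-D")

    @property
    def n_voxels(self) -> int:
        return int(self.membership.sum())


# ---------------------------------------------------------------------------
# TAC table I/O (CSV, seconds on disk)
# ---------------------------------------------------------------------------

def read_tac_table(path) -> list[TimeActivityCurve]:
    """Read a TAC table.

    The CSV has header columns ``frame_start_s`` and ``frame_duration_s``
    followed by one value column per ROI; an optional ``<roi>_sd`` column
    holds per-frame standard deviations.
    """
    df = pd.read_csv(path)
    for col in ("frame_start_s", "frame_duration_s"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df.isna().any().any():
        row = int(np.where(df.isna().any(axis=1))[0][0])
        raise ValueError(f"{path}: ragged/missing data at row {row}")
    starts = df["frame_start_s"].to_numpy(float)
    durs = df["frame_duration_s"].to_numpy(float)
    if np.any(np.diff(starts) <= 0):
        row = int(np.where(np.diff(starts) <= 0)[0][0]) + 1
        raise ValueError(f"{path}: non-monotone frame_start_s at row {row}")
    if np.any(durs <= 0):
        row = int(np.where(durs <= 0)[0][0])
        raise ValueError(f"{path}: non-positive frame_duration_s at row {row}")
    gap = ~np.isclose(starts[1:], starts[:-1] + durs[:-1], atol=1e-6)
    if np.any(gap):
        row = int(np.where(gap)[0][0]) + 1
        raise ValueError(f"{path}: frames not contiguous at row {row}")
    schedule = FrameSchedule.from_seconds(starts, durs)
    roi_cols = [c for c in df.columns
                if c not in ("frame_start_s", "frame_duration_s") and not c.endswith("_sd")]
    tacs = []
    for roi in roi_cols:
        sd = df[f"{roi}_sd"].to_numpy(float) if f"{roi}_sd" in df.columns else None
        tacs.append(TimeActivityCurve(schedule, df[roi].to_numpy(float),
                                      roi_label=roi, sd=sd))
    return tacs


def write_tac_table(tacs: list[TimeActivityCurve], path) -> None:
    """Write TACs sharing one schedule to the CSV dialect of read_tac_table."""
    if not tacs:
        raise ValueError("no TACs to write")
    schedule = tacs[0].schedule
    for t in tacs[1:]:
        if t.schedule != schedule:
            raise ValueError("all TACs in one table must share a schedule")
    data = {
        "frame_start_s": schedule.starts * SEC_PER_MIN,
        "frame_duration_s": schedule.durations * SEC_PER_MIN,
    }
    for t in tacs:
        data[t.roi_label] = t.values
        if t.sd is not None:
            data[f"{t.roi_label}_sd"] = t.sd
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Numerical primitives
# ---------------------------------------------------------------------------

def cumulative_integral(tac: TimeActivityCurve) -> np.ndarray:
    """Running integral of a TAC at its frame midpoints, kBq*min/cm^3.

    Trapezoidal rule on the midpoint samples, anchored by a virtual point
    (t=0, C=0) before the first midpoint (bolus injection starts at zero
    activity), so the first element is the initial triangle area.
    """
    if tac.schedule.n_frames < 2:
        raise ValueError("cumulative_integral needs at least 2 frames")
    t = tac.midpoints
    v = tac.values
    out = np.empty_like(v)
    out[0] = 0.5 * t[0] * v[0]
    out[1:] = 0.5 * (v[1:] + v[:-1]) * np.diff(t)
    return np.cumsum(out)


def to_suv(tac: TimeActivityCurve, meta: StudyMeta) -> TimeActivityCurve:
    """Normalise a TAC to SUV: C [kBq/cm^3] / (dose [kBq] / weight [g])."""
    factor = meta.body_weight_g / meta.injected_dose_kbq
    sd = None if tac.sd is None else tac.sd * factor
    return replace(tac, values=tac.values * factor, sd=sd)


# ---------------------------------------------------------------------------
# NIfTI I/O for volumes and masks
# ---------------------------------------------------------------------------

def save_grid_nifti(grid: VoxelGrid4D, path) -> None:
    import nibabel as nib
    affine = np.diag([*grid.voxel_size_mm, 1.0])
    img = nib.Nifti1Image(grid.values.astype(np.float64), affine)
    img.header.set_zooms((*grid.voxel_size_mm, 1.0))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))


def load_grid_nifti(path, schedule: FrameSchedule) -> VoxelGrid4D:
    import nibabel as nib
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return VoxelGrid4D(np.asarray(img.get_fdata(), float), tuple(float(z) for z in zooms),
                       schedule)


def save_mask_nifti(mask: RoiMask, voxel_size_mm, path) -> None:
    import nibabel as nib
    affine = np.diag([*voxel_size_mm, 1.0])
    img = nib.Nifti1Image(mask.membership.astype(np.uint8), affine)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))


def load_mask_nifti(path, label: str = "") -> RoiMask:
    import nibabel as nib
    img = nib.load(str(path))
    return RoiMask(np.asarray(img.get_fdata()) > 0.5, label=label)
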