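"""Core data containers for dynamic PET quantification.

The time axis of every analysis is a :class:`FrameSchedule` — the sequence of
acquisition frame start times and durations.  Regional and voxel measurements
are :class:`TimeActivityCurve` objects (frame-resolved radioactivity
concentration, decay-corrected to injection time), 4-D scans are
:class:`DynamicImage` and label volumes are :class:`RoiMask`.

All activity values are assumed decay-corrected to injection time, the
standard scanner output; the isotope decay constant enters only the noise
model and the exponent-grid derivation of the basis-function analysis.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "DynamicImage",
    "RoiMask",
    "build_frame_schedule",
    "extract_roi_tac",
    "read_tac_table",
    "write_tac_table",
]

VALID_UNITS = ("kBq/cm3", "SUV")


class ScheduleParseError(ValueError):
    """Raised when a frame-schedule specification string cannot be parsed."""


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping acquisition frames starting at injection.

    Parameters
    ----------
    frame_start : array of float
        Frame start times in seconds from injection; ``frame_start[0] == 0``.
    frame_duration : array of float
        Frame durations in seconds, all positive.
    """

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)
        if start.ndim != 1 or dur.shape != start.shape or start.size == 0:
            raise ValueError("frame_start and frame_duration must be equal-length 1-D arrays")
        if not np.all(dur > 0):
            raise ValueError("all frame durations must be > 0")
        if start[0] != 0:
            raise ValueError("first frame must start at t = 0")
        if not np.allclose(start[1:], start[:-1] + dur[:-1], rtol=0, atol=1e-9):
            raise ValueError("frames must be contiguous and non-overlapping")
        if not np.all(np.diff(self.mid_times_s) > 0):
            raise ValueError("frame mid-times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frame_start.size

    @property
    def frame_end_s(self) -> np.ndarray:
        return self.frame_start + self.frame_duration

    @property
    def mid_times_s(self) -> np.ndarray:
        """Frame mid-times in seconds; the TAC's time coordinate for fitting."""
        return self.frame_start + 0.5 * self.frame_duration

    @property
    def mid_times_min(self) -> np.ndarray:
        return self.mid_times_s / 60.0

    @property
    def total_duration_s(self) -> float:
        return float(self.frame_end_s[-1])

    @property
    def total_duration_min(self) -> float:
        return self.total_duration_s / 60.0

    def truncate(self, duration_min: float) -> "FrameSchedule":
        """Keep the frames whose end falls within ``duration_min`` minutes."""
        keep = self.frame_end_s <= duration_min * 60.0 + 1e-9
        if not np.any(keep):
            raise ValueError(f"no frames end within {duration_min} min")
        return FrameSchedule(self.frame_start[keep], self.frame_duration[keep])

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame_start": self.frame_start, "frame_duration": self.frame_duration}
        )

    def __repr__(self):  # pragma: no cover - cosmetic
        return (
            f"FrameSchedule(n_frames={self.n_frames}, "
            f"total={self.total_duration_min:g} min)"
        )


def build_frame_schedule(spec: str) -> FrameSchedule:
    """Parse a compact schedule string like ``"9x10,2x15,3x20,4x30,4x60,4x180,12x360"``.

    Each comma-separated token is ``<count>x<duration_s>`` with positive
    integers.  Frames are laid out contiguously starting at t = 0.
    """
    if not isinstance(spec, str) or not spec.strip():
        raise ScheduleParseError("empty frame-schedule specification")
    durations: list[float] = []
    for token in spec.split(","):
        token = token.strip()
        parts = token.split("x")
        if len(parts) != 2:
            raise ScheduleParseError(f"malformed token {token!r}: expected countxduration")
        try:
            count, dur = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise ScheduleParseError(f"malformed token {token!r}: {exc}") from None
        if count <= 0 or dur <= 0:
            raise ValueError(f"token {token!r}: count and duration must be positive")
        durations.extend([float(dur)] * count)
    dur = np.asarray(durations)
    start = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
    return FrameSchedule(start, dur)


@dataclass
class TimeActivityCurve:
    """Frame-resolved radioactivity concentration for one ROI or voxel.

    ``values`` are kBq/cm3 decay-corrected to injection time (or SUV after
    metadata-driven relabeling; quantification always runs on kBq/cm3).
    """

    schedule: FrameSchedule
    values: np.ndarray
    label: str = "roi"
    units: str = "kBq/cm3"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.schedule.n_frames,):
            raise ValueError(
                f"values length {self.values.size} != number of frames "
                f"{self.schedule.n_frames}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TAC values must be finite")
        if self.units not in VALID_UNITS:
            raise ValueError(f"units must be one of {VALID_UNITS}")

    @property
    def mid_times_min(self) -> np.ndarray:
        return self.schedule.mid_times_min

    def truncate(self, duration_min: float) -> "TimeActivityCurve":
        sched = self.schedule.truncate(duration_min)
        return TimeActivityCurve(sched, self.values[: sched.n_frames], self.label, self.units)

    def to_suv(self, injected_dose_MBq: float, body_weight_kg: float) -> "TimeActivityCurve":
        """Relabel kBq/cm3 values as SUV using injected dose and body weight.

        SUV = C [kBq/cm3] / (dose [kBq] / weight [g]); pure metadata-driven
        rescaling, no change to the kinetic analysis (which uses kBq/cm3).
        """
        if self.units != "kBq/cm3":
            raise ValueError("to_suv expects a kBq/cm3 curve")
        factor = (body_weight_kg * 1000.0) / (injected_dose_MBq * 1000.0)
        return TimeActivityCurve(self.schedule, self.values * factor, self.label, "SUV")

    def to_table(self) -> pd.DataFrame:
        df = self.schedule.to_table()
        df["value"] = self.values
        df["label"] = self.label
        return df


def write_tac_table(path, tacs, sep: str = ",") -> None:
    """Write one or more TACs sharing a schedule to a delimited text table."""
    if isinstance(tacs, TimeActivityCurve):
        tacs = [tacs]
    frames = [t.to_table() for t in tacs]
    # %.17g guarantees a value-exact write -> read round trip for float64
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False,
                                                float_format="%.17g")


def read_tac_table(path, sep: str = ",") -> list[TimeActivityCurve]:
    """Read TAC(s) from a delimited table with columns
    frame_start, frame_duration, value, label.  Schedule invariants are
    re-validated on read; the write→read round trip is value-exact.
    """
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    required = {"frame_start", "frame_duration", "value", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TAC table missing required column(s): {sorted(missing)}")
    out = []
    for label, grp in df.groupby("label", sort=False):
        sched = FrameSchedule(grp["frame_start"].to_numpy(), grp["frame_duration"].to_numpy())
        out.append(TimeActivityCurve(sched, grp["value"].to_numpy(), label=str(label)))
    return out


@dataclass
class DynamicImage:
    """A 4-D dynamic PET image: 3 spatial dimensions x frames, kBq/cm3."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    schedule: FrameSchedule

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DynamicImage data must be 4-D (x, y, z, frame)")
        if self.data.shape[3] != self.schedule.n_frames:
            raise ValueError("4th dimension must equal the schedule frame count")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be > 0")

    @property
    def shape(self):
        return self.data.shape

    def to_nifti(self, path) -> None:
        affine = np.diag(list(self.voxel_size_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.data, affine), os.fspath(path))
        self.schedule.to_table().to_csv(os.fspath(path) + ".frames.csv", index=False)

    @classmethod
    def from_nifti(cls, path, schedule: FrameSchedule | None = None) -> "DynamicImage":
        img = nib.load(os.fspath(path))
        vox = tuple(float(z) for z in img.header.get_zooms()[:3])
        if schedule is None:
            df = pd.read_csv(os.fspath(path) + ".frames.csv")
            schedule = FrameSchedule(df["frame_start"].to_numpy(), df["frame_duration"].to_numpy())
        return cls(np.asarray(img.dataobj, dtype=float), vox, schedule)


@dataclass
class RoiMask:
    """Integer label volume on the dynamic-image grid.

    ``labels`` maps names to label values, e.g. {"lung": 1, "aorta": 2,
    "excluded": 255}.  Masks are assumed co-registered to the PET grid by
    construction.
    """

    data: np.ndarray
    labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("RoiMask data must be 3-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            self.data = self.data.astype(np.int32)
        if self.data.min() < 0:
            raise ValueError("mask labels must be nonnegative")

    def resolve(self, label) -> int:
        if isinstance(label, str):
            if label not in self.labels:
                raise KeyError(f"label {label!r} not in mask label dictionary {self.labels}")
            return self.labels[label]
        return int(label)

    def to_nifti(self, path, voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
        affine = np.diag(list(voxel_size_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.int16), affine), os.fspath(path))

    @classmethod
    def from_nifti(cls, path, labels=None) -> "RoiMask":
        img = nib.load(os.fspath(path))
        return cls(np.asarray(img.dataobj).astype(np.int32), labels or {})


def extract_roi_tac(
    img: DynamicImage, mask: RoiMask, label, name: str | None = None
) -> TimeActivityCurve:
    """Per-frame mean over the voxels carrying ``label``; inherits the schedule."""
    value = mask.resolve(label)
    if mask.data.shape != img.data.shape[:3]:
        raise ValueError("mask shape does not match image spatial shape")
    sel = mask.data == value
    if not np.any(sel):
        raise ValueError(f"label {label!r} (value {value}) selects no voxels")
    tac = img.data[sel].mean(axis=0)
    return TimeActivityCurve(img.schedule, tac, label=name or str(label))
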