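"""Sweeping-bar mapping stimulus: bar masks and the aperture movie.

The mapping protocol presents a narrow bar that traverses a circular region
of the visual field in discrete one-second jumps.  A run consists of eight
sweeps (the sweep direction rotating 45° clockwise each time, starting with
bottom-to-top), with a blank baseline block after the fourth and eighth
sweep, preceded by dummy volumes discarded from analysis.  The pRF forward
model consumes only the binary aperture — which pixels of the visual field
carry stimulus energy at each frame — so the movie is a stack of binary
masks on a square pixel grid spanning the aperture's bounding box.

Conventions: visual-field x increases rightward, y upward, origin at
fixation; the pixel at index (row i, col j) has its centre at
``x = (j + 0.5) * deg_per_px - radius`` and ``y = (i + 0.5) * deg_per_px -
radius`` (row 0 is the bottom of the visual field).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np

__all__ = [
    "BarDesign",
    "FrameLabel",
    "ApertureMovie",
    "bar_mask",
    "generate_apertures",
]

#: Compass labels for the first sweep direction, as angles of the direction
#: of bar *motion* in visual-field coordinates (deg counter-clockwise from +x).
_DIRECTION_ANGLES = {
    "bottom-to-top": 90.0,
    "left-to-right": 0.0,
    "top-to-bottom": 270.0,
    "right-to-left": 180.0,
}


@dataclass(frozen=True)
class BarDesign:
    """Parameters of one mapping run's bar protocol.

    ``step_deg_per_s`` holds the literal printed step size (0.38°/s); with
    the default ``step_mode="full-coverage"`` the effective step is instead
    ``aperture_diameter_deg / steps_per_sweep`` (0.76°) so that 25 steps
    traverse the full aperture.  ``step_mode="literal"`` uses 0.38° exactly,
    mapping only the central strip.
    """

    aperture_diameter_deg: float = 19.0
    bar_width_deg: float = 0.53
    step_deg_per_s: float = 0.38
    step_mode: str = "full-coverage"
    steps_per_sweep: int = 25
    n_sweeps: int = 8
    first_sweep_direction: str | float = "bottom-to-top"
    rotation_per_sweep_deg: float = 45.0
    baseline_after_sweeps: tuple[int, ...] = (4, 8)
    baseline_duration_s: float = 25.0
    n_dummies: int = 10
    mask_resolution_px: int = 100
    frame_duration_s: float = 1.0
    central_hole_deg: float = 0.53  # radius of the unstimulated foveal hole

    def __post_init__(self) -> None:
        if self.aperture_diameter_deg <= 0 or self.bar_width_deg <= 0:
            raise ValueError("aperture diameter and bar width must be positive")
        if self.steps_per_sweep < 1 or self.n_sweeps < 1:
            raise ValueError("steps_per_sweep and n_sweeps must be positive")
        if self.baseline_duration_s <= 0 or self.frame_duration_s <= 0:
            raise ValueError("durations must be positive")
        if self.n_dummies < 0:
            raise ValueError("n_dummies must be nonnegative")
        if self.mask_resolution_px < 16:
            raise ValueError("mask_resolution_px must be at least 16")
        if self.step_mode not in ("full-coverage", "literal"):
            raise ValueError(f"unknown step_mode: {self.step_mode!r}")
        if any(b < 1 or b > self.n_sweeps for b in self.baseline_after_sweeps):
            raise ValueError("baseline_after_sweeps indices must be in 1..n_sweeps")
        if isinstance(self.first_sweep_direction, str):
            if self.first_sweep_direction not in _DIRECTION_ANGLES:
                raise ValueError(
                    f"unknown direction label: {self.first_sweep_direction!r}"
                )

    @property
    def aperture_radius_deg(self) -> float:
        return self.aperture_diameter_deg / 2.0

    @property
    def deg_per_px(self) -> float:
        return self.aperture_diameter_deg / self.mask_resolution_px

    @property
    def step_size_deg(self) -> float:
        """Effective bar step per frame, depending on ``step_mode``."""
        if self.step_mode == "full-coverage":
            return self.aperture_diameter_deg / self.steps_per_sweep
        return self.step_deg_per_s * self.frame_duration_s

    @property
    def first_direction_deg(self) -> float:
        if isinstance(self.first_sweep_direction, str):
            angle = _DIRECTION_ANGLES[self.first_sweep_direction]
        else:
            angle = float(self.first_sweep_direction)
        return angle % 360.0

    def sweep_direction_deg(self, sweep: int) -> float:
        """Direction of motion of sweep ``sweep`` (1-based).

        Clockwise rotation in a y-up coordinate frame decreases the angle.
        """
        if not 1 <= sweep <= self.n_sweeps:
            raise ValueError(f"sweep must be in 1..{self.n_sweeps}")
        return (
            self.first_direction_deg - (sweep - 1) * self.rotation_per_sweep_deg
        ) % 360.0

    @property
    def n_baseline_frames(self) -> int:
        per_block = int(round(self.baseline_duration_s / self.frame_duration_s))
        return len(self.baseline_after_sweeps) * per_block

    def n_frames(self, include_dummies: bool = True) -> int:
        n = self.n_sweeps * self.steps_per_sweep + self.n_baseline_frames
        if include_dummies:
            n += self.n_dummies
        return n

    def pixel_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Visual-field coordinates (X, Y) of pixel centres, each px × px."""
        r = self.aperture_radius_deg
        centres = (np.arange(self.mask_resolution_px) + 0.5) * self.deg_per_px - r
        X, Y = np.meshgrid(centres, centres)  # Y varies along rows (y-up)
        return X, Y


class FrameLabel(NamedTuple):
    """Schedule entry for a single frame of the aperture movie."""

    kind: str  # "dummy" | "bar" | "baseline"
    sweep: int  # 1-based sweep index, 0 for non-bar frames
    step: int  # 0-based step within sweep, -1 for non-bar frames


@dataclass
class ApertureMovie:
    """Time-ordered stack of binary visual-field masks.

    frames has shape (n_frames, px, px) with entries in {0, 1}; ``schedule``
    labels each frame as dummy, bar (with sweep and step), or baseline.
    """

    frames: np.ndarray
    deg_per_px: float
    frame_duration_s: float
    schedule: list[FrameLabel]
    design: BarDesign | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[1] != self.frames.shape[2]:
            raise ValueError("frames must be (n_frames, px, px)")
        if len(self.schedule) != self.frames.shape[0]:
            raise ValueError("schedule length must match frame count")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def resolution_px(self) -> int:
        return int(self.frames.shape[1])

    @property
    def aperture_radius_deg(self) -> float:
        return self.resolution_px * self.deg_per_px / 2.0

    def pixel_grid(self) -> tuple[np.ndarray, np.ndarray]:
        r = self.aperture_radius_deg
        centres = (np.arange(self.resolution_px) + 0.5) * self.deg_per_px - r
        return np.meshgrid(centres, centres)

    def flat_frames(self) -> np.ndarray:
        """(n_frames, n_pixels) float view used by the forward model."""
        return self.frames.reshape(self.n_frames, -1).astype(np.float64)

    def without_dummies(self) -> "ApertureMovie":
        keep = [i for i, lab in enumerate(self.schedule) if lab.kind != "dummy"]
        return ApertureMovie(
            frames=self.frames[keep],
            deg_per_px=self.deg_per_px,
            frame_duration_s=self.frame_duration_s,
            schedule=[self.schedule[i] for i in keep],
            design=self.design,
        )

    # -- I/O ---------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a NIfTI stack (px × px × time) with a JSON sidecar."""
        import nibabel as nib

        path = Path(path)
        img = nib.Nifti1Image(
            np.moveaxis(self.frames, 0, -1).astype(np.uint8), affine=np.eye(4)
        )
        nib.save(img, str(path))
        sidecar = {
            "deg_per_px": self.deg_per_px,
            "frame_duration_s": self.frame_duration_s,
            "schedule": [list(lab) for lab in self.schedule],
        }
        path.with_suffix("").with_suffix(".json").write_text(
            json.dumps(sidecar, indent=1)
        )

    @classmethod
    def load(cls, path: str | Path) -> "ApertureMovie":
        import nibabel as nib

        path = Path(path)
        img = nib.load(str(path))
        frames = np.moveaxis(np.asarray(img.dataobj), -1, 0).astype(np.uint8)
        sidecar = json.loads(path.with_suffix("").with_suffix(".json").read_text())
        schedule = [FrameLabel(k, int(s), int(j)) for k, s, j in sidecar["schedule"]]
        return cls(
            frames=frames,
            deg_per_px=float(sidecar["deg_per_px"]),
            frame_duration_s=float(sidecar["frame_duration_s"]),
            schedule=schedule,
        )


def _bar_positions(design: BarDesign) -> np.ndarray:
    """Centre offsets of the bar along the sweep axis, symmetric about fixation."""
    n = design.steps_per_sweep
    return (np.arange(n) - (n - 1) / 2.0) * design.step_size_deg


def bar_mask(step_index: int, orientation_deg: float, design: BarDesign) -> np.ndarray:
    """Binary mask of the bar at one step of a sweep.

    ``orientation_deg`` is the direction of bar *motion* (the bar itself is
    perpendicular to it).  A pixel is 1 iff its centre lies inside the bar
    strip, inside the circular aperture, and outside the central foveal hole.
    """
    if not 0 <= step_index < design.steps_per_sweep:
        raise ValueError(
            f"step_index must be in 0..{design.steps_per_sweep - 1}, got {step_index}"
        )
    X, Y = design.pixel_grid()
    theta = np.deg2rad(orientation_deg % 360.0)
    along = X * np.cos(theta) + Y * np.sin(theta)
    pos = _bar_positions(design)[step_index]
    R = np.hypot(X, Y)
    mask = (
        (np.abs(along - pos) <= design.bar_width_deg / 2.0)
        & (R <= design.aperture_radius_deg)
        & (R >= design.central_hole_deg)
    )
    return mask.astype(np.uint8)


def generate_apertures(design: BarDesign, include_dummies: bool = True) -> ApertureMovie:
    """Build the full aperture movie for one run.

    Frame order: [dummies] then sweeps 1..n_sweeps, with a baseline block
    inserted after each sweep listed in ``baseline_after_sweeps``.  Sweep k's
    motion direction is the first direction rotated (k−1)·45° clockwise.
    Dummy and baseline frames are all-zero.
    """
    px = design.mask_resolution_px
    zero = np.zeros((px, px), dtype=np.uint8)
    per_baseline = int(round(design.baseline_duration_s / design.frame_duration_s))

    frames: list[np.ndarray] = []
    schedule: list[FrameLabel] = []
    if include_dummies:
        for _ in range(design.n_dummies):
            frames.append(zero)
            schedule.append(FrameLabel("dummy", 0, -1))
    for sweep in range(1, design.n_sweeps + 1):
        direction = design.sweep_direction_deg(sweep)
        for step in range(design.steps_per_sweep):
            frames.append(bar_mask(step, direction, design))
            schedule.append(FrameLabel("bar", sweep, step))
        if sweep in design.baseline_after_sweeps:
            for _ in range(per_baseline):
                frames.append(zero)
                schedule.append(FrameLabel("baseline", 0, -1))
    return ApertureMovie(
        frames=np.stack(frames),
        deg_per_px=design.deg_per_px,
        frame_duration_s=design.frame_duration_s,
        schedule=schedule,
        design=design,
    )


def aperture_coverage(movie: ApertureMovie) -> float:
    """Fraction of aperture pixels touched by at least one bar frame.

    The central foveal hole is never stimulated by construction, so with the
    full-coverage step mode this sits just below 1.
    """
    X, Y = movie.pixel_grid()
    inside = np.hypot(X, Y) <= movie.aperture_radius_deg
    union = movie.frames.any(axis=0)
    return float(union[inside].sum() / inside.sum())
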