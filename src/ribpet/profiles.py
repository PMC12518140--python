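"""Depth-profile range-verification metrics.

In-beam PET range verification compares the depth profile of the delivered
dose with the depth profile of the implanted positron activity.  Both are
reduced from 3-D volumes by summing over a narrow beam's-eye-view (BEV)
aperture around the beam axis, normalised to their maximum, and characterised
by two scalar depths: the (sub-sample refined) peak depth and the distal
depth where the falling edge crosses a given level (80% by default).  For a
radioactive ion beam the activity peak is expected to align with the 80%
distal fall-off of the spread-out Bragg peak dose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DepthProfile",
    "Volume3D",
    "bev_profile",
    "normalize_max",
    "distal_falloff_depth",
    "peak_depth",
    "range_shift",
]


@dataclass(frozen=True)
class DepthProfile:
    """Dose or activity versus depth on a uniform, strictly increasing grid.

    ``depths`` are voxel/bin-centre depths in mm (water-equivalent, beam
    travelling towards increasing depth); ``values`` are nonnegative and in
    arbitrary units.
    """

    depths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.depths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if d.ndim != 1 or v.ndim != 1 or d.size != v.size:
            raise ValueError("depths and values must be 1-D arrays of equal length")
        if d.size < 2:
            raise ValueError("a profile needs at least 2 samples")
        steps = np.diff(d)
        if np.any(steps <= 0):
            raise ValueError("depths must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("depth grid must be uniform")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("values must be finite and >= 0")
        object.__setattr__(self, "depths", d)
        object.__setattr__(self, "values", v)

    @property
    def step(self) -> float:
        return float(self.depths[1] - self.depths[0])

    def __len__(self) -> int:
        return self.depths.size


@dataclass(frozen=True)
class Volume3D:
    """A 3-D scalar field on a regular voxel grid.

    Axis convention: index 0 = x (lateral), 1 = y (vertical), 2 = z (beam
    depth).  ``spacing`` is mm per voxel along each axis and ``origin`` the
    position (mm) of the centre of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        if vox.ndim != 3:
            raise ValueError("voxels must be a 3-D array")
        if not np.all(np.isfinite(vox)):
            raise ValueError("voxel values must be finite")
        if np.any(vox < 0):
            raise ValueError("voxel values must be >= 0")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError("spacing must be three positive lengths")
        origin = tuple(float(o) for o in self.origin)
        if len(origin) != 3:
            raise ValueError("origin must have three components")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates (mm) along one axis."""
        n = self.voxels.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)


def bev_profile(
    vol: Volume3D,
    center_xy: tuple[float, float] = (0.0, 0.0),
    half_aperture: float = 1.0,
) -> DepthProfile:
    """Laterally integrate a volume over a BEV aperture into a depth profile.

    Sums, per depth slice, all voxels whose x and y centres lie within
    ``+-half_aperture`` mm of ``center_xy`` (inclusive on both boundaries).

    Raises
    ------
    ValueError
        If no voxel centre falls inside the aperture.
    """
    if half_aperture <= 0:
        raise ValueError("half_aperture must be > 0")
    cx, cy = center_xy
    x = vol.axis_coords(0)
    y = vol.axis_coords(1)
    mx = np.abs(x - cx) <= half_aperture
    my = np.abs(y - cy) <= half_aperture
    if not mx.any() or not my.any():
        raise ValueError("aperture contains no voxel centres")
    values = vol.voxels[mx][:, my, :].sum(axis=(0, 1))
    return DepthProfile(vol.axis_coords(2), values)


def normalize_max(p: DepthProfile) -> DepthProfile:
    """Scale a profile so its maximum equals 1."""
    m = float(np.max(p.values))
    if m <= 0:
        raise ValueError("cannot normalize an all-zero profile")
    return DepthProfile(p.depths, p.values / m)


def _deepest_max_index(values: np.ndarray) -> int:
    """Index of the maximum; ties broken toward the deeper depth."""
    m = values.max()
    return int(np.flatnonzero(values == m)[-1])


def peak_depth(p: DepthProfile) -> float:
    """Depth (mm) of the profile maximum with 3-point parabolic refinement.

    The refinement fits a parabola through the maximal sample and its two
    neighbours, recovering sub-grid peak positions for smooth profiles.  Ties
    (plateaus of equal maxima) resolve to the deepest plateau sample, where
    the parabolic correction degenerates and is skipped.
    """
    v = p.values
    i = _deepest_max_index(v)
    if 0 < i < v.size - 1 and v[i - 1] < v[i] and v[i + 1] < v[i]:
        # strict local maximum -> parabolic vertex (plateau ties skip this)
        denom = v[i - 1] - 2.0 * v[i] + v[i + 1]
        delta = 0.5 * (v[i - 1] - v[i + 1]) / denom
        if abs(delta) <= 0.5:
            return float(p.depths[i] + delta * p.step)
    return float(p.depths[i])


def distal_falloff_depth(p: DepthProfile, level: float = 0.8) -> float:
    """Depth (mm) where the distal falling edge crosses ``level``.

    The profile is normalised to its maximum; the crossing is searched from
    the deepest depth backwards so that the *distal* crossing is found even
    when the entrance region also passes through the level.  Linear
    interpolation locates the crossing between samples.  ``level = 1``
    degenerates to the depth of the peak sample.
    """
    if not 0.0 < level <= 1.0:
        raise ValueError("level must lie in (0, 1]")
    v = p.values / np.max(p.values)
    if np.max(p.values) <= 0:
        raise ValueError("profile has no positive values")
    ipk = _deepest_max_index(v)
    if level >= 1.0:
        return float(p.depths[ipk])
    if v[-1] >= level:
        raise ValueError(
            f"profile never falls below level {level:g} distal of the peak"
        )
    # walk from the deepest sample towards the peak; first sample >= level
    j = p.depths.size - 1
    while j > ipk and v[j] < level:
        j -= 1
    # crossing lies between j (>= level) and j+1 (< level)
    frac = (v[j] - level) / (v[j] - v[j + 1])
    return float(p.depths[j] + frac * p.step)


def range_shift(a: DepthProfile, b: DepthProfile, mode: str = "falloff80") -> float:
    """Signed depth shift (mm) between two profiles; positive = ``a`` deeper.

    ``mode='peak'`` compares refined peak depths; ``mode='falloff80'``
    compares 80% distal fall-off depths.
    """
    if mode == "peak":
        return peak_depth(a) - peak_depth(b)
    if mode == "falloff80":
        return distal_falloff_depth(a, 0.8) - distal_falloff_depth(b, 0.8)
    raise ValueError("mode must be 'peak' or 'falloff80'")
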