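"""Deterministic streamline tractography by Euler integration.

Streamlines follow the principal eigenvector field of a fitted tensor,
x_{k+1} = x_k + h * v(x_k), bidirectionally from each seed, with the vector
sign-aligned to the previous step. Propagation stops when the next point
leaves the tracking mask, its FA falls below the stopping threshold, or the
turning angle between consecutive steps exceeds the angle threshold. Tracks
shorter than the minimum length are discarded.

Direction lookup is nearest-voxel by default: trilinear interpolation of
eigenvectors is ill-defined across sign flips, and nearest lookup keeps the
geometric test oracles exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from .dti import TensorField
from .io import ScalarVolume, Volume


@dataclass
class TrackingParams:
    step_size: float = 1.0          # mm
    angle_threshold: float = 35.0   # degrees
    min_length: float = 20.0        # mm
    fa_start: float = 0.3
    fa_stop: float = 0.2
    seed_density: int = 1           # seeds per voxel along each axis offset grid

    def __post_init__(self) -> None:
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if not 0 < self.angle_threshold < 90:
            raise ValueError("angle_threshold must be in (0, 90) degrees")
        if self.min_length <= 0:
            raise ValueError("min_length must be > 0")


class DirectionField:
    """Minimal interface tracking needs: a direction, an FA and a mask lookup."""

    def direction(self, point_mm: np.ndarray) -> np.ndarray | None:
        raise NotImplementedError

    def fa(self, point_mm: np.ndarray) -> float:
        raise NotImplementedError

    def in_mask(self, point_mm: np.ndarray) -> bool:
        raise NotImplementedError


class TensorDirections(DirectionField):
    """Nearest-voxel principal-eigenvector lookup over a TensorField."""

    def __init__(self, tensor: TensorField, fa: ScalarVolume, mask: Volume):
        self._dirs = tensor.principal_direction()
        self._valid = tensor.valid
        self._fa = fa
        self._mask = mask
        self._shape = np.asarray(tensor.shape)
        self._inv = np.linalg.inv(mask.affine)

    def _voxel(self, point_mm: np.ndarray) -> tuple[int, int, int] | None:
        v = np.rint(self._inv[:3, :3] @ point_mm + self._inv[:3, 3]).astype(int)
        if np.any(v < 0) or np.any(v >= self._shape):
            return None
        return tuple(v)  # type: ignore[return-value]

    def direction(self, point_mm):
        v = self._voxel(point_mm)
        if v is None or not self._valid[v]:
            return None
        return self._dirs[v]

    def fa(self, point_mm):
        v = self._voxel(point_mm)
        return float(self._fa.data[v]) if v is not None else 0.0

    def in_mask(self, point_mm):
        v = self._voxel(point_mm)
        return bool(self._mask.data[v]) if v is not None else False


class AnalyticField(DirectionField):
    """Direction field given by a callable; used for geometric oracles."""

    def __init__(
        self,
        direction_fn: Callable[[np.ndarray], np.ndarray],
        bounds_mm: tuple[np.ndarray, np.ndarray],
        fa_value: float = 1.0,
    ):
        self._fn = direction_fn
        self._lo, self._hi = (np.asarray(b, dtype=float) for b in bounds_mm)
        self._fa_value = fa_value

    def direction(self, point_mm):
        if not self.in_mask(point_mm):
            return None
        d = np.asarray(self._fn(np.asarray(point_mm, dtype=float)), dtype=float)
        n = np.linalg.norm(d)
        return d / n if n > 0 else None

    def fa(self, point_mm):
        return self._fa_value if self.in_mask(point_mm) else 0.0

    def in_mask(self, point_mm):
        p = np.asarray(point_mm, dtype=float)
        return bool(np.all(p >= self._lo) and np.all(p <= self._hi))


def _half_track(
    seed: np.ndarray, first_dir: np.ndarray, field: DirectionField, params: TrackingParams
) -> list[np.ndarray]:
    """Points after the seed, stepping along ``first_dir``."""
    cos_thr = np.cos(np.radians(params.angle_threshold))
    h = params.step_size
    points: list[np.ndarray] = []
    x = np.asarray(seed, dtype=float)
    prev = np.asarray(first_dir, dtype=float)
    for _ in range(100_000):  # hard stop; never reached on sane grids
        xn = x + h * prev
        if not field.in_mask(xn) or field.fa(xn) < params.fa_stop:
            break
        v = field.direction(xn)
        if v is None:
            break
        if v @ prev < 0:
            v = -v
        turned_too_far = (v @ prev) < cos_thr
        points.append(xn)
        if turned_too_far:
            break
        x, prev = xn, v
    return points


def track_streamline(
    seed: np.ndarray, field: DirectionField, params: TrackingParams
) -> np.ndarray | None:
    """Bidirectional Euler track from one seed; None if shorter than min_length."""
    seed = np.asarray(seed, dtype=float)
    if not field.in_mask(seed):
        raise ValueError(f"seed {seed} outside the tracking mask/volume")
    v0 = field.direction(seed)
    if v0 is None or field.fa(seed) < params.fa_stop:
        return None
    fwd = _half_track(seed, v0, field, params)
    bwd = _half_track(seed, -v0, field, params)
    points = bwd[::-1] + [seed] + fwd
    if len(points) < 2:
        return None
    arr = np.asarray(points)
    length = np.linalg.norm(np.diff(arr, axis=0), axis=1).sum()
    if length < params.min_length:
        return None
    return arr


def streamline_length(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(np.asarray(points), axis=0), axis=1).sum())


def track_whole_mask(
    tensor: TensorField,
    fa: ScalarVolume,
    mask: Volume,
    params: TrackingParams | None = None,
) -> list[np.ndarray]:
    """Seed every masked voxel centre with FA >= fa_start; deterministic order.

    ``seed_density`` > 1 places a regular sub-grid of density^3 seeds per
    voxel instead of the single centre seed.
    """
    params = params or TrackingParams()
    field = TensorDirections(tensor, fa, mask)
    seed_vox = np.argwhere(mask.data.astype(bool) & (fa.data >= params.fa_start))
    d = params.seed_density
    if d == 1:
        offsets = np.zeros((1, 3))
    else:
        g = (np.arange(d) + 0.5) / d - 0.5
        offsets = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1).reshape(-1, 3)
    streamlines: list[np.ndarray] = []
    for vox in seed_vox:
        for off in offsets:
            seed = mask.voxel_to_world(vox + off)[0]
            s = track_streamline(seed, field, params)
            if s is not None:
                streamlines.append(s)
    return streamlines
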