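"""Voxel-wise diffusion tensor estimation and the derived scalar maps.

The signal model is the single diffusion tensor,

    S_i = S0 * exp(-b_i * g_i^T D g_i),

fitted per voxel by ordinary least squares on the log-signal. Multiple b0
volumes are averaged into a single S0 estimate before fitting, and voxels
with any non-positive diffusion-weighted signal are flagged invalid rather
than clamped (clamping would bias MD downward). Tensors are stored in
mm^2/s; MD is reported in um^2/ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import ScalarVolume

#: eigenvalue floor in mm^2/s; keeps noise-driven negative eigenvalues from
#: breaking the FA bound
EIGENVALUE_FLOOR = 1e-6

#: index order of the six unique tensor elements
TENSOR_ELEMENTS = ("xx", "yy", "zz", "xy", "xz", "yz")


class GradientSchemeError(ValueError):
    pass


@dataclass
class GradientScheme:
    """Diffusion gradient table: b-values (s/mm^2) and unit directions."""

    b_values: np.ndarray
    directions: np.ndarray
    b0_threshold: float = 50.0

    def __post_init__(self) -> None:
        self.b_values = np.asarray(self.b_values, dtype=float).ravel()
        self.directions = np.asarray(self.directions, dtype=float)
        if self.directions.shape != (len(self.b_values), 3):
            raise GradientSchemeError("directions must be (n_volumes, 3)")
        dwi = ~self.b0_flags
        norms = np.linalg.norm(self.directions[dwi], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise GradientSchemeError("diffusion directions must be unit vectors")
        if self.b0_flags.sum() < 1:
            raise GradientSchemeError("at least one b0 volume is required")
        uniq = _unique_axes(self.directions[dwi])
        if uniq < 6:
            raise GradientSchemeError(
                f"need >= 6 non-collinear diffusion directions, got {uniq}"
            )

    @property
    def b0_flags(self) -> np.ndarray:
        return self.b_values <= self.b0_threshold

    @classmethod
    def from_fsl(cls, bval_path: str | Path, bvec_path: str | Path) -> "GradientScheme":
        bvals = np.loadtxt(bval_path).ravel()
        bvecs = np.loadtxt(bvec_path)
        if bvecs.shape[0] == 3:
            bvecs = bvecs.T
        return cls(b_values=bvals, directions=bvecs)

    def to_fsl(self, bval_path: str | Path, bvec_path: str | Path) -> None:
        np.savetxt(bval_path, self.b_values[None, :], fmt="%.1f")
        np.savetxt(bvec_path, self.directions.T, fmt="%.8f")


def _unique_axes(directions: np.ndarray, tol: float = 1e-6) -> int:
    """Count directions that are pairwise non-collinear (g and -g identical)."""
    kept: list[np.ndarray] = []
    for g in directions:
        if all(abs(abs(g @ k) - 1.0) > tol for k in kept):
            kept.append(g)
    return len(kept)


def design_matrix(scheme: GradientScheme) -> np.ndarray:
    """Rows b_i * (gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz) for DWI volumes."""
    g = scheme.directions[~scheme.b0_flags]
    b = scheme.b_values[~scheme.b0_flags]
    return b[:, None] * np.column_stack(
        [
            g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
        ]
    )


@dataclass
class TensorField:
    """Per-voxel symmetric tensor (6 unique elements, mm^2/s) with S0 and validity."""

    tensor: np.ndarray  # (X, Y, Z, 6) in TENSOR_ELEMENTS order
    s0: np.ndarray
    valid: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    _eigen: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensor.shape[:3]  # type: ignore[return-value]

    def as_matrices(self) -> np.ndarray:
        """Full (X, Y, Z, 3, 3) symmetric matrices."""
        t = self.tensor
        m = np.empty(t.shape[:3] + (3, 3))
        m[..., 0, 0] = t[..., 0]
        m[..., 1, 1] = t[..., 1]
        m[..., 2, 2] = t[..., 2]
        m[..., 0, 1] = m[..., 1, 0] = t[..., 3]
        m[..., 0, 2] = m[..., 2, 0] = t[..., 4]
        m[..., 1, 2] = m[..., 2, 1] = t[..., 5]
        return m

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (ascending, floored) and eigenvectors, cached."""
        if self._eigen is None:
            evals, evecs = np.linalg.eigh(self.as_matrices())
            evals = np.maximum(evals, EIGENVALUE_FLOOR)
            evals[~self.valid] = EIGENVALUE_FLOOR
            self._eigen = (evals, evecs)
        return self._eigen

    def principal_direction(self) -> np.ndarray:
        """(X, Y, Z, 3) unit vector of the largest eigenvalue."""
        _, evecs = self.eigensystem()
        return evecs[..., :, 2]


def fit_tensor(
    dwi: np.ndarray,
    scheme: GradientScheme,
    mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
) -> TensorField:
    """Ordinary-least-squares log-linear tensor fit.

    Voxels outside ``mask`` or with any non-positive signal (b0 average or
    diffusion-weighted) are excluded from the validity mask; their tensor is
    left at zero.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4 or dwi.shape[3] != len(scheme.b_values):
        raise ValueError(
            f"DWI shape {dwi.shape} inconsistent with {len(scheme.b_values)} gradients"
        )
    if np.any(dwi < 0):
        raise ValueError("DWI signal must be non-negative")
    shape = dwi.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    b0_mean = dwi[..., scheme.b0_flags].mean(axis=3)
    dw = dwi[..., ~scheme.b0_flags]
    valid = mask & (b0_mean > 0) & np.all(dw > 0, axis=3)

    design = design_matrix(scheme)
    pinv = np.linalg.pinv(design)
    if np.linalg.matrix_rank(design) < 6:
        raise GradientSchemeError("rank-deficient gradient design (collinear directions)")

    tensor = np.zeros(shape + (6,))
    if valid.any():
        # y = ln(S0) - ln(S_i) = b g^T D g
        y = np.log(b0_mean[valid])[:, None] - np.log(dw[valid])
        tensor[valid] = y @ pinv.T
    return TensorField(
        tensor=tensor,
        s0=b0_mean,
        valid=valid,
        affine=np.eye(4) if affine is None else np.asarray(affine, dtype=float),
    )


def compute_md(tensor: TensorField) -> ScalarVolume:
    """Mean diffusivity, trace(D)/3, in um^2/ms."""
    md = tensor.tensor[..., :3].sum(axis=-1) / 3.0 * 1e3
    md[~tensor.valid] = 0.0
    return ScalarVolume(data=md, affine=tensor.affine, metric="MD")


def compute_fa(tensor: TensorField) -> ScalarVolume:
    """Fractional anisotropy from the (floored) eigenvalues, clipped to [0, 1]."""
    evals, _ = tensor.eigensystem()
    l1, l2, l3 = evals[..., 2], evals[..., 1], evals[..., 0]
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l1 - l3) ** 2
    den = l1**2 + l2**2 + l3**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(0.5) * np.sqrt(num / den)
    fa = np.nan_to_num(fa, nan=0.0)
    fa[~tensor.valid] = 0.0
    return ScalarVolume(data=np.clip(fa, 0.0, 1.0), affine=tensor.affine, metric="FA")


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """FA of eigenvalue triples (..., 3); 0 where all eigenvalues are 0."""
    e = np.asarray(evals, dtype=float)
    l1, l2, l3 = e[..., 0], e[..., 1], e[..., 2]
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l1 - l3) ** 2
    den = l1**2 + l2**2 + l3**2
    out = np.zeros(np.broadcast(l1, l2).shape if e.ndim > 1 else ())
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, np.sqrt(0.5) * np.sqrt(num / np.where(den > 0, den, 1)), 0.0)
    return out
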