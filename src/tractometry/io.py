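"""Volume / streamline / table I/O and the shared spatial containers.

Conventions used throughout the package: voxel indices are 0-based, world
coordinates are millimetres in RAS orientation, and every volume carries a
4x4 voxel-to-world affine. MD is expressed in um^2/ms (1e-3 mm^2/s) to match
the clinical thresholds used elsewhere in the package; FA is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

GROUPS = ("control", "ILAE1", "ILAE2plus")
TRACTS = ("fimbria_fornix", "parahippocampal_wmb", "uncinate")
LATERALITIES = ("ipsilateral", "contralateral")

#: laterality label used for controls after left/right pooling
POOLED = "pooled"


class FormatError(ValueError):
    """Raised for malformed or mismatched input files."""


@dataclass
class Volume:
    """A 3D grid with a voxel-to-world affine (mm, RAS)."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(f"expected a 3D volume, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world-mm coordinates to (fractional) voxel indices."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(ijk, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def contains(self, points_mm: np.ndarray) -> np.ndarray:
        """True where the point falls inside the voxel grid."""
        v = self.world_to_voxel(points_mm)
        lo = v >= -0.5
        hi = v <= np.asarray(self.shape) - 0.5
        return np.all(lo & hi, axis=-1)

    def sample_nearest(self, points_mm: np.ndarray, outside: float = 0.0) -> np.ndarray:
        v = np.rint(self.world_to_voxel(points_mm)).astype(int)
        inside = np.all((v >= 0) & (v < np.asarray(self.shape)), axis=-1)
        out = np.full(len(v), outside, dtype=float)
        if inside.any():
            vi = v[inside]
            out[inside] = self.data[vi[:, 0], vi[:, 1], vi[:, 2]]
        return out

    def sample_trilinear(self, points_mm: np.ndarray) -> np.ndarray:
        """Trilinear interpolation; NaN outside the grid."""
        v = self.world_to_voxel(points_mm)
        vals = map_coordinates(self.data.astype(float), v.T, order=1, mode="nearest")
        vals = np.where(self.contains(points_mm), vals, np.nan)
        return vals


@dataclass
class ScalarVolume(Volume):
    """Scalar map (MD in um^2/ms, FA dimensionless, or other)."""

    metric: str = "other"


@dataclass
class LacunaMask(Volume):
    """Binary template-space mask of surgically resected tissue."""

    subject: str = ""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(bool)


def load_volume(path: str | Path, cls=ScalarVolume, **kwargs) -> Volume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D NIfTI, got {data.ndim}D")
    return cls(data=data, affine=np.asarray(img.affine), **kwargs)


def save_volume(vol: Volume, path: str | Path) -> None:
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


def load_dwi(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 4D DWI series; returns (data, affine)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(f"{path}: expected 4D DWI, got {data.ndim}D")
    return data, np.asarray(img.affine)


def save_dwi(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine)), str(path))


# ---------------------------------------------------------------------------
# Streamlines (TRK / TCK, world-mm coordinates)
# ---------------------------------------------------------------------------

def save_streamlines(
    streamlines: Sequence[np.ndarray],
    path: str | Path,
    reference: Volume | None = None,
) -> None:
    """Write streamlines (world mm) to TRK or TCK, by extension."""
    path = Path(path)
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in streamlines],
        affine_to_rasmm=np.eye(4),
    )
    if path.suffix == ".trk":
        header = {}
        if reference is not None:
            header = {
                "voxel_to_rasmm": reference.affine.astype(np.float32),
                "voxel_sizes": np.sqrt((reference.affine[:3, :3] ** 2).sum(0)).astype(
                    np.float32
                ),
                "dimensions": np.asarray(reference.shape, dtype=np.uint16),
            }
        nib.streamlines.save(tractogram, str(path), header=header)
    elif path.suffix == ".tck":
        nib.streamlines.save(tractogram, str(path))
    else:
        raise FormatError(f"unknown streamline format: {path.suffix}")


def load_streamlines(path: str | Path) -> list[np.ndarray]:
    """Read a TRK/TCK file as a list of (N,3) world-mm point arrays."""
    path = Path(path)
    if path.suffix not in (".trk", ".tck"):
        raise FormatError(f"unknown streamline format: {path.suffix}")
    tractogram_file = nib.streamlines.load(str(path))
    return [np.asarray(s, dtype=float) for s in tractogram_file.tractogram.streamlines]


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

COHORT_COLUMNS = [
    "subject", "group", "side", "sex", "age", "onset_age", "duration",
    "seizure_frequency", "febrile", "invasive", "histopathology", "operated",
]


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Check the cohort-table contract; returns the table unchanged."""
    missing = [c for c in ("subject", "group", "side") if c not in table.columns]
    if missing:
        raise FormatError(f"cohort table missing columns: {missing}")
    if table["subject"].duplicated().any():
        raise FormatError("cohort table has duplicate subject ids")
    bad = set(table["group"]) - set(GROUPS)
    if bad:
        raise FormatError(f"unknown group labels: {sorted(bad)}")
    ctrl = table[table["group"] == "control"]
    if not (ctrl["side"] == "none").all():
        raise FormatError("controls must have side == 'none'")
    return table


def read_cohort(path: str | Path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path))


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(table).to_csv(path, index=False)


def tract_laterality(hemisphere: str, seizure_side: str) -> str:
    """Resolve a tract's laterality from its hemisphere and the seizure side."""
    if seizure_side == "none":
        return POOLED
    if hemisphere not in ("left", "right") or seizure_side not in ("left", "right"):
        raise ValueError(f"cannot resolve laterality for {hemisphere}/{seizure_side}")
    return "ipsilateral" if hemisphere == seizure_side else "contralateral"
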