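"""Tract-resection overlap: per-section resected proportions, group
comparison of total resection extent, and voxel-wise group resection maps.

The per-section resected proportion reuses the along-tract profiling
machinery over a binary lacuna mask: node i's value is the weighted
fraction of member streamlines whose node-i position falls inside the
resected tissue (nearest-voxel membership); the total proportion is the
mean over the 100 sections. Group maps rasterise each subject's bundle,
intersect it with the lacuna, mirror right-ipsilateral subjects across the
mid-sagittal plane so the ipsilateral side is always displayed on the left,
and average voxel-wise across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bundles import Bundle, node_weights, resample_streamline, resampled_positions
from .io import LacunaMask, Volume
from .stats import fdr_adjust, two_sample_t


@dataclass
class ResectionProfile:
    subject: str
    tract: str
    laterality: str
    node_proportions: np.ndarray  # (100,) in [0, 1]

    @property
    def total(self) -> float:
        return float(self.node_proportions.mean())


def resection_profile(
    bundle: Bundle,
    lacuna: LacunaMask,
    subject: str = "",
    laterality: str = "not_applicable",
    weighting: str = "gaussian",
) -> ResectionProfile:
    """Per-section resected proportion of a detected bundle.

    An empty lacuna is valid and yields an all-zero profile.
    """
    pos = resampled_positions(bundle)
    w = node_weights(pos, weighting)
    inside = lacuna.sample_nearest(pos.reshape(-1, 3), outside=0.0).reshape(pos.shape[:2])
    props = np.einsum("sn,sn->n", w, inside)
    return ResectionProfile(
        subject=subject,
        tract=bundle.tract,
        laterality=laterality,
        node_proportions=np.clip(props, 0.0, 1.0),
    )


def compare_resection(
    totals: pd.DataFrame,
    group_a: str = "ILAE1",
    group_b: str = "ILAE2plus",
    alpha: float = 0.05,
    variant: str = "student",
) -> pd.DataFrame:
    """Per-tract comparison of total resected proportions between groups.

    ``totals`` columns: subject, group, tract, total. FDR is applied across
    tracts; means/SDs are also reported as percent for mean +/- SD tables.
    """
    rows = []
    for tract, sub in totals.groupby("tract", sort=True):
        a = sub.loc[sub["group"] == group_a, "total"].to_numpy(dtype=float)
        b = sub.loc[sub["group"] == group_b, "total"].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            continue
        t, df, p = two_sample_t(a, b, variant)
        rows.append(
            {
                "tract": tract, "n_a": len(a), "n_b": len(b),
                "mean_a_pct": 100 * a.mean(), "sd_a_pct": 100 * a.std(ddof=1),
                "mean_b_pct": 100 * b.mean(), "sd_b_pct": 100 * b.std(ddof=1),
                "t": t, "df": df, "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        q, sig = fdr_adjust(out["p"].to_numpy(), alpha)
        out["q"], out["significant"] = q, sig
    return out


def rasterize_bundle(streamlines: list[np.ndarray], reference: Volume) -> np.ndarray:
    """Binary mask of voxels traversed by >= 1 streamline.

    Streamlines are densified to a step of at most half the smallest voxel
    size before rasterisation so no traversed voxel is skipped.
    """
    voxel_sizes = np.sqrt((reference.affine[:3, :3] ** 2).sum(axis=0))
    max_step = voxel_sizes.min() / 2.0
    mask = np.zeros(reference.shape, dtype=bool)
    shape = np.asarray(reference.shape)
    for sl in streamlines:
        sl = np.asarray(sl, dtype=float)
        if len(sl) < 2:
            dense = sl
        else:
            length = np.linalg.norm(np.diff(sl, axis=0), axis=1).sum()
            n = max(len(sl), int(np.ceil(length / max_step)) + 1)
            dense = resample_streamline(sl, n_nodes=n)
        v = np.rint(reference.world_to_voxel(dense)).astype(int)
        ok = np.all((v >= 0) & (v < shape), axis=1)
        v = v[ok]
        mask[v[:, 0], v[:, 1], v[:, 2]] = True
    return mask


def flip_lr(data: np.ndarray) -> np.ndarray:
    """Mirror across the mid-sagittal plane (x -> -x on a symmetric grid)."""
    return np.ascontiguousarray(np.asarray(data)[::-1, :, :])


@dataclass
class ResectionMap:
    group: str
    data: np.ndarray  # voxel-wise fraction of subjects, in [0, 1]
    affine: np.ndarray
    n_subjects: int


def build_resection_map(
    subjects: list[tuple[list[np.ndarray], LacunaMask, str]],
    reference: Volume,
    group: str = "",
) -> ResectionMap:
    """Average of per-subject bundle-and-lacuna intersection masks.

    ``subjects`` is a list of (streamlines, lacuna, ipsilateral_side); a
    right-sided ipsilateral subject's intersection is mirrored to the left
    hemisphere before averaging.
    """
    if not subjects:
        raise ValueError("need at least one subject")
    acc = np.zeros(reference.shape, dtype=float)
    for streamlines, lacuna, side in subjects:
        inter = rasterize_bundle(streamlines, reference) & lacuna.data.astype(bool)
        if side == "right":
            inter = flip_lr(inter)
        acc += inter
    return ResectionMap(
        group=group,
        data=acc / len(subjects),
        affine=reference.affine,
        n_subjects=len(subjects),
    )


def bundle_distribution_map(
    bundles: list[list[np.ndarray]], reference: Volume
) -> np.ndarray:
    """Voxel-wise mean of binary bundle masks (anatomical reference map)."""
    if not bundles:
        raise ValueError("need at least one bundle")
    acc = np.zeros(reference.shape, dtype=float)
    for streamlines in bundles:
        acc += rasterize_bundle(streamlines, reference)
    return acc / len(bundles)
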