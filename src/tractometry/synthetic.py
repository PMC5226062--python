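"""Synthetic cohorts: tract-profile populations, image-space DWI phantoms
with tube bundles and waypoints, resection lacunae, and clinical tables.

The generator defines the study conditions the rest of the package is
exercised under. Profile mode draws, for each subject x tract x side x
metric, a smooth 100-node baseline curve plus a per-subject offset,
node-autocorrelated Gaussian noise (moving-average smoothed white noise),
and the group effects listed in the effect table. The default effect table
encodes the qualitative group structure of mesial TLE tractometry: shared
MD elevation (both outcome groups) along the uncinate bilaterally, the
ipsilateral parahippocampal bundle and the temporal fimbria-fornix
(ROIs 4-5), and poor-outcome-only elevation in the dorsal ipsilateral
fornix (ROIs 1-3) and contralateral parahippocampal ROIs 1-3.

Image mode builds single-tensor DWI phantoms (60 directions at
b = 1000 s/mm^2 plus 6 b0) on a 64 x 64 x 40 grid at 1.75 mm isotropic,
containing one curved tube bundle per tract and hemisphere whose principal
eigenvector follows the tube tangent, with optional Rician noise, waypoint
boxes at the tube ends and the analytic centreline kept as ground truth.

Lacuna masks are ellipsoids over the anterior temporal region whose
anterior extent is drawn per group; the defaults are calibrated so mean
uncinate resection proportions approximate 0.42 (good outcome) vs 0.20
(poor outcome) with SD near 0.21, i.e. larger resections in seizure-free
patients.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .bundles import BoxROI, WaypointPair
from .dti import GradientScheme
from .io import GROUPS, LacunaMask, TRACTS, Volume, validate_cohort

N_NODES = 100


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Effects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Effect:
    """Group shift on a node range of one tract x laterality.

    MD shift in um^2/ms, FA shift dimensionless; nodes are 1-based and
    inclusive. ``groups`` lists the patient groups the shift applies to.
    """

    tract: str
    laterality: str
    node_start: int
    node_end: int
    groups: frozenset[str]
    md_shift: float = 0.0
    fa_shift: float = 0.0

    def __post_init__(self) -> None:
        if not (1 <= self.node_start <= self.node_end <= N_NODES):
            raise ConfigurationError(
                f"node range [{self.node_start}, {self.node_end}] outside [1, {N_NODES}]"
            )
        if self.tract not in TRACTS:
            raise ConfigurationError(f"unknown tract {self.tract!r}")


_BOTH = frozenset({"ILAE1", "ILAE2plus"})
_POOR = frozenset({"ILAE2plus"})

#: default group-effect structure (see module docstring)
DEFAULT_EFFECTS: tuple[Effect, ...] = (
    Effect("uncinate", "ipsilateral", 1, 100, _BOTH, md_shift=0.12, fa_shift=-0.03),
    Effect("uncinate", "contralateral", 1, 100, _BOTH, md_shift=0.10, fa_shift=-0.02),
    Effect("parahippocampal_wmb", "ipsilateral", 1, 100, _BOTH, md_shift=0.12),
    Effect("fimbria_fornix", "ipsilateral", 61, 100, _BOTH, md_shift=0.12),
    Effect("fimbria_fornix", "ipsilateral", 1, 60, _POOR, md_shift=0.12, fa_shift=-0.02),
    Effect("parahippocampal_wmb", "contralateral", 1, 60, _POOR, md_shift=0.10, fa_shift=-0.02),
)


# ---------------------------------------------------------------------------
# Lacuna parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LacunaParams:
    """Ellipsoid resection-cavity model for one outcome group (mm).

    The x and z half-axes are wide enough to span the temporal bundles; the
    anterior (y) half-axis is the random variable controlling how much of
    the uncinate falls inside the cavity.
    """

    centre_mean: tuple[float, float, float] = (33.0, 35.0, 0.0)
    centre_sd: tuple[float, float, float] = (2.0, 2.0, 2.0)
    half_axis_x: float = 25.0
    half_axis_z: float = 20.0
    anterior_extent_mean: float = 21.0
    anterior_extent_sd: float = 9.0
    anterior_extent_min: float = 0.0


#: calibrated so uncinate resection proportions approximate 0.42 vs 0.20
DEFAULT_LACUNA_PARAMS: dict[str, LacunaParams] = {
    "ILAE1": LacunaParams(anterior_extent_mean=21.0, anterior_extent_sd=9.0),
    "ILAE2plus": LacunaParams(anterior_extent_mean=9.8, anterior_extent_sd=8.5),
}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    seed: int = 0
    n_controls: int = 44
    n_ilae1: int = 22
    n_ilae2plus: int = 21
    mode: str = "profile"
    effect_table: tuple[Effect, ...] = DEFAULT_EFFECTS
    #: per-node noise SD after smoothing (MD: um^2/ms; FA uses fa_noise_scale)
    noise_sd_profile: float = 0.05
    #: between-subject SD of the whole-profile offset
    subject_sd_md: float = 0.05
    subject_sd_fa: float = 0.03
    #: FA per-node noise = noise_sd_profile * fa_noise_scale
    fa_noise_scale: float = 0.6
    noise_window: int = 5
    rician_sigma: float = 0.0
    grid_shape: tuple[int, int, int] = (64, 64, 40)
    voxel_size: float = 1.75
    tube_radius: float = 4.0
    n_truth_streamlines: int = 20
    lacuna_params: dict[str, LacunaParams] = field(
        default_factory=lambda: dict(DEFAULT_LACUNA_PARAMS)
    )
    #: fixed contingency counts; None samples categories from proportions
    clinical_counts: dict | None = None

    def __post_init__(self) -> None:
        for name in ("n_controls", "n_ilae1", "n_ilae2plus"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.mode not in ("profile", "image"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        for par in ("noise_sd_profile", "subject_sd_md", "subject_sd_fa", "rician_sigma"):
            if getattr(self, par) < 0:
                raise ConfigurationError(f"{par} must be >= 0")

    def affine(self) -> np.ndarray:
        """Centred voxel-to-world affine (mid-sagittal plane at x = 0)."""
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = -self.voxel_size * (np.asarray(self.grid_shape) - 1) / 2.0
        return aff


def _subject_rng(config: GeneratorConfig, subject_id: str, salt: int) -> np.random.Generator:
    return np.random.default_rng(
        [int(config.seed), zlib.crc32(subject_id.encode()) & 0x7FFFFFFF, salt]
    )


# ---------------------------------------------------------------------------
# Clinical table (contingency structure of the study cohort)
# ---------------------------------------------------------------------------

#: printed 43-patient contingency structure; rows are (ILAE1, ILAE2plus)
STUDY_CLINICAL_COUNTS: dict = {
    "n": (22, 21),
    "sex_female_male": ((8, 14), (15, 6)),
    "side_left_right": ((11, 11), (16, 5)),
    "invasive_no_yes": ((16, 6), (14, 7)),
    "febrile_no_yes": ((15, 7), (14, 7)),
    "histopathology_1_2_3": ((20, 2, 0), (17, 4, 0)),
    # continuous covariates: (location, scale) per group
    "age": ((38.8, 11.3), (40.6, 13.9)),
    "onset_age": ((16.05, 11.49), (15.6, 10.5)),
    "duration": ((22.7, 13.9), (25.0, 15.8)),
    "seizure_frequency": ((8.8, 18.7), (4.2, 2.3)),
}


def _categorical(rng, n: int, counts: tuple[int, ...], values: list) -> list:
    if sum(counts) != n:
        raise ConfigurationError(
            f"counts {counts} inconsistent with group size {n}"
        )
    seq = [v for v, c in zip(values, counts) for _ in range(c)]
    return list(rng.permutation(np.asarray(seq, dtype=object)))


def generate_clinical_table(config: GeneratorConfig) -> pd.DataFrame:
    """Cohort table with the configured contingency structure.

    With fixed counts (the default uses the study's printed 43-patient
    structure) the categorical contingency tables are reproduced exactly;
    with ``clinical_counts=None`` categories are sampled from the printed
    proportions. Continuous covariates are always sampled.
    """
    counts = config.clinical_counts or STUDY_CLINICAL_COUNTS
    sampled = config.clinical_counts is None and (
        config.n_ilae1, config.n_ilae2plus
    ) != counts["n"]
    rng = np.random.default_rng([int(config.seed), 11])
    rows: list[dict] = []
    group_sizes = {"ILAE1": config.n_ilae1, "ILAE2plus": config.n_ilae2plus}
    for gi, (group, n) in enumerate(group_sizes.items()):
        cats = {}
        cat_map = {
            "sex": ("sex_female_male", ["F", "M"]),
            "side": ("side_left_right", ["left", "right"]),
            "invasive": ("invasive_no_yes", [False, True]),
            "febrile": ("febrile_no_yes", [False, True]),
            "histopathology": ("histopathology_1_2_3", [1, 2, 3]),
        }
        for col, (key, values) in cat_map.items():
            c = counts[key][gi]
            if sampled:
                probs = np.asarray(c, dtype=float)
                probs = probs / probs.sum()
                cats[col] = list(rng.choice(np.asarray(values, dtype=object), size=n, p=probs))
            else:
                cats[col] = _categorical(rng, n, c, values)
        for i in range(n):
            loc_age, sc_age = counts["age"][gi]
            loc_on, sc_on = counts["onset_age"][gi]
            loc_du, sc_du = counts["duration"][gi]
            loc_fr, sc_fr = counts["seizure_frequency"][gi]
            rows.append(
                {
                    "subject": f"{'P' if group == 'ILAE1' else 'Q'}{i + 1:03d}",
                    "group": group,
                    "side": cats["side"][i],
                    "sex": cats["sex"][i],
                    "age": round(max(18.0, rng.normal(loc_age, sc_age / 1.35)), 1),
                    "onset_age": round(max(0.5, rng.normal(loc_on, sc_on / 1.35)), 1),
                    "duration": round(max(1.0, rng.normal(loc_du, sc_du / 1.35)), 1),
                    "seizure_frequency": round(max(0.1, rng.normal(loc_fr, sc_fr / 1.35)), 1),
                    "febrile": cats["febrile"][i],
                    "invasive": cats["invasive"][i],
                    "histopathology": cats["histopathology"][i],
                    "operated": True,
                }
            )
    for i in range(config.n_controls):
        rows.append(
            {
                "subject": f"C{i + 1:03d}",
                "group": "control",
                "side": "none",
                "sex": "F" if i % 2 == 0 else "M",
                "age": round(max(18.0, rng.normal(38.0, 11.0)), 1),
                "onset_age": np.nan,
                "duration": np.nan,
                "seizure_frequency": np.nan,
                "febrile": False,
                "invasive": False,
                "histopathology": pd.NA,
                "operated": False,
            }
        )
    return validate_cohort(pd.DataFrame(rows))


def contingency_tables(cohort: pd.DataFrame) -> dict[str, np.ndarray]:
    """Patient contingency tables (rows ILAE1, ILAE2plus) from a cohort table."""
    pat = cohort[cohort["group"] != "control"]
    out: dict[str, np.ndarray] = {}

    def count(group, col, value):
        sub = pat[pat["group"] == group]
        return int((sub[col] == value).sum())

    out["sex_female_male"] = np.array(
        [[count(g, "sex", "F"), count(g, "sex", "M")] for g in ("ILAE1", "ILAE2plus")]
    )
    out["side_left_right"] = np.array(
        [[count(g, "side", "left"), count(g, "side", "right")] for g in ("ILAE1", "ILAE2plus")]
    )
    out["invasive_no_yes"] = np.array(
        [[count(g, "invasive", False), count(g, "invasive", True)] for g in ("ILAE1", "ILAE2plus")]
    )
    out["febrile_no_yes"] = np.array(
        [[count(g, "febrile", False), count(g, "febrile", True)] for g in ("ILAE1", "ILAE2plus")]
    )
    out["histopathology_1_2_3"] = np.array(
        [[count(g, "histopathology", k) for k in (1, 2, 3)] for g in ("ILAE1", "ILAE2plus")]
    )
    return out


# ---------------------------------------------------------------------------
# Profile cohorts
# ---------------------------------------------------------------------------

#: smooth control-plausible baseline curves over t in [0, 1]; fornix MD sits
#: high (~1.05 um^2/ms, CSF partial volume), parahippocampal ~0.9, so the
#: clinical decision thresholds (1.12 / 0.93 um^2/ms) fall between the
#: control-like and shifted group means
BASELINES: dict[tuple[str, str], Callable[[np.ndarray], np.ndarray]] = {
    ("fimbria_fornix", "MD"): lambda t: 1.05 + 0.03 * np.sin(np.pi * t),
    ("parahippocampal_wmb", "MD"): lambda t: 0.88 + 0.03 * np.cos(np.pi * t),
    ("uncinate", "MD"): lambda t: 0.80 + 0.04 * np.sin(np.pi * t),
    ("fimbria_fornix", "FA"): lambda t: 0.45 + 0.05 * np.sin(np.pi * t),
    ("parahippocampal_wmb", "FA"): lambda t: 0.50 + 0.03 * np.cos(np.pi * t),
    ("uncinate", "FA"): lambda t: 0.42 + 0.05 * np.sin(np.pi * t),
}


def baseline_profile(tract: str, metric: str) -> np.ndarray:
    t = np.linspace(0.0, 1.0, N_NODES)
    return BASELINES[(tract, metric)](t)


def _smoothed_noise(rng: np.random.Generator, sd: float, window: int) -> np.ndarray:
    """Node-autocorrelated noise: MA(window) of white noise, per-node SD = sd."""
    if sd == 0:
        return np.zeros(N_NODES)
    white = rng.normal(0.0, sd * np.sqrt(window), N_NODES + window - 1)
    return np.convolve(white, np.ones(window) / window, mode="valid")


@dataclass
class SyntheticCohort:
    cohort_table: pd.DataFrame
    profiles: pd.DataFrame | None
    truth: tuple[Effect, ...]
    config: GeneratorConfig


def _effect_shift(
    effects: tuple[Effect, ...], group: str, tract: str, laterality: str, metric: str
) -> np.ndarray:
    shift = np.zeros(N_NODES)
    key = "md_shift" if metric == "MD" else "fa_shift"
    for e in effects:
        if e.tract == tract and e.laterality == laterality and group in e.groups:
            shift[e.node_start - 1 : e.node_end] += getattr(e, key)
    return shift


def generate_profile_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Profile-mode synthetic cohort.

    Patients carry ipsilateral/contralateral profiles; controls are
    generated on both sides and stored pooled (node-wise mean of left and
    right), as done for control tract profiles in practice.
    """
    if config.mode != "profile":
        raise ConfigurationError("generate_profile_cohort needs mode='profile'")
    cohort = generate_clinical_table(config)
    rows: list[dict] = []
    node_cols = [f"node_{i}" for i in range(1, N_NODES + 1)]
    for _, subj in cohort.iterrows():
        rng = _subject_rng(config, subj["subject"], salt=1)
        is_control = subj["group"] == "control"
        sides = ("left", "right") if is_control else ("ipsilateral", "contralateral")
        for tract in TRACTS:
            for metric in ("MD", "FA"):
                base = baseline_profile(tract, metric)
                subject_sd = config.subject_sd_md if metric == "MD" else config.subject_sd_fa
                node_sd = config.noise_sd_profile * (
                    1.0 if metric == "MD" else config.fa_noise_scale
                )
                per_side = {}
                for side in sides:
                    offset = rng.normal(0.0, subject_sd) if subject_sd > 0 else 0.0
                    noise = _smoothed_noise(rng, node_sd, config.noise_window)
                    shift = (
                        np.zeros(N_NODES)
                        if is_control
                        else _effect_shift(config.effect_table, subj["group"], tract, side, metric)
                    )
                    vals = base + offset + noise + shift
                    if metric == "FA":
                        vals = np.clip(vals, 0.01, 0.99)
                    else:
                        vals = np.maximum(vals, 0.05)
                    per_side[side] = vals
                if is_control:
                    out = {"pooled": (per_side["left"] + per_side["right"]) / 2.0}
                else:
                    out = per_side
                for lat, vals in out.items():
                    row = {
                        "subject": subj["subject"],
                        "group": subj["group"],
                        "tract": tract,
                        "laterality": lat,
                        "metric": metric,
                    }
                    row.update(dict(zip(node_cols, vals)))
                    rows.append(row)
    return SyntheticCohort(
        cohort_table=cohort,
        profiles=pd.DataFrame(rows),
        truth=tuple(config.effect_table),
        config=config,
    )


# ---------------------------------------------------------------------------
# Image phantoms
# ---------------------------------------------------------------------------

#: eigenvalues of in-tube voxels, mm^2/s (prolate tensor, FA ~ 0.72)
TUBE_EIGENVALUES = (1.7e-3, 0.3e-3, 0.3e-3)
#: isotropic background diffusivity, mm^2/s
BACKGROUND_DIFFUSIVITY = 0.7e-3
S0 = 1000.0


def fibonacci_sphere_directions(n: int = 60) -> np.ndarray:
    """Deterministic, roughly uniform unit directions on the sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    golden = np.pi * (1 + np.sqrt(5))
    theta = golden * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def default_scheme(n_directions: int = 60, n_b0: int = 6, b: float = 1000.0) -> GradientScheme:
    dirs = fibonacci_sphere_directions(n_directions)
    b_values = np.concatenate([np.zeros(n_b0), np.full(n_directions, b)])
    directions = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientScheme(b_values=b_values, directions=directions)


def centreline(
    tract: str, hemisphere: str, n_points: int = 121, jitter: np.ndarray | None = None
) -> np.ndarray:
    """Analytic tube centreline in world mm; node index increases with ROI number."""
    sx = -1.0 if hemisphere == "left" else 1.0
    t = np.linspace(0.0, 1.0, n_points)
    if tract == "fimbria_fornix":
        # dorsal-posterior (extratemporal) to anterior-inferior (temporal)
        theta = np.pi * (1.0 + 0.5 * t)
        pts = np.column_stack(
            [np.full_like(t, sx * 14.0), 5.0 + 30.0 * np.cos(theta), 20.0 + 30.0 * np.sin(theta)]
        )
    elif tract == "parahippocampal_wmb":
        pts = np.column_stack(
            [np.full_like(t, sx * 25.0), -30.0 + 50.0 * t, -12.0 + 4.0 * np.sin(np.pi * t)]
        )
    elif tract == "uncinate":
        phi = np.pi * (t - 0.5)
        pts = np.column_stack(
            [np.full_like(t, sx * 38.0), 12.5 + 17.5 * np.sin(phi), -4.0 + 10.0 * np.cos(phi)]
        )
    else:
        raise ConfigurationError(f"unknown tract {tract!r}")
    if jitter is not None:
        pts = pts + np.asarray(jitter, dtype=float)
    return pts


def _frame(tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-point perpendicular frame (n1 constant-ish, n2 = t x n1)."""
    ref = np.array([1.0, 0.0, 0.0])
    n1 = ref - tangents * (tangents @ ref)[:, None]
    bad = np.linalg.norm(n1, axis=1) < 1e-6
    if bad.any():
        alt = np.array([0.0, 0.0, 1.0])
        n1[bad] = alt - tangents[bad] * (tangents[bad] @ alt)[:, None]
    n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
    n2 = np.cross(tangents, n1)
    return n1, n2


def _tangents(points: np.ndarray) -> np.ndarray:
    g = np.gradient(points, axis=0)
    return g / np.linalg.norm(g, axis=1, keepdims=True)


def _tube_rng(
    config: GeneratorConfig, subject_id: str, tract: str, hemisphere: str
) -> np.random.Generator:
    tube_index = 2 * TRACTS.index(tract) + (hemisphere == "right")
    return np.random.default_rng(
        [int(config.seed), zlib.crc32(subject_id.encode()) & 0x7FFFFFFF, 2, tube_index]
    )


def generate_truth_bundle(
    config: GeneratorConfig, subject_id: str, tract: str, hemisphere: str
) -> tuple[np.ndarray, list[np.ndarray], WaypointPair]:
    """Ground-truth geometry for one subject's tube: (centreline, member
    streamlines, waypoints). The same draws underlie the DWI phantom, so a
    subject's truth bundle matches its simulated volume."""
    rng = _tube_rng(config, subject_id, tract, hemisphere)
    jitter = rng.normal(0.0, 1.0, 3)
    pts = centreline(tract, hemisphere, jitter=jitter)
    tan = _tangents(pts)
    n1, n2 = _frame(tan)
    sls = [pts.copy()]
    for _ in range(max(0, config.n_truth_streamlines - 1)):
        r = config.tube_radius * 0.7 * np.sqrt(rng.uniform())
        ang = rng.uniform(0, 2 * np.pi)
        sls.append(pts + r * np.cos(ang) * n1 + r * np.sin(ang) * n2)
    half = config.tube_radius + 3.0
    wp = WaypointPair(
        roi_start=BoxROI(pts[0] - half, pts[0] + half),
        roi_end=BoxROI(pts[-1] - half, pts[-1] + half),
        tract=tract,
        hemisphere=hemisphere,
    )
    return pts, sls, wp


@dataclass
class SubjectPhantom:
    subject: str
    group: str
    dwi: np.ndarray
    scheme: GradientScheme
    affine: np.ndarray
    brain_mask: Volume
    centrelines: dict[tuple[str, str], np.ndarray]
    truth_bundles: dict[tuple[str, str], list[np.ndarray]]
    waypoints: dict[tuple[str, str], WaypointPair]
    tube_radius: float


def generate_image_subject(config: GeneratorConfig, subject_id: str, group: str = "control") -> SubjectPhantom:
    """Single-tensor DWI phantom for one subject (see module docstring)."""
    if config.mode != "image":
        raise ConfigurationError("generate_image_subject needs mode='image'")
    rng = _subject_rng(config, subject_id, salt=4)
    scheme = default_scheme()
    affine = config.affine()
    shape = tuple(config.grid_shape)
    brain = Volume(data=np.ones(shape, dtype=bool), affine=affine)

    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    centres = brain.voxel_to_world(vox)

    lines: dict[tuple[str, str], np.ndarray] = {}
    truth: dict[tuple[str, str], list[np.ndarray]] = {}
    waypoints: dict[tuple[str, str], WaypointPair] = {}
    all_pts, all_tan = [], []
    for tract in TRACTS:
        for hemisphere in ("left", "right"):
            pts, sls, wp = generate_truth_bundle(config, subject_id, tract, hemisphere)
            key = (tract, hemisphere)
            lines[key], truth[key], waypoints[key] = pts, sls, wp
            all_pts.append(pts)
            all_tan.append(_tangents(pts))
    cat_pts = np.vstack(all_pts)
    cat_tan = np.vstack(all_tan)

    tree = cKDTree(cat_pts)
    dist, idx = tree.query(centres, k=1)
    in_tube = dist <= config.tube_radius

    # MD shifts from the effect table (image mode applies MD shifts only; the
    # resolved laterality depends on group side, which image phantoms leave
    # to the caller -- effects here use hemisphere-as-ipsilateral on the left)
    tensors = np.empty((len(centres), 3, 3))
    iso = np.eye(3) * BACKGROUND_DIFFUSIVITY
    tensors[:] = iso
    if in_tube.any():
        tang = cat_tan[idx[in_tube]]
        l1, l2, _ = TUBE_EIGENVALUES
        outer = np.einsum("ni,nj->nij", tang, tang)
        tensors[in_tube] = l2 * np.eye(3) + (l1 - l2) * outer

    # signal: S = S0 exp(-b g^T D g), computed per gradient volume
    n_vols = len(scheme.b_values)
    dwi = np.empty(shape + (n_vols,), dtype=float)
    for v in range(n_vols):
        b = scheme.b_values[v]
        if b == 0:
            sig = np.full(len(centres), S0)
        else:
            g = scheme.directions[v]
            adc = np.einsum("nij,i,j->n", tensors, g, g)
            sig = S0 * np.exp(-b * adc)
        dwi[..., v] = sig.reshape(shape)
    if config.rician_sigma > 0:
        noise_r = rng.normal(0.0, config.rician_sigma, dwi.shape)
        noise_i = rng.normal(0.0, config.rician_sigma, dwi.shape)
        dwi = np.sqrt((dwi + noise_r) ** 2 + noise_i**2)

    return SubjectPhantom(
        subject=subject_id,
        group=group,
        dwi=dwi,
        scheme=scheme,
        affine=affine,
        brain_mask=brain,
        centrelines=lines,
        truth_bundles=truth,
        waypoints=waypoints,
        tube_radius=config.tube_radius,
    )


def straight_tube_phantom(
    config: GeneratorConfig | None = None,
    axis: str = "y",
    radius: float = 4.0,
    rician_sigma: float = 0.0,
    seed: int = 0,
) -> SubjectPhantom:
    """Minimal single-tube phantom (straight tube through the origin) for
    tracking and tensor-fit oracles."""
    config = config or GeneratorConfig(mode="image")
    affine = config.affine()
    shape = tuple(config.grid_shape)
    brain = Volume(data=np.ones(shape, dtype=bool), affine=affine)
    scheme = default_scheme()
    axes = {"x": 0, "y": 1, "z": 2}
    a = axes[axis]
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    centres = brain.voxel_to_world(np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]))
    perp = np.delete(centres, a, axis=1)
    in_tube = (perp**2).sum(axis=1) <= radius**2

    direction = np.zeros(3)
    direction[a] = 1.0
    l1, l2, _ = TUBE_EIGENVALUES
    tube_tensor = l2 * np.eye(3) + (l1 - l2) * np.outer(direction, direction)
    iso = np.eye(3) * BACKGROUND_DIFFUSIVITY

    n_vols = len(scheme.b_values)
    dwi = np.empty(shape + (n_vols,))
    for v in range(n_vols):
        b = scheme.b_values[v]
        if b == 0:
            sig = np.full(len(centres), S0)
        else:
            g = scheme.directions[v]
            adc_tube = g @ tube_tensor @ g
            adc_iso = g @ iso @ g
            sig = S0 * np.exp(-b * np.where(in_tube, adc_tube, adc_iso))
        dwi[..., v] = sig.reshape(shape)
    if rician_sigma > 0:
        rng = np.random.default_rng(seed)
        dwi = np.sqrt(
            (dwi + rng.normal(0, rician_sigma, dwi.shape)) ** 2
            + rng.normal(0, rician_sigma, dwi.shape) ** 2
        )
    lo = [affine[:3, 3][i] for i in range(3)]
    extent = [affine[i, i] * (shape[i] - 1) for i in range(3)]
    start = np.zeros(3)
    end = np.zeros(3)
    start[a] = lo[a]
    end[a] = lo[a] + extent[a]
    pts = np.linspace(start, end, 121)
    half = radius + 3.0
    key = ("uncinate", "left")
    return SubjectPhantom(
        subject="straight_tube",
        group="control",
        dwi=dwi,
        scheme=scheme,
        affine=affine,
        brain_mask=brain,
        centrelines={key: pts},
        truth_bundles={key: [pts]},
        waypoints={
            key: WaypointPair(
                roi_start=BoxROI(pts[0] - half, pts[0] + half),
                roi_end=BoxROI(pts[-1] - half, pts[-1] + half),
                tract="uncinate",
                hemisphere="left",
            )
        },
        tube_radius=radius,
    )


# ---------------------------------------------------------------------------
# Lacunae
# ---------------------------------------------------------------------------

def generate_lacuna(
    config: GeneratorConfig, subject_id: str, group: str, side: str = "right"
) -> LacunaMask:
    """Ellipsoidal resection-cavity mask for one operated subject.

    The cavity sits over the anterior temporal region of the resected
    hemisphere; its anterior (y) half-axis is drawn from the group's
    distribution, larger on average for seizure-free (ILAE1) subjects.
    """
    if group not in config.lacuna_params:
        raise ConfigurationError(f"no lacuna parameters for group {group!r}")
    params = config.lacuna_params[group]
    rng = _subject_rng(config, subject_id, salt=3)
    sx = -1.0 if side == "left" else 1.0
    centre = np.asarray(params.centre_mean, dtype=float)
    centre[0] *= sx
    centre = centre + rng.normal(0.0, np.asarray(params.centre_sd))
    ay = max(
        params.anterior_extent_min,
        rng.normal(params.anterior_extent_mean, params.anterior_extent_sd),
    )
    return lacuna_from_ellipsoid(
        config, centre, (params.half_axis_x, ay, params.half_axis_z), subject_id
    )


def lacuna_from_ellipsoid(
    config: GeneratorConfig,
    centre: np.ndarray,
    half_axes: tuple[float, float, float],
    subject_id: str = "",
) -> LacunaMask:
    """Rasterise an ellipsoid into a binary lacuna mask (empty if any axis <= 0)."""
    affine = config.affine()
    shape = tuple(config.grid_shape)
    vol = Volume(data=np.zeros(shape, dtype=bool), affine=affine)
    centre = np.asarray(centre, dtype=float)
    lo = vol.voxel_to_world(np.zeros(3))[0]
    hi = vol.voxel_to_world(np.asarray(shape) - 1.0)[0]
    if np.any(centre < lo - 1e-9) or np.any(centre > hi + 1e-9):
        raise ConfigurationError(f"ellipsoid centre {centre} outside volume bounds")
    ax = np.asarray(half_axes, dtype=float)
    if np.any(ax <= 0):
        return LacunaMask(data=np.zeros(shape, dtype=bool), affine=affine, subject=subject_id)
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    centres = vol.voxel_to_world(np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]))
    inside = (((centres - centre) / ax) ** 2).sum(axis=1) <= 1.0
    return LacunaMask(data=inside.reshape(shape), affine=affine, subject=subject_id)
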