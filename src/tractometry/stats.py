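"""Group statistics: 5-ROI summaries, t-tests with FDR, effect sizes,
section-wise t-score profiles and clinical contingency tests.

Profiles are reduced to five ROI means over fixed blocks of 20 consecutive
nodes (nodes 1-20, 21-40, 41-60, 61-80, 81-100). Group contrasts use a
two-sample Student t-test (pooled variance; Welch available), two-sided
p-values, Benjamini-Hochberg FDR within a configurable family, and Cohen's
d with the convention that d > 0 means the first (patient) group exceeds
the second.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import LATERALITIES, POOLED, TRACTS

N_NODES = 100
N_ROIS = 5

#: default comparison plan: each patient group vs controls, then between
#: patient outcome groups
DEFAULT_PAIRS = (("ILAE1", "control"), ("ILAE2plus", "control"), ("ILAE1", "ILAE2plus"))


def roi_average(values: np.ndarray) -> np.ndarray:
    """Means over the five fixed 20-node blocks of a complete 100-node profile."""
    v = np.asarray(values, dtype=float)
    if v.shape[-1] != N_NODES:
        raise ValueError(f"profile must have {N_NODES} nodes")
    if np.isnan(v).any():
        raise ValueError("incomplete profile: ROI averaging needs all 100 nodes")
    return v.reshape(v.shape[:-1] + (N_ROIS, N_NODES // N_ROIS)).mean(axis=-1)


def two_sample_t(
    a: np.ndarray, b: np.ndarray, variant: str = "student"
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test; returns (t, df, p).

    Degenerate zero-variance samples with equal means give (0, df, 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    equal_var = variant == "student"
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    df = float(res.df)
    if not np.isfinite(t):  # zero variance in both samples
        if np.isclose(a.mean(), b.mean()):
            return 0.0, df if np.isfinite(df) else len(a) + len(b) - 2.0, 1.0
        return np.inf if a.mean() > b.mean() else -np.inf, df, 0.0
    return t, df, p


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with pooled SD; NaN when the pooled SD is zero."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs n >= 2")
    s_pool = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if s_pool == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / s_pool)


def fdr_adjust(
    p_values: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (q_values, significant_flags)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def sectionwise_t(
    profiles_a: np.ndarray,
    profiles_b: np.ndarray,
    alpha: float = 0.05,
    correction: str = "fdr",
    variant: str = "student",
) -> pd.DataFrame:
    """Node-wise t statistics across subjects with significance flags.

    ``correction`` is 'fdr' (BH across the 100 nodes, the default) or 'none'
    (uncorrected, for display-style plots).
    """
    a = np.asarray(profiles_a, dtype=float)
    b = np.asarray(profiles_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("need 2D (subjects x nodes) arrays with matching nodes")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 complete profiles per group")
    res = sps.ttest_ind(a, b, axis=0, equal_var=variant == "student")
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    if correction == "fdr":
        _, sig = fdr_adjust(p, alpha)
    elif correction == "none":
        sig = p <= alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return pd.DataFrame(
        {"node": np.arange(1, a.shape[1] + 1), "t": t, "p": p, "significant": sig}
    )


def chi_square_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square without continuity correction, df = columns - 1.

    All-zero columns are dropped first (an empty category carries no
    information). A zero row/column margin after dropping makes the
    statistic undefined; (nan, nan) is returned.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or np.any(t < 0):
        raise ValueError("need a 2D table of non-negative counts")
    t = t[:, t.sum(axis=0) > 0]
    t = t[t.sum(axis=1) > 0, :]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return float("nan"), float("nan")
    chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


@dataclass
class ComparisonPlan:
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS
    metrics: tuple[str, ...] = ("MD", "FA")
    tracts: tuple[str, ...] = TRACTS
    lateralities: tuple[str, ...] = LATERALITIES
    alpha: float = 0.05
    variant: str = "student"
    #: FDR family: 'metric_pair' pools all tract x laterality x ROI cells of
    #: one metric and comparison pair; 'cell' adjusts each test alone
    family: str = "metric_pair"


def profile_matrix(
    profiles: pd.DataFrame,
    group: str,
    tract: str,
    laterality: str,
    metric: str,
) -> np.ndarray:
    """(subjects x 100) complete-profile matrix for one cohort cell.

    Controls are stored under the pooled laterality label and are selected
    that way regardless of the requested patient laterality.
    """
    lat = POOLED if group == "control" else laterality
    node_cols = [f"node_{i}" for i in range(1, N_NODES + 1)]
    sel = profiles[
        (profiles["group"] == group)
        & (profiles["tract"] == tract)
        & (profiles["laterality"] == lat)
        & (profiles["metric"] == metric)
    ]
    mat = sel[node_cols].to_numpy(dtype=float)
    return mat[~np.isnan(mat).any(axis=1)]


def run_group_comparison(
    profiles: pd.DataFrame, plan: ComparisonPlan | None = None
) -> pd.DataFrame:
    """ROI-level group contrasts over a long profile table.

    ``profiles`` columns: subject, group, tract, laterality, metric,
    node_1..node_100. Subjects with undetected tracts are simply absent from
    the table for that tract and are thereby excluded per-tract. Returns one
    row per comparison cell with t, df, p, q, d, group means/SDs and the
    significance flag; cells with < 2 subjects in either group are skipped.
    """
    plan = plan or ComparisonPlan()
    rows: list[dict] = []
    for metric in plan.metrics:
        for ga, gb in plan.pairs:
            family_rows: list[dict] = []
            for tract in plan.tracts:
                for lat in plan.lateralities:
                    a = profile_matrix(profiles, ga, tract, lat, metric)
                    b = profile_matrix(profiles, gb, tract, lat, metric)
                    if len(a) < 2 or len(b) < 2:
                        continue
                    roi_a = roi_average(a)
                    roi_b = roi_average(b)
                    for k in range(N_ROIS):
                        t, df, p = two_sample_t(roi_a[:, k], roi_b[:, k], plan.variant)
                        family_rows.append(
                            {
                                "group_a": ga, "group_b": gb, "tract": tract,
                                "laterality": lat, "metric": metric, "roi": k + 1,
                                "n_a": len(a), "n_b": len(b),
                                "mean_a": roi_a[:, k].mean(),
                                "sd_a": roi_a[:, k].std(ddof=1),
                                "mean_b": roi_b[:, k].mean(),
                                "sd_b": roi_b[:, k].std(ddof=1),
                                "t": t, "df": df, "p": p,
                                "d": cohens_d(roi_a[:, k], roi_b[:, k]),
                            }
                        )
            if not family_rows:
                continue
            if plan.family == "metric_pair":
                q, sig = fdr_adjust([r["p"] for r in family_rows], plan.alpha)
                for r, qi, si in zip(family_rows, q, sig):
                    r["q"], r["significant"] = qi, bool(si)
            elif plan.family == "cell":
                for r in family_rows:
                    r["q"], r["significant"] = r["p"], r["p"] <= plan.alpha
            else:
                raise ValueError(f"unknown FDR family {plan.family!r}")
            rows.extend(family_rows)
    return pd.DataFrame(rows)
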