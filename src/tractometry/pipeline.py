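"""Top-level pipeline orchestration and the run manifest.

Two end-to-end modes over synthetic cohorts:

* profile mode — generate a tract-profile cohort, run the ROI-level group
  comparisons with FDR, the section-wise t-profiles, the ROC curves for the
  two outcome-discriminating features, and the combined two-threshold rule;
* image mode — generate per-subject DWI phantoms, fit tensors, run Euler
  tractography, segment/clean the bundles, extract MD/FA profiles, and for
  operated subjects compute lacuna overlap and the resection comparison.

Every stage writes CSV; a JSON manifest records the seed, parameters and
per-tract detection counts so a run is reproducible from (config, seed).
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bundles import clean_bundle, compute_profile, segment_bundle
from .classify import CombinedRule, apply_combined_rule, confusion_summary, roc_curve
from .dti import compute_fa, compute_md, fit_tensor
from .io import TRACTS, LATERALITIES
from .resection import compare_resection, resection_profile
from .stats import ComparisonPlan, profile_matrix, roi_average, run_group_comparison, sectionwise_t
from .synthetic import (
    GeneratorConfig,
    SubjectPhantom,
    generate_image_subject,
    generate_lacuna,
    generate_profile_cohort,
)
from .tracking import TrackingParams, track_whole_mask


@dataclass
class PipelineConfig:
    seed: int = 0
    mode: str = "profile"
    out_dir: str = "results"
    generator: GeneratorConfig | None = None
    tracking: TrackingParams = field(default_factory=TrackingParams)
    plan: ComparisonPlan = field(default_factory=ComparisonPlan)
    combined_rule: CombinedRule = field(default_factory=CombinedRule)
    weighting: str = "gaussian"
    #: image-mode cohort size per group (kept desk-scale)
    image_subjects_per_group: int = 2
    #: stage toggles; None enables everything, () writes the manifest only
    stages: tuple[str, ...] | None = None

    def stage_enabled(self, name: str) -> bool:
        return self.stages is None or name in self.stages

    def resolved_generator(self) -> GeneratorConfig:
        if self.generator is not None:
            return self.generator
        return GeneratorConfig(seed=self.seed, mode=self.mode)


def _write_manifest(out: Path, payload: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=str)


def combined_rule_table(
    profiles: pd.DataFrame, rule: CombinedRule
) -> pd.DataFrame:
    """Per-patient combined-rule features and decision.

    Features are the ROI means the rule is defined on: ipsilateral
    fimbria-fornix dorsal ROI (ROI 2) MD and contralateral parahippocampal
    ROI 2 MD; positive predicts persistent seizures (ILAE2plus).
    """
    rows = []
    for group in ("ILAE1", "ILAE2plus"):
        sel = profiles[(profiles["group"] == group) & (profiles["metric"] == "MD")]
        subjects = sorted(sel["subject"].unique())
        for subj in subjects:
            feats = {}
            for (tract, lat), col in (
                (("fimbria_fornix", "ipsilateral"), "ff_ipsi_md"),
                (("parahippocampal_wmb", "contralateral"), "pwmb_contra_md"),
            ):
                row = sel[
                    (sel["subject"] == subj)
                    & (sel["tract"] == tract)
                    & (sel["laterality"] == lat)
                ]
                if len(row) == 1:
                    vals = row[[f"node_{i}" for i in range(1, 101)]].to_numpy(float)[0]
                    feats[col] = float(roi_average(vals)[1])  # ROI 2
                else:
                    feats[col] = float("nan")
            decision = apply_combined_rule(feats["ff_ipsi_md"], feats["pwmb_contra_md"], rule)
            rows.append(
                {
                    "subject": subj,
                    "group": group,
                    **feats,
                    "positive": decision,
                }
            )
    return pd.DataFrame(rows)


def run_profile_pipeline(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen = config.resolved_generator()
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "mode": "profile",
        "seed": config.seed,
        "generator": asdict(gen),
    }
    if not config.stage_enabled("synthesize"):
        _write_manifest(out, manifest)
        return manifest
    cohort = generate_profile_cohort(gen)
    cohort.cohort_table.to_csv(out / "cohort.csv", index=False)
    cohort.profiles.to_csv(out / "profiles.csv", index=False)
    if not config.stage_enabled("compare"):
        _write_manifest(out, manifest)
        return manifest

    comparison = run_group_comparison(cohort.profiles, config.plan)
    comparison.to_csv(out / "group_comparison.csv", index=False)

    tscore_rows = []
    for tract in TRACTS:
        for lat in LATERALITIES:
            for ga in ("ILAE1", "ILAE2plus"):
                a = profile_matrix(cohort.profiles, ga, tract, lat, "MD")
                b = profile_matrix(cohort.profiles, "control", tract, lat, "MD")
                if len(a) < 2 or len(b) < 2:
                    continue
                ts = sectionwise_t(a, b, alpha=config.plan.alpha)
                ts.insert(0, "tract", tract)
                ts.insert(1, "laterality", lat)
                ts.insert(2, "group", ga)
                tscore_rows.append(ts)
    tscores = pd.concat(tscore_rows, ignore_index=True) if tscore_rows else pd.DataFrame()
    tscores.to_csv(out / "sectionwise_t.csv", index=False)
    manifest["n_comparisons"] = int(len(comparison))
    if not config.stage_enabled("classify"):
        _write_manifest(out, manifest)
        return manifest

    combined = combined_rule_table(cohort.profiles, config.combined_rule)
    combined.to_csv(out / "combined_rule.csv", index=False)
    classifiable = combined[combined["positive"].notna()]
    summary = {}
    if len(classifiable):
        cs = confusion_summary(
            classifiable["positive"].astype(bool).to_numpy(),
            (classifiable["group"] == "ILAE2plus").to_numpy(),
        )
        pct = {
            k: (None if isinstance(v, float) and np.isnan(v) else v)
            for k, v in cs.as_percent().items()
        }
        summary = {"counts": [cs.tp, cs.fp, cs.tn, cs.fn], **pct}

    roc_results = {}
    for label, (tract, lat) in {
        "ff_ipsi_md": ("fimbria_fornix", "ipsilateral"),
        "pwmb_contra_md": ("parahippocampal_wmb", "contralateral"),
    }.items():
        vals = combined[label].to_numpy(float)
        labels = (combined["group"] == "ILAE2plus").to_numpy()
        ok = np.isfinite(vals)
        if labels[ok].any() and (~labels[ok]).any():
            roc_results[label] = roc_curve(vals[ok], labels[ok], label=label).auc
    manifest["combined_rule"] = summary
    manifest["auc"] = roc_results
    _write_manifest(out, manifest)
    return manifest


def process_image_subject(
    phantom: SubjectPhantom,
    params: TrackingParams,
    weighting: str = "gaussian",
) -> dict:
    """Fit -> track -> segment -> profile one phantom; returns per-tract results."""
    tensor = fit_tensor(phantom.dwi, phantom.scheme, phantom.brain_mask.data, phantom.affine)
    md = compute_md(tensor)
    fa = compute_fa(tensor)
    streamlines = track_whole_mask(tensor, fa, phantom.brain_mask, params)
    results: dict = {"n_streamlines": len(streamlines), "bundles": {}}
    for key, wp in phantom.waypoints.items():
        bundle = segment_bundle(streamlines, wp)
        if bundle.detected:
            bundle = clean_bundle(bundle)
        entry: dict = {"detected": bundle.detected, "n": len(bundle.streamlines)}
        if bundle.detected:
            entry["bundle"] = bundle
            entry["md_profile"] = compute_profile(
                bundle, md, subject=phantom.subject, weighting=weighting
            )
            entry["fa_profile"] = compute_profile(
                bundle, fa, subject=phantom.subject, weighting=weighting
            )
        results["bundles"][key] = entry
    results["md"], results["fa"] = md, fa
    return results


def run_image_pipeline(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen = config.generator
    if gen is None:
        # image-mode cohorts are desk-scale by default; DWI simulation and
        # whole-mask tracking dominate runtime per subject
        gen = GeneratorConfig(
            seed=config.seed, mode="image",
            n_controls=config.image_subjects_per_group,
            n_ilae1=config.image_subjects_per_group,
            n_ilae2plus=config.image_subjects_per_group,
        )
    elif gen.mode != "image":
        gen = replace(gen, mode="image")
    detection: dict[str, list] = {}
    totals = []
    profile_rows = []
    node_cols = [f"node_{i}" for i in range(1, 101)]
    groups = (
        [("control", i) for i in range(gen.n_controls)]
        + [("ILAE1", i) for i in range(gen.n_ilae1)]
        + [("ILAE2plus", i) for i in range(gen.n_ilae2plus)]
    )
    for group, i in groups:
        sid = f"{group}_{i + 1:03d}_img"
        phantom = generate_image_subject(gen, sid, group=group)
        res = process_image_subject(phantom, config.tracking, config.weighting)
        side = "right" if group != "control" else "none"
        lacuna = (
            generate_lacuna(gen, sid, group, side=side) if group != "control" else None
        )
        for key, entry in res["bundles"].items():
            tract, hemisphere = key
            detection.setdefault(f"{tract}_{hemisphere}_{group}", []).append(
                entry["detected"]
            )
            if not entry["detected"]:
                continue
            for metric in ("md_profile", "fa_profile"):
                prof = entry[metric]
                row = {
                    "subject": sid, "group": group, "tract": tract,
                    "laterality": hemisphere, "metric": prof.metric,
                }
                row.update(dict(zip(node_cols, prof.values)))
                profile_rows.append(row)
            if lacuna is not None and hemisphere == side:
                rp = resection_profile(
                    entry["bundle"], lacuna, subject=sid, weighting=config.weighting
                )
                totals.append(
                    {"subject": sid, "group": group, "tract": tract, "total": rp.total}
                )
    pd.DataFrame(profile_rows).to_csv(out / "image_profiles.csv", index=False)
    totals_df = pd.DataFrame(totals)
    totals_df.to_csv(out / "resection_totals.csv", index=False)
    resection_cmp = (
        compare_resection(totals_df) if len(totals_df) else pd.DataFrame()
    )
    resection_cmp.to_csv(out / "resection_comparison.csv", index=False)
    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "mode": "image",
        "seed": config.seed,
        "generator": {
            k: v for k, v in asdict(gen).items() if k not in ("effect_table", "lacuna_params")
        },
        "detection": {
            k: f"identified in {sum(v)} of {len(v)} subjects" for k, v in detection.items()
        },
    }
    _write_manifest(out, manifest)
    return manifest


def run_pipeline(config: PipelineConfig) -> dict:
    if config.mode == "profile":
        return run_profile_pipeline(config)
    if config.mode == "image":
        return run_image_pipeline(config)
    raise ValueError(f"unknown pipeline mode {config.mode!r}")
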