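"""End-to-end orchestration: simulate -> GLM -> reliability -> ROI -> report.

Runs the full test-retest analysis for each task variant from a single
declarative config, writing every intermediate as a NIfTI/TSV artifact in a
BIDS-derivatives-like layout, and assembles a per-condition summary table
(median thresholded ICC, ROI ICC, activation-masked sweep medians, overlap
percentage) mirroring the study's headline tables.

Stages communicate through the output directory, so the CLI can run them
individually; every random stream is spawned from the single config seed,
making reruns byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .glm import (
    GroupResult,
    build_design_matrix,
    fit_first_level,
    fixed_effects_combine,
    group_one_sample,
    smooth_gaussian,
)
from .reliability import (
    DEFAULT_SWEEP_THRESHOLDS,
    EmptyMaskError,
    activation_masked_medians,
    classify_icc,
    icc_map,
    icc_standardize,
    median_icc,
    overlap_percentage,
    pairing_permutation_null,
    threshold_icc_map,
)
from .roi_analysis import ROISpec, default_roi_specs, read_roi_specs, roi_icc_table
from .synthetic import (
    AcquisitionSpec,
    VarianceModel,
    default_topology,
    simulate_cohort,
    write_motion_par,
)
from .task_design import ACTIVE_CONDITIONS, VARIANTS, generate_schedule, write_events

log = logging.getLogger("taskrel")

_VARIANT_SLUG = {"eye-movement": "eyemove", "working-memory": "workmem"}
_COGNITIVE_LABEL = {"eye-movement": "eye-movement", "working-memory": "working memory"}


@dataclass
class PipelineConfig:
    """Declarative configuration of a full synthetic reliability run."""

    variants: tuple[str, ...] = VARIANTS
    n_subjects: int = 15
    seed: int = 42
    session_orders: tuple[str, str] = ("forward", "forward")

    # acquisition
    tr: float = 2.0
    n_volumes: int = 155
    grid_shape: tuple[int, int, int] = (20, 24, 20)
    voxel_size: float = 3.0

    # effect topology and variance components
    mu: float = 1.0
    region_radius_mm: float = 7.5
    sigma_b: float = 0.5
    sigma_w: float = 0.2
    sigma_n: float = 1.0
    ar1_rho: float = 0.3
    drift_amp: float = 1.0
    motion_step_sd: float = 0.01

    # GLM / inference
    fwhm_mm: float = 6.0
    highpass_s: float = 100.0
    z_thresh: float = 3.1
    alpha: float = 0.05
    cluster_method: str = "permutation"
    cluster_k: int | None = None
    n_perm: int = 1000

    # reliability / ROI
    sweep_thresholds: tuple[float, ...] = DEFAULT_SWEEP_THRESHOLDS
    roi_spec_file: str | None = None
    family_alpha: float = 0.05
    n_comparisons: int = 8

    def acquisition(self) -> AcquisitionSpec:
        return AcquisitionSpec(
            tr=self.tr,
            n_volumes=self.n_volumes,
            grid_shape=tuple(self.grid_shape),
            voxel_size=self.voxel_size,
        )

    def variance_model(self) -> VarianceModel:
        return VarianceModel(
            sigma_b=self.sigma_b,
            sigma_w=self.sigma_w,
            sigma_n=self.sigma_n,
            ar1_rho=self.ar1_rho,
            drift_amp=self.drift_amp,
        )

    def roi_specs(self, variant: str) -> tuple[ROISpec, ...]:
        if self.roi_spec_file:
            return read_roi_specs(self.roi_spec_file)
        return default_roi_specs(variant)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("variants", "session_orders", "grid_shape", "sweep_thresholds"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def validate_config(config: PipelineConfig) -> list[str]:
    """Range / consistency checks; returns violations, never raises."""
    v: list[str] = []
    for variant in config.variants:
        if variant not in VARIANTS:
            v.append(f"variants: unknown variant {variant!r}")
    if config.n_subjects < 3:
        v.append("n_subjects: need at least 3 subjects")
    if config.tr <= 0:
        v.append("tr: must be positive")
    if config.n_volumes < 1:
        v.append("n_volumes: must be >= 1")
    for name in ("sigma_b", "sigma_w", "sigma_n", "drift_amp", "motion_step_sd"):
        if getattr(config, name) < 0:
            v.append(f"{name}: must be >= 0")
    if not 0 <= config.ar1_rho < 1:
        v.append("ar1_rho: must lie in [0, 1)")
    if config.region_radius_mm <= 0:
        v.append("region_radius_mm: must be positive")
    if config.fwhm_mm < 0:
        v.append("fwhm_mm: must be >= 0")
    if config.highpass_s <= 2 * config.tr:
        v.append("highpass_s: must exceed twice the TR")
    if config.z_thresh <= 0:
        v.append("z_thresh: must be positive")
    if not 0 < config.alpha < 1:
        v.append("alpha: must lie in (0, 1)")
    if config.cluster_method not in ("permutation", "fixed_extent"):
        v.append("cluster_method: must be 'permutation' or 'fixed_extent'")
    if config.cluster_method == "fixed_extent" and not config.cluster_k:
        v.append("cluster_k: required when cluster_method is 'fixed_extent'")
    if list(config.sweep_thresholds) != sorted(config.sweep_thresholds):
        v.append("sweep_thresholds: must be sorted ascending")
    if config.roi_spec_file and not Path(config.roi_spec_file).exists():
        v.append(f"roi_spec_file: {config.roi_spec_file} does not exist")
    else:
        for variant in config.variants:
            if variant in VARIANTS:
                for spec in config.roi_specs(variant):
                    if spec.radius <= 0:
                        v.append(f"roi {spec.name}: radius must be positive")
    if config.n_comparisons < 1:
        v.append("n_comparisons: must be >= 1")
    return v


@dataclass
class RunReport:
    summary: pd.DataFrame
    out_dir: Path
    provenance: dict


# ---------------------------------------------------------------------------
# Artifact helpers
# ---------------------------------------------------------------------------

def _save_nii(arr: np.ndarray, affine: np.ndarray, path: Path, dtype=np.float64) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype), affine), str(path))


def _load_nii(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, float)


def _vdir(out_dir: Path, variant: str) -> Path:
    return Path(out_dir) / f"variant-{_VARIANT_SLUG[variant]}"


def _seed_for(config: PipelineConfig, variant: str, purpose: str) -> np.random.Generator:
    idx = {"simulate": 0, "cluster": 1, "icc_null": 2}[purpose]
    children = np.random.SeedSequence(config.seed).spawn(len(VARIANTS) * 3)
    return np.random.default_rng(children[VARIANTS.index(variant) * 3 + idx])


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_events(config: PipelineConfig, out_dir: Path) -> None:
    """Write each variant's session schedules as BIDS events and FSL EVs."""
    for variant in config.variants:
        d = _vdir(out_dir, variant) / "events"
        d.mkdir(parents=True, exist_ok=True)
        for j, order in enumerate(config.session_orders, start=1):
            sched = generate_schedule(variant, order)
            write_events(sched, "bids_events_tsv", d / f"ses-{j}_events.tsv")
            write_events(sched, "fsl_ev3col", d / f"ses-{j}_fsl_ev")


def stage_simulate(config: PipelineConfig, out_dir: Path) -> None:
    """Simulate the two-session cohort per variant and write BOLD/motion/truth."""
    acq = config.acquisition()
    variance = config.variance_model()
    for variant in config.variants:
        t0 = time.time()
        rng = _seed_for(config, variant, "simulate")
        seed = int(rng.integers(2**31 - 1))
        schedules = [generate_schedule(variant, order) for order in config.session_orders]
        topology = default_topology(variant, acq, mu=config.mu, radius_mm=config.region_radius_mm)
        bold, motion, truth = simulate_cohort(
            config.n_subjects, schedules, topology, variance, acq, seed,
            motion_step_sd=config.motion_step_sd,
        )
        d = _vdir(out_dir, variant) / "bold"
        d.mkdir(parents=True, exist_ok=True)
        rows = []
        for (s, j), ds in bold.items():
            stem = f"sub-{s + 1:02d}_ses-{j + 1}"
            _save_nii(ds.data, acq.affine, d / f"{stem}_bold.nii", dtype=np.float32)
            write_motion_par(motion[(s, j)], d / f"{stem}_motion.par")
            rows.append({"subject": s + 1, "session": j + 1, "bold": f"{stem}_bold.nii",
                         "motion": f"{stem}_motion.par"})
        _save_nii(truth.icc_map, acq.affine, d / "truth_icc.nii")
        pd.DataFrame(rows).to_csv(d / "cohort.tsv", sep="\t", index=False)
        log.info("simulate[%s]: %d runs in %.1fs", variant, len(bold), time.time() - t0)


def stage_glm(config: PipelineConfig, out_dir: Path) -> None:
    """Smooth, fit first-level GLMs, fixed-effects average, group maps."""
    acq = config.acquisition()
    for variant in config.variants:
        t0 = time.time()
        vdir = _vdir(out_dir, variant)
        bold_dir, fl_dir, grp_dir = vdir / "bold", vdir / "firstlevel", vdir / "group"
        fl_dir.mkdir(parents=True, exist_ok=True)
        grp_dir.mkdir(parents=True, exist_ok=True)
        schedules = [generate_schedule(variant, order) for order in config.session_orders]

        effects: dict[tuple[int, int], dict[str, np.ndarray]] = {}
        variances: dict[tuple[int, int], dict[str, np.ndarray]] = {}
        for s in range(config.n_subjects):
            for j in (0, 1):
                stem = f"sub-{s + 1:02d}_ses-{j + 1}"
                data = _load_nii(bold_dir / f"{stem}_bold.nii")
                data = smooth_gaussian(data, config.fwhm_mm, acq.voxel_size)
                mot = np.loadtxt(bold_dir / f"{stem}_motion.par")
                design = build_design_matrix(schedules[j], mot, acq, config.highpass_s)
                res = fit_first_level(data, design)
                effects[(s, j)], variances[(s, j)] = res.effects, res.variances
                for cond in ACTIVE_CONDITIONS:
                    _save_nii(res.effects[cond], acq.affine, fl_dir / f"{stem}_cond-{cond}_effect.nii")
                    _save_nii(res.variances[cond], acq.affine, fl_dir / f"{stem}_cond-{cond}_variance.nii")
                    _save_nii(res.zmaps[cond], acq.affine, fl_dir / f"{stem}_cond-{cond}_z.nii")

        rng = _seed_for(config, variant, "cluster")
        for cond in ACTIVE_CONDITIONS:
            # per-session group maps
            for j in (0, 1):
                grp = group_one_sample(
                    [effects[(s, j)][cond] for s in range(config.n_subjects)],
                    z_thresh=config.z_thresh, alpha=config.alpha,
                    method=config.cluster_method, n_perm=config.n_perm,
                    rng=rng, cluster_k=config.cluster_k,
                )
                _save_nii(grp.z, acq.affine, grp_dir / f"cond-{cond}_ses-{j + 1}_group_z.nii")
            # cross-session fixed effects per subject, then group
            ffx = []
            for s in range(config.n_subjects):
                eff, _var = fixed_effects_combine(
                    [effects[(s, 0)][cond], effects[(s, 1)][cond]],
                    [variances[(s, 0)][cond], variances[(s, 1)][cond]],
                )
                ffx.append(eff)
                _save_nii(eff, acq.affine, fl_dir / f"sub-{s + 1:02d}_cond-{cond}_ffx_effect.nii")
            grp = group_one_sample(
                ffx, z_thresh=config.z_thresh, alpha=config.alpha,
                method=config.cluster_method, n_perm=config.n_perm,
                rng=rng, cluster_k=config.cluster_k,
            )
            _save_nii(grp.z, acq.affine, grp_dir / f"cond-{cond}_xses_group_z.nii")
            _save_nii(grp.corrected_mask.astype(np.uint8), acq.affine,
                      grp_dir / f"cond-{cond}_activation_mask.nii", dtype=np.uint8)
        log.info("glm[%s]: fitted %d runs in %.1fs", variant, 2 * config.n_subjects, time.time() - t0)


def stage_reliability(config: PipelineConfig, out_dir: Path) -> None:
    """Voxel-wise ICC maps, thresholding, sweep medians and overlap."""
    acq = config.acquisition()
    for variant in config.variants:
        t0 = time.time()
        vdir = _vdir(out_dir, variant)
        fl_dir, grp_dir, rel_dir = vdir / "firstlevel", vdir / "group", vdir / "reliability"
        rel_dir.mkdir(parents=True, exist_ok=True)
        rng = _seed_for(config, variant, "icc_null")
        rows = []
        for cond in ACTIVE_CONDITIONS:
            stack = np.stack(
                [
                    np.stack(
                        [_load_nii(fl_dir / f"sub-{s + 1:02d}_ses-{j + 1}_cond-{cond}_effect.nii")
                         for j in (0, 1)]
                    )
                    for s in range(config.n_subjects)
                ]
            )
            icc = icc_map(stack)
            z = icc_standardize(icc, config.n_subjects)
            kwargs = {}
            if config.cluster_method == "permutation":
                kwargs["null_zmaps"] = pairing_permutation_null(stack, config.n_perm, rng)
            else:
                kwargs["cluster_k"] = config.cluster_k
            mapped = threshold_icc_map(
                icc, z, config.n_subjects, z_thresh=config.z_thresh,
                alpha=config.alpha, method=config.cluster_method, **kwargs,
            )
            _save_nii(mapped.icc, acq.affine, rel_dir / f"cond-{cond}_icc.nii")
            _save_nii(mapped.z, acq.affine, rel_dir / f"cond-{cond}_icc_z.nii")
            _save_nii(mapped.sig_mask.astype(np.uint8), acq.affine,
                      rel_dir / f"cond-{cond}_sig_mask.nii", dtype=np.uint8)
            _save_nii(mapped.masked_icc, acq.affine, rel_dir / f"cond-{cond}_icc_masked.nii")

            act_z = _load_nii(grp_dir / f"cond-{cond}_xses_group_z.nii")
            sweep = activation_masked_medians(icc, act_z, config.sweep_thresholds)
            sweep.to_csv(rel_dir / f"cond-{cond}_sweep.tsv", sep="\t", index=False)

            act_mask = _load_nii(grp_dir / f"cond-{cond}_activation_mask.nii") > 0
            try:
                med = median_icc(mapped.masked_icc)
            except EmptyMaskError:
                med = np.nan
            try:
                ovl = overlap_percentage(mapped.sig_mask, act_mask)
            except EmptyMaskError:
                ovl = np.nan
            row = {"condition": cond, "median_thresholded_icc": med,
                   "n_sig_voxels": int(mapped.sig_mask.sum()), "overlap_pct": ovl}
            for thr, m in zip(sweep["z_threshold"], sweep["median_icc"]):
                row[f"sweep_median_z{thr:g}"] = m
            rows.append(row)
        pd.DataFrame(rows).to_csv(rel_dir / "reliability_summary.tsv", sep="\t", index=False)
        log.info("reliability[%s]: done in %.1fs", variant, time.time() - t0)


def stage_roi(config: PipelineConfig, out_dir: Path) -> None:
    """ROI-level ICC and paired-test table per variant."""
    acq = config.acquisition()
    for variant in config.variants:
        vdir = _vdir(out_dir, variant)
        fl_dir = vdir / "firstlevel"
        roi_dir = vdir / "roi"
        roi_dir.mkdir(parents=True, exist_ok=True)
        effects = {
            (s, j): {
                cond: _load_nii(fl_dir / f"sub-{s + 1:02d}_ses-{j + 1}_cond-{cond}_effect.nii")
                for cond in ACTIVE_CONDITIONS
            }
            for s in range(config.n_subjects)
            for j in (0, 1)
        }
        table = roi_icc_table(
            effects, config.roi_specs(variant), acq.affine, acq.grid_shape,
            family_alpha=config.family_alpha, n_comparisons=config.n_comparisons,
        )
        table.to_csv(roi_dir / "roi_table.tsv", sep="\t", index=False)


def stage_report(config: PipelineConfig, out_dir: Path) -> RunReport:
    """Assemble the per-condition summary table and provenance manifest."""
    out_dir = Path(out_dir)
    frames = []
    for variant in config.variants:
        vdir = _vdir(out_dir, variant)
        rel = pd.read_csv(vdir / "reliability" / "reliability_summary.tsv", sep="\t")
        roi = pd.read_csv(vdir / "roi" / "roi_table.tsv", sep="\t")
        roi_small = roi[["condition", "roi", "icc31", "classification"]].rename(
            columns={"roi": "roi_name", "icc31": "roi_icc", "classification": "roi_classification"}
        )
        merged = rel.merge(roi_small, on="condition", how="left")
        merged.insert(0, "variant", variant)
        merged.insert(
            2, "condition_label",
            merged["condition"].map(
                lambda c: _COGNITIVE_LABEL[variant] if c == "cognitive" else c
            ),
        )
        merged.to_csv(vdir / "summary.tsv", sep="\t", index=False)
        frames.append(merged)
    summary = pd.concat(frames, ignore_index=True)
    ordered = ["variant", "condition", "condition_label", "median_thresholded_icc",
               "roi_name", "roi_icc", "roi_classification"]
    sweep_cols = [c for c in summary.columns if c.startswith("sweep_median_")]
    summary = summary[ordered + sweep_cols + ["overlap_pct", "n_sig_voxels"]]
    summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)

    cfg_dict = config.to_dict()
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    provenance = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "taskrel_version": __version__,
        "numpy_version": np.__version__,
    }
    (out_dir / "manifest.json").write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    return RunReport(summary=summary, out_dir=out_dir, provenance=provenance)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


_STAGES = (
    ("events", stage_events),
    ("simulate", stage_simulate),
    ("glm", stage_glm),
    ("reliability", stage_reliability),
    ("roi", stage_roi),
)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunReport:
    """Execute all stages for every configured variant and build the report.

    Deterministic given the config seed: reruns with an identical config
    produce byte-identical TSV outputs.
    """
    violations = validate_config(config)
    if violations:
        raise PipelineError("invalid config: " + "; ".join(violations))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")
    for name, fn in _STAGES:
        t0 = time.time()
        try:
            fn(config, out_dir)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        log.info("stage %s finished in %.1fs", name, time.time() - t0)
    try:
        return stage_report(config, out_dir)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'report' failed: {exc}") from exc
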