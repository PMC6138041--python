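"""Sphere-ROI definition, signal extraction and ROI-level reliability.

Each ROI is a 5 mm-radius sphere around an mm-space centre; per condition the
ROI-mean contrast estimate is extracted for every subject and session, the
n x 2 table feeds ICC(3,1) with its qualitative classification, and a paired
t-test compares the two sessions with a Bonferroni-corrected alpha
(0.05 / 8 = 0.00625 for the default two-variant, four-condition family).

The shipped default coordinates are synthetic placeholders on the simulated
grid (the study's Neurosynth-derived MNI centres are not published); users
analysing real data supply their own specs via TSV/JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reliability import classify_icc, icc31
from .synthetic import SYNTHETIC_REGION_CENTRES_MM


@dataclass(frozen=True)
class ROISpec:
    name: str
    centre: tuple[float, float, float]  # mm coordinates
    radius: float = 5.0  # mm
    condition: str = ""

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")


def default_roi_specs(variant: str) -> tuple[ROISpec, ...]:
    """Four matched ROIs for one variant (cognitive site is FEF or DLPFC).

    Centres are synthetic placeholders aligned with the simulated topology.
    """
    cognitive = "fef" if variant == "eye-movement" else "dlpfc"
    mapping = [("auditory", "auditory"), ("visual", "visual"), ("motor", "motor"), (cognitive, "cognitive")]
    return tuple(
        ROISpec(name=name, centre=SYNTHETIC_REGION_CENTRES_MM[name], radius=5.0, condition=cond)
        for name, cond in mapping
    )


def write_roi_specs(specs: Sequence[ROISpec], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"name": s.name, "x": s.centre[0], "y": s.centre[1], "z": s.centre[2],
         "radius_mm": s.radius, "condition": s.condition}
        for s in specs
    ]
    if path.suffix == ".json":
        path.write_text(json.dumps(rows, indent=2) + "\n")
    else:
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_roi_specs(path: str | Path) -> tuple[ROISpec, ...]:
    path = Path(path)
    if path.suffix == ".json":
        rows = json.loads(path.read_text())
    else:
        rows = pd.read_csv(path, sep="\t").to_dict("records")
    return tuple(
        ROISpec(name=r["name"], centre=(float(r["x"]), float(r["y"]), float(r["z"])),
                radius=float(r["radius_mm"]), condition=str(r["condition"]))
        for r in rows
    )


def sphere_mask(spec: ROISpec, affine: np.ndarray, shape: Sequence[int]) -> np.ndarray:
    """Binary sphere mask on the grid: voxel centres within ``radius`` mm.

    Distances are affine-aware (voxel centre to ROI centre, in mm) with an
    inclusive boundary.  If no voxel centre falls inside the sphere the
    single nearest voxel is included, so the mask is never empty.  A centre
    outside the grid's bounding box is an error.
    """
    affine = np.asarray(affine, float)
    shape = tuple(int(s) for s in shape)
    inv = np.linalg.inv(affine)
    centre_vox = (inv @ np.append(spec.centre, 1.0))[:3]
    if np.any(centre_vox < -0.5) or np.any(centre_vox > np.asarray(shape) - 0.5):
        raise ValueError(f"ROI {spec.name!r} centre {spec.centre} maps outside the grid")
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    mm = vox @ affine.T
    d2 = ((mm[..., :3] - np.asarray(spec.centre)) ** 2).sum(axis=-1)
    mask = d2 <= spec.radius**2
    if not mask.any():
        mask.flat[np.argmin(d2)] = True
    return mask


def extract_mean(effect_map: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of an effect map over a binary mask."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    return float(np.asarray(effect_map, float)[mask].mean())


def roi_icc_table(
    effects: Mapping[tuple[int, int], Mapping[str, np.ndarray]],
    roi_specs: Sequence[ROISpec],
    affine: np.ndarray,
    shape: Sequence[int],
    family_alpha: float = 0.05,
    n_comparisons: int = 8,
) -> pd.DataFrame:
    """ROI-level reliability table.

    Parameters
    ----------
    effects : (subject, session) -> {condition -> 3D effect map}; every
        subject must have exactly sessions 0 and 1.
    n_comparisons : size of the paired-test family for the Bonferroni
        correction (8 for the two-variant, four-condition study design).

    Returns one row per ROI: per-session means, ICC(3,1) with its
    classification, and the two-sided paired t-test across sessions flagged
    at the corrected alpha.
    """
    subjects = sorted({s for s, _ in effects})
    for s in subjects:
        if (s, 0) not in effects or (s, 1) not in effects:
            raise ValueError(f"subject {s} is missing a session")
    corrected_alpha = family_alpha / n_comparisons
    rows = []
    for spec in roi_specs:
        mask = sphere_mask(spec, affine, shape)
        vals = np.array(
            [[extract_mean(effects[(s, j)][spec.condition], mask) for j in (0, 1)] for s in subjects]
        )
        icc = icc31(vals)
        if np.allclose(vals[:, 0], vals[:, 1]):
            tstat, pval = 0.0, 1.0
        else:
            tstat, pval = stats.ttest_rel(vals[:, 0], vals[:, 1])
        rows.append(
            {
                "condition": spec.condition,
                "roi": spec.name,
                "n_voxels": int(mask.sum()),
                "mean_session1": float(vals[:, 0].mean()),
                "mean_session2": float(vals[:, 1].mean()),
                "icc31": icc,
                "classification": classify_icc(float(np.clip(icc, -1.0, 1.0))),
                "paired_t": float(tstat),
                "p_value": float(pval),
                "corrected_alpha": corrected_alpha,
                "significant": bool(pval < corrected_alpha),
            }
        )
    return pd.DataFrame(rows)
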