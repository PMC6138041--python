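"""Voxel-wise and scalar ICC(3,1) reliability statistics.

The consistency intraclass correlation ICC(3,1) (two-way mixed effects,
single measure) for an n-subject x k-session table is

    ICC(3,1) = (BMS - EMS) / (BMS + (k - 1) * EMS)

with BMS the between-subjects and EMS the residual mean square of the
two-way ANOVA decomposition; session (rater) main effects are absorbed by
the model, so an additive session offset leaves the coefficient unchanged.
Negative estimates are reported as computed — flooring at zero would bias
the median summaries.

For map-level thresholding, ICC values are standardized with the Fisher
variance-stabilizing transform, z = atanh(ICC) * sqrt(n - 3), which is
approximately standard normal under the null, and the resulting Z image is
cluster-corrected with the same extent machinery as the activation maps.
The surviving mask is applied to the *original* ICC image, so the reported
map retains interpretable ICC values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .glm import cluster_correct

DEFAULT_SWEEP_THRESHOLDS = (2.3, 3.1, 3.7, 4.3)

_ATANH_CLIP = 1.0 - 1e-7


class IccUndefinedError(ValueError):
    """ICC requested on data with zero subject-plus-residual variance."""


class EmptyMaskError(ValueError):
    """A summary statistic was requested over an empty voxel mask."""


@dataclass(frozen=True)
class AnovaMeanSquares:
    """Two-way ANOVA mean squares underlying ICC(3,1)."""

    bms: float | np.ndarray  # between subjects
    jms: float | np.ndarray  # between sessions (raters)
    ems: float | np.ndarray  # residual
    n: int
    k: int


@dataclass
class ICCMap:
    """Voxel-wise ICC image with its standardized-Z companion and mask."""

    icc: np.ndarray
    z: np.ndarray
    sig_mask: np.ndarray
    masked_icc: np.ndarray
    n_subjects: int


def anova_mean_squares(data: np.ndarray) -> AnovaMeanSquares:
    """Two-way decomposition of an (n, k, ...) table: BMS, JMS, EMS.

    Trailing axes (e.g. voxels) are carried through element-wise.
    """
    data = np.asarray(data, float)
    if data.ndim < 2:
        raise ValueError("data must be at least (n_subjects, k_sessions)")
    n, k = data.shape[:2]
    if n < 2 or k < 2:
        raise ValueError("need n >= 2 subjects and k >= 2 sessions")
    gm = data.mean(axis=(0, 1))
    rm = data.mean(axis=1)
    cm = data.mean(axis=0)
    ss_rows = k * ((rm - gm) ** 2).sum(axis=0)
    ss_cols = n * ((cm - gm) ** 2).sum(axis=0)
    ss_tot = ((data - gm) ** 2).sum(axis=(0, 1))
    ss_err = np.maximum(ss_tot - ss_rows - ss_cols, 0.0)
    return AnovaMeanSquares(
        bms=ss_rows / (n - 1),
        jms=ss_cols / (k - 1),
        ems=ss_err / ((n - 1) * (k - 1)),
        n=n,
        k=k,
    )


def icc31(data: np.ndarray) -> float:
    """Consistency ICC(3,1) of an (n_subjects, k_sessions) matrix.

    Raises IccUndefinedError when the subject and residual variance are both
    zero (the ratio is 0/0) rather than silently returning 0.
    """
    data = np.asarray(data, float)
    if data.ndim != 2:
        raise ValueError("expected a 2-D subjects-by-sessions matrix")
    if not np.all(np.isfinite(data)):
        raise ValueError("data must be finite")
    ms = anova_mean_squares(data)
    denom = ms.bms + (ms.k - 1) * ms.ems
    if denom == 0:
        raise IccUndefinedError("zero subject and residual variance; ICC undefined")
    return float((ms.bms - ms.ems) / denom)


def icc31_confint(data: np.ndarray, conf: float = 0.95) -> tuple[float, float]:
    """Exact F-based confidence interval for ICC(3,1) (Shrout-Fleiss)."""
    ms = anova_mean_squares(np.asarray(data, float))
    if ms.ems == 0:
        return (1.0, 1.0) if ms.bms > 0 else (np.nan, np.nan)
    f_obs = ms.bms / ms.ems
    df1, df2 = ms.n - 1, (ms.n - 1) * (ms.k - 1)
    a = 1.0 - conf
    fl = f_obs / stats.f.ppf(1 - a / 2, df1, df2)
    fu = f_obs * stats.f.ppf(1 - a / 2, df2, df1)
    return (fl - 1) / (fl + ms.k - 1), (fu - 1) / (fu + ms.k - 1)


def icc_map(contrast_stack: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Voxel-wise ICC(3,1) over a (n_subjects, 2, x, y, z) contrast stack.

    Out-of-mask and zero-variance voxels are NaN.  Only the two-session case
    is supported.
    """
    stack = np.asarray(contrast_stack, float)
    if stack.ndim < 3:
        raise ValueError("expected (n_subjects, n_sessions, ...) stack")
    if stack.shape[1] != 2:
        raise ValueError("only exactly 2 sessions are supported")
    ms = anova_mean_squares(stack)
    denom = ms.bms + (ms.k - 1) * ms.ems
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = np.where(denom > 0, (ms.bms - ms.ems) / denom, np.nan)
    if mask is not None:
        icc = np.where(np.asarray(mask, bool), icc, np.nan)
    return icc


def icc_standardize(icc_image: np.ndarray, n: int) -> np.ndarray:
    """Fisher-transform standardization: z = atanh(ICC) * sqrt(n - 3).

    ICC is clipped to +/-(1 - 1e-7) before atanh; the map is monotone in ICC.
    """
    if n < 4:
        raise ValueError("standardization needs n >= 4 subjects")
    icc = np.clip(np.asarray(icc_image, float), -_ATANH_CLIP, _ATANH_CLIP)
    return np.arctanh(icc) * np.sqrt(n - 3.0)


def pairing_permutation_null(
    contrast_stack: np.ndarray,
    n_perm: int,
    rng: int | np.random.Generator = 0,
    mask: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Null standardized-Z maps obtained by shuffling the session-2 pairing.

    Randomly re-assigning each subject's session-2 map to another subject
    destroys within-subject consistency while preserving the marginal
    distributions, giving an ICC ~ 0 null for cluster correction.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    stack = np.asarray(contrast_stack, float)
    n = stack.shape[0]
    out = []
    for _ in range(n_perm):
        perm = rng.permutation(n)
        shuffled = np.stack([stack[:, 0], stack[perm, 1]], axis=1)
        out.append(icc_standardize(icc_map(shuffled, mask), n))
    return out


def threshold_icc_map(
    icc_image: np.ndarray,
    z_image: np.ndarray,
    n_subjects: int,
    z_thresh: float = 3.1,
    alpha: float = 0.05,
    method: str = "permutation",
    mask: np.ndarray | None = None,
    **cluster_kwargs,
) -> ICCMap:
    """Cluster-correct the standardized map and mask the original ICC image.

    The surviving voxels retain their original ICC values; everything else is
    NaN in ``masked_icc``.  ``cluster_kwargs`` are forwarded to
    ``cluster_correct`` (``null_zmaps`` for the permutation null,
    ``cluster_k`` for a fixed extent).
    """
    icc_image = np.asarray(icc_image, float)
    z_image = np.asarray(z_image, float)
    if icc_image.shape != z_image.shape:
        raise ValueError("icc and z images must share a shape")
    sig = cluster_correct(
        z_image, z_thresh=z_thresh, alpha=alpha, method=method, mask=mask, **cluster_kwargs
    )
    masked = np.where(sig, icc_image, np.nan)
    return ICCMap(icc=icc_image, z=z_image, sig_mask=sig, masked_icc=masked, n_subjects=n_subjects)


def median_icc(masked_icc: np.ndarray) -> float:
    """Median over the retained (non-NaN) voxels of a thresholded ICC image."""
    vals = np.asarray(masked_icc, float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise EmptyMaskError("no retained voxels; median undefined")
    return float(np.median(vals))


def activation_masked_medians(
    icc_image: np.ndarray,
    activation_zmap: np.ndarray,
    thresholds: Sequence[float] = DEFAULT_SWEEP_THRESHOLDS,
) -> pd.DataFrame:
    """Median unthresholded ICC within progressively stricter activation masks.

    Each row: the plain voxel threshold on the activation Z map (no cluster
    step), the mask's voxel count, the median ICC inside it, and an
    ``empty`` flag when no voxel survives (the row is kept, with NaN median).
    """
    icc_image = np.asarray(icc_image, float)
    activation_zmap = np.asarray(activation_zmap, float)
    if icc_image.shape != activation_zmap.shape:
        raise ValueError("icc and activation images must share a shape")
    rows = []
    for thr in thresholds:
        m = (activation_zmap > thr) & np.isfinite(icc_image)
        n_vox = int(m.sum())
        med = float(np.median(icc_image[m])) if n_vox else np.nan
        rows.append({"z_threshold": thr, "median_icc": med, "n_voxels": n_vox, "empty": n_vox == 0})
    return pd.DataFrame(rows)


def overlap_percentage(icc_sig_mask: np.ndarray, activation_mask: np.ndarray) -> float:
    """Percentage of supra-threshold ICC voxels also supra-threshold in activation."""
    icc_sig_mask = np.asarray(icc_sig_mask, bool)
    activation_mask = np.asarray(activation_mask, bool)
    if icc_sig_mask.shape != activation_mask.shape:
        raise ValueError("masks must share a grid")
    n_icc = icc_sig_mask.sum()
    if n_icc == 0:
        raise EmptyMaskError("empty ICC mask; overlap undefined")
    return 100.0 * float((icc_sig_mask & activation_mask).sum()) / float(n_icc)


def classify_icc(value: float) -> str:
    """Cicchetti-style qualitative band for an ICC value.

    excellent: > 0.75; good: [0.6, 0.75]; fair: [0.4, 0.6); poor: < 0.4.
    """
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"ICC value {value} outside [-1, 1]")
    if value > 0.75:
        return "excellent"
    if value >= 0.6:
        return "good"
    if value >= 0.4:
        return "fair"
    return "poor"
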