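"""First-level GLM estimation, session averaging and group activation maps.

Per subject-session the BOLD time-series is regressed voxel-wise on four
HRF-convolved condition regressors, their temporal derivatives, a 24-column
extended head-motion confound set and a discrete-cosine drift basis (100 s
high-pass).  Contrasts isolate each active condition against the implicit
null-trial baseline.  A subject's two sessions are combined with
inverse-variance-weighted fixed effects; group inference is a one-sample OLS
t-test across subjects converted to Z, with cluster-extent correction by a
sign-flip permutation null (or a user-supplied fixed extent).

Design choices that differ from the common FSL pipeline: the group model is
plain OLS (not FLAME mixed effects), the high-pass is a DCT projection basis
rather than a Gaussian-weighted running line, and no prewhitening is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .synthetic import AcquisitionSpec, BOLDDataset, MOTION_COLUMNS, condition_regressor
from .task_design import ACTIVE_CONDITIONS, EventSchedule

Z_CAP = 38.0  # |z| beyond which the normal quantile overflows double precision

#: 26-neighbour connectivity for volumetric cluster labelling
CLUSTER_STRUCTURE = np.ones((3, 3, 3), dtype=bool)


class DesignError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Confounds and filtering
# ---------------------------------------------------------------------------

def extend_motion_regressors(motion: np.ndarray) -> pd.DataFrame:
    """Expand 6 rigid-body parameters to the 24-column Friston-style set.

    Columns, in order: the 6 parameters, their 6 backward-difference temporal
    derivatives (first row 0), the 6 squared parameters, and the 6 squared
    derivatives.
    """
    motion = np.asarray(motion, float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise DesignError(f"motion trace must have 6 columns, got shape {motion.shape}")
    deriv = np.zeros_like(motion)
    deriv[1:] = np.diff(motion, axis=0)
    blocks = [motion, deriv, motion**2, deriv**2]
    names = (
        list(MOTION_COLUMNS)
        + [f"{c}_derivative" for c in MOTION_COLUMNS]
        + [f"{c}_sq" for c in MOTION_COLUMNS]
        + [f"{c}_derivative_sq" for c in MOTION_COLUMNS]
    )
    return pd.DataFrame(np.hstack(blocks), columns=names)


def highpass_filter(n_volumes: int, tr: float, cutoff_s: float = 100.0) -> pd.DataFrame:
    """Discrete-cosine drift basis implementing a high-pass at ``cutoff_s``.

    Returns the basis columns (constant term first, then DCT-II cosines with
    periods longer than the cutoff: K = floor(2 * T * tr / cutoff) of them).
    Residualizing a series against this basis removes fluctuations slower
    than the cutoff.
    """
    if cutoff_s <= 2 * tr:
        raise DesignError("high-pass cutoff must exceed twice the TR")
    total = n_volumes * tr
    n_cos = int(math.floor(2.0 * total / cutoff_s))
    t = np.arange(n_volumes)
    cols = [np.ones(n_volumes)]
    names = ["drift_0"]
    for k in range(1, n_cos + 1):
        cols.append(np.cos(np.pi * k * (2 * t + 1) / (2 * n_volumes)))
        names.append(f"drift_{k}")
    basis = np.stack(cols, axis=1)
    basis /= np.linalg.norm(basis, axis=0)
    return pd.DataFrame(basis, columns=names)


def residualize(series: np.ndarray, basis: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Project out the drift basis from a time-series (last axis = time)."""
    B = np.asarray(basis, float)
    proj = B @ np.linalg.pinv(B)
    return series - series @ proj.T


def smooth_gaussian(volume4d: np.ndarray, fwhm_mm: float = 6.0, voxel_size: float = 3.0) -> np.ndarray:
    """Per-volume 3D Gaussian smoothing; fwhm 0 is the identity.

    sigma = fwhm / (2 sqrt(2 ln 2)) converted to voxel units; zero-padded
    (``constant``) boundaries, so total intensity is conserved away from the
    edges only.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return volume4d.copy()
    sigma_vox = fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / voxel_size
    out = np.empty_like(volume4d, dtype=float)
    for t in range(volume4d.shape[-1]):
        out[..., t] = ndimage.gaussian_filter(volume4d[..., t], sigma_vox, mode="constant")
    return out


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Named design matrix: conditions, derivatives, motion, drift."""

    frame: pd.DataFrame
    condition_names: tuple[str, ...]

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def names(self) -> list[str]:
        return list(self.frame.columns)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def build_design_matrix(
    schedule: EventSchedule,
    motion: np.ndarray,
    acq: AcquisitionSpec,
    highpass_s: float = 100.0,
) -> DesignMatrix:
    """Assemble the first-level design for one run.

    Columns, in order: 4 HRF-convolved condition regressors, their 4
    backward-difference temporal derivatives, 24 extended motion confounds,
    then the DCT drift basis (constant included).  Condition columns are not
    mean-centred — the null trials are the implicit baseline.
    """
    active = [c for c in ACTIVE_CONDITIONS if schedule.condition_counts()[c] > 0]
    if not active:
        raise DesignError("schedule contains no active-condition trials")
    cols: dict[str, np.ndarray] = {}
    for c in active:
        cols[c] = condition_regressor(schedule, c, acq.tr, acq.n_volumes)
    for c in active:
        d = np.zeros(acq.n_volumes)
        d[1:] = np.diff(cols[c])
        cols[f"{c}_derivative"] = d
    mot = extend_motion_regressors(motion[: acq.n_volumes])
    for name in mot.columns:
        cols[name] = mot[name].to_numpy()
    drift = highpass_filter(acq.n_volumes, acq.tr, highpass_s)
    for name in drift.columns:
        cols[name] = drift[name].to_numpy()
    frame = pd.DataFrame(cols)
    return DesignMatrix(frame=frame, condition_names=tuple(active))


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

def t_to_z(t: np.ndarray, dof: float) -> np.ndarray:
    """Map t statistics to standard-normal quantiles of equal tail mass."""
    t = np.asarray(t, float)
    z = np.empty_like(t)
    pos = t >= 0
    with np.errstate(divide="ignore"):
        z[pos] = stats.norm.isf(stats.t.sf(t[pos], dof))
        z[~pos] = stats.norm.ppf(stats.t.cdf(t[~pos], dof))
    return np.clip(np.nan_to_num(z, nan=0.0, posinf=Z_CAP, neginf=-Z_CAP), -Z_CAP, Z_CAP)


@dataclass
class FirstLevelResult:
    """Per-condition effect, variance and Z maps for one subject-session."""

    effects: dict[str, np.ndarray]
    variances: dict[str, np.ndarray]
    zmaps: dict[str, np.ndarray]
    betas: pd.DataFrame  # regressor x voxel (flattened) betas
    dof: int
    grid_shape: tuple[int, ...]


def fit_first_level(
    bold: BOLDDataset | np.ndarray,
    design: DesignMatrix,
    mask: np.ndarray | None = None,
) -> FirstLevelResult:
    """Voxel-wise OLS fit; each active condition's contrast is its canonical
    regressor's beta against zero, with t mapped to Z at the residual dof."""
    data = bold.data if isinstance(bold, BOLDDataset) else bold
    grid_shape = data.shape[:-1]
    n_vol = data.shape[-1]
    X = design.matrix
    if X.shape[0] != n_vol:
        raise DesignError("design rows must equal number of volumes")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify near-dependent columns via the R diagonal of a pivoted QR
        r_diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        bad = [design.names[i] for i in np.flatnonzero(r_diag < 1e-8 * r_diag.max())]
        raise DesignError(f"rank-deficient design; collinear columns involve {bad or design.names}")
    Y = data.reshape(-1, n_vol).T  # time x voxels
    if mask is not None:
        flat_mask = np.asarray(mask, bool).ravel()
        Y = Y[:, flat_mask]
    else:
        flat_mask = np.ones(int(np.prod(grid_shape)), bool)

    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    dof = n_vol - rank
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)

    def unflatten(v: np.ndarray) -> np.ndarray:
        full = np.full(flat_mask.size, np.nan)
        full[flat_mask] = v
        return full.reshape(grid_shape)

    effects, variances, zmaps = {}, {}, {}
    for cond in design.condition_names:
        i = design.names.index(cond)
        eff = beta[i]
        var = sigma2 * xtx_inv[i, i]
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(var > 0, eff / np.sqrt(var), np.sign(eff) * np.inf)
        effects[cond] = unflatten(eff)
        variances[cond] = unflatten(var)
        zmaps[cond] = unflatten(t_to_z(tstat, dof))
    betas = pd.DataFrame(beta, index=design.names)
    return FirstLevelResult(
        effects=effects, variances=variances, zmaps=zmaps, betas=betas, dof=dof, grid_shape=grid_shape
    )


def fixed_effects_combine(
    effects: Sequence[np.ndarray], variances: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-variance-weighted average of session-level contrast estimates.

    Returns (combined effect, combined variance) with
    v = 1 / sum(1/v_j); an infinite-variance session contributes nothing.
    """
    effects = [np.asarray(e, float) for e in effects]
    variances = [np.asarray(v, float) for v in variances]
    if len({e.shape for e in effects} | {v.shape for v in variances}) != 1:
        raise DesignError("session maps must share one grid")
    with np.errstate(divide="ignore"):
        weights = [1.0 / v for v in variances]
    wsum = np.sum(weights, axis=0)
    comb_var = 1.0 / wsum
    comb_eff = np.sum([w * e for w, e in zip(weights, effects)], axis=0) * comb_var
    return comb_eff, comb_var


# ---------------------------------------------------------------------------
# Group inference and cluster correction
# ---------------------------------------------------------------------------

@dataclass
class GroupResult:
    mean: np.ndarray
    z: np.ndarray
    corrected_mask: np.ndarray
    meta: dict


def _label_sizes(binary: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels, n = ndimage.label(binary, structure=CLUSTER_STRUCTURE)
    sizes = np.bincount(labels.ravel())[1:] if n else np.array([], int)
    return labels, sizes


def _sign_flip_max_sizes(
    subject_maps: np.ndarray,
    t_thresh: float,
    grid_shape: tuple[int, ...],
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Max cluster extent under the one-sample sign-flip null, per permutation.

    Vectorized: the squared data are sign-invariant, so each permutation's t
    map needs only the flipped mean.
    """
    X = subject_maps.reshape(subject_maps.shape[0], -1)
    n = X.shape[0]
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    means = signs @ X / n
    msq = (X**2).mean(axis=0)
    var = (msq - means**2) * n / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tmaps = means / np.sqrt(var / n)
    tmaps = np.nan_to_num(tmaps, nan=0.0, posinf=np.inf, neginf=-np.inf)
    out = np.zeros(n_perm, int)
    supra = tmaps > t_thresh
    for p in range(n_perm):
        _, sizes = _label_sizes(supra[p].reshape(grid_shape))
        if sizes.size:
            out[p] = sizes.max()
    return out


def _null_zmap_max_sizes(null_zmaps: Sequence[np.ndarray], z_thresh: float) -> np.ndarray:
    out = np.zeros(len(null_zmaps), int)
    for p, zm in enumerate(null_zmaps):
        _, sizes = _label_sizes(np.asarray(zm) > z_thresh)
        if sizes.size:
            out[p] = sizes.max()
    return out


def cluster_correct(
    zmap: np.ndarray,
    z_thresh: float = 3.1,
    alpha: float = 0.05,
    method: str = "permutation",
    mask: np.ndarray | None = None,
    *,
    subject_maps: np.ndarray | None = None,
    null_zmaps: Sequence[np.ndarray] | None = None,
    cluster_k: int | None = None,
    n_perm: int = 1000,
    rng: int | np.random.Generator = 0,
) -> np.ndarray:
    """Cluster-extent correction of a Z map.

    Voxels with z > ``z_thresh`` are grouped into 26-connected clusters; a
    cluster survives if its extent is improbably large under the chosen null:

    - ``method="permutation"``: the max-cluster-extent null comes either from
      one-sample sign flips of ``subject_maps`` or from pre-computed
      ``null_zmaps``; a cluster of size s survives if
      (1 + #{null max >= s}) / (n_perm + 1) <= alpha.
    - ``method="fixed_extent"``: clusters of at least ``cluster_k`` voxels
      survive.

    Returns the binary mask of surviving voxels.
    """
    if z_thresh <= 0:
        raise ValueError("z_thresh must be positive")
    zmap = np.asarray(zmap, float)
    work = np.where(np.isnan(zmap), -np.inf, zmap)
    if mask is not None:
        work = np.where(np.asarray(mask, bool), work, -np.inf)
    labels, sizes = _label_sizes(work > z_thresh)
    surviving = np.zeros(zmap.shape, bool)
    if sizes.size == 0:
        return surviving

    if method == "fixed_extent":
        if cluster_k is None:
            raise ValueError("fixed_extent requires cluster_k")
        keep = np.flatnonzero(sizes >= cluster_k) + 1
    elif method == "permutation":
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        if subject_maps is not None:
            n = subject_maps.shape[0]
            t_thr = stats.t.isf(stats.norm.sf(z_thresh), n - 1)
            null_max = _sign_flip_max_sizes(subject_maps, t_thr, zmap.shape, n_perm, rng)
        elif null_zmaps is not None:
            null_max = _null_zmap_max_sizes(null_zmaps, z_thresh)
        else:
            raise ValueError("permutation method needs subject_maps or null_zmaps")
        n_null = null_max.size
        pvals = np.array([(1 + (null_max >= s).sum()) / (n_null + 1) for s in sizes])
        keep = np.flatnonzero(pvals <= alpha) + 1
    else:
        raise ValueError(f"unknown cluster-correction method {method!r}")

    if keep.size:
        surviving = np.isin(labels, keep)
    return surviving


def group_one_sample(
    maps: Sequence[np.ndarray],
    mask: np.ndarray | None = None,
    z_thresh: float = 3.1,
    alpha: float = 0.05,
    method: str = "permutation",
    n_perm: int = 1000,
    rng: int | np.random.Generator = 0,
    cluster_k: int | None = None,
) -> GroupResult:
    """One-sample group activation map: mean, voxel-wise t -> Z, cluster mask.

    Voxels with zero between-subject variance get the capped |Z| consistent
    with the sign of the mean (0 if the mean is also zero).
    """
    stack = np.stack([np.asarray(m, float) for m in maps], axis=0)
    n = stack.shape[0]
    if n < 3:
        raise ValueError("group analysis needs at least 3 subjects")
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / math.sqrt(n)), np.sign(mean) * np.inf)
    z = t_to_z(t, n - 1)
    corrected = cluster_correct(
        z,
        z_thresh=z_thresh,
        alpha=alpha,
        method=method,
        mask=mask,
        subject_maps=stack if method == "permutation" else None,
        cluster_k=cluster_k,
        n_perm=n_perm,
        rng=rng,
    )
    meta = {"z_thresh": z_thresh, "alpha": alpha, "method": method, "n_subjects": n, "n_perm": n_perm}
    return GroupResult(mean=mean, z=z, corrected_mask=corrected, meta=meta)
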