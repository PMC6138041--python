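"""Synthetic two-session BOLD cohorts with known reliability structure.

Simulates the statistical structure of a 15-subject, two-session
event-related control-task study: condition-specific regional activation
whose amplitude has a stable between-subject component (SD ``sigma_b``,
identical across sessions) and a session-specific component (SD ``sigma_w``),
superimposed on slow drift and AR(1) scan noise.  The population consistency
ICC of the regional amplitudes is then known by construction,

    ICC_true = sigma_b**2 / (sigma_b**2 + sigma_w**2),

which is what the downstream voxel-wise and ROI ICC(3,1) estimators target.

The default grid is a small synthetic volume with an affine that mimics
MNI-style millimetre coordinates (3 mm isotropic, origin at the grid centre),
so sphere ROIs specified in mm work unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy import signal, stats

from .task_design import ACTIVE_CONDITIONS, EventSchedule

DEFAULT_TR_S = 2.0
DEFAULT_GRID_SHAPE = (20, 24, 20)
DEFAULT_VOXEL_MM = 3.0


def _centered_affine(shape: tuple[int, int, int], voxel_mm: float) -> np.ndarray:
    """Voxel->mm affine: isotropic scaling with the mm origin at grid centre."""
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    aff[:3, 3] = -voxel_mm * (np.asarray(shape) - 1) / 2.0
    return aff


@dataclass(frozen=True)
class AcquisitionSpec:
    """EPI acquisition geometry: TR, volume count, grid and voxel->mm affine."""

    tr: float = DEFAULT_TR_S
    n_volumes: int = 155
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    voxel_size: float = DEFAULT_VOXEL_MM
    affine: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.affine is None:
            object.__setattr__(self, "affine", _centered_affine(self.grid_shape, self.voxel_size))
        if abs(float(np.linalg.det(np.asarray(self.affine)[:3, :3]))) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))


@dataclass(frozen=True)
class Region:
    """One activated region: a voxel mask tied to a condition and a mean amplitude."""

    name: str
    mask: np.ndarray  # boolean, grid_shape
    condition: str
    mu: float  # mean response amplitude, arbitrary signal units


@dataclass(frozen=True)
class EffectTopology:
    regions: tuple[Region, ...]

    def __post_init__(self):
        conds = {r.condition for r in self.regions}
        missing = set(ACTIVE_CONDITIONS) - conds
        if missing:
            raise ValueError(f"every active condition needs >=1 region; missing {sorted(missing)}")

    def truth_amplitude_map(self, grid_shape) -> np.ndarray:
        out = np.zeros(grid_shape)
        for r in self.regions:
            out[r.mask] += r.mu
        return out


@dataclass(frozen=True)
class VarianceModel:
    """Variance components of the simulated response amplitudes and noise.

    sigma_b : SD of the stable between-subject amplitude component.
    sigma_w : SD of the session-specific amplitude component.
    sigma_n : stationary SD of the AR(1) scan noise per volume.
    ar1_rho : lag-1 temporal autocorrelation of the scan noise, in [0, 1).
    drift_amp : SD of the per-voxel slow polynomial drift coefficients.
    """

    sigma_b: float = 0.5
    sigma_w: float = 0.2
    sigma_n: float = 1.0
    ar1_rho: float = 0.3
    drift_amp: float = 1.0

    def __post_init__(self):
        if min(self.sigma_b, self.sigma_w, self.sigma_n, self.drift_amp) < 0:
            raise ValueError("all SDs must be >= 0")
        if not 0 <= self.ar1_rho < 1:
            raise ValueError("ar1_rho must lie in [0, 1)")


@dataclass
class BOLDDataset:
    """One subject-session 4D acquisition (x, y, z, t) in arbitrary units."""

    data: np.ndarray
    affine: np.ndarray
    tr: float


def true_icc(sigma_b: float, sigma_w: float) -> float:
    """Population consistency ICC implied by the two variance components."""
    if sigma_b == 0 and sigma_w == 0:
        raise ValueError("true ICC undefined when both variance components are zero")
    return sigma_b**2 / (sigma_b**2 + sigma_w**2)


def n_volumes_for(schedule: EventSchedule, tr: float) -> int:
    """Smallest volume count whose span covers the run (trials + buffer)."""
    if tr <= 0:
        raise ValueError("tr must be positive")
    return math.ceil(schedule.duration / tr)


# ---------------------------------------------------------------------------
# Haemodynamics
# ---------------------------------------------------------------------------

def double_gamma_hrf(
    dt: float,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 1.0 / 6.0,
    duration: float = 32.0,
) -> np.ndarray:
    """Canonical double-gamma haemodynamic response kernel, peak-normalized.

    Difference of two gamma densities (positive lobe peaking at
    ``peak_delay - peak_disp`` s, undershoot scaled by ``ratio``), sampled at
    step ``dt`` over ``duration`` seconds and scaled so max(kernel) == 1.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, duration + dt / 2, dt)
    peak = stats.gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    under = stats.gamma.pdf(t, undershoot_delay / undershoot_disp, scale=undershoot_disp)
    h = peak - ratio * under
    return h / h.max()


_FINE_DT = 0.1


def condition_regressor(
    schedule: EventSchedule,
    condition: str,
    tr: float,
    n_volumes: int,
    hrf: np.ndarray | None = None,
) -> np.ndarray:
    """HRF-convolved event regressor sampled at volume acquisition times.

    A boxcar (1 during the condition's trials) is built on a 0.1 s grid,
    convolved with the double-gamma kernel sampled at the same step, and read
    out at t = 0, TR, 2*TR, ...  Null trials are the implicit baseline and
    may not be requested.
    """
    if condition == "null":
        raise ValueError("null trials form the implicit baseline, not a regressor")
    if condition not in ACTIVE_CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if hrf is None:
        hrf = double_gamma_hrf(_FINE_DT)
    fine_len = int(round(n_volumes * tr / _FINE_DT)) + 1
    box = np.zeros(fine_len)
    for t in schedule.trials:
        if t.condition != condition:
            continue
        i0 = int(round(t.onset / _FINE_DT))
        i1 = int(round((t.onset + t.duration) / _FINE_DT))
        box[i0 : min(i1, fine_len)] = 1.0
    conv = np.convolve(box, hrf)[:fine_len] * _FINE_DT
    vol_idx = np.round(np.arange(n_volumes) * tr / _FINE_DT).astype(int)
    return conv[vol_idx]


# ---------------------------------------------------------------------------
# Nuisance processes
# ---------------------------------------------------------------------------

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


def simulate_motion(n_volumes: int, step_sd: float = 0.01, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Gaussian random-walk head motion: (n_volumes, 6) — mm then radians.

    Motion enters the analysis only as confound regressors; the images
    themselves are not displaced.
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    steps = rng.normal(0.0, step_sd, size=(n_volumes, 6)) if step_sd > 0 else np.zeros((n_volumes, 6))
    return np.cumsum(steps, axis=0)


def write_motion_par(trace: np.ndarray, path: str | Path) -> Path:
    """Write a 6-column whitespace-delimited motion file (FSL .par convention)."""
    path = Path(path)
    np.savetxt(path, trace, fmt="%.8f")
    return path


def _ar1_noise(rng: np.random.Generator, shape_vt: tuple[int, int], sigma: float, rho: float) -> np.ndarray:
    """Stationary AR(1) noise along the last axis, SD ``sigma`` per sample."""
    if sigma == 0:
        return np.zeros(shape_vt)
    innov = rng.normal(0.0, 1.0, size=shape_vt)
    if rho == 0:
        return sigma * innov
    out = signal.lfilter([1.0], [1.0, -rho], innov, axis=-1)
    return sigma * math.sqrt(1.0 - rho**2) * out


def _legendre_drift(n_volumes: int, order: int = 2) -> np.ndarray:
    """Legendre polynomial drift basis of orders 1..order on [-1, 1], (T, order)."""
    x = np.linspace(-1.0, 1.0, n_volumes)
    cols = [np.polynomial.legendre.Legendre.basis(k)(x) for k in range(1, order + 1)]
    return np.stack(cols, axis=1)


# ---------------------------------------------------------------------------
# Default topology
# ---------------------------------------------------------------------------

# Placeholder region centres in the synthetic grid's mm coordinates.  These are
# NOT the study's (unpublished, Neurosynth-derived) MNI coordinates — they are
# synthetic stand-ins chosen to lie well inside the default grid while keeping
# regions disjoint; users analysing real data supply their own.
SYNTHETIC_REGION_CENTRES_MM: dict[str, tuple[float, float, float]] = {
    "auditory": (-21.0, -12.0, 6.0),
    "visual": (0.0, -30.0, 3.0),
    "motor": (-21.0, -15.0, 24.0),
    "fef": (-9.0, 3.0, 24.0),
    "dlpfc": (-15.0, 21.0, 12.0),
}

_REGION_CONDITION = {
    "auditory": "auditory",
    "visual": "visual",
    "motor": "motor",
    "fef": "cognitive",
    "dlpfc": "cognitive",
}


def sphere_voxels(centre_mm: Sequence[float], radius_mm: float, affine: np.ndarray, shape) -> np.ndarray:
    """Boolean mask of voxels whose centres lie within ``radius_mm`` of a point."""
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1)
    mm = vox @ np.asarray(affine).T
    d2 = ((mm[..., :3] - np.asarray(centre_mm)) ** 2).sum(axis=-1)
    return d2 <= radius_mm**2


def default_topology(variant: str, acq: AcquisitionSpec, mu: float = 1.0, radius_mm: float = 7.5) -> EffectTopology:
    """Five-region topology matching one task variant (FEF or DLPFC cognitive site)."""
    cognitive_site = "fef" if variant == "eye-movement" else "dlpfc"
    regions = []
    for name in ("auditory", "visual", "motor", cognitive_site):
        mask = sphere_voxels(SYNTHETIC_REGION_CENTRES_MM[name], radius_mm, acq.affine, acq.grid_shape)
        regions.append(Region(name=name, mask=mask, condition=_REGION_CONDITION[name], mu=mu))
    return EffectTopology(regions=tuple(regions))


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortTruth:
    """Ground truth for a simulated cohort."""

    icc_map: np.ndarray  # true amplitude ICC per voxel (NaN outside regions)
    amplitudes: dict  # (subject, session, region name) -> realized amplitude
    variance_model: VarianceModel


def simulate_amplitude_matrix(
    n_subjects: int,
    n_sessions: int,
    mu: float,
    sigma_b: float,
    sigma_w: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-subject/session response amplitudes (n_subjects, n_sessions).

    Subject traits a_s ~ N(mu, sigma_b^2) drawn once; each session observes
    a_s + e_{s,j}, e ~ N(0, sigma_w^2).
    """
    trait = rng.normal(mu, sigma_b, size=n_subjects)
    sess = rng.normal(0.0, sigma_w, size=(n_subjects, n_sessions))
    return trait[:, None] + sess


def simulate_cohort(
    n_subjects: int,
    schedules: EventSchedule | Sequence[EventSchedule],
    topology: EffectTopology,
    variance: VarianceModel,
    acq: AcquisitionSpec,
    seed: int,
    n_sessions: int = 2,
    motion_step_sd: float = 0.01,
) -> tuple[dict[tuple[int, int], BOLDDataset], dict[tuple[int, int], np.ndarray], CohortTruth]:
    """Simulate a full two-session cohort of 4D BOLD runs.

    Parameters
    ----------
    schedules : one schedule shared by all sessions, or one per session.
    seed : master seed; every random stream is spawned from it, so identical
        arguments give bit-identical cohorts.

    Returns
    -------
    bold : dict (subject, session) -> BOLDDataset
    motion : dict (subject, session) -> (n_volumes, 6) motion trace
    truth : CohortTruth with the voxel-wise true-ICC map and realized amplitudes
    """
    if isinstance(schedules, EventSchedule):
        schedules = [schedules] * n_sessions
    if len(schedules) != n_sessions:
        raise ValueError("need one schedule per session (or a single shared one)")
    for sched in schedules:
        if n_volumes_for(sched, acq.tr) > acq.n_volumes:
            raise ValueError("acquisition too short for schedule")

    ss = np.random.SeedSequence(seed)
    amp_rng, noise_rng, motion_rng, drift_rng = (np.random.default_rng(s) for s in ss.spawn(4))

    # session-specific regressors per condition (shared across subjects)
    regressors = []
    for sched in schedules:
        regressors.append(
            {c: condition_regressor(sched, c, acq.tr, acq.n_volumes) for c in ACTIVE_CONDITIONS}
        )

    # subject trait amplitudes per region, then session perturbations
    traits = {
        r.name: amp_rng.normal(r.mu, variance.sigma_b, size=n_subjects) for r in topology.regions
    }
    sess_dev = {
        r.name: amp_rng.normal(0.0, variance.sigma_w, size=(n_subjects, n_sessions))
        for r in topology.regions
    }

    shape = acq.grid_shape
    n_vox = acq.n_voxels
    drift_basis = _legendre_drift(acq.n_volumes)

    bold: dict[tuple[int, int], BOLDDataset] = {}
    motion: dict[tuple[int, int], np.ndarray] = {}
    amplitudes: dict[tuple[int, int, str], float] = {}
    for s in range(n_subjects):
        for j in range(n_sessions):
            vol = np.zeros((n_vox, acq.n_volumes))
            for r in topology.regions:
                a = traits[r.name][s] + sess_dev[r.name][s, j]
                amplitudes[(s, j, r.name)] = float(a)
                vol[r.mask.ravel()] += a * regressors[j][r.condition]
            if variance.drift_amp > 0:
                coef = drift_rng.normal(0.0, variance.drift_amp, size=(n_vox, drift_basis.shape[1]))
                vol += coef @ drift_basis.T
            vol += _ar1_noise(noise_rng, (n_vox, acq.n_volumes), variance.sigma_n, variance.ar1_rho)
            bold[(s, j)] = BOLDDataset(
                data=vol.reshape(*shape, acq.n_volumes), affine=acq.affine, tr=acq.tr
            )
            motion[(s, j)] = simulate_motion(acq.n_volumes, motion_step_sd, motion_rng)

    icc_map = np.full(shape, np.nan)
    if variance.sigma_b > 0 or variance.sigma_w > 0:
        icc_val = true_icc(variance.sigma_b, variance.sigma_w)
        for r in topology.regions:
            icc_map[r.mask] = icc_val
    truth = CohortTruth(icc_map=icc_map, amplitudes=amplitudes, variance_model=variance)
    return bold, motion, truth
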