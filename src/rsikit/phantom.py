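"""Synthetic lesion phantoms with known ground truth.

Each phantom is an ellipsoidal whole-tumor lesion on a small 3D grid.
Voxelwise tissue is described by three compartment volume fractions
(restricted / hindered / free water) drawn hierarchically: a patient-level
triple from a group-specific Dirichlet law calibrated by quantile matching
to the reported cohort quartiles, then logistic-normal voxel jitter
renormalized back onto the simplex.  A small necrotic core (elevated free
water) is embedded and flagged so ROI aggregation can exclude it, mirroring
the reading-room practice of avoiding obviously necrotic regions.

Signals follow the three-compartment forward model; magnitude (Rician)
noise is added per excitation and averaged over NEX, emulating scanner
magnitude averaging.  A second observer's ROI is a bounded morphological
perturbation of the first observer's ROI.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.stats import beta as beta_dist

from .acquisition import AcquisitionScheme, default_scheme
from .signal_models import CompartmentDiffusivities

__all__ = [
    "TissueParameters",
    "LesionPhantom",
    "add_rician_noise",
    "generate_lesion_phantom",
    "dirichlet_alpha_from_quantiles",
    "group_fraction_alphas",
    "FRACTION_QUARTILES",
]

# Cohort quartiles (q25, median, q75) of the compartment fractions per group,
# used to calibrate the patient-level Dirichlet law.
FRACTION_QUARTILES = {
    "positive": {"f1": (0.35, 0.43, 0.50),
                 "f2": (0.07, 0.12, 0.19),
                 "f3": (0.20, 0.27, 0.30)},
    "negative": {"f1": (0.09, 0.21, 0.38),
                 "f2": (0.06, 0.13, 0.22),
                 "f3": (0.28, 0.36, 0.55)},
}


@dataclass(frozen=True)
class TissueParameters:
    """Ground-truth voxel tissue state: simplex fractions + b=0 signal."""

    f1: float
    f2: float
    f3: float
    s0: float
    necrotic: bool = False

    def __post_init__(self):
        f = np.array([self.f1, self.f2, self.f3])
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(f.sum() - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1 within 1e-12")
        if not self.s0 > 0:
            raise ValueError("s0 must be positive")


@dataclass
class LesionPhantom:
    """A simulated patient: noisy 4D DWI, observer ROIs, and the truth."""

    dwi: np.ndarray                  # (x, y, z, b)
    roi_observer1: np.ndarray        # 3D bool
    roi_observer2: np.ndarray        # 3D bool
    necrosis_mask: np.ndarray        # 3D bool
    truth: dict                      # 3D arrays: f1, f2, f3, s0
    scheme: AcquisitionScheme
    group: str
    seed: int

    @property
    def grid_shape(self):
        return self.dwi.shape[:3]


def add_rician_noise(signal, snr_at_b0, nex, seed=None, rng=None,
                     s0_reference=None):
    """Corrupt a magnitude signal with NEX-averaged Rician noise.

    Each of the per-b excitations receives independent complex Gaussian
    noise with per-channel standard deviation sigma = s0_reference /
    snr_at_b0; the magnitudes of the excitations are averaged, as a scanner
    averages magnitude images.  ``signal`` may be a vector over b or an
    (n_voxels, n_b) array.  ``s0_reference`` defaults to the mean b=0 entry.
    """
    if not snr_at_b0 > 0:
        raise ValueError("snr_at_b0 must be positive")
    sig = np.atleast_2d(np.asarray(signal, dtype=float))
    nex = np.asarray(nex, dtype=int)
    if nex.shape[0] != sig.shape[-1]:
        raise ValueError("nex length must match number of b-values")
    if rng is None:
        rng = np.random.default_rng(seed)
    if s0_reference is None:
        s0_reference = float(np.mean(sig[:, 0]))
    sigma = s0_reference / snr_at_b0
    out = np.empty_like(sig)
    for j in range(sig.shape[-1]):
        n = int(nex[j])
        re = sig[:, j][None, :] + rng.normal(0.0, sigma, size=(n, sig.shape[0]))
        im = rng.normal(0.0, sigma, size=(n, sig.shape[0]))
        out[:, j] = np.hypot(re, im).mean(axis=0)
    return out.reshape(np.shape(signal))


def _quantile_residuals(log_alpha, targets, median_weight):
    alpha = np.exp(log_alpha)
    a0 = alpha.sum()
    res = []
    for i, (q25, q50, q75) in enumerate(targets):
        a, bb = alpha[i], a0 - alpha[i]
        res.extend([
            beta_dist.ppf(0.25, a, bb) - q25,
            median_weight * (beta_dist.ppf(0.50, a, bb) - q50),
            beta_dist.ppf(0.75, a, bb) - q75,
        ])
    return np.asarray(res)


def dirichlet_alpha_from_quantiles(quartiles, median_weight=4.0) -> np.ndarray:
    """Least-squares fit of a Dirichlet concentration vector to target
    marginal quartiles (q25, median, q75) of each of the three fractions.

    Dirichlet marginals are Beta(alpha_i, alpha_0 - alpha_i); the three
    concentration parameters are fit to the nine quantile targets.  Three
    parameters cannot satisfy nine targets exactly (marginal medians of a
    Dirichlet need not sum to the targets' sum), so median residuals are
    up-weighted: the medians are the generator's primary contract, the
    quartiles shape the spread.
    """
    targets = [tuple(q) for q in quartiles]
    med = np.array([t[1] for t in targets])
    # moment-style start: medians need not sum to 1, scale to the simplex
    x0 = np.log(np.maximum(med / med.sum(), 1e-3) * 2.0)
    sol = least_squares(_quantile_residuals, x0,
                        args=(targets, float(median_weight)),
                        method="lm", xtol=1e-12, ftol=1e-12)
    return np.exp(sol.x)


@lru_cache(maxsize=None)
def group_fraction_alphas(group: str) -> tuple:
    """Calibrated Dirichlet concentration for 'positive' or 'negative'."""
    q = FRACTION_QUARTILES[group]
    alpha = dirichlet_alpha_from_quantiles((q["f1"], q["f2"], q["f3"]))
    return tuple(float(a) for a in alpha)


def _ellipsoid_mask(grid_shape, center, semi_axes) -> np.ndarray:
    coords = np.indices(grid_shape, dtype=float)
    d2 = sum(((coords[i] - center[i]) / semi_axes[i]) ** 2 for i in range(3))
    return d2 <= 1.0


def _perturb_roi(roi, rng, max_boundary_fraction=0.10):
    """Second-observer ROI: toggle at most the given fraction of boundary
    voxels (random erosions inside, dilations outside), seeded."""
    inner = roi & ~ndimage.binary_erosion(roi)
    outer = ndimage.binary_dilation(roi) & ~roi
    n_boundary = int(inner.sum())
    n_change = int(np.floor(max_boundary_fraction * n_boundary))
    roi2 = roi.copy()
    if n_change == 0:
        return roi2
    inner_idx = np.argwhere(inner)
    outer_idx = np.argwhere(outer)
    n_remove = rng.integers(0, n_change + 1)
    n_add = n_change - n_remove
    if n_remove > 0 and len(inner_idx) >= n_remove:
        sel = rng.choice(len(inner_idx), size=n_remove, replace=False)
        for i, j, k in inner_idx[sel]:
            roi2[i, j, k] = False
    if n_add > 0 and len(outer_idx) >= n_add:
        sel = rng.choice(len(outer_idx), size=min(n_add, len(outer_idx)),
                         replace=False)
        for i, j, k in outer_idx[sel]:
            roi2[i, j, k] = True
    if not roi2.any():
        return roi.copy()
    return roi2


def _jitter_fractions(base, n, rng, tau=0.10):
    """Voxel-level logistic-normal jitter around a patient-level triple,
    renormalized onto the simplex."""
    logs = np.log(np.maximum(base, 1e-6))[None, :] + rng.normal(0, tau, (n, 3))
    x = np.exp(logs)
    return x / x.sum(axis=1, keepdims=True)


# background (non-tumor pelvic tissue) composition and signal level
_BACKGROUND_FRACTIONS = np.array([0.15, 0.45, 0.40])
_BACKGROUND_S0 = 600.0
_LESION_S0 = 1000.0
_NECROSIS_F3 = 0.85


def generate_lesion_phantom(group, grid_shape=(16, 16, 8), seed=0,
                            snr_at_b0=50.0,
                            scheme: AcquisitionScheme = None,
                            diffs: CompartmentDiffusivities = CompartmentDiffusivities(),
                            noiseless=False, jitter_tau=0.10,
                            min_lesion_voxels=50) -> LesionPhantom:
    """Simulate one patient's lesion phantom.

    Parameters
    ----------
    group : {"positive", "negative"}
        Nodal-status group whose fraction distribution the lesion follows.
    grid_shape : tuple of int
        3D grid; must be able to contain an ellipsoid of at least
        ``min_lesion_voxels`` voxels.
    snr_at_b0 : float
        b=0 signal-to-noise ratio defining the per-channel Gaussian sigma.
    noiseless : bool
        Skip the noise stage (useful for exact-recovery tests).
    """
    if group not in ("positive", "negative"):
        raise ValueError("group must be 'positive' or 'negative'")
    grid_shape = tuple(int(g) for g in grid_shape)
    if len(grid_shape) != 3 or min(grid_shape) < 4:
        raise ValueError("degenerate grid")
    rng = np.random.default_rng(seed)
    if scheme is None:
        scheme = default_scheme()

    center = np.array(grid_shape) / 2.0 - 0.5
    semi = np.maximum(np.array(grid_shape) * rng.uniform(0.25, 0.38, 3), 1.6)
    roi1 = _ellipsoid_mask(grid_shape, center, semi)
    if roi1.sum() < min_lesion_voxels:
        raise ValueError(
            f"grid {grid_shape} cannot contain a lesion of "
            f">= {min_lesion_voxels} voxels")

    # necrotic core: small ball near the lesion center, capped below 20% of ROI
    core_r = max(1.2, 0.18 * semi.min())
    offset = rng.uniform(-1.0, 1.0, 3)
    core = _ellipsoid_mask(grid_shape, center + offset, np.full(3, core_r))
    core &= ndimage.binary_erosion(roi1)
    max_core = max(1, int(0.18 * roi1.sum()))
    if core.sum() > max_core:
        idx = np.argwhere(core)
        keep = rng.choice(len(idx), size=max_core, replace=False)
        new = np.zeros_like(core)
        for i, j, k in idx[keep]:
            new[i, j, k] = True
        core = new
    if not core.any():  # guarantee a non-empty flagged core
        i, j, k = np.argwhere(roi1)[0]
        core = np.zeros_like(roi1)
        core[i, j, k] = True

    alpha = np.asarray(group_fraction_alphas(group))
    patient_f = rng.dirichlet(alpha)

    nvox = int(np.prod(grid_shape))
    f_vox = np.tile(_BACKGROUND_FRACTIONS, (nvox, 1))
    s0_vox = np.full(nvox, _BACKGROUND_S0)

    flat_roi = roi1.ravel()
    n_lesion = int(flat_roi.sum())
    f_vox[flat_roi] = _jitter_fractions(patient_f, n_lesion, rng, tau=jitter_tau)
    s0_vox[flat_roi] = _LESION_S0 * rng.normal(1.0, 0.03, n_lesion)

    flat_core = core.ravel()
    n_core = int(flat_core.sum())
    necro = _jitter_fractions(
        np.array([(1 - _NECROSIS_F3) * 0.4, (1 - _NECROSIS_F3) * 0.6,
                  _NECROSIS_F3]), n_core, rng, tau=jitter_tau)
    f_vox[flat_core] = necro

    b = scheme.b
    design = np.exp(-b[:, None] * diffs.as_array[None, :])
    clean = s0_vox[:, None] * (f_vox @ design.T)
    if noiseless:
        dwi_flat = clean
    else:
        dwi_flat = add_rician_noise(clean, snr_at_b0, scheme.nex, rng=rng,
                                    s0_reference=_LESION_S0)
    dwi = dwi_flat.reshape(grid_shape + (len(scheme),))

    roi2 = _perturb_roi(roi1, rng)
    truth = {
        "f1": f_vox[:, 0].reshape(grid_shape),
        "f2": f_vox[:, 1].reshape(grid_shape),
        "f3": f_vox[:, 2].reshape(grid_shape),
        "s0": s0_vox.reshape(grid_shape),
    }
    return LesionPhantom(dwi=dwi, roi_observer1=roi1, roi_observer2=roi2,
                         necrosis_mask=core, truth=truth, scheme=scheme,
                         group=group, seed=int(seed))
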