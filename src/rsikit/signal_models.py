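"""Per-voxel diffusion signal models and their fitters.

Three models over one multi-b acquisition:

* mono-exponential DWI, ``S_b/S_0 = exp(-b * ADC)``, inverted from exactly two
  shells (default b = 0 and 800 s/mm^2);
* diffusion kurtosis imaging (DKI),
  ``S_b = S_0 * exp(-b*D_app + b^2 * D_app^2 * K_app / 6)``, fitted as a
  quadratic-in-b linear regression in the log domain with constraint
  projection;
* three-compartment restriction spectrum imaging (RSI),
  ``S(b) = S_0 * (f1*exp(-b*D1) + f2*exp(-b*D2) + f3*exp(-b*D3))`` with fixed
  compartment diffusivities ``D1 < D2 < D3`` (restricted, hindered, free
  water), solved by non-negative least squares; fractions are the normalized
  non-negative weights.

All diffusivities are stored in mm^2/s; b-values in s/mm^2.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares, nnls

from .acquisition import AcquisitionScheme

__all__ = [
    "CompartmentDiffusivities",
    "AdcFit",
    "DkiFit",
    "RsiFit",
    "DwiSeries",
    "ParameterMapSet",
    "adc_signal",
    "dki_signal",
    "forward_rsi_signal",
    "fit_adc",
    "fit_dki",
    "fit_rsi",
    "fit_volume",
]

PARAMETER_NAMES = ("adc", "d_app", "k_app", "f1", "f2", "f3")


@dataclass(frozen=True)
class CompartmentDiffusivities:
    """Fixed apparent diffusivities (mm^2/s) of the restricted, hindered and
    free-water compartments; must satisfy 0 < d1 < d2 < d3.

    Defaults are the standardized values 0.5e-3, 1.3e-3 and 3.0e-3 mm^2/s,
    chosen to linearize the compartment fit and keep fractions comparable.
    """

    d1: float = 0.5e-3
    d2: float = 1.3e-3
    d3: float = 3.0e-3

    def __post_init__(self):
        if not (0.0 < self.d1 < self.d2 < self.d3):
            raise ValueError("diffusivities must satisfy 0 < d1 < d2 < d3")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.d1, self.d2, self.d3], dtype=float)


@dataclass
class AdcFit:
    adc: float
    s0_est: float
    clipped: bool = False
    failed: bool = False


@dataclass
class DkiFit:
    d_app: float
    k_app: float
    s0_est: float
    fit_residual: float
    failed: bool = False


@dataclass
class RsiFit:
    f1: float
    f2: float
    f3: float
    raw_coefficients: np.ndarray = field(default_factory=lambda: np.zeros(3))
    fit_residual: float = np.nan
    poor_fit: bool = False
    failed: bool = False

    @property
    def fractions(self) -> np.ndarray:
        return np.array([self.f1, self.f2, self.f3], dtype=float)


@dataclass
class DwiSeries:
    """A 4D diffusion-weighted volume (x, y, z, b) tied to its scheme."""

    data: np.ndarray
    scheme: AcquisitionScheme
    affine: Optional[np.ndarray] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4D (x, y, z, b)")
        if self.data.shape[-1] != len(self.scheme):
            raise ValueError("last axis of DWI data must match scheme length")
        if self.affine is None:
            self.affine = np.eye(4)

    @property
    def grid_shape(self):
        return self.data.shape[:3]


@dataclass
class ParameterMapSet:
    """Co-registered 3D parameter maps on the DWI grid.

    Unfitted / failed voxels carry NaN (a sentinel distinct from 0);
    ``fitted_mask`` is True exactly where all requested fits succeeded.
    """

    maps: dict
    fitted_mask: np.ndarray
    n_failed: int = 0
    affine: Optional[np.ndarray] = None

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]

    @property
    def parameter_names(self):
        return tuple(self.maps.keys())


# ----------------------------------------------------------------- forwards

def _as_b(scheme_or_b) -> np.ndarray:
    if isinstance(scheme_or_b, AcquisitionScheme):
        b = scheme_or_b.b
    else:
        b = np.atleast_1d(np.asarray(scheme_or_b, dtype=float))
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    return b


def adc_signal(s0, adc, scheme_or_b) -> np.ndarray:
    """Mono-exponential decay S(b) = s0 * exp(-b * ADC)."""
    b = _as_b(scheme_or_b)
    return s0 * np.exp(-b * adc)


def dki_signal(s0, d_app, k_app, scheme_or_b) -> np.ndarray:
    """Kurtosis-model decay S(b) = s0 * exp(-b*D + b^2*D^2*K/6)."""
    b = _as_b(scheme_or_b)
    return s0 * np.exp(-b * d_app + b**2 * d_app**2 * k_app / 6.0)


def forward_rsi_signal(params, diffs: CompartmentDiffusivities, scheme_or_b) -> np.ndarray:
    """Three-compartment signal S(b) = s0 * sum_i f_i * exp(-b * d_i).

    ``params`` is anything with attributes f1, f2, f3, s0 (e.g.
    :class:`rsikit.phantom.TissueParameters`) or a (f1, f2, f3, s0) tuple.
    """
    b = _as_b(scheme_or_b)
    if hasattr(params, "f1"):
        f = np.array([params.f1, params.f2, params.f3], dtype=float)
        s0 = float(params.s0)
    else:
        f1, f2, f3, s0 = params
        f = np.array([f1, f2, f3], dtype=float)
    d = diffs.as_array
    return s0 * (np.exp(-b[:, None] * d[None, :]) @ f)


# ------------------------------------------------------------------ fitters

def fit_adc(signal, scheme: AcquisitionScheme, b_pair=(0.0, 800.0),
            all_b: bool = False) -> AdcFit:
    """Apparent diffusion coefficient from two shells (default b = 0, 800).

    ADC = ln(S_b1 / S_b2) / (b2 - b1).  Negative estimates (noise pushing
    S_b2 above S_b1) are clipped to 0 and flagged.  ``all_b=True`` instead
    performs a log-linear regression over every shell of the scheme.
    """
    signal = np.asarray(signal, dtype=float)
    if all_b:
        if np.any(signal <= 0):
            return AdcFit(np.nan, np.nan, failed=True)
        b = scheme.b
        coef = np.polyfit(b, np.log(signal), 1)
        adc = -coef[0]
        clipped = adc < 0
        return AdcFit(max(adc, 0.0), float(np.exp(coef[1])), clipped=bool(clipped))
    i0 = scheme.index_of(b_pair[0])
    i1 = scheme.index_of(b_pair[1])
    s0, s1 = signal[i0], signal[i1]
    if s0 <= 0 or s1 <= 0:
        return AdcFit(np.nan, np.nan, failed=True)
    adc = np.log(s0 / s1) / (scheme.b_values[i1] - scheme.b_values[i0])
    clipped = adc < 0
    return AdcFit(float(max(adc, 0.0)), float(s0), clipped=bool(clipped))


def _dki_design(b: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(b), -b, b**2])


def fit_dki(signal, scheme: AcquisitionScheme, k_max: float = 3.0,
            nex_weighted: bool = False) -> DkiFit:
    """Diffusion kurtosis fit in the log domain.

    Solves ``ln S = ln S0 - b*c1 + b^2*c2`` by (weighted) linear least
    squares with c1 = D_app and c2 = D_app^2 * K_app / 6, then projects onto
    the constraints D_app > 0 and 0 <= K_app <= k_max via a bounded
    non-linear refit when the unconstrained solution violates them.

    With ``nex_weighted=True`` the rows are weighted assuming signal-domain
    variance proportional to 1/NEX, propagated to the log domain
    (var(ln S) ~ 1/(NEX * S^2)), i.e. weight ~ S * sqrt(NEX).
    """
    signal = np.asarray(signal, dtype=float)
    b = scheme.b
    if np.any(signal <= 0):
        return DkiFit(np.nan, np.nan, np.nan, np.nan, failed=True)
    if len(np.unique(b[signal > 0])) < 4:
        return DkiFit(np.nan, np.nan, np.nan, np.nan, failed=True)
    if np.allclose(signal, signal[0]):
        return DkiFit(np.nan, np.nan, np.nan, np.nan, failed=True)

    y = np.log(signal)
    X = _dki_design(b)
    if nex_weighted:
        w = signal * np.sqrt(scheme.nex_array)
        Xw, yw = X * w[:, None], y * w
    else:
        w = np.ones_like(b)
        Xw, yw = X, y
    coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    lns0, c1, c2 = coef
    d = c1
    k = 6.0 * c2 / d**2 if d > 0 else np.nan

    if not (d > 0 and 0.0 <= k <= k_max):
        # bounded refit in (ln S0, D, K)
        def resid(theta):
            ls0, dd, kk = theta
            model = ls0 - b * dd + b**2 * dd**2 * kk / 6.0
            return w * (model - y)

        x0 = np.array([lns0,
                       max(d, 1e-6) if np.isfinite(d) else 1e-3,
                       np.clip(k if np.isfinite(k) else 0.0, 0.0, k_max)])
        sol = least_squares(resid, x0,
                            bounds=([-np.inf, 1e-12, 0.0],
                                    [np.inf, np.inf, k_max]))
        lns0, d, k = sol.x
    model = lns0 - b * d + b**2 * d**2 * k / 6.0
    rms = float(np.sqrt(np.mean((model - y) ** 2)))
    return DkiFit(float(d), float(k), float(np.exp(lns0)), rms)


def fit_rsi(signal, scheme: AcquisitionScheme,
            diffs: CompartmentDiffusivities = CompartmentDiffusivities(),
            residual_tol: float = 0.05) -> RsiFit:
    """Three-compartment NNLS fit with fixed diffusivities.

    The signal is normalized by S(0); non-negative least squares against the
    design [exp(-b*d1), exp(-b*d2), exp(-b*d3)] yields raw compartment
    weights; fractions are the weights divided by their sum, so they always
    lie on the simplex.  ``poor_fit`` flags a root-mean-square residual (in
    normalized signal units) above ``residual_tol``.
    """
    signal = np.asarray(signal, dtype=float)
    b = scheme.b
    i0 = int(np.argmin(b))
    s0 = signal[i0]
    if not (s0 > 0):
        return RsiFit(np.nan, np.nan, np.nan, failed=True)
    y = signal / s0
    A = np.exp(-b[:, None] * diffs.as_array[None, :])
    weights, rnorm = nnls(A, y)
    total = weights.sum()
    if total <= 0:
        return RsiFit(np.nan, np.nan, np.nan, raw_coefficients=weights,
                      failed=True)
    f = weights / total
    rms = rnorm / np.sqrt(len(b))
    return RsiFit(float(f[0]), float(f[1]), float(f[2]),
                  raw_coefficients=weights, fit_residual=float(rms),
                  poor_fit=bool(rms > residual_tol))


def fit_volume(dwi: DwiSeries, mask, models="all",
               diffs: CompartmentDiffusivities = CompartmentDiffusivities(),
               k_max: float = 3.0, nex_weighted: bool = False,
               adc_b_pair=(0.0, 800.0)) -> ParameterMapSet:
    """Apply the selected per-voxel fitters to every voxel inside ``mask``.

    ``models`` is "all" or an iterable drawn from {"adc", "dki", "rsi"}.
    Failed voxels carry NaN in every map of the failing model and are removed
    from ``fitted_mask``; the failure count is recorded.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.grid_shape:
        raise ValueError("mask grid does not match DWI grid")
    if not mask.any():
        raise ValueError("empty mask")
    if models == "all":
        models = ("adc", "dki", "rsi")
    models = tuple(models)

    shape = dwi.grid_shape
    maps = {}
    if "adc" in models:
        maps["adc"] = np.full(shape, np.nan)
    if "dki" in models:
        maps["d_app"] = np.full(shape, np.nan)
        maps["k_app"] = np.full(shape, np.nan)
    if "rsi" in models:
        for name in ("f1", "f2", "f3"):
            maps[name] = np.full(shape, np.nan)

    fitted = np.zeros(shape, dtype=bool)
    n_failed = 0
    scheme = dwi.scheme
    for idx in zip(*np.nonzero(mask)):
        sig = dwi.data[idx]
        ok = True
        if "adc" in models:
            fa = fit_adc(sig, scheme, b_pair=adc_b_pair)
            if fa.failed:
                ok = False
            else:
                maps["adc"][idx] = fa.adc
        if "dki" in models:
            fd = fit_dki(sig, scheme, k_max=k_max, nex_weighted=nex_weighted)
            if fd.failed:
                ok = False
            else:
                maps["d_app"][idx] = fd.d_app
                maps["k_app"][idx] = fd.k_app
        if "rsi" in models:
            fr = fit_rsi(sig, scheme, diffs=diffs)
            if fr.failed:
                ok = False
            else:
                maps["f1"][idx] = fr.f1
                maps["f2"][idx] = fr.f2
                maps["f3"][idx] = fr.f3
        if ok:
            fitted[idx] = True
        else:
            n_failed += 1
    return ParameterMapSet(maps=maps, fitted_mask=fitted, n_failed=n_failed,
                           affine=dwi.affine)
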