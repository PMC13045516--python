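"""Diffusion-weighted MRI models and voxelwise fitting.

Two forward models of signal attenuation versus diffusion weighting b
(s/mm^2):

* monoexponential: ``S(b) = S0 * exp(-b * ADC)`` — Gaussian diffusion,
  yielding the apparent diffusion coefficient ADC (mm^2/s);
* non-Gaussian IVIM (NG-IVIM):
  ``S(b) = S0 * [f*exp(-b*Dstar) + (1-f)*exp(-b*D + (1/6)*K*(b*D)^2)]``
  separating capillary pseudo-diffusion (perfusion fraction f, Dstar) from
  tissue diffusion D, with a kurtosis coefficient K capturing the deviation
  of water displacement from a Gaussian profile.

Fitting is per voxel.  The monoexponential fit is weighted log-linear least
squares (weights proportional to the squared signal, the correct first-order
weighting for log-transformed data).  The NG-IVIM fit is segmented by
default: a kurtosis-only fit on the high-b regime (b >= ``B_SPLIT``), where
the perfusion term has decayed, then a perfusion fit on the full curve, then
one bounded joint refinement of all five parameters.

Parameter bounds (physiological, and preventing term-swapping between D and
Dstar): ADC, D in [1e-6, 4e-3] mm^2/s; Dstar in [4e-3, 0.2] mm^2/s; f in
[0, 1]; K in [0, 3].  Fits that land on a bound are flagged rather than
silently reported, as is a fitted Dstar < 2*D (perfusion-unidentifiable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import AlignmentError, InsufficientDataError
from .image_io import ImageVolume, ROIMask, extract_roi_signals, write_back_voxels

__all__ = [
    "DWISeries",
    "MonoexpFit",
    "NGIVIMFit",
    "monoexp_signal",
    "ngivim_signal",
    "fit_monoexp",
    "fit_ngivim",
    "fit_dwi_volume",
    "ADC_BOUNDS",
    "DSTAR_BOUNDS",
    "K_BOUNDS",
    "B_SPLIT",
    "FLAG_NOT_CONVERGED",
    "FLAG_BOUND_HIT",
    "FLAG_PERFUSION_UNIDENTIFIABLE",
    "FLAG_FALLBACK",
    "FLAG_KURTOSIS_CLAMPED",
]

ADC_BOUNDS = (1e-6, 4e-3)   # mm^2/s, also bounds for D
DSTAR_BOUNDS = (4e-3, 0.2)  # mm^2/s
F_BOUNDS = (0.0, 1.0)
K_BOUNDS = (0.0, 3.0)
B_SPLIT = 200.0  # s/mm^2; perfusion term ~fully decayed above this for Dstar ~ 25e-3

# diagnostic flag bits (shared with the DCE volume fitter)
FLAG_NOT_CONVERGED = 1
FLAG_BOUND_HIT = 2
FLAG_PERFUSION_UNIDENTIFIABLE = 4
FLAG_FALLBACK = 8
FLAG_KURTOSIS_CLAMPED = 16


@dataclass
class DWISeries:
    """Per-voxel signal versus b-value; sorted ascending by b on construction."""

    bvalues: np.ndarray
    signals: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.bvalues, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        if b.shape != s.shape or b.ndim != 1:
            raise ValueError("bvalues and signals must be matching 1D arrays")
        if (b < 0).any():
            raise ValueError("b-values must be non-negative")
        order = np.argsort(b, kind="stable")
        self.bvalues = b[order]
        self.signals = s[order]


@dataclass
class MonoexpFit:
    S0: float
    ADC: float
    rss: float
    converged: bool
    flags: int = 0


@dataclass
class NGIVIMFit:
    S0: float
    f: float
    Dstar: float
    D: float
    K: float
    rss: float
    converged: bool
    flags: int = 0


def _check_nonneg(**kwargs):
    for name, val in kwargs.items():
        if np.any(np.asarray(val) < 0):
            raise ValueError(f"{name} must be non-negative")


def monoexp_signal(S0, ADC, b):
    """Monoexponential DW signal ``S0 * exp(-b * ADC)``."""
    _check_nonneg(S0=S0, ADC=ADC, b=b)
    return S0 * np.exp(-np.asarray(b, dtype=float) * ADC)


def _kurtosis_exponent(bD, K):
    """Tissue-term exponent -x + K x^2 / 6 with its growth clamped.

    The quadratic kurtosis expansion is only valid for moderate b*D; past its
    minimum at x = 3/K the modelled signal would turn upward, which is
    unphysical.  The exponent is held at its minimum beyond that point so the
    signal stays non-increasing and <= S0.
    """
    bD = np.asarray(bD, dtype=float)
    if K <= 0:
        return -bD, np.zeros(bD.shape, dtype=bool)
    x_min = 3.0 / K
    clamped = bD > x_min
    x = np.where(clamped, x_min, bD)
    return -x + K * x * x / 6.0, clamped


def ngivim_signal(S0, f, Dstar, D, K, b, check_bounds: bool = True):
    """Non-Gaussian IVIM forward signal (perfusion + kurtosis tissue term)."""
    if check_bounds:
        _check_nonneg(S0=S0, b=b)
        if not (F_BOUNDS[0] <= f <= F_BOUNDS[1]):
            raise ValueError(f"perfusion fraction f={f} outside [0, 1]")
        if not (K_BOUNDS[0] <= K <= K_BOUNDS[1]):
            raise ValueError(f"kurtosis K={K} outside {K_BOUNDS}")
        if not (ADC_BOUNDS[0] <= D <= ADC_BOUNDS[1]):
            raise ValueError(f"D={D} outside {ADC_BOUNDS} mm^2/s")
        if not (DSTAR_BOUNDS[0] <= Dstar <= DSTAR_BOUNDS[1]):
            raise ValueError(f"Dstar={Dstar} outside {DSTAR_BOUNDS} mm^2/s")
    b = np.asarray(b, dtype=float)
    expo, _ = _kurtosis_exponent(b * D, K)
    return S0 * (f * np.exp(-b * Dstar) + (1.0 - f) * np.exp(expo))


def _ngivim_model(params, b):
    S0, f, Dstar, D, K = params
    expo, _ = _kurtosis_exponent(b * D, K)
    return S0 * (f * np.exp(-b * Dstar) + (1.0 - f) * np.exp(expo))


def fit_monoexp(series: DWISeries) -> MonoexpFit:
    """Estimate {S0, ADC} by weighted log-linear least squares.

    Weights are proportional to the squared signal.  Non-positive signals
    cannot be log-transformed; such series fall back to a bounded nonlinear
    fit and are flagged.
    """
    b, s = series.bvalues, series.signals
    if np.unique(b).size < 2:
        raise InsufficientDataError("monoexponential fit needs >= 2 distinct b-values")
    flags = 0
    if (s <= 0).any():
        # bounded nonlinear fallback
        s0_init = max(float(s.max()), 1e-6)
        res = least_squares(
            lambda p: p[0] * np.exp(-b * p[1]) - s,
            x0=[s0_init, 1e-3],
            bounds=([0.0, ADC_BOUNDS[0]], [np.inf, ADC_BOUNDS[1]]),
        )
        S0, ADC = res.x
        flags |= FLAG_FALLBACK
        rss = float(np.sum(res.fun**2))
        converged = bool(res.success)
    else:
        w = s**2
        X = np.column_stack([np.ones_like(b), -b])
        y = np.log(s)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        S0 = float(np.exp(coef[0]))
        ADC = float(coef[1])
        rss = float(np.sum((monoexp_signal(S0, max(ADC, 0.0), b) - s) ** 2)) if ADC >= 0 else float(
            np.sum((S0 * np.exp(-b * ADC) - s) ** 2)
        )
        converged = True
    if not (ADC_BOUNDS[0] <= ADC <= ADC_BOUNDS[1]):
        ADC = float(np.clip(ADC, *ADC_BOUNDS))
        flags |= FLAG_BOUND_HIT
        rss = float(np.sum((S0 * np.exp(-b * ADC) - s) ** 2))
    if not converged:
        flags |= FLAG_NOT_CONVERGED
    return MonoexpFit(S0=float(S0), ADC=float(ADC), rss=rss, converged=converged, flags=flags)


def _check_coverage(b: np.ndarray) -> None:
    distinct = np.unique(b)
    if distinct.size < 6:
        raise InsufficientDataError("NG-IVIM fit needs >= 6 distinct b-values")
    if distinct.min() >= 100 or distinct.max() < 800:
        raise InsufficientDataError(
            "NG-IVIM fit needs b-values spanning low (<100) and high (>=800) s/mm^2"
        )


def fit_ngivim(series: DWISeries, strategy: str = "segmented") -> NGIVIMFit:
    """Fit the five NG-IVIM parameters {S0, f, Dstar, D, K}.

    ``segmented`` (default): kurtosis fit on b >= B_SPLIT, perfusion fit on
    the full curve, then a bounded joint refinement.  ``joint`` skips the
    segmented initialization and runs the joint fit from a generic start.
    """
    if strategy not in ("segmented", "joint"):
        raise ValueError(f"unknown strategy {strategy!r}")
    b, s = series.bvalues, series.signals
    _check_coverage(b)
    s_max = max(float(np.abs(s).max()), 1e-12)

    lo = [0.0, F_BOUNDS[0], DSTAR_BOUNDS[0], ADC_BOUNDS[0], K_BOUNDS[0]]
    hi = [np.inf, F_BOUNDS[1], DSTAR_BOUNDS[1], ADC_BOUNDS[1], K_BOUNDS[1]]

    if strategy == "segmented":
        hi_sel = b >= B_SPLIT
        bh, sh = b[hi_sel], s[hi_sel]
        # step 1: tissue-only kurtosis fit on the high-b regime
        def kurt_resid(p):
            S0t, D, K = p
            expo, _ = _kurtosis_exponent(bh * D, K)
            return S0t * np.exp(expo) - sh

        mono0 = 1e-3
        if (sh > 0).all() and np.unique(bh).size >= 2:
            coef = np.polyfit(bh, np.log(sh), 1)
            mono0 = float(np.clip(-coef[0], *ADC_BOUNDS))
        step1 = least_squares(
            kurt_resid,
            x0=[max(float(sh.max()), 1e-6), mono0, 0.5],
            bounds=([0.0, ADC_BOUNDS[0], K_BOUNDS[0]], [np.inf, ADC_BOUNDS[1], K_BOUNDS[1]]),
            x_scale=[max(float(sh.max()), 1e-6), 1e-3, 0.5],
        )
        S0t, D1, K1 = step1.x
        # step 2: perfusion parameters on the full curve, tissue term fixed
        s0_full = max(float(s[b == b.min()].mean()), 1e-6)
        f0 = float(np.clip(1.0 - S0t / s0_full, 0.02, 0.98))

        def perf_resid(p):
            f, Dstar = p
            expo, _ = _kurtosis_exponent(b * D1, K1)
            return s0_full * (f * np.exp(-b * Dstar) + (1 - f) * np.exp(expo)) - s

        step2 = least_squares(
            perf_resid,
            x0=[f0, 20e-3],
            bounds=([F_BOUNDS[0], DSTAR_BOUNDS[0]], [F_BOUNDS[1], DSTAR_BOUNDS[1]]),
            x_scale=[0.1, 1e-2],
        )
        f2, Dstar2 = step2.x
        x0 = [s0_full, f2, Dstar2, D1, K1]
    else:
        x0 = [s_max, 0.1, 20e-3, 1e-3, 0.5]

    x0 = np.clip(x0, np.asarray(lo) + 1e-12, [s_max * 10, *np.asarray(hi[1:])])
    joint = least_squares(lambda p: _ngivim_model(p, b) - s, x0=x0, bounds=(lo, hi),
                          x_scale=[s_max, 0.1, 1e-2, 1e-3, 0.5],
                          xtol=1e-12, ftol=1e-12, gtol=1e-12)
    S0, f, Dstar, D, K = joint.x
    rss = float(np.sum(joint.fun**2))
    flags = 0
    converged = bool(joint.success)
    if not converged:
        flags |= FLAG_NOT_CONVERGED
    atol = 1e-10
    if (
        f <= F_BOUNDS[0] + atol or f >= F_BOUNDS[1] - atol
        or Dstar <= DSTAR_BOUNDS[0] + atol or Dstar >= DSTAR_BOUNDS[1] - atol
        or D <= ADC_BOUNDS[0] + atol or D >= ADC_BOUNDS[1] - atol
        or K >= K_BOUNDS[1] - atol
    ):
        flags |= FLAG_BOUND_HIT
    if Dstar < 2 * D:
        flags |= FLAG_PERFUSION_UNIDENTIFIABLE
    _, clamped = _kurtosis_exponent(b * D, K)
    if clamped.any():
        flags |= FLAG_KURTOSIS_CLAMPED
    return NGIVIMFit(S0=float(S0), f=float(f), Dstar=float(Dstar), D=float(D),
                     K=float(K), rss=rss, converged=converged, flags=flags)


_MODEL_PARAMS = {
    "monoexp": ("S0", "ADC"),
    "ngivim": ("S0", "f", "Dstar", "D", "K"),
}


def fit_dwi_volume(volume: ImageVolume, bvalues, mask: ROIMask, model: str = "ngivim",
                   label: int = 1, strategy: str = "segmented"):
    """Fit every masked voxel of a 4D DW series independently.

    Returns ``(maps, flags_map)`` where ``maps`` is a dict of parameter name
    -> 3D :class:`ImageVolume` (NaN outside the mask) and ``flags_map`` is an
    integer diagnostics volume.  Per-voxel failures are flagged; they never
    abort the volume.
    """
    if model not in _MODEL_PARAMS:
        raise ValueError(f"unknown model {model!r}")
    bvalues = np.asarray(bvalues, dtype=float)
    if volume.data.ndim != 4 or volume.data.shape[3] != bvalues.size:
        raise AlignmentError(
            f"frame count {volume.n_frames} does not match {bvalues.size} b-values"
        )
    signals, idx = extract_roi_signals(volume, mask, label)
    names = _MODEL_PARAMS[model]
    values = {n: np.full(signals.shape[0], np.nan) for n in names}
    flags = np.zeros(signals.shape[0], dtype=float)
    for i in range(signals.shape[0]):
        series = DWISeries(bvalues=bvalues, signals=signals[i])
        try:
            if model == "monoexp":
                fit = fit_monoexp(series)
                values["S0"][i], values["ADC"][i] = fit.S0, fit.ADC
            else:
                fit = fit_ngivim(series, strategy=strategy)
                for n in names:
                    values[n][i] = getattr(fit, n)
            flags[i] = fit.flags
        except Exception:
            flags[i] = FLAG_NOT_CONVERGED | FLAG_FALLBACK
    shape = volume.spatial_shape
    maps = {
        n: ImageVolume(write_back_voxels(shape, idx, values[n]), volume.affine, volume.spacing)
        for n in names
    }
    flags_map = ImageVolume(write_back_voxels(shape, idx, flags, fill=0.0),
                            volume.affine, volume.spacing)
    return maps, flags_map
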