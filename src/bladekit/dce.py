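"""Dynamic contrast-enhanced MRI quantification.

The chain is: variable-flip-angle (VFA) T1 mapping with the spoiled
gradient-echo (SPGR) steady-state signal equation, conversion of the dynamic
signal to tissue contrast-agent concentration under the fast-exchange-limit
relation ``R1(t) = R10 + r1 * Ct(t)``, and tracer-kinetic fitting with either
the Patlak graphical model (Ktrans, vp; linear) or the three-parameter
extended Tofts model (Ktrans, ve, vp; nonlinear), where
``Ct(t) = Ktrans * int_0^t exp(-kep (t - tau)) Cp(tau) dtau + vp * Cp(t)``
and ``kep = Ktrans / ve`` is always derived from the fitted pair, never fit
independently.

Time is handled in minutes internally; Ktrans and kep are reported in
min^-1.  The arterial input function (AIF) Cp(t) is an explicit input in mM.
No hematocrit correction is applied: the AIF is taken as plasma
concentration directly.  Negative concentrations arising from noise are kept
as-is for fitting to avoid censoring bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares

from .errors import AlignmentError, ConversionError, InsufficientDataError
from .image_io import ImageVolume, ROIMask, extract_roi_signals, write_back_voxels
from .dwi import (
    FLAG_BOUND_HIT,
    FLAG_FALLBACK,
    FLAG_NOT_CONVERGED,
)

__all__ = [
    "VFASeries",
    "T10Fit",
    "AIF",
    "ConcentrationCurve",
    "ConversionSettings",
    "PatlakFit",
    "ExtToftsFit",
    "spgr_signal",
    "fit_t10_vfa",
    "signal_to_concentration",
    "concentration_to_signal",
    "patlak_fit",
    "ext_tofts_forward",
    "fit_ext_tofts",
    "fit_dce_volume",
    "T10_BOUNDS",
]

T10_BOUNDS = (0.05, 10.0)   # s
KTRANS_BOUNDS = (0.0, 10.0)  # min^-1
VE_BOUNDS = (1e-6, 1.0)
VP_BOUNDS = (0.0, 1.0)

FLAG_VE_VP_SUM = 32  # ve + vp > 1 after clamping


@dataclass
class VFASeries:
    """Signals of one voxel acquired at several flip angles (degrees), fixed TR (s)."""

    flip_angles_deg: np.ndarray
    signals: np.ndarray
    TR_s: float

    def __post_init__(self):
        a = np.asarray(self.flip_angles_deg, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        if a.shape != s.shape or a.ndim != 1:
            raise ValueError("flip_angles_deg and signals must be matching 1D arrays")
        if np.unique(a).size < 2:
            raise InsufficientDataError("VFA fit needs >= 2 distinct flip angles")
        if (a <= 0).any() or (a > 90).any():
            raise ValueError("flip angles must lie in (0, 90] degrees")
        if self.TR_s <= 0:
            raise ValueError("TR must be positive")
        self.flip_angles_deg = a
        self.signals = s


@dataclass
class T10Fit:
    T10_s: float
    M0: float
    converged: bool
    flags: int = 0


@dataclass
class AIF:
    """Plasma contrast-agent concentration time course Cp(t): t in min, Cp in mM."""

    t_min: np.ndarray
    Cp_mM: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t_min, dtype=float)
        c = np.asarray(self.Cp_mM, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("t_min and Cp_mM must be matching 1D arrays")
        if (np.diff(t) <= 0).any():
            raise ValueError("AIF time grid must be strictly increasing")
        if (c < 0).any():
            raise ValueError("Cp must be non-negative")
        self.t_min = t
        self.Cp_mM = c

    def resample(self, t_min) -> "AIF":
        """Linear interpolation onto a new time grid (must lie within coverage)."""
        t_min = np.asarray(t_min, dtype=float)
        if t_min.min() < self.t_min.min() - 1e-9 or t_min.max() > self.t_min.max() + 1e-9:
            raise AlignmentError("AIF does not cover the requested time window")
        return AIF(t_min=t_min, Cp_mM=np.interp(t_min, self.t_min, self.Cp_mM))


@dataclass
class ConcentrationCurve:
    t_min: np.ndarray
    Ct_mM: np.ndarray
    R1_t: np.ndarray = None

    def __post_init__(self):
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.Ct_mM = np.asarray(self.Ct_mM, dtype=float)
        if self.t_min.shape != self.Ct_mM.shape:
            raise ValueError("t_min and Ct_mM must have matching shapes")
        if self.R1_t is not None:
            self.R1_t = np.asarray(self.R1_t, dtype=float)


@dataclass
class ConversionSettings:
    """Constants of the signal-to-concentration conversion.

    r1_mM_s: contrast-agent longitudinal relaxivity (mM^-1 s^-1).
    n_baseline: pre-contrast frames averaged for the baseline signal.
    """

    r1_mM_s: float = 3.9
    n_baseline: int = 3
    TR_s: float = 0.005
    flip_angle_deg: float = 15.0

    def __post_init__(self):
        if self.r1_mM_s <= 0:
            raise ValueError("relaxivity r1 must be positive")
        if self.n_baseline < 1:
            raise ValueError("n_baseline must be >= 1")
        if self.TR_s <= 0 or not (0 < self.flip_angle_deg <= 90):
            raise ValueError("TR must be positive and flip angle in (0, 90] degrees")


@dataclass
class PatlakFit:
    Ktrans_per_min: float
    vp: float
    r2: float
    n_used: int = 0
    n_excluded: int = 0


@dataclass
class ExtToftsFit:
    Ktrans_per_min: float
    ve: float
    vp: float
    rss: float
    converged: bool
    flags: int = 0

    @property
    def kep_per_min(self) -> float:
        return self.Ktrans_per_min / self.ve


def spgr_signal(M0, T1_s, flip_angle_deg, TR_s):
    """Spoiled gradient-echo steady-state signal.

    ``S = M0 * sin(a) * (1 - E) / (1 - E cos(a))`` with ``E = exp(-TR/T1)``.
    """
    if np.any(np.asarray(T1_s) <= 0):
        raise ValueError("T1 must be positive")
    a = np.deg2rad(np.asarray(flip_angle_deg, dtype=float))
    if np.any(a < 0) or np.any(a > np.pi / 2):
        raise ValueError("flip angle must lie in [0, 90] degrees")
    if TR_s <= 0:
        raise ValueError("TR must be positive")
    E = np.exp(-TR_s / np.asarray(T1_s, dtype=float))
    return M0 * np.sin(a) * (1 - E) / (1 - E * np.cos(a))


def fit_t10_vfa(series: VFASeries) -> T10Fit:
    """Pre-contrast T1 from a multi-flip-angle SPGR series.

    Linearized fit of S/sin(a) against S/tan(a) — the slope is
    ``E = exp(-TR/T10)`` — followed by one bounded nonlinear refinement.
    A slope outside (0, 1), or a poor post-refinement fit (relative RMSE
    above 1%, e.g. identical signals at all angles), is flagged.
    """
    a = np.deg2rad(series.flip_angles_deg)
    s = series.signals
    if (s <= 0).any():
        raise ValueError("VFA signals must be positive")
    y = s / np.sin(a)
    x = s / np.tan(a)
    slope, intercept = np.polyfit(x, y, 1)
    flags = 0
    if not (0 < slope < 1):
        flags |= FLAG_BOUND_HIT
        slope = np.clip(slope, 1e-6, 1 - 1e-9)
    T10 = -series.TR_s / np.log(slope)
    M0 = intercept / (1 - slope) if abs(1 - slope) > 1e-12 else s.max()
    T10 = float(np.clip(T10, *T10_BOUNDS))
    M0 = float(max(M0, 1e-12))

    res = least_squares(
        lambda p: spgr_signal(p[0], p[1], series.flip_angles_deg, series.TR_s) - s,
        x0=[M0, T10],
        bounds=([0.0, T10_BOUNDS[0]], [np.inf, T10_BOUNDS[1]]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    M0, T10 = res.x
    converged = bool(res.success)
    rel_rmse = np.sqrt(np.mean(res.fun**2)) / max(np.abs(s).mean(), 1e-12)
    if rel_rmse > 0.01:
        flags |= FLAG_NOT_CONVERGED
        converged = False
    atol = 1e-9
    if T10 <= T10_BOUNDS[0] + atol or T10 >= T10_BOUNDS[1] - atol:
        flags |= FLAG_BOUND_HIT
    return T10Fit(T10_s=float(T10), M0=float(M0), converged=converged, flags=flags)


def _spgr_shape(T1_s, settings: ConversionSettings):
    a = np.deg2rad(settings.flip_angle_deg)
    E = np.exp(-settings.TR_s / np.asarray(T1_s, dtype=float))
    return np.sin(a) * (1 - E) / (1 - E * np.cos(a))


def signal_to_concentration(signal_t, T10_s, settings: ConversionSettings,
                            t_min=None) -> ConcentrationCurve:
    """Convert one voxel's dynamic SPGR signal to tissue CA concentration (mM).

    M0 is calibrated from the mean of the first ``n_baseline`` frames with
    R10 = 1/T10; each frame's R1 is recovered by inverting the SPGR equation
    and ``Ct = (R1 - R10) / r1``.  Saturated frames where the inversion has
    no solution are set to NaN rather than clamped.
    """
    s = np.asarray(signal_t, dtype=float)
    if s.ndim != 1 or s.size < settings.n_baseline:
        raise ConversionError("dynamic signal must be 1D with at least n_baseline frames")
    if T10_s <= 0:
        raise ConversionError("T10 must be positive")
    baseline = float(s[: settings.n_baseline].mean())
    if baseline <= 0:
        raise ConversionError("non-positive baseline signal; cannot calibrate M0")
    M0 = baseline / _spgr_shape(T10_s, settings)
    a = np.deg2rad(settings.flip_angle_deg)
    sin_a, cos_a = np.sin(a), np.cos(a)
    # invert S = M0 sin(a) (1-E)/(1-E cos(a))  =>  E = (M0 sin(a) - S)/(M0 sin(a) - S cos(a))
    num = M0 * sin_a - s
    den = M0 * sin_a - s * cos_a
    with np.errstate(divide="ignore", invalid="ignore"):
        E = num / den
        R1 = np.where((E > 0) & (E <= 1), -np.log(np.maximum(E, 1e-300)) / settings.TR_s, np.nan)
    R10 = 1.0 / T10_s
    Ct = (R1 - R10) / settings.r1_mM_s
    if t_min is None:
        t_min = np.arange(s.size, dtype=float)
    return ConcentrationCurve(t_min=np.asarray(t_min, dtype=float), Ct_mM=Ct, R1_t=R1)


def concentration_to_signal(Ct_mM, T10_s, settings: ConversionSettings,
                            baseline_signal: float = 1.0) -> np.ndarray:
    """Inverse helper: tissue concentration to SPGR dynamic signal.

    ``baseline_signal`` is the pre-contrast (Ct = 0) signal level; M0 is
    derived from it exactly as the forward conversion does.
    """
    if T10_s <= 0 or baseline_signal <= 0:
        raise ConversionError("T10 and baseline signal must be positive")
    M0 = baseline_signal / _spgr_shape(T10_s, settings)
    R1 = 1.0 / T10_s + settings.r1_mM_s * np.asarray(Ct_mM, dtype=float)
    a = np.deg2rad(settings.flip_angle_deg)
    E = np.exp(-settings.TR_s * R1)
    return M0 * np.sin(a) * (1 - E) / (1 - E * np.cos(a))


def patlak_fit(curve: ConcentrationCurve, aif: AIF, t_window=None,
               cp_floor_frac: float = 0.05) -> PatlakFit:
    """Patlak graphical analysis: OLS of Ct/Cp against int_0^t Cp / Cp.

    The slope is Ktrans (min^-1) and the intercept vp.  Frames before bolus
    arrival or with Cp below ``cp_floor_frac`` of its peak are excluded and
    counted.  ``t_window`` optionally restricts the fit to a (t_lo, t_hi)
    range in minutes.
    """
    if curve.t_min.shape != aif.t_min.shape or not np.allclose(curve.t_min, aif.t_min):
        raise AlignmentError("concentration curve and AIF must share the time grid")
    t, Ct, Cp = curve.t_min, curve.Ct_mM, aif.Cp_mM
    cum_cp = cumulative_trapezoid(Cp, t, initial=0.0)
    floor = cp_floor_frac * Cp.max() if Cp.max() > 0 else np.inf
    usable = (Cp >= floor) & np.isfinite(Ct)
    if t_window is not None:
        usable &= (t >= t_window[0]) & (t <= t_window[1])
    n_used = int(usable.sum())
    if n_used < 3:
        raise InsufficientDataError(f"Patlak fit needs >= 3 usable frames, got {n_used}")
    x = cum_cp[usable] / Cp[usable]
    y = Ct[usable] / Cp[usable]
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PatlakFit(Ktrans_per_min=float(slope), vp=float(intercept), r2=float(r2),
                     n_used=n_used, n_excluded=int(t.size - n_used))


def _ext_tofts_ct(Ktrans, ve, vp, t, Cp):
    """Trapezoidal evaluation of the extended Tofts convolution on the AIF grid."""
    Ct = vp * Cp.copy()
    if Ktrans == 0:
        return Ct
    kep = Ktrans / ve
    n = t.size
    conv = np.zeros(n)
    for i in range(1, n):
        g = np.exp(-kep * (t[i] - t[: i + 1])) * Cp[: i + 1]
        conv[i] = np.trapezoid(g, t[: i + 1])
    return Ct + Ktrans * conv


def ext_tofts_forward(Ktrans, ve, vp, aif: AIF) -> np.ndarray:
    """Tissue concentration predicted by the extended Tofts model on the AIF grid."""
    if Ktrans < 0 or not (VP_BOUNDS[0] <= vp <= VP_BOUNDS[1]):
        raise ValueError("Ktrans must be >= 0 and vp within [0, 1]")
    if Ktrans > 0 and not (0 < ve <= 1):
        raise ValueError("ve must lie in (0, 1] when Ktrans > 0")
    return _ext_tofts_ct(float(Ktrans), float(ve) if Ktrans > 0 else 1.0,
                         float(vp), aif.t_min, aif.Cp_mM)


def fit_ext_tofts(curve: ConcentrationCurve, aif: AIF) -> ExtToftsFit:
    """Bounded nonlinear least squares for {Ktrans, ve, vp}.

    Three starts are tried (one Patlak-informed) and the best residual kept.
    ``kep`` is available as a derived property, never a free parameter.
    """
    if curve.t_min.size < 10:
        raise InsufficientDataError("extended Tofts fit needs >= 10 frames")
    if curve.t_min.shape != aif.t_min.shape or not np.allclose(curve.t_min, aif.t_min):
        raise AlignmentError("concentration curve and AIF must share the time grid")
    t, Cp = aif.t_min, aif.Cp_mM
    finite = np.isfinite(curve.Ct_mM)
    if finite.sum() < 10:
        raise InsufficientDataError("fewer than 10 finite concentration frames")
    Ct = curve.Ct_mM

    def resid(p):
        model = _ext_tofts_ct(p[0], p[1], p[2], t, Cp)
        return (model - Ct)[finite]

    starts = [(0.1, 0.2, 0.02), (0.5, 0.5, 0.05)]
    try:
        pk = patlak_fit(ConcentrationCurve(t_min=t, Ct_mM=np.where(finite, Ct, 0.0)), aif)
        starts.insert(0, (max(pk.Ktrans_per_min, 1e-3), 0.3,
                          float(np.clip(pk.vp, 1e-4, 0.5))))
    except Exception:
        pass

    lo = [KTRANS_BOUNDS[0], VE_BOUNDS[0], VP_BOUNDS[0]]
    hi = [KTRANS_BOUNDS[1], VE_BOUNDS[1], VP_BOUNDS[1]]
    best, best_rss = None, np.inf
    any_success = False
    for x0 in starts:
        res = least_squares(resid, x0=np.clip(x0, lo, hi), bounds=(lo, hi),
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        rss = float(np.sum(res.fun**2))
        if rss < best_rss:
            best, best_rss = res, rss
        any_success |= bool(res.success)
    Ktrans, ve, vp = best.x
    flags = 0
    converged = any_success
    if not converged:
        flags |= FLAG_NOT_CONVERGED
    if ve + vp > 1.0:
        flags |= FLAG_VE_VP_SUM
    atol = 1e-10
    if Ktrans >= KTRANS_BOUNDS[1] - atol or ve <= VE_BOUNDS[0] + atol or vp >= VP_BOUNDS[1] - atol:
        flags |= FLAG_BOUND_HIT
    return ExtToftsFit(Ktrans_per_min=float(Ktrans), ve=float(ve), vp=float(vp),
                       rss=best_rss, converged=converged, flags=flags)


_DCE_PARAMS = {
    "patlak": ("Ktrans", "vp"),
    "ext_tofts": ("Ktrans", "ve", "vp", "kep"),
}


def fit_dce_volume(volume: ImageVolume, frame_times_s, aif: AIF, T10, settings: ConversionSettings,
                   mask: ROIMask, model: str = "ext_tofts", label: int = 1):
    """Convert each masked voxel to concentration, then fit the chosen model.

    ``T10`` may be a scalar (s) or a 3D map aligned to the volume.  Returns
    ``(maps, flags_map)`` with NaN outside the mask; per-voxel failures are
    flagged and never abort the volume.
    """
    if model not in _DCE_PARAMS:
        raise ValueError(f"unknown model {model!r}")
    frame_times_s = np.asarray(frame_times_s, dtype=float)
    if volume.data.ndim != 4 or volume.data.shape[3] != frame_times_s.size:
        raise AlignmentError(
            f"frame count {volume.n_frames} does not match {frame_times_s.size} frame times"
        )
    t_min = frame_times_s / 60.0
    aif_grid = aif.resample(t_min)
    signals, idx = extract_roi_signals(volume, mask, label)
    if np.isscalar(T10) or np.ndim(T10) == 0:
        t10_vox = np.full(signals.shape[0], float(T10))
    else:
        t10_data = T10.data if isinstance(T10, ImageVolume) else np.asarray(T10)
        if t10_data.shape != volume.spatial_shape:
            raise AlignmentError("T10 map does not match the image grid")
        t10_vox = t10_data[idx[:, 0], idx[:, 1], idx[:, 2]].astype(float)
    names = _DCE_PARAMS[model]
    values = {n: np.full(signals.shape[0], np.nan) for n in names}
    flags = np.zeros(signals.shape[0], dtype=float)
    for i in range(signals.shape[0]):
        try:
            curve = signal_to_concentration(signals[i], t10_vox[i], settings, t_min=t_min)
            n_bad = int((~np.isfinite(curve.Ct_mM)).sum())
            if model == "patlak":
                fit = patlak_fit(curve, aif_grid)
                values["Ktrans"][i], values["vp"][i] = fit.Ktrans_per_min, fit.vp
                flags[i] = FLAG_FALLBACK if n_bad else 0
            else:
                fit = fit_ext_tofts(curve, aif_grid)
                values["Ktrans"][i] = fit.Ktrans_per_min
                values["ve"][i] = fit.ve
                values["vp"][i] = fit.vp
                values["kep"][i] = fit.kep_per_min
                flags[i] = fit.flags | (FLAG_FALLBACK if n_bad else 0)
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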