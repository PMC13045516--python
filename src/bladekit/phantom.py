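"""Seeded digital phantoms with known ground truth.

Every generator is a pure function of its specification and seed: repeated
calls are bit-identical, and noiseless output equals the corresponding
forward model to machine precision.  Ground-truth parameter maps are stored
before any noise is applied, so simulation studies always compare against
the clean truth.

Noise is Rician by default — the magnitude-MRI distribution, biased upward
at low SNR — with a Gaussian option for quick tests.  The noise level is
expressed as an sd relative to S0 (so SNR = 1/sd).

Default acquisition settings reflect a typical bladder protocol: nine
b-values from 0 to 1000 s/mm^2 spanning both the perfusion (< 100) and
kurtosis (>= 800) regimes for DWI, and 35 dynamic frames at 5 s per phase
for DCE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dce import (
    AIF,
    ConversionSettings,
    VFASeries,
    concentration_to_signal,
    ext_tofts_forward,
    spgr_signal,
)
from .dwi import monoexp_signal, ngivim_signal
from .dfa import FeatureMatrix
from .errors import ConfigError
from .image_io import ImageVolume, ROIMask

__all__ = [
    "PhantomSpec",
    "DEFAULT_BVALUES",
    "DEFAULT_FRAME_TIMES_S",
    "DEFAULT_FLIP_ANGLES",
    "make_dwi_phantom",
    "biexponential_aif",
    "population_aif",
    "make_dce_phantom",
    "make_vfa_phantom",
    "make_feature_dataset",
]

DEFAULT_BVALUES = np.array([0, 30, 60, 100, 200, 400, 600, 800, 1000], dtype=float)
DEFAULT_FRAME_TIMES_S = np.arange(35, dtype=float) * 5.0
DEFAULT_FLIP_ANGLES = np.array([2.0, 10.0, 15.0])


@dataclass
class PhantomSpec:
    """Declarative phantom description.

    ``regions`` maps a positive mask label to a ground-truth parameter dict;
    voxels are assigned to labels by splitting the grid into equal slabs
    along the first axis (one slab per region, in label order).
    """

    grid_shape: tuple = (8, 8, 2)
    regions: dict = field(default_factory=dict)
    acquisition: np.ndarray = None
    noise_model: str = "none"
    noise_sd: float = 0.0
    seed: int = None

    def __post_init__(self):
        if self.noise_model not in ("none", "rician", "gaussian"):
            raise ConfigError(f"unknown noise model {self.noise_model!r}")
        if self.noise_sd < 0:
            raise ConfigError("noise sd must be non-negative")
        if self.noise_model != "none" and self.seed is None:
            raise ConfigError("a seed is mandatory whenever noise is enabled")
        if not self.regions:
            raise ConfigError("at least one region is required")
        for lab in self.regions:
            if int(lab) <= 0:
                raise ConfigError("region labels must be positive integers")


def _region_mask(spec: PhantomSpec) -> ROIMask:
    mask = np.zeros(spec.grid_shape, dtype=np.int32)
    labels = sorted(spec.regions)
    edges = np.linspace(0, spec.grid_shape[0], len(labels) + 1).astype(int)
    for i, lab in enumerate(labels):
        mask[edges[i]: edges[i + 1]] = lab
    return ROIMask(data=mask)


def _add_noise(clean: np.ndarray, spec: PhantomSpec, scale: float) -> np.ndarray:
    if spec.noise_model == "none" or spec.noise_sd == 0:
        return clean
    rng = np.random.default_rng(spec.seed)
    sd = spec.noise_sd * scale
    if spec.noise_model == "gaussian":
        return clean + rng.normal(0, sd, clean.shape)
    n1 = rng.normal(0, sd, clean.shape)
    n2 = rng.normal(0, sd, clean.shape)
    return np.sqrt((clean + n1) ** 2 + n2**2)


def _truth_maps(spec: PhantomSpec, mask: ROIMask, param_names) -> dict:
    maps = {}
    for name in param_names:
        m = np.full(spec.grid_shape, np.nan)
        for lab, params in spec.regions.items():
            m[mask.data == lab] = params[name]
        maps[name] = ImageVolume(m, np.eye(4))
    return maps


def make_dwi_phantom(spec: PhantomSpec, model: str = "ngivim"):
    """4D DW series whose noiseless voxel signals equal the forward model exactly.

    Returns ``(volume, mask, truth_maps)``; region parameter dicts need
    {S0, ADC} for ``monoexp`` or {S0, f, Dstar, D, K} for ``ngivim``.
    """
    b = np.asarray(spec.acquisition if spec.acquisition is not None else DEFAULT_BVALUES,
                   dtype=float)
    if not (b == 0).any():
        raise ConfigError("DWI phantom acquisition must include b = 0")
    mask = _region_mask(spec)
    names = ("S0", "ADC") if model == "monoexp" else ("S0", "f", "Dstar", "D", "K")
    data = np.zeros(spec.grid_shape + (b.size,))
    s0_ref = 0.0
    for lab, p in spec.regions.items():
        try:
            if model == "monoexp":
                sig = monoexp_signal(p["S0"], p["ADC"], b)
            else:
                sig = ngivim_signal(p["S0"], p["f"], p["Dstar"], p["D"], p["K"], b)
        except (ValueError, KeyError) as exc:
            raise ConfigError(f"region {lab}: invalid ground-truth parameters: {exc}") from exc
        data[mask.data == lab] = sig
        s0_ref = max(s0_ref, p["S0"])
    data = _add_noise(data, spec, scale=s0_ref)
    vol = ImageVolume(data, np.eye(4))
    return vol, mask, _truth_maps(spec, mask, names)


def biexponential_aif(A1, m1, A2, m2, t_min, bolus_arrival_min=0.0) -> AIF:
    """Bi-exponential decay AIF: ``A1 e^{-m1 dt} + A2 e^{-m2 dt}`` after bolus arrival.

    Amplitudes in mM, rates in min^-1; Cp is exactly 0 before arrival.
    """
    if min(A1, m1, A2, m2) <= 0:
        raise ValueError("AIF amplitudes and rates must be positive")
    t = np.asarray(t_min, dtype=float)
    if (np.diff(t) <= 0).any():
        raise ValueError("time grid must be strictly increasing")
    dt = t - bolus_arrival_min
    cp = np.where(dt >= 0, A1 * np.exp(-m1 * np.maximum(dt, 0))
                  + A2 * np.exp(-m2 * np.maximum(dt, 0)), 0.0)
    return AIF(t_min=t, Cp_mM=cp)


def population_aif(t_min, bolus_arrival_min=0.5) -> AIF:
    """Standard population bi-exponential shape (fast + slow clearance terms)."""
    return biexponential_aif(A1=3.99, m1=4.0, A2=1.06, m2=0.1,
                             t_min=t_min, bolus_arrival_min=bolus_arrival_min)


def make_dce_phantom(spec: PhantomSpec, aif: AIF, conversion: ConversionSettings,
                     T10_truth: float = 1.16, baseline_signal: float = 100.0):
    """Dynamic DCE signal phantom via extended Tofts -> relaxation -> SPGR signal.

    Region parameter dicts need {Ktrans, ve, vp} (Ktrans in min^-1).  Frame
    times come from ``spec.acquisition`` (seconds) or default to 35 frames at
    5 s/phase; the AIF is resampled onto that grid.  Returns
    ``(volume, mask, truth_maps, aif_on_grid)``.
    """
    frame_s = np.asarray(spec.acquisition if spec.acquisition is not None
                         else DEFAULT_FRAME_TIMES_S, dtype=float)
    t_min = frame_s / 60.0
    aif_grid = aif.resample(t_min)
    mask = _region_mask(spec)
    data = np.zeros(spec.grid_shape + (frame_s.size,))
    for lab, p in spec.regions.items():
        try:
            ct = ext_tofts_forward(p["Ktrans"], p.get("ve", 1.0), p["vp"], aif_grid)
        except (ValueError, KeyError) as exc:
            raise ConfigError(f"region {lab}: invalid ground-truth parameters: {exc}") from exc
        sig = concentration_to_signal(ct, T10_truth, conversion,
                                      baseline_signal=baseline_signal)
        data[mask.data == lab] = sig
    data = _add_noise(data, spec, scale=baseline_signal)
    vol = ImageVolume(data, np.eye(4))
    truth = _truth_maps(spec, mask, ("Ktrans", "ve", "vp"))
    return vol, mask, truth, aif_grid


def make_vfa_phantom(T10_truth, M0=1000.0, flip_angles=None, TR_s=0.005,
                     noise_model: str = "none", noise_sd: float = 0.0,
                     seed: int = None, n_voxels: int = 1):
    """SPGR signals at several flip angles for each of ``n_voxels`` voxels.

    ``T10_truth`` may be a scalar or an array of per-voxel values.  Returns a
    list of :class:`VFASeries`.
    """
    angles = np.asarray(DEFAULT_FLIP_ANGLES if flip_angles is None else flip_angles,
                        dtype=float)
    t10 = np.broadcast_to(np.asarray(T10_truth, dtype=float), (n_voxels,)).copy()
    clean = np.stack([spgr_signal(M0, t, angles, TR_s) for t in t10])
    spec = PhantomSpec(grid_shape=(1, 1, 1), regions={1: {}},
                       noise_model=noise_model, noise_sd=noise_sd, seed=seed)
    noisy = _add_noise(clean, spec, scale=M0)
    return [VFASeries(flip_angles_deg=angles, signals=noisy[i], TR_s=TR_s)
            for i in range(n_voxels)]


def make_feature_dataset(n_samples: int = 200, n_features: int = 50,
                         n_informative: int = 5, class_separation: float = 2.0,
                         seed: int = 0):
    """Two balanced Gaussian classes with a known informative-feature subset.

    Informative features carry a between-class mean offset of
    ``class_separation`` standard deviations; the rest are i.i.d. noise.
    Returns ``(FeatureMatrix, informative_indices)``.
    """
    if n_informative > n_features:
        raise ValueError("n_informative cannot exceed n_features")
    if class_separation < 0:
        raise ValueError("class_separation must be non-negative")
    rng = np.random.default_rng(seed)
    n_pos = n_samples // 2
    y = np.zeros(n_samples, dtype=int)
    y[:n_pos] = 1
    X = rng.standard_normal((n_samples, n_features))
    informative = np.arange(n_informative)
    X[np.ix_(y == 1, informative)] += class_separation
    perm = rng.permutation(n_samples)
    return FeatureMatrix(X=X[perm], y=y[perm]), informative
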