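"""Closed-form single-molecule photophysics and detection-chain calculators.

Covers the formula set needed to reason about ultrafast (0.1-ms frame)
single fluorescent-molecule imaging:

* the triplet-bottleneck-limited maximum emission rate
  k_em = Phi / (tau_s + Phi_T * tau_T) of a three-state fluorophore;
* the per-frame photon budget through a collection/quantum-efficiency chain;
* the output signal-to-noise of an intensified sensor,
  S/N(G) = S_p G / (N_p G + N_r);
* the pixelized Gaussian PSF photon distribution
  I(m,n) = I_total * E_m * E_n with error-function pixel integrals;
* the Mortensen localization-precision formula with excess noise factor F;
* the spot signal-to-noise ratio (I_spot - I_bg) / sqrt(sd_spot^2 + sd_bg^2).

Default constants for Cy3 and the intensified CMOS camera live in
:mod:`spthop.constants`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erf


@dataclass
class FluorophoreParams:
    """Three-state (ground / singlet / triplet) fluorophore photophysics.

    phi: fluorescence quantum yield; phi_t: triplet formation yield;
    tau_s / tau_t: singlet and triplet lifetimes (s).
    """

    phi: float
    phi_t: float
    tau_s: float
    tau_t: float

    def __post_init__(self) -> None:
        if not 0 < self.phi <= 1:
            raise ValueError("phi must be in (0, 1]")
        if not 0 <= self.phi_t < 1:
            raise ValueError("phi_t must be in [0, 1)")
        if self.tau_s <= 0 or self.tau_t <= 0:
            raise ValueError("lifetimes must be positive")

    @property
    def k_isc(self) -> float:
        """Intersystem crossing rate Phi_T / tau_s (1/s)."""
        return self.phi_t / self.tau_s


@dataclass
class DetectionChain:
    """Photon collection from emitter to detected photoelectrons."""

    collection_eff_lo: float = 0.05
    collection_eff_hi: float = 0.10
    qe: float = 0.40
    frame_time: float = 1e-4

    def __post_init__(self) -> None:
        for v in (self.collection_eff_lo, self.collection_eff_hi, self.qe):
            if not 0 <= v <= 1:
                raise ValueError("efficiencies must be in [0, 1]")


@dataclass
class IntensifierModel:
    """Signal/noise at the photocathode plus sensor readout noise and gain."""

    s_p: float
    n_p: float
    n_r: float
    gain: float

    def __post_init__(self) -> None:
        if min(self.s_p, self.n_p, self.n_r) < 0:
            raise ValueError("signal and noise terms must be >= 0")
        if self.gain < 1:
            raise ValueError("gain must be >= 1")


@dataclass
class PixelizedPsf:
    """A Gaussian spot of i_total photons, SD s (pixels), centered at
    (m0, n0) in pixel units (integer coordinates are pixel centers)."""

    i_total: float
    center: tuple[float, float] = (0.0, 0.0)
    s: float = 2.2

    def __post_init__(self) -> None:
        if self.i_total < 0:
            raise ValueError("i_total must be >= 0")
        if self.s <= 0:
            raise ValueError("s must be > 0")


@dataclass
class MortensenParams:
    """Inputs of the Mortensen precision formula (lengths in nm)."""

    n_photons: float
    s_nm: float = 123.0
    a_nm: float = 55.1
    b: float = 0.059
    f: float = 1.2

    def __post_init__(self) -> None:
        if self.n_photons <= 0:
            raise ValueError("n_photons must be > 0")
        if self.f < 1:
            raise ValueError("excess noise factor must be >= 1")


@dataclass
class SnrInputs:
    """Mean and SD of the spot and background intensity distributions."""

    i_spot: float
    i_bg: float
    sd_spot: float
    sd_bg: float

    def __post_init__(self) -> None:
        if self.sd_spot < 0 or self.sd_bg < 0:
            raise ValueError("standard deviations must be >= 0")


def max_emission_rate(fp: FluorophoreParams) -> float:
    """Triplet-bottleneck-limited emission rate Phi/(tau_s + Phi_T tau_T)
    in photons/s."""
    return fp.phi / (fp.tau_s + fp.phi_t * fp.tau_t)


def photon_budget(fp: FluorophoreParams, chain: DetectionChain) -> dict:
    """Per-frame photon budget: emitted photons, the range reaching the
    photocathode, and the range detected after the quantum efficiency."""
    emitted = max_emission_rate(fp) * chain.frame_time
    at_pc = (emitted * chain.collection_eff_lo, emitted * chain.collection_eff_hi)
    detected = (at_pc[0] * chain.qe, at_pc[1] * chain.qe)
    return {
        "emitted": emitted,
        "at_photocathode_range": at_pc,
        "detected_range": detected,
    }


def intensifier_snr(model: IntensifierModel) -> float:
    """Output S/N(G) = S_p G / (N_p G + N_r).

    At G=1 with N_p << N_r this is readout-dominated (~S_p/N_r); at
    G = N_r/N_p it equals half the photocathode S/N; as G -> infinity it
    saturates at S_p/N_p.
    """
    denom = model.n_p * model.gain + model.n_r
    if denom <= 0:
        raise ValueError("S/N undefined: zero noise denominator")
    return model.s_p * model.gain / denom


def _pixel_edge_integral(m: np.ndarray | float, m0: float, s: float):
    """E_m: fraction of a unit-total 1-D Gaussian (mean m0, SD s) falling in
    the unit pixel centered on integer m."""
    m = np.asarray(m, dtype=float)
    root2s = math.sqrt(2.0) * s
    return 0.5 * (erf((m - m0 + 0.5) / root2s) - erf((m - m0 - 0.5) / root2s))


def pixelized_psf_intensity(psf: PixelizedPsf, m, n):
    """Expected photons in pixel (m, n): I_total * E_m * E_n."""
    em = _pixel_edge_integral(m, psf.center[0], psf.s)
    en = _pixel_edge_integral(n, psf.center[1], psf.s)
    out = psf.i_total * em * en
    return float(out) if np.isscalar(m) and np.isscalar(n) else out


def pixelized_psf_image(
    psf: PixelizedPsf, shape: tuple[int, int]
) -> np.ndarray:
    """Expected-photon image on a (rows, cols) grid of whole pixels."""
    rows, cols = shape
    em = _pixel_edge_integral(np.arange(cols), psf.center[0], psf.s)
    en = _pixel_edge_integral(np.arange(rows), psf.center[1], psf.s)
    return psf.i_total * np.outer(en, em)


def mortensen_precision(p: MortensenParams) -> float:
    """Localization precision (nm):

    sigma_xy = F * sqrt( 16 (s^2 + a^2/12) / (9 N)
                         + 8 pi b^2 (s^2 + a^2/12)^2 / (a^2 N^2) ).
    """
    sa2 = p.s_nm**2 + p.a_nm**2 / 12.0
    shot = 16.0 * sa2 / (9.0 * p.n_photons)
    bg = 8.0 * math.pi * p.b**2 * sa2**2 / (p.a_nm**2 * p.n_photons**2)
    return p.f * math.sqrt(shot + bg)


def snr(inputs: SnrInputs) -> float:
    """Spot SNR = (I_spot - I_bg) / sqrt(sd_spot^2 + sd_bg^2)."""
    denom = math.hypot(inputs.sd_spot, inputs.sd_bg)
    if denom == 0:
        raise ValueError("SNR undefined: both standard deviations are zero")
    return (inputs.i_spot - inputs.i_bg) / denom
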