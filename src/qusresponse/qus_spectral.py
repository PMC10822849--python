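"""Quantitative-ultrasound spectroscopy: normalized spectra and the five
QUS parameters.

The chain per analysis block is

1. :func:`block_power_spectrum` — Hann-gated, zero-padded periodogram per
   scan line, averaged across lines, in dB;
2. :func:`normalize_spectrum` — reference-phantom normalization with
   round-trip attenuation compensation ``+ 4 (alpha_s - alpha_r) f d``;
3. :func:`fit_spectral_params` — ordinary least squares of the normalized
   dB spectrum against frequency on the -6 dB band: spectral slope (SS,
   dB/MHz), 0 MHz spectral intercept (SI, dB) and midband fit (MBF, dB, the
   fitted value at the centre frequency, so MBF = SI + SS*fc identically);
4. :func:`estimate_bsc` + :func:`fit_gaussian_form_factor` — transfer the
   phantom's known backscatter coefficient to the sample, then fit
   ``BSC(f) = C f^4 exp(-0.827 k^2 a_eff^2)`` by linearized (log-domain)
   least squares of ``ln(BSC/f^4)`` against ``k^2``; the slope gives the
   effective radius (average scatterer diameter ASD = 2 a_eff) and the
   intercept the amplitude factor, reported as average acoustic
   concentration AAC = 10 log10(C / ASD_um^6) on a relative dB scale so it
   tracks scatterer number density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    AlignmentError,
    FitFailureError,
    InsufficientSupportError,
    ValidationError,
)
from .synthetic_rf import GAUSSIAN_FF_CONSTANT, PulseSpec

__all__ = [
    "PowerSpectrum",
    "SpectralParams",
    "BSCCurve",
    "ScattererParams",
    "DB_FLOOR",
    "block_power_spectrum",
    "normalize_spectrum",
    "fit_spectral_params",
    "estimate_bsc",
    "fit_gaussian_form_factor",
]

#: dB clamp for zero-power bins; spectra touching the floor are flagged.
DB_FLOOR = -200.0


@dataclass
class PowerSpectrum:
    """Power spectrum on a MHz grid, in dB, tagged raw or normalized."""

    frequencies_mhz: np.ndarray
    values_db: np.ndarray
    block_depth_cm: float = 0.0
    kind: str = "raw"  # "raw" | "normalized"

    def __post_init__(self) -> None:
        self.frequencies_mhz = np.asarray(self.frequencies_mhz, dtype=float)
        self.values_db = np.asarray(self.values_db, dtype=float)
        if self.frequencies_mhz.shape != self.values_db.shape:
            raise ValidationError("frequency and value grids differ in shape")
        if self.frequencies_mhz.size and np.any(np.diff(self.frequencies_mhz) <= 0):
            raise ValidationError("frequency grid must be strictly increasing")

    def band(self, low_mhz: float, high_mhz: float) -> np.ndarray:
        return (self.frequencies_mhz >= low_mhz) & (self.frequencies_mhz <= high_mhz)


@dataclass(frozen=True)
class SpectralParams:
    """Linear-fit parameters of the normalized spectrum."""

    mbf_db: float
    ss_db_per_mhz: float
    si_db: float


@dataclass
class BSCCurve:
    """Backscatter coefficient (relative linear scale) on a MHz grid."""

    frequencies_mhz: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies_mhz = np.asarray(self.frequencies_mhz, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.frequencies_mhz.shape != self.values.shape:
            raise ValidationError("frequency and BSC grids differ in shape")


@dataclass(frozen=True)
class ScattererParams:
    """Gaussian form-factor fit results."""

    asd_um: float  # average scatterer diameter = 2 * effective radius
    aac_db: float  # average acoustic concentration, relative dB


def block_power_spectrum(
    rf_block: np.ndarray,
    pulse: PulseSpec,
    block_depth_cm: float = 0.0,
) -> PowerSpectrum:
    """Hann-gated averaged periodogram of an RF block (lines x samples).

    Each scan-line segment is tapered with a Hann window, transformed with an
    FFT zero-padded to the next power of two >= 4x the gate length,
    magnitude-squared, averaged across lines arithmetically and converted to
    dB (floor-clamped at ``DB_FLOOR``).
    """
    block = np.atleast_2d(np.asarray(rf_block, dtype=float))
    if block.size == 0 or block.shape[0] < 1 or block.shape[1] < 16:
        raise ValidationError("RF block needs >= 1 scan line and >= 16 samples")
    gate = block.shape[1]
    nfft = 1 << int(np.ceil(np.log2(4 * gate)))
    window = np.hanning(gate)
    spectra = np.abs(np.fft.rfft(block * window[None, :], n=nfft, axis=1)) ** 2
    mean_power = spectra.mean(axis=0)
    freqs_mhz = np.fft.rfftfreq(nfft, d=1.0 / pulse.sampling_frequency)
    with np.errstate(divide="ignore"):
        values_db = 10.0 * np.log10(mean_power)
    values_db = np.maximum(values_db, DB_FLOOR)
    return PowerSpectrum(freqs_mhz, values_db, block_depth_cm=block_depth_cm, kind="raw")


def normalize_spectrum(
    sample: PowerSpectrum,
    reference: PowerSpectrum,
    depth_cm: float,
    alpha_sample_db_mhz_cm: float,
    alpha_ref_db_mhz_cm: float,
) -> PowerSpectrum:
    """Reference-phantom normalization with attenuation compensation.

    ``normalized(f) = S(f) - R(f) + 4 (alpha_s - alpha_r) f d`` with ``f`` in
    MHz and ``d`` in cm — the 4 f d term undoes the round-trip (two-way,
    there-and-back) attenuation difference between tissue and phantom.
    """
    if sample.frequencies_mhz.shape != reference.frequencies_mhz.shape or not np.allclose(
        sample.frequencies_mhz, reference.frequencies_mhz
    ):
        raise AlignmentError("sample and reference spectra are on different grids")
    comp = (
        4.0
        * (alpha_sample_db_mhz_cm - alpha_ref_db_mhz_cm)
        * sample.frequencies_mhz
        * depth_cm
    )
    return PowerSpectrum(
        sample.frequencies_mhz.copy(),
        sample.values_db - reference.values_db + comp,
        block_depth_cm=depth_cm,
        kind="normalized",
    )


def fit_spectral_params(nps: PowerSpectrum, pulse: PulseSpec) -> SpectralParams:
    """OLS line through the normalized spectrum on the -6 dB band.

    SS is the slope (dB/MHz), SI the 0 MHz intercept (dB) and MBF the fitted
    value at the centre frequency, so ``MBF = SI + SS * fc`` by construction.
    """
    if nps.kind != "normalized":
        raise ValidationError("spectral parameters are fitted on normalized spectra")
    mask = nps.band(pulse.band_low, pulse.band_high)
    if int(mask.sum()) < 3:
        raise InsufficientSupportError("fewer than 3 grid points inside the fit band")
    f = nps.frequencies_mhz[mask]
    y = nps.values_db[mask]
    if not np.all(np.isfinite(y)) or np.any(y <= DB_FLOOR):
        raise ValidationError("non-finite or floor-clamped values inside the fit band")
    slope, intercept = np.polyfit(f, y, 1)
    return SpectralParams(
        mbf_db=float(intercept + slope * pulse.center_frequency),
        ss_db_per_mhz=float(slope),
        si_db=float(intercept),
    )


def estimate_bsc(nps: PowerSpectrum, reference_bsc: BSCCurve) -> BSCCurve:
    """Transfer the phantom's known BSC to the sample:
    ``BSC_s(f) = BSC_ref(f) * 10^(NPS(f)/10)``."""
    if nps.kind != "normalized":
        raise ValidationError("BSC estimation requires a normalized spectrum")
    if nps.frequencies_mhz.shape != reference_bsc.frequencies_mhz.shape or not np.allclose(
        nps.frequencies_mhz, reference_bsc.frequencies_mhz
    ):
        raise AlignmentError("normalized spectrum and reference BSC grids differ")
    return BSCCurve(
        nps.frequencies_mhz.copy(),
        reference_bsc.values * 10.0 ** (nps.values_db / 10.0),
    )


def fit_gaussian_form_factor(
    bsc: BSCCurve,
    sound_speed: float,
    band_mhz: tuple[float, float] | None = None,
) -> ScattererParams:
    """Fit the spherical Gaussian form-factor model to a BSC curve.

    Linear regression of ``ln(BSC / f^4)`` on ``k^2`` (``k = 2 pi f 1e6 / c``):
    the slope is ``-0.827 a_eff^2`` (ASD = 2 a_eff, um) and the intercept
    ``ln C``.  AAC folds the model's diameter dependence back out,
    ``AAC = 10 log10(C) - 60 log10(ASD_um)`` (relative dB), so it follows
    acoustic concentration rather than size.  A non-negative slope means the
    spectrum shows no Gaussian decay and the effective radius is not
    identifiable; that is raised, never returned as a silent number.
    """
    if band_mhz is not None:
        mask = (bsc.frequencies_mhz >= band_mhz[0]) & (bsc.frequencies_mhz <= band_mhz[1])
        freqs, values = bsc.frequencies_mhz[mask], bsc.values[mask]
    else:
        freqs, values = bsc.frequencies_mhz, bsc.values
    pos = freqs > 0
    freqs, values = freqs[pos], values[pos]
    if freqs.size < 3:
        raise InsufficientSupportError("form-factor fit needs >= 3 positive-frequency points")
    if np.any(values <= 0) or not np.all(np.isfinite(values)):
        raise ValidationError("BSC must be strictly positive and finite on the fit band")
    k = 2.0 * np.pi * freqs * 1e6 / sound_speed  # 1/m
    y = np.log(values / freqs**4)
    slope, intercept = np.polyfit(k**2, y, 1)
    if slope >= 0:
        raise FitFailureError(
            f"non-decaying BSC (slope {slope:.3g} >= 0): effective radius not identifiable"
        )
    a_eff_m = float(np.sqrt(-slope / GAUSSIAN_FF_CONSTANT))
    asd_um = 2.0 * a_eff_m * 1e6
    c_amp = float(np.exp(intercept))
    aac_db = 10.0 * np.log10(c_amp) - 60.0 * np.log10(asd_um)
    return ScattererParams(asd_um=asd_um, aac_db=aac_db)
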