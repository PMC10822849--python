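"""Synthetic radiofrequency (RF) ultrasound cohorts with known ground truth.

The clinical data this pipeline was designed around (pre-treatment breast
tumour scans) cannot be redistributed, so every downstream stage is exercised
on simulated RF frames instead.  The simulator is a 2-D point-scatterer model:
each scatterer returns a replica of the transmit pulse delayed by its
round-trip time and filtered, across the whole band, by

* a Rayleigh ``f^2`` amplitude factor (so backscattered *power* grows as
  ``f^4``),
* the square root of a spherical Gaussian form factor
  ``FF(f) = exp(-0.827 k^2 a^2)`` with ``k = 2 pi f / c`` and ``a`` the
  effective scatterer radius, and
* frequency-dependent round-trip attenuation.  The package-wide convention
  is that ``alpha`` dB/(MHz cm) produces a round-trip *power* loss of
  ``4 alpha f d`` dB at depth ``d`` cm — exactly the loss the reference
  phantom normalization compensates — so the forward amplitude factor is
  ``10^(-4 alpha f d / 20)``.

Scatterer amplitudes scale with ``(a / 25 um)^3`` so that the backscatter
prefactor carries the Rayleigh ``a^6`` dependence and acoustic concentration
estimates track number density.  Echoes are spread over neighbouring scan
lines by a Gaussian lateral beam profile, which gives frames realistic
lateral speckle correlation.  No full-wave propagation, elevational beam or
nonlinear effects are modelled.

All randomness flows through :class:`numpy.random.Generator` objects seeded
from explicit integers; regeneration with the same seed is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
import h5py
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ValidationError

__all__ = [
    "PulseSpec",
    "FrameGeometry",
    "ScattererField",
    "PhantomSpec",
    "RFFrame",
    "ClassParams",
    "CohortConfig",
    "PatientRecord",
    "SyntheticCohort",
    "simulate_rf_frame",
    "make_reference_frame",
    "generate_cohort",
    "homogeneous_field",
    "form_factor",
    "analytic_bsc",
    "save_cohort",
    "load_cohort",
]

#: reference radius (um) used to normalise the a^3 amplitude scaling.
REFERENCE_RADIUS_UM = 25.0

#: spherical Gaussian form-factor constant (Insana-style formulation).
GAUSSIAN_FF_CONSTANT = 0.827


@dataclass(frozen=True)
class PulseSpec:
    """Transmit pulse / transducer description.

    The -6 dB *power* bandwidth spans ``band_low``..``band_high`` MHz; the
    pulse envelope is Gaussian, so the power spectrum is Gaussian around the
    centre frequency with standard deviation chosen to honour that width.
    """

    center_frequency: float = 6.0  # MHz
    sampling_frequency: float = 40.0  # MHz
    band_low: float = 3.0  # MHz
    band_high: float = 8.0  # MHz
    sound_speed: float = 1540.0  # m/s

    def __post_init__(self) -> None:
        if not (self.band_low < self.center_frequency < self.band_high):
            raise ValidationError(
                "band_low < center_frequency < band_high required, got "
                f"{self.band_low}, {self.center_frequency}, {self.band_high}"
            )
        if self.sampling_frequency <= 2.0 * self.band_high:
            raise ValidationError(
                f"sampling frequency {self.sampling_frequency} MHz violates "
                f"Nyquist for band edge {self.band_high} MHz"
            )
        if self.sound_speed <= 0:
            raise ValidationError("sound speed must be positive")

    @property
    def power_sigma_mhz(self) -> float:
        """Std of the Gaussian power spectrum implied by the -6 dB band."""
        half_width = 0.5 * (self.band_high - self.band_low)
        return half_width / math.sqrt(2.0 * math.log(10.0 ** 0.6))

    @property
    def axial_spacing_mm(self) -> float:
        """Axial distance between RF samples, c / (2 fs)."""
        return self.sound_speed / (2.0 * self.sampling_frequency * 1e6) * 1e3

    def amplitude_spectrum(self, freq_hz: np.ndarray) -> np.ndarray:
        """One-sided pulse amplitude spectrum on a Hz grid."""
        sigma = self.power_sigma_mhz * 1e6
        return np.exp(-((freq_hz - self.center_frequency * 1e6) ** 2) / (4.0 * sigma**2))


@dataclass(frozen=True)
class FrameGeometry:
    """Scan geometry: lateral line raster and imaged depth range (mm)."""

    n_lines: int = 120
    line_pitch_mm: float = 0.1
    depth_start_mm: float = 8.0
    depth_end_mm: float = 26.0

    def __post_init__(self) -> None:
        if self.n_lines < 1 or self.line_pitch_mm <= 0:
            raise ValidationError("geometry needs >= 1 line with positive pitch")
        if self.depth_end_mm <= self.depth_start_mm:
            raise ValidationError("depth_end_mm must exceed depth_start_mm")

    def n_samples(self, pulse: PulseSpec) -> int:
        return int(round((self.depth_end_mm - self.depth_start_mm) / pulse.axial_spacing_mm))

    @property
    def lateral_positions_mm(self) -> np.ndarray:
        return np.arange(self.n_lines) * self.line_pitch_mm

    @property
    def width_mm(self) -> float:
        return (self.n_lines - 1) * self.line_pitch_mm


@dataclass
class ScattererField:
    """Discrete scatterers in the imaging plane.

    positions: (N, 2) array of (axial mm from transducer face, lateral mm).
    ``effective_radius_um`` and ``relative_amplitude`` may be scalars
    (homogeneous field) or per-scatterer arrays.
    """

    positions: np.ndarray
    effective_radius_um: np.ndarray | float
    relative_amplitude: np.ndarray | float = 1.0
    number_density_per_mm2: float | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size == 0:
            self.positions = self.positions.reshape(0, 2)
        if self.positions.shape[1] != 2:
            raise ValidationError("positions must be an (N, 2) array")
        n = len(self.positions)
        self.effective_radius_um = np.broadcast_to(
            np.asarray(self.effective_radius_um, dtype=float), (n,)
        ).copy()
        self.relative_amplitude = np.broadcast_to(
            np.asarray(self.relative_amplitude, dtype=float), (n,)
        ).copy()
        if n and np.any(self.effective_radius_um <= 0):
            raise ValidationError("scatterer radii must be positive")
        if self.number_density_per_mm2 is not None and n > 0 and self.number_density_per_mm2 <= 0:
            raise ValidationError("number density must be positive for non-empty fields")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class PhantomSpec:
    """Reference phantom: known attenuation, sound speed and bead population."""

    attenuation_db_mhz_cm: float = 0.576
    sound_speed: float = 1488.0
    bead_radius_um: float = 12.0
    bead_density_per_mm2: float = 10.0

    def __post_init__(self) -> None:
        if self.attenuation_db_mhz_cm < 0:
            raise ValidationError("attenuation coefficient must be >= 0")


@dataclass
class RFFrame:
    """Raw RF echo data: ``samples[line, time_sample]`` plus geometry."""

    samples: np.ndarray  # (n_lines, n_samples)
    axial_spacing_mm: float
    lateral_spacing_mm: float
    pulse: PulseSpec
    depth_offset_mm: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError("RF samples must be 2-D (line x sample)")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("RF samples must be finite")

    @property
    def n_lines(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def sample_depth_mm(self, sample_index: np.ndarray | int) -> np.ndarray | float:
        """Depth (mm from the transducer face) of a time-sample index."""
        return self.depth_offset_mm + np.asarray(sample_index) * self.axial_spacing_mm


def form_factor(freq_hz: np.ndarray, radius_um: float | np.ndarray, sound_speed: float) -> np.ndarray:
    """Spherical Gaussian form factor ``exp(-0.827 k^2 a^2)``."""
    k = 2.0 * np.pi * np.asarray(freq_hz, dtype=float) / sound_speed  # 1/m
    a_m = np.asarray(radius_um, dtype=float) * 1e-6
    return np.exp(-GAUSSIAN_FF_CONSTANT * (k * a_m) ** 2)


def analytic_bsc(
    freq_mhz: np.ndarray,
    radius_um: float,
    density_per_mm2: float,
    amplitude: float = 1.0,
    sound_speed: float = 1540.0,
    center_frequency_mhz: float = 6.0,
) -> np.ndarray:
    """Relative backscatter coefficient implied by the simulator's model.

    ``BSC(f) = n * A^2 * (a/a0)^6 * (f/fc)^4 * FF(f, a)`` — the expected
    block-power ratio between a field with these parameters and any other is
    exactly the ratio of their ``analytic_bsc`` curves (pulse, beam and
    windowing factors cancel).  Units are relative, not 1/(sr cm).
    """
    f = np.asarray(freq_mhz, dtype=float)
    rel = (radius_um / REFERENCE_RADIUS_UM) ** 6
    return (
        density_per_mm2
        * amplitude**2
        * rel
        * (f / center_frequency_mhz) ** 4
        * form_factor(f * 1e6, radius_um, sound_speed)
    )


def homogeneous_field(
    geometry: FrameGeometry,
    density_per_mm2: float,
    radius_um: float,
    amplitude: float,
    rng: np.random.Generator,
) -> ScattererField:
    """Uniform random scatterers filling the frame's field of view."""
    area = geometry.width_mm * (geometry.depth_end_mm - geometry.depth_start_mm)
    n = rng.poisson(density_per_mm2 * area)
    ax = rng.uniform(geometry.depth_start_mm, geometry.depth_end_mm, n)
    lat = rng.uniform(0.0, geometry.width_mm, n)
    return ScattererField(
        positions=np.column_stack([ax, lat]),
        effective_radius_um=radius_um,
        relative_amplitude=amplitude,
        number_density_per_mm2=density_per_mm2,
    )


def simulate_rf_frame(
    fieldspec: ScattererField,
    pulse: PulseSpec,
    attenuation_db_mhz_cm: float,
    geometry: FrameGeometry,
    seed: int | None = 0,
    snr_db: float | None = 30.0,
    lateral_beam_sigma_mm: float = 0.05,
) -> RFFrame:
    """Synthesize one RF frame from a scatterer field.

    Echo synthesis is done per scan line in the frequency domain: every
    scatterer contributes the pulse spectrum, phase-delayed by its round-trip
    time and filtered by sqrt(form factor), the Rayleigh ``f^2`` amplitude and
    round-trip attenuation, then weighted by a Gaussian lateral beam profile
    truncated at three sigma.  ``snr_db=None`` (or ``inf``) disables noise.
    """
    if snr_db is not None and np.isfinite(snr_db) and snr_db < 0:
        raise ValidationError("SNR in dB must be non-negative (or None for noise-free)")
    pos = fieldspec.positions
    if len(fieldspec):
        in_ax = (pos[:, 0] >= geometry.depth_start_mm - 1e-9) & (
            pos[:, 0] <= geometry.depth_end_mm + 1e-9
        )
        in_lat = (pos[:, 1] >= -1e-9) & (pos[:, 1] <= geometry.width_mm + 1e-9)
        if not np.all(in_ax & in_lat):
            raise ValidationError("scatterer positions fall outside the frame geometry")

    n_samples = geometry.n_samples(pulse)
    fs_hz = pulse.sampling_frequency * 1e6
    # guard band against circular wraparound of echoes near the window edges
    pad = 64
    n_total = n_samples + 2 * pad
    freq_hz = np.fft.rfftfreq(n_total, d=1.0 / fs_hz)
    pulse_spec = pulse.amplitude_spectrum(freq_hz)

    line_spectra = np.zeros((geometry.n_lines, freq_hz.size), dtype=complex)
    if len(fieldspec):
        depths_mm = pos[:, 0]
        lat_mm = pos[:, 1]
        radii = np.asarray(fieldspec.effective_radius_um, dtype=float)
        amps = np.asarray(fieldspec.relative_amplitude, dtype=float) * (
            radii / REFERENCE_RADIUS_UM
        ) ** 3

        f_mhz = freq_hz / 1e6
        fc = pulse.center_frequency
        rayleigh = (f_mhz / fc) ** 2
        # sqrt of the power form factor — amplitude filtering
        k = 2.0 * np.pi * freq_hz / pulse.sound_speed
        t_delay = (
            2.0 * (depths_mm - geometry.depth_start_mm) * 1e-3 / pulse.sound_speed
            + pad / fs_hz
        )
        # round-trip power loss 4*alpha*f*d dB -> amplitude 10^(-4 a f d / 20)
        atten_exp = -4.0 * attenuation_db_mhz_cm * (depths_mm / 10.0) / 20.0  # per MHz

        line_x = geometry.lateral_positions_mm
        reach = 3.0 * lateral_beam_sigma_mm
        for i in range(len(fieldspec)):
            j0 = int(np.searchsorted(line_x, lat_mm[i] - reach))
            j1 = int(np.searchsorted(line_x, lat_mm[i] + reach, side="right"))
            if j1 <= j0:
                continue
            w = np.exp(
                -((line_x[j0:j1] - lat_mm[i]) ** 2) / (2.0 * lateral_beam_sigma_mm**2)
            )
            a_m = radii[i] * 1e-6
            spec_i = (
                amps[i]
                * rayleigh
                * np.exp(-0.5 * GAUSSIAN_FF_CONSTANT * (k * a_m) ** 2)
                * 10.0 ** (atten_exp[i] * f_mhz)
                * np.exp(-2j * np.pi * freq_hz * t_delay[i])
            )
            line_spectra[j0:j1] += w[:, None] * spec_i[None, :]

    rf = np.fft.irfft(line_spectra * pulse_spec[None, :], n=n_total, axis=1)[:, pad : pad + n_samples]

    if snr_db is not None and np.isfinite(snr_db):
        rng = np.random.default_rng(seed)
        signal_rms = float(np.sqrt(np.mean(rf**2)))
        if signal_rms > 0:
            noise_sigma = signal_rms * 10.0 ** (-snr_db / 20.0)
            rf = rf + rng.normal(0.0, noise_sigma, rf.shape)

    return RFFrame(
        samples=rf,
        axial_spacing_mm=pulse.axial_spacing_mm,
        lateral_spacing_mm=geometry.line_pitch_mm,
        pulse=pulse,
        depth_offset_mm=geometry.depth_start_mm,
    )


def make_reference_frame(
    phantom: PhantomSpec,
    pulse: PulseSpec,
    geometry: FrameGeometry,
    seed: int = 0,
    snr_db: float | None = None,
) -> RFFrame:
    """RF frame of the homogeneous reference phantom.

    The phantom is scanned over the same *time* window as tissue frames: the
    geometry's depth range is rescaled by ``c_phantom / c_tissue`` so every
    time-sample index gates the same arrival times in both media and the RF
    rasters share a shape.  The analytic per-block expected backscatter
    spectrum is available through :func:`analytic_bsc` with the phantom's
    bead parameters.
    """
    ref_pulse = replace(pulse, sound_speed=phantom.sound_speed)
    scale = phantom.sound_speed / pulse.sound_speed
    ref_geometry = replace(
        geometry,
        depth_start_mm=geometry.depth_start_mm * scale,
        depth_end_mm=geometry.depth_end_mm * scale,
    )
    rng = np.random.default_rng(seed)
    fieldspec = homogeneous_field(
        ref_geometry,
        phantom.bead_density_per_mm2,
        phantom.bead_radius_um,
        1.0,
        rng,
    )
    return simulate_rf_frame(
        fieldspec,
        ref_pulse,
        phantom.attenuation_db_mhz_cm,
        ref_geometry,
        seed=seed + 1,
        snr_db=snr_db,
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassParams:
    """Per-class tumour-core scatterer statistics (between-patient normals)."""

    radius_mean_um: float
    radius_sd_um: float
    density_mean_per_mm2: float
    density_sd_per_mm2: float


@dataclass
class CohortConfig:
    """Study conditions for a synthetic two-class cohort.

    Defaults mirror the clinical cohort structure this pipeline targets:
    174 patients split 37 nonresponders (NR) / 137 responders (RR), each
    imaged at 4-7 planes across the tumour.  Nonresponder tumour cores carry
    larger, sparser scatterers than responder cores; the surrounding tissue
    (and the 5 mm margin) is class-independent.
    """

    n_nr: int = 37
    n_rr: int = 137
    frames_per_patient: tuple[int, int] = (4, 7)
    pulse: PulseSpec = field(default_factory=PulseSpec)
    geometry: FrameGeometry = field(default_factory=FrameGeometry)
    nr_core: ClassParams = ClassParams(36.0, 1.0, 4.0, 0.4)
    rr_core: ClassParams = ClassParams(20.0, 1.0, 14.0, 0.8)
    background_radius_um: float = 20.0
    background_density_per_mm2: float = 8.0
    tumor_center_mm: tuple[float, float] = (16.0, 6.0)  # (axial, lateral)
    tumor_semiaxes_mm: tuple[float, float] = (3.5, 4.0)
    center_jitter_mm: float = 0.8
    margin_mm: float = 5.0
    sample_attenuation_db_mhz_cm: float = 1.0
    snr_db: float | None = 30.0

    def __post_init__(self) -> None:
        if self.n_nr <= 0 or self.n_rr <= 0:
            raise ValidationError("class counts must be positive")
        lo, hi = self.frames_per_patient
        if not (1 <= lo <= hi):
            raise ValidationError("frames_per_patient range must satisfy 1 <= lo <= hi")

    @classmethod
    def null_effect(cls, **kwargs) -> "CohortConfig":
        """Zero class effect: both classes share one core distribution."""
        shared = ClassParams(26.0, 1.5, 8.0, 0.8)
        return cls(nr_core=shared, rr_core=shared, **kwargs)


@dataclass
class PatientRecord:
    patient_id: str
    label: str  # "NR" or "RR"
    frames: list[RFFrame]
    rois: list  # list[ROIMask] — typed loosely to avoid an import cycle
    truth: dict


@dataclass
class SyntheticCohort:
    patients: list[PatientRecord]
    config: CohortConfig
    seed: int

    def __len__(self) -> int:
        return len(self.patients)

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": p.patient_id,
                "label": p.label,
                "n_frames": len(p.frames),
                **{f"true_{k}": v for k, v in p.truth.items()},
            }
            for p in self.patients
        ]
        return pd.DataFrame(rows)


def _elliptical_core_mask(
    frame: RFFrame, center_mm: tuple[float, float], semiaxes_mm: tuple[float, float]
) -> np.ndarray:
    """Binary core ellipse on the (axial sample, scan line) raster."""
    ax = frame.depth_offset_mm + np.arange(frame.n_samples) * frame.axial_spacing_mm
    lat = np.arange(frame.n_lines) * frame.lateral_spacing_mm
    da = (ax[:, None] - center_mm[0]) / semiaxes_mm[0]
    dl = (lat[None, :] - center_mm[1]) / semiaxes_mm[1]
    return (da**2 + dl**2) <= 1.0


def _margin_ring(core: np.ndarray, spacing_mm: tuple[float, float], margin_mm: float) -> np.ndarray:
    """5 mm morphological-dilation ring: within ``margin_mm`` of the core."""
    dist = ndimage.distance_transform_edt(~core, sampling=spacing_mm)
    return (dist <= margin_mm) & ~core


def _tumor_field(
    config: CohortConfig,
    center_mm: tuple[float, float],
    radius_um: float,
    density: float,
    rng: np.random.Generator,
) -> ScattererField:
    """Background scatterers everywhere except the core, patient-specific
    scatterers inside the elliptical core."""
    geom = config.geometry
    bg = homogeneous_field(
        geom, config.background_density_per_mm2, config.background_radius_um, 1.0, rng
    )
    sa, sl = config.tumor_semiaxes_mm
    inside = (
        ((bg.positions[:, 0] - center_mm[0]) / sa) ** 2
        + ((bg.positions[:, 1] - center_mm[1]) / sl) ** 2
    ) <= 1.0
    bg_pos = bg.positions[~inside]

    n_core = rng.poisson(density * np.pi * sa * sl)
    core_pos = []
    while len(core_pos) < n_core:
        cand = rng.uniform(-1.0, 1.0, size=(max(16, 2 * n_core), 2))
        cand = cand[cand[:, 0] ** 2 + cand[:, 1] ** 2 <= 1.0]
        core_pos.extend(cand.tolist())
    core_pos = np.asarray(core_pos[:n_core]).reshape(n_core, 2)
    core_xy = np.column_stack(
        [center_mm[0] + core_pos[:, 0] * sa, center_mm[1] + core_pos[:, 1] * sl]
    )
    core_xy[:, 0] = np.clip(core_xy[:, 0], geom.depth_start_mm, geom.depth_end_mm)
    core_xy[:, 1] = np.clip(core_xy[:, 1], 0.0, geom.width_mm)

    positions = np.vstack([bg_pos, core_xy])
    radii = np.concatenate(
        [np.full(len(bg_pos), config.background_radius_um), np.full(n_core, radius_um)]
    )
    return ScattererField(positions=positions, effective_radius_um=radii)


def generate_cohort(config: CohortConfig, seed: int) -> SyntheticCohort:
    """Generate a labelled synthetic cohort with stored ground truth.

    Each patient draws a core scatterer radius and number density from their
    class distribution; every image plane re-draws scatterer positions (new
    speckle) around a jittered tumour centre while the patient-level truth is
    held fixed.  ROI masks carry the elliptical core and a 5 mm dilation ring.
    """
    from .parametric_maps import ROIMask  # deferred: ROIMask lives with the maps

    ss = np.random.SeedSequence(seed)
    labels = ["NR"] * config.n_nr + ["RR"] * config.n_rr
    patients: list[PatientRecord] = []
    for idx, (label, child) in enumerate(zip(labels, ss.spawn(len(labels)))):
        rng = np.random.default_rng(child)
        cls = config.nr_core if label == "NR" else config.rr_core
        radius = max(5.0, rng.normal(cls.radius_mean_um, cls.radius_sd_um))
        density = max(0.5, rng.normal(cls.density_mean_per_mm2, cls.density_sd_per_mm2))
        lo, hi = config.frames_per_patient
        n_frames = int(rng.integers(lo, hi + 1))
        center = (
            config.tumor_center_mm[0] + rng.uniform(-1, 1) * config.center_jitter_mm,
            config.tumor_center_mm[1] + rng.uniform(-1, 1) * config.center_jitter_mm,
        )
        frames, rois = [], []
        for _ in range(n_frames):
            fieldspec = _tumor_field(config, center, radius, density, rng)
            frame = simulate_rf_frame(
                fieldspec,
                config.pulse,
                config.sample_attenuation_db_mhz_cm,
                config.geometry,
                seed=int(rng.integers(0, 2**31 - 1)),
                snr_db=config.snr_db,
            )
            core = _elliptical_core_mask(frame, center, config.tumor_semiaxes_mm)
            margin = _margin_ring(
                core, (frame.axial_spacing_mm, frame.lateral_spacing_mm), config.margin_mm
            )
            rois.append(
                ROIMask(
                    core=core,
                    margin=margin,
                    axial_spacing_mm=frame.axial_spacing_mm,
                    lateral_spacing_mm=frame.lateral_spacing_mm,
                    depth_offset_mm=frame.depth_offset_mm,
                )
            )
            frames.append(frame)
        patients.append(
            PatientRecord(
                patient_id=f"P{idx:03d}",
                label=label,
                frames=frames,
                rois=rois,
                truth={"core_radius_um": radius, "core_density_per_mm2": density},
            )
        )
    return SyntheticCohort(patients=patients, config=config, seed=seed)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_cohort(cohort: SyntheticCohort, h5_path, manifest_csv=None) -> None:
    """Write a cohort to HDF5 (frames + masks) and optionally a CSV manifest."""
    with h5py.File(h5_path, "w") as f:
        f.attrs["seed"] = cohort.seed
        f.attrs["n_patients"] = len(cohort)
        for p in cohort.patients:
            g = f.create_group(p.patient_id)
            g.attrs["label"] = p.label
            for k, v in p.truth.items():
                g.attrs[k] = v
            for i, (frame, roi) in enumerate(zip(p.frames, p.rois)):
                fg = g.create_group(f"frame{i}")
                fg.create_dataset("rf", data=frame.samples, compression="gzip")
                fg.create_dataset("core", data=roi.core.astype(np.uint8), compression="gzip")
                fg.create_dataset("margin", data=roi.margin.astype(np.uint8), compression="gzip")
                fg.attrs["axial_spacing_mm"] = frame.axial_spacing_mm
                fg.attrs["lateral_spacing_mm"] = frame.lateral_spacing_mm
                fg.attrs["depth_offset_mm"] = frame.depth_offset_mm
    if manifest_csv is not None:
        cohort.manifest().to_csv(manifest_csv, index=False)


def load_cohort(h5_path, config: CohortConfig | None = None) -> SyntheticCohort:
    """Read a cohort written by :func:`save_cohort`."""
    from .parametric_maps import ROIMask

    config = config or CohortConfig()
    patients = []
    with h5py.File(h5_path, "r") as f:
        seed = int(f.attrs["seed"])
        for pid in sorted(f.keys()):
            g = f[pid]
            frames, rois = [], []
            for key in sorted(g.keys(), key=lambda s: int(s.removeprefix("frame"))):
                fg = g[key]
                frame = RFFrame(
                    samples=fg["rf"][()],
                    axial_spacing_mm=float(fg.attrs["axial_spacing_mm"]),
                    lateral_spacing_mm=float(fg.attrs["lateral_spacing_mm"]),
                    pulse=config.pulse,
                    depth_offset_mm=float(fg.attrs["depth_offset_mm"]),
                )
                frames.append(frame)
                rois.append(
                    ROIMask(
                        core=fg["core"][()].astype(bool),
                        margin=fg["margin"][()].astype(bool),
                        axial_spacing_mm=frame.axial_spacing_mm,
                        lateral_spacing_mm=frame.lateral_spacing_mm,
                        depth_offset_mm=frame.depth_offset_mm,
                    )
                )
            truth = {
                k: float(v) for k, v in g.attrs.items() if k not in ("label",)
            }
            patients.append(
                PatientRecord(
                    patient_id=pid,
                    label=str(g.attrs["label"]),
                    frames=frames,
                    rois=rois,
                    truth=truth,
                )
            )
    return SyntheticCohort(patients=patients, config=config, seed=seed)
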