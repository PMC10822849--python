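"""Sliding-window parametric imaging over the tumour ROI.

A square analysis window slides over the region of interest (tumour core
plus a 5 mm margin ring); each block runs the full spectral chain from
:mod:`qusresponse.qus_spectral` against a depth-matched reference-phantom
block, producing five co-registered parametric maps (MBF, SS, SI, ASD, AAC).
Maps are then cropped to the ROI, zeroed outside it, min-max scaled and
bilinearly resized to 224 x 224 for the convolutional feature extractor.

Coordinate convention: axial = rows, lateral = columns, 0-based; block
centres are physical millimetres measured from the transducer face.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .errors import InsufficientSupportError, QUSError, ValidationError
from .qus_spectral import (
    BSCCurve,
    block_power_spectrum,
    estimate_bsc,
    fit_gaussian_form_factor,
    fit_spectral_params,
    normalize_spectrum,
)
from .synthetic_rf import PhantomSpec, PulseSpec, analytic_bsc

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_rf import RFFrame

__all__ = [
    "ROIMask",
    "WindowPlan",
    "ParametricMap",
    "MapImage",
    "QUSMapConfig",
    "PARAMETERS",
    "plan_windows",
    "build_maps",
    "render_map_image",
]

PARAMETERS = ("MBF", "SS", "SI", "ASD", "AAC")


@dataclass
class ROIMask:
    """Tumour core and 5 mm margin ring on the RF raster (axial x lateral)."""

    core: np.ndarray
    margin: np.ndarray
    axial_spacing_mm: float
    lateral_spacing_mm: float
    depth_offset_mm: float = 0.0

    def __post_init__(self) -> None:
        self.core = np.asarray(self.core, dtype=bool)
        self.margin = np.asarray(self.margin, dtype=bool)
        if self.core.shape != self.margin.shape:
            raise ValidationError("core and margin rasters differ in shape")
        if np.any(self.core & self.margin):
            raise ValidationError("core and margin must be disjoint")

    @property
    def combined(self) -> np.ndarray:
        return self.core | self.margin

    def contains_mm(self, axial_mm: float, lateral_mm: float) -> bool:
        r = int(round((axial_mm - self.depth_offset_mm) / self.axial_spacing_mm))
        c = int(round(lateral_mm / self.lateral_spacing_mm))
        if 0 <= r < self.core.shape[0] and 0 <= c < self.core.shape[1]:
            return bool(self.combined[r, c])
        return False


@dataclass
class WindowPlan:
    """Block geometry: candidate centre grid and the in-ROI inclusion mask."""

    block_side_mm: float
    step_mm: float
    axial_centers_mm: np.ndarray
    lateral_centers_mm: np.ndarray
    inclusion: np.ndarray  # (n_axial, n_lateral) bool: centre inside combined ROI

    @property
    def centers(self) -> list[tuple[float, float]]:
        """In-ROI block centres, row-major and axial-major."""
        out = []
        for i, a in enumerate(self.axial_centers_mm):
            for j, l in enumerate(self.lateral_centers_mm):
                if self.inclusion[i, j]:
                    out.append((float(a), float(l)))
        return out

    @property
    def n_blocks(self) -> int:
        return int(self.inclusion.sum())


@dataclass
class ParametricMap:
    """One QUS parameter sampled on the window plan's centre grid."""

    parameter: str
    values: np.ndarray  # (n_axial, n_lateral), NaN where invalid
    valid: np.ndarray  # bool, same shape
    plan: WindowPlan

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise ValidationError(f"unknown parameter {self.parameter!r}")
        if self.values.shape != self.valid.shape or self.values.shape != self.plan.inclusion.shape:
            raise ValidationError("map grids must match the window plan")

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-block export (block_id, axial/lateral mm, value, valid)."""
        rows = []
        bid = 0
        for i, a in enumerate(self.plan.axial_centers_mm):
            for j, l in enumerate(self.plan.lateral_centers_mm):
                if not self.plan.inclusion[i, j]:
                    continue
                rows.append(
                    {
                        "block_id": bid,
                        "axial_mm": float(a),
                        "lateral_mm": float(l),
                        "parameter": self.parameter,
                        "value": float(self.values[i, j]),
                        "valid": bool(self.valid[i, j]),
                    }
                )
                bid += 1
        return pd.DataFrame(rows)


@dataclass
class MapImage:
    """224 x 224 rendering of a parametric map for the feature extractor."""

    pixels: np.ndarray  # (224, 224), float in [0, 1]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (224, 224):
            raise ValidationError(f"map image must be 224x224, got {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("map image must be finite")

    def to_3channel(self) -> np.ndarray:
        return np.repeat(self.pixels[:, :, None], 3, axis=2)


@dataclass
class QUSMapConfig:
    """Everything the per-block spectral chain needs to know."""

    alpha_sample_db_mhz_cm: float = 1.0
    phantom: PhantomSpec = PhantomSpec()
    block_side_mm: float = 2.2  # explicit side wins over the 10-wavelength rule
    overlap: float = 0.94
    max_invalid_fraction: float = 0.5
    #: "full": reference spectra average all phantom lines at the block's
    #: axial gate (lowest-variance, the default); "matched": use the same
    #: lateral gate as the sample block, so a frame normalized against
    #: itself yields exactly-zero spectra block by block.
    reference_gating: str = "full"


def plan_windows(
    roi: ROIMask,
    pulse: PulseSpec,
    sound_speed: float = 1540.0,
    overlap: float = 0.94,
    block_side_mm: float | None = 2.2,
) -> WindowPlan:
    """Lay out sliding analysis windows over the combined ROI.

    The block side defaults to an explicit 2.2 mm; pass ``block_side_mm=None``
    to use ten ultrasonic wavelengths (``10 c / fc``) instead — the two
    prescriptions differ (10 wavelengths at 6 MHz and 1540 m/s is about
    2.57 mm) and both are supported.  ``step = (1 - overlap) * side``.
    """
    if not (0.0 <= overlap < 1.0):
        raise ValidationError("overlap must lie in [0, 1)")
    combined = roi.combined
    if not combined.any():
        raise InsufficientSupportError("empty ROI")
    if block_side_mm is None:
        block_side_mm = 10.0 * sound_speed / (pulse.center_frequency * 1e6) * 1e3
    step = (1.0 - overlap) * block_side_mm

    rows = np.any(combined, axis=1).nonzero()[0]
    cols = np.any(combined, axis=0).nonzero()[0]
    ax_lo = roi.depth_offset_mm + rows[0] * roi.axial_spacing_mm
    ax_hi = roi.depth_offset_mm + rows[-1] * roi.axial_spacing_mm
    lat_lo = cols[0] * roi.lateral_spacing_mm
    lat_hi = cols[-1] * roi.lateral_spacing_mm
    if ax_hi - ax_lo < block_side_mm or lat_hi - lat_lo < block_side_mm:
        raise InsufficientSupportError("ROI smaller than one analysis block")

    half = block_side_mm / 2.0
    axial = np.arange(ax_lo + half, ax_hi - half + 1e-9, step)
    lateral = np.arange(lat_lo + half, lat_hi - half + 1e-9, step)
    inclusion = np.zeros((axial.size, lateral.size), dtype=bool)
    for i, a in enumerate(axial):
        for j, l in enumerate(lateral):
            inclusion[i, j] = roi.contains_mm(a, l)
    if not inclusion.any():
        raise InsufficientSupportError("no block centre falls inside the ROI")
    return WindowPlan(
        block_side_mm=float(block_side_mm),
        step_mm=float(step),
        axial_centers_mm=axial,
        lateral_centers_mm=lateral,
        inclusion=inclusion,
    )


def _block_slices(
    frame: "RFFrame", center_ax_mm: float, center_lat_mm: float, side_mm: float
) -> tuple[slice, slice]:
    half = side_mm / 2.0
    s0 = int(round((center_ax_mm - half - frame.depth_offset_mm) / frame.axial_spacing_mm))
    s1 = int(round((center_ax_mm + half - frame.depth_offset_mm) / frame.axial_spacing_mm))
    l0 = int(round((center_lat_mm - half) / frame.lateral_spacing_mm))
    l1 = int(round((center_lat_mm + half) / frame.lateral_spacing_mm))
    s0, s1 = max(s0, 0), min(s1, frame.n_samples)
    l0, l1 = max(l0, 0), min(l1, frame.n_lines)
    return slice(s0, s1), slice(l0, l1)


def build_maps(
    frame: "RFFrame",
    reference: "RFFrame",
    roi: ROIMask,
    plan: WindowPlan,
    config: QUSMapConfig | None = None,
) -> dict[str, ParametricMap]:
    """Run the spectral chain in every window; return the five maps.

    Reference spectra are computed over the same axial gates as the sample
    blocks (depth-matched) and cached per axial row.  Per-block failures are
    recorded in the validity mask; the whole call aborts only when more than
    ``max_invalid_fraction`` of blocks fail.
    """
    config = config or QUSMapConfig()
    if frame.samples.shape != reference.samples.shape:
        raise ValidationError("sample and reference frames must share geometry")
    pulse = frame.pulse
    shape = plan.inclusion.shape
    grids = {p: np.full(shape, np.nan) for p in PARAMETERS}
    valid = np.zeros(shape, dtype=bool)

    ref_cache: dict[tuple[int, int], object] = {}
    ref_bsc_cache: dict[int, BSCCurve] = {}
    n_total, n_failed = plan.n_blocks, 0
    for i, a_mm in enumerate(plan.axial_centers_mm):
        for j, l_mm in enumerate(plan.lateral_centers_mm):
            if not plan.inclusion[i, j]:
                continue
            srow, scol = _block_slices(frame, a_mm, l_mm, plan.block_side_mm)
            depth_cm = a_mm / 10.0
            try:
                sample_ps = block_power_spectrum(
                    frame.samples[scol, srow], pulse, block_depth_cm=depth_cm
                )
                key = (srow.start, srow.stop)
                if config.reference_gating == "matched":
                    key = (srow.start, srow.stop, scol.start, scol.stop)
                if key not in ref_cache:
                    # average the phantom over all lines at this gate: the
                    # phantom is homogeneous, so this is the best reference
                    ref_lines = (
                        reference.samples[scol, srow]
                        if config.reference_gating == "matched"
                        else reference.samples[:, srow]
                    )
                    ref_ps = block_power_spectrum(ref_lines, pulse, block_depth_cm=depth_cm)
                    # the time-matched phantom gate sits at a slightly
                    # different physical depth (sound-speed ratio); fold the
                    # phantom attenuation over that depth difference into the
                    # reference so the shared-depth compensation is exact
                    scale = config.phantom.sound_speed / pulse.sound_speed
                    ref_ps.values_db = ref_ps.values_db + 4.0 * config.phantom.attenuation_db_mhz_cm * ref_ps.frequencies_mhz * (scale - 1.0) * depth_cm
                    ref_cache[key] = ref_ps
                ref_ps = ref_cache[key]
                nps = normalize_spectrum(
                    sample_ps,
                    ref_ps,
                    depth_cm,
                    config.alpha_sample_db_mhz_cm,
                    config.phantom.attenuation_db_mhz_cm,
                )
                sp = fit_spectral_params(nps, pulse)
                if key[0] not in ref_bsc_cache:
                    ref_bsc_cache[key[0]] = BSCCurve(
                        nps.frequencies_mhz,
                        analytic_bsc(
                            nps.frequencies_mhz,
                            config.phantom.bead_radius_um,
                            config.phantom.bead_density_per_mm2,
                            sound_speed=config.phantom.sound_speed,
                            center_frequency_mhz=pulse.center_frequency,
                        ),
                    )
                bsc = estimate_bsc(nps, ref_bsc_cache[key[0]])
                scat = fit_gaussian_form_factor(
                    bsc, pulse.sound_speed, band_mhz=(pulse.band_low, pulse.band_high)
                )
            except QUSError:
                n_failed += 1
                continue
            grids["MBF"][i, j] = sp.mbf_db
            grids["SS"][i, j] = sp.ss_db_per_mhz
            grids["SI"][i, j] = sp.si_db
            grids["ASD"][i, j] = scat.asd_um
            grids["AAC"][i, j] = scat.aac_db
            valid[i, j] = True

    if n_failed > config.max_invalid_fraction * n_total:
        raise InsufficientSupportError(
            f"{n_failed}/{n_total} analysis blocks failed — frame unusable"
        )
    return {p: ParametricMap(p, grids[p], valid.copy(), plan) for p in PARAMETERS}


def render_map_image(pmap: ParametricMap, roi: ROIMask, provenance: dict | None = None) -> MapImage:
    """Crop, scale and resize one parametric map to a 224 x 224 image.

    The map grid is cropped to the tight bounding box of in-ROI centres and
    valid values are min-max scaled to [0, 1] (a constant map maps to 1).
    In-ROI blocks whose fit failed are inpainted with the median of the
    valid values — rendering them as holes would imprint the failure
    pattern on the image — while out-of-ROI cells are 0.  The raster is
    bilinearly resized to 224 x 224; pixels with no in-ROI support stay
    exactly 0.
    """
    mask = pmap.valid & pmap.plan.inclusion
    if not mask.any():
        raise ValidationError("cannot render a map with no valid block")
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    box = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    sub = pmap.values[box]
    submask = mask[box]
    inroi = pmap.plan.inclusion[box]

    vals = sub[submask]
    vmin, vmax = float(vals.min()), float(vals.max())
    scaled = np.zeros_like(sub, dtype=float)
    if vmax > vmin:
        scaled[submask] = (sub[submask] - vmin) / (vmax - vmin)
        scaled[inroi & ~submask] = float(
            (np.median(vals) - vmin) / (vmax - vmin)
        )
    else:
        scaled[inroi] = 1.0

    out = _sk_resize(scaled, (224, 224), order=1, mode="edge", anti_aliasing=False)
    support = _sk_resize(inroi.astype(float), (224, 224), order=1, mode="edge", anti_aliasing=False)
    out[support <= 0.0] = 0.0
    out = np.clip(out, 0.0, 1.0)
    return MapImage(pixels=out, provenance=provenance or {})
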