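import numpy as np
import pytest

import qusresponse as q


@pytest.fixture(scope="session")
def pulse():
    return q.PulseSpec()


@pytest.fixture(scope="session")
def phantom():
    return q.PhantomSpec()


@pytest.fixture(scope="session")
def small_geometry():
    # compact frame: 6 mm wide, 12 mm deep — enough for a few dozen blocks
    return q.FrameGeometry(n_lines=60, line_pitch_mm=0.1, depth_start_mm=8.0, depth_end_mm=20.0)


@pytest.fixture(scope="session")
def reference_frame(phantom, pulse, small_geometry):
    return q.make_reference_frame(phantom, pulse, small_geometry, seed=101)


@pytest.fixture(scope="session")
def homogeneous_frame(pulse, small_geometry):
    """Speckle frame from a homogeneous 28 um / 8 mm^-2 field, alpha = 1."""
    rng = np.random.default_rng(5)
    fieldspec = q.homogeneous_field(small_geometry, 8.0, 28.0, 1.0, rng)
    return q.simulate_rf_frame(fieldspec, pulse, 1.0, small_geometry, seed=6, snr_db=30)


@pytest.fixture(scope="session")
def full_roi(homogeneous_frame):
    """Whole-frame ROI (all core, no margin)."""
    core = np.ones((homogeneous_frame.n_samples, homogeneous_frame.n_lines), dtype=bool)
    return q.ROIMask(
        core=core,
        margin=np.zeros_like(core),
        axial_spacing_mm=homogeneous_frame.axial_spacing_mm,
        lateral_spacing_mm=homogeneous_frame.lateral_spacing_mm,
        depth_offset_mm=homogeneous_frame.depth_offset_mm,
    )


@pytest.fixture(scope="session")
def homogeneous_maps(homogeneous_frame, reference_frame, full_roi, pulse):
    plan = q.plan_windows(full_roi, pulse, pulse.sound_speed, overlap=0.5)
    config = q.QUSMapConfig(alpha_sample_db_mhz_cm=1.0, overlap=0.5, max_invalid_fraction=0.8)
    return q.build_maps(homogeneous_frame, reference_frame, full_roi, plan, config)


@pytest.fixture(scope="session")
def backbone():
    return q.RandomConvBackbone()


@pytest.fixture(scope="session")
def tiny_cohort():
    cfg = q.CohortConfig(n_nr=2, n_rr=2, frames_per_patient=(2, 2))
    return q.generate_cohort(cfg, seed=9)
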