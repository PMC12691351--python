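import numpy as np
import pytest
from shapely.geometry import box

from qusrad.config import FormFactorConfig, SpectralConfig
from qusrad.phantom import (
    AcquisitionGeometry,
    PhantomSpec,
    RegionAcoustics,
    ROISet,
    generate_reference_frames,
    generate_scatterer_field,
    synthesize_rf_frame,
)
from qusrad.spectral import build_parametric_maps, reference_spectrum


@pytest.fixture(scope="session")
def acq():
    """Small acquisition used throughout: 20 x 20 mm plane."""
    return AcquisitionGeometry(depth_mm=20.0, width_mm=20.0)


@pytest.fixture(scope="session")
def spectral_cfg():
    return SpectralConfig()


@pytest.fixture(scope="session")
def ff_cfg():
    return FormFactorConfig()


@pytest.fixture(scope="session")
def reference(acq, spectral_cfg):
    frames, meta = generate_reference_frames(acq, n_frames=3, seed=5)
    return reference_spectrum(frames, meta, spectral_cfg)


@pytest.fixture(scope="session")
def square_roi():
    """8 x 8 mm square core centered in the 20 mm frame."""
    return ROISet(core=box(6.0, 6.0, 14.0, 14.0))


def homogeneous_frame(acq, asd_um=80.0, aac_db=3.0, alpha=0.0, seed=11):
    spec = PhantomSpec(
        regions={"background": RegionAcoustics(asd_um / 2, aac_db)},
        attenuation_db_cm_mhz=alpha,
        seed=seed,
    )
    field = generate_scatterer_field(
        spec, None, (acq.depth_mm, acq.width_mm), seed=seed
    )
    return synthesize_rf_frame(field, spec, acq, seed=seed + 1)


@pytest.fixture(scope="session")
def homogeneous_maps(acq, square_roi, reference, spectral_cfg, ff_cfg):
    frame = homogeneous_frame(acq)
    return build_parametric_maps(
        frame, square_roi, reference, spectral_cfg, ff_cfg
    )
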