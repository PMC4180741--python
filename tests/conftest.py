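import numpy as np
import pytest

from scatterkit import synthgen
from scatterkit.geometry import ExperimentGeometry, build_qmap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def saxs_geom():
    """Transmission geometry, beam centered on a 64x64 detector."""
    return ExperimentGeometry(wavelength=0.1, distance=500.0,
                              beam_center=(31.5, 31.5), pixel_size=(1.0, 1.0))


@pytest.fixture
def gisaxs_geom():
    """Grazing geometry, direct beam bottom-center of a 64x80 detector."""
    return ExperimentGeometry(wavelength=0.096, distance=2750.0,
                              beam_center=(39.5, 63.0), pixel_size=(0.172, 0.172),
                              incidence=0.5, mode="grazing")


@pytest.fixture
def random_frame(rng):
    """Seeded random frame with a sprinkling of masked pixels."""
    from scatterkit.image_io import Frame

    data = rng.integers(0, 1000, size=(64, 64)).astype(float)
    mask = (rng.random((64, 64)) < 0.05).astype(np.uint8)
    return Frame(data=data, mask=mask)


@pytest.fixture
def sphere_frame_truth():
    """Polydisperse-sphere pattern on the default synthetic geometry."""
    geom = synthgen.default_saxs_geometry((128, 128))
    spec = synthgen.SynthSpec(kind="isotropic_spheres", geometry=geom,
                              shape=(128, 128), seed=7, flux=1e3)
    frame, truth = synthgen.sphere_pattern(spec, r_mean=2.0, poly=0.1)
    return frame, truth, geom


@pytest.fixture
def aniso_frame_truth():
    geom = synthgen.default_saxs_geometry((128, 128))
    spec = synthgen.SynthSpec(kind="anisotropic", geometry=geom,
                              shape=(128, 128), seed=11, flux=1e3)
    frame, truth = synthgen.anisotropic_pattern(spec, chi0=40.0, amplitude=5.0,
                                                fwhm=40.0, q_peak=3.0, q_width=1.5)
    return frame, truth, geom
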