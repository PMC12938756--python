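import numpy as np
import pytest

from neotrs import (
    CohortConfig,
    ExtinctionTable,
    InstrumentResponse,
    OpticalProperties,
    ProbeGeometry,
    TimeAxis,
    TimeHistogram,
    convolve_with_irf,
    diffusion_reflectance,
)
from neotrs.cohort import make_irf


@pytest.fixture(scope="session")
def axis():
    return TimeAxis.regular(1000, 10.0)


@pytest.fixture(scope="session")
def geometry():
    return ProbeGeometry(rho_mm=30.0, n_tissue=1.4)


@pytest.fixture(scope="session")
def irf(axis):
    return make_irf(axis, fwhm_ps=150.0, t0_ps=300.0, area=1e6,
                    total_incident=1e12, acquisition_s=300.0)


@pytest.fixture(scope="session")
def extinction():
    return ExtinctionTable.default()


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort configuration for end-to-end tests."""
    return CohortConfig(n_subjects=4, counts_per_wavelength=2e5,
                        n_segments=5, seed=7)


def expected_histogram(optics, geometry, axis, irf, total_counts,
                       acquisition_s=300.0):
    """Noise-free forward-generated histogram scaled to a photon budget."""
    tpsf = diffusion_reflectance(optics, geometry, axis)
    conv = convolve_with_irf(
        tpsf, InstrumentResponse(axis, irf.counts / irf.counts.sum()))
    values = conv.values * (total_counts / conv.values.sum())
    return TimeHistogram(axis, values, acquisition_s,
                         wavelength_nm=optics.wavelength_nm)


@pytest.fixture(scope="session")
def make_expected():
    return expected_histogram
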