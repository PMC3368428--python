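"""Shared fixtures: small but physically sensible simulation objects.

Monte Carlo sizes here are chosen for test runtime; the acceptance
suite re-runs the expensive checks at the sizes quoted in the docs.
"""

import numpy as np
import pytest

import oisbold as ob
from oisbold.spectroscopy import baseline_concentrations
from oisbold.synthetic_data import (default_light_mua_grid, default_regions,
                                    generate_haemodynamics, make_paradigm,
                                    render_wavelength_stack)


@pytest.fixture(scope="session")
def optics():
    return ob.OpticalConstants()


@pytest.fixture(scope="session")
def tissue_hom():
    return ob.TissueModel.homogeneous()


@pytest.fixture(scope="session")
def tissue_het():
    return ob.TissueModel.heterogeneous()


@pytest.fixture(scope="session")
def light_lut_hom(tissue_hom, optics):
    return ob.build_lut(tissue_hom, optics, default_light_mua_grid(),
                        n_photons=20_000, seed=101)


@pytest.fixture(scope="session")
def light_lut_het(tissue_het, optics):
    return ob.build_lut(tissue_het, optics, default_light_mua_grid(),
                        n_photons=20_000, seed=102)


@pytest.fixture(scope="session")
def baseline_hom(tissue_hom, optics):
    return baseline_concentrations(tissue_hom, optics)


@pytest.fixture(scope="session")
def baseline_het(tissue_het, optics):
    return baseline_concentrations(tissue_het, optics)


@pytest.fixture(scope="session")
def paradigm():
    return make_paradigm()


@pytest.fixture(scope="session")
def small_field(paradigm):
    return generate_haemodynamics(paradigm, default_regions(24), grid=24)


@pytest.fixture(scope="session")
def small_stack(small_field, tissue_hom, light_lut_hom, optics):
    return render_wavelength_stack(small_field, tissue_hom, light_lut_hom,
                                   optics, noise_sd=0.0)


@pytest.fixture(scope="session")
def mr_small():
    return ob.MRSimConfig(n_protons=2000, n_geometries=4)


@pytest.fixture(scope="session")
def bold_lut_small(mr_small):
    return ob.build_bold_lut(mr_small, v_grid=np.linspace(0.03, 0.10, 8),
                             y_grid=np.linspace(0.2, 0.95, 16), seed=7)
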