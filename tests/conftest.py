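import numpy as np
import pytest

from implumen import phantoms, photon_transport as pt, spectra


@pytest.fixture(scope="session")
def spectrum():
    return spectra.load_spectra()


@pytest.fixture()
def phantom2d():
    return phantoms.make_phantom_2d()


@pytest.fixture()
def source660():
    return pt.SourceSpec(lambda_nm=660.0)


@pytest.fixture()
def absorbing_slab():
    """Single absorption-only slab with unit optical depth (mua * L = 1)."""

    def _make(mua_per_m=1000.0, thickness_mm=1.0, mus_per_m=0.0, n=1.0):
        layer = spectra.TissueOpticalProps(
            name="slab",
            refractive_index=n,
            mua=mua_per_m,
            mus=mus_per_m,
            thickness=thickness_mm,
        )
        return pt.LayeredPhantom2D(
            layers=(layer,), vessel_diameter_mm=0.0, width_mm=500.0, ambient_index=n
        )

    return _make


@pytest.fixture()
def normal_source():
    """Pencil beam at normal incidence (no refraction, no array spread)."""
    return pt.SourceSpec(
        lambda_nm=660.0, n_sources=1, source_diameter_mm=0.0, incidence_deg=0.0
    )
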