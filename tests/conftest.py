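import numpy as np
import pytest
from hypothesis import settings

from larvanet import (
    SyntheticOceanConfig,
    VelocityField,
    generate_field,
    load_mpa_registry,
    load_species_table,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_uniform_field(u0=0.0, v0=0.0, lon=(110.0, 135.0), lat=(15.0, 45.0),
                       spacing=0.5, depths=(5.0,), years=("2015", "2019")):
    """All-water field with constant (u0, v0); for analytic advection checks."""
    lon_ax = np.arange(lon[0], lon[1] + spacing / 2, spacing)
    lat_ax = np.arange(lat[0], lat[1] + spacing / 2, spacing)
    times = np.array([np.datetime64(y, "ns") for y in years])
    shape = (times.size, len(depths), lat_ax.size, lon_ax.size)
    return VelocityField(
        lon_axis=lon_ax, lat_axis=lat_ax,
        depth_axis=np.asarray(depths, float), time_axis=times,
        u=np.full(shape, float(u0)), v=np.full(shape, float(v0)),
        land_mask=np.zeros((lat_ax.size, lon_ax.size), bool),
    )


@pytest.fixture(scope="session")
def species_table():
    return load_species_table()


@pytest.fixture(scope="session")
def registry():
    return load_mpa_registry()


@pytest.fixture(scope="session")
def still_field():
    """Zero-velocity, noise-free synthetic field (default domain/coastline)."""
    return generate_field(SyntheticOceanConfig(core_speed_ms=0.0,
                                               noise_amplitude_ms=0.0))


@pytest.fixture(scope="session")
def default_field():
    """The default synthetic seasonal coastal-current field (seed 0)."""
    return generate_field(SyntheticOceanConfig())


@pytest.fixture(scope="session")
def jet_field():
    """Noise-free seasonal jet, for smooth-field reversibility checks."""
    return generate_field(SyntheticOceanConfig(noise_amplitude_ms=0.0))
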