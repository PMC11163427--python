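import numpy as np
import pytest

from stericfit.iqa_io import default_ionization_table
from stericfit.synthetic import AtomSpec, SyntheticSpec, default_carbonyl_atoms, generate_scan


@pytest.fixture(scope="session")
def ip_table():
    return default_ionization_table()


@pytest.fixture
def clean_spec():
    """One synthetic carbonyl with no charge transfer, dip or noise."""
    return SyntheticSpec(
        molecule_id="clean",
        atoms=default_carbonyl_atoms(),
        ct_amplitude=0.0,
        dip_amplitude=0.0,
        noise_sigma=0.0,
        seed=7,
    )


@pytest.fixture
def ct_spec():
    """Charge-transfer contamination only (q0=0.05 e, b_q=1.5 1/A), no noise."""
    return SyntheticSpec(
        molecule_id="ct",
        atoms=default_carbonyl_atoms(),
        ct_amplitude=0.05,
        ct_decay=1.5,
        dip_amplitude=0.0,
        noise_sigma=0.0,
        seed=7,
    )


@pytest.fixture
def dip_spec():
    """Polarization dip strong enough to push short-range deformation negative."""
    atoms = default_carbonyl_atoms()
    # pair deformation at r_min: A exp(-B*2) - P exp(-B_p*2) < 0 requires
    # P > A exp(-(B - B_p) * 2); with A=5e4, B=2.5, B_p=1.0 that is ~2490.
    return SyntheticSpec(
        molecule_id="dip",
        atoms=atoms,
        ct_amplitude=0.0,
        dip_amplitude=6000.0,
        dip_decay=1.0,
        noise_sigma=0.0,
        seed=7,
    )


@pytest.fixture
def clean_records(clean_spec, ip_table):
    return generate_scan(clean_spec, ip_table)


@pytest.fixture
def ct_records(ct_spec, ip_table):
    return generate_scan(ct_spec, ip_table)
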