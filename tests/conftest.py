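import numpy as np
import pytest

from specfp.kernels import KernelParams
from specfp.spectra import Peak, Spectrum
from specfp.synthetic import generate_toy_world


def random_spectrum(rng, n_peaks=5, with_precursor=True, spectrum_id=None):
    """A random but valid MS2 spectrum; precursor above every peak."""
    masses = np.sort(rng.uniform(60, 320, n_peaks))
    intens = rng.uniform(0.05, 1.0, n_peaks)
    return Spectrum(
        peaks=[Peak(float(m), float(i)) for m, i in zip(masses, intens)],
        precursor_mass=float(masses[-1] + rng.uniform(5, 60)) if with_precursor else None,
        spectrum_id=spectrum_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    return KernelParams(sigma_mass=0.01, sigma_intensity=0.05)


@pytest.fixture(scope="session")
def toy_world_small():
    return generate_toy_world(
        n_molecules=20, m_bits=10, seed=7, n_energies=2, mass_jitter_sd=0.002
    )


MASSBANK_FIXTURE = """\
ACCESSION: TOY000001
RECORD_TITLE: fixture record
CH$NAME: MOL-A
AC$INSTRUMENT_TYPE: LC-ESI-ITFT
AC$MASS_SPECTROMETRY: MS_TYPE MS2
AC$MASS_SPECTROMETRY: ION_MODE POSITIVE
MS$FOCUSED_ION: PRECURSOR_M/Z 182.0578
PK$NUM_PEAK: 3
PK$PEAK: m/z int. rel.int.
  100.05 12 12
  150.10 99 99
  181.07 50 50
//
"""


@pytest.fixture
def massbank_fixture_text():
    return MASSBANK_FIXTURE
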