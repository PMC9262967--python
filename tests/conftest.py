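import numpy as np
import pytest

from stageglyco import cf_calling, chem, proteo, search
from stageglyco.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def mods():
    return chem.default_modifications()


@pytest.fixture(scope="session")
def small_dataset():
    """A 30-protein simulated dataset, shared across tests that only read it."""
    return simulate_dataset(SimulationConfig(seed=11, n_proteins=30, n_plain_spectra=20))


@pytest.fixture(scope="session")
def small_search_results(small_dataset):
    """Search results + validated site calls on the small dataset."""
    ds = small_dataset
    psms = search.search_dataset(ds.proteins, ds.spectra)
    prot_map = {p.accession: p for p in ds.proteins}
    calls = cf_calling.validate_and_call(psms, None, prot_map)
    return ds, psms, calls


def make_spectrum(mz, intensity, spec_id="s1", precursor_mz=500.0, charge=2):
    from stageglyco.spectra_io import Spectrum

    return Spectrum(
        id=spec_id,
        precursor_mz=precursor_mz,
        charge=charge,
        mz=np.asarray(mz, dtype=float),
        intensity=np.asarray(intensity, dtype=float),
    )
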