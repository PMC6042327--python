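import numpy as np
import pytest

from dimerlab import confgen


@pytest.fixture(scope="session")
def arch():
    return confgen.sgta_like_architecture()


@pytest.fixture(scope="session")
def open_dimers(arch):
    """Small fixed-seed ensemble of open dimers shared across tests."""
    return [confgen.build_dimer(arch, False, 100 + i) for i in range(12)]


@pytest.fixture(scope="session")
def closed_dimers(arch):
    return [confgen.build_dimer(arch, True, 200 + i) for i in range(12)]


@pytest.fixture(scope="session")
def flexible_arch_50():
    """A 50-residue fully flexible chain architecture."""
    return confgen.DomainArchitecture(
        segments=(confgen.Segment("chain", 1, 50, "flexible"),),
        n_residues=50)


def make_bead_model(coords, weights=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return confgen.BeadModel(
        protomer_id=np.array(["A"] * n),
        residue_index=np.arange(1, n + 1),
        coords=coords,
        domain_label=np.array(["x"] * n),
        scattering_weight=weights)
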