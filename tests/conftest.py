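import numpy as np
import pytest

from mdbind.io import ConformationalEnsemble, Topology
from mdbind.synthetic import generate_ligand_system


def make_topology(n_atoms: int, atoms_per_residue: int = 1,
                  atom_name: str = "CA") -> Topology:
    res_ids = np.repeat(np.arange(1, n_atoms // atoms_per_residue + 1),
                        atoms_per_residue)[:n_atoms]
    return Topology(
        atom_names=[atom_name] * n_atoms,
        elements=["C"] * n_atoms,
        res_ids=res_ids,
        res_names=["GLY"] * n_atoms,
        chain_ids=["A"] * n_atoms,
    )


def make_ensemble(coords: np.ndarray, topology: Topology | None = None
                  ) -> ConformationalEnsemble:
    coords = np.asarray(coords, float)
    if topology is None:
        topology = make_topology(coords.shape[1])
    return ConformationalEnsemble(topology, coords)


@pytest.fixture(scope="session")
def toy_complex():
    """Deterministic toy ligand-receptor complex with parameters."""
    return generate_ligand_system(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
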