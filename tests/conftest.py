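"""Shared fixtures: toy two-basin systems and synthetic atomic structures."""

import numpy as np
import pytest

from dualbasin.energy import ForceFieldParams, TopologySystem
from dualbasin.fixtures import make_toy_complex, make_toy_two_basin


@pytest.fixture(scope="session")
def toy():
    return make_toy_two_basin(seed=1)


@pytest.fixture(scope="session")
def toy_complex():
    return make_toy_complex(seed=1)


@pytest.fixture(scope="session")
def nocut_params():
    """Force field with truncation disabled (closed-form comparisons)."""
    return ForceFieldParams(
        lj_cutoff_factor=None, excl_cutoff_factor=None, dh_cutoff_factor=None
    )


@pytest.fixture(scope="session")
def complex_system(toy_complex, nocut_params):
    return TopologySystem(toy_complex.topology, nocut_params)


# ---------------------------------------------------------------------------
# synthetic atomic structures (built programmatically, never read from disk)
# ---------------------------------------------------------------------------

_BACKBONE_OFFSETS = {
    "N": np.array([-1.2, 0.5, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.2, 0.5, 0.0]),
    "O": np.array([1.6, 1.6, 0.3]),
    "CB": np.array([0.0, -1.4, 0.6]),
}


def peptide_atoms(ca_positions, res_names=None, chain_id="A", res_start=1):
    """Synthetic all-backbone peptide with CA atoms at the given positions."""
    import biotite.structure as struc

    ca_positions = np.asarray(ca_positions, float)
    n_res = len(ca_positions)
    if res_names is None:
        cycle = ["ALA", "ARG", "GLY", "ASP", "SER", "LYS", "THR", "GLU"]
        res_names = [cycle[k % len(cycle)] for k in range(n_res)]
    names = list(_BACKBONE_OFFSETS)
    atoms = struc.AtomArray(n_res * len(names))
    coords, res_ids, rnames, anames, elements = [], [], [], [], []
    for k in range(n_res):
        for nm in names:
            coords.append(ca_positions[k] + _BACKBONE_OFFSETS[nm])
            res_ids.append(res_start + k)
            rnames.append(res_names[k])
            anames.append(nm)
            elements.append(nm[0])
    atoms.coord = np.array(coords)
    atoms.chain_id = np.full(len(coords), chain_id)
    atoms.res_id = np.array(res_ids)
    atoms.res_name = np.array(rnames)
    atoms.atom_name = np.array(anames)
    atoms.element = np.array(elements)
    atoms.hetero = np.zeros(len(coords), bool)
    return atoms


@pytest.fixture
def peptide_factory():
    return peptide_atoms
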