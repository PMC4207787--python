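import numpy as np
import pytest

from dimerstab.structio import Structure
from dimerstab.synth import SynthSpec, make_toy_dimer


def make_structure(coords, elements=None, chain_ids=None, res_seqs=None,
                   names=None, res_names=None):
    """Assemble a Structure from coordinate arrays with sensible defaults."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    return Structure(
        serials=np.arange(1, n + 1),
        names=np.array(names if names is not None else ["CA"] * n),
        elements=np.array(elements if elements is not None else ["C"] * n),
        chain_ids=np.array(chain_ids if chain_ids is not None else ["A"] * n),
        res_names=np.array(res_names if res_names is not None else ["ALA"] * n),
        res_seqs=np.array(res_seqs if res_seqs is not None
                          else np.arange(1, n + 1)),
        coords=coords,
        b_factors=np.zeros(n),
        hetero=np.zeros(n, dtype=bool),
    )


def shell_structure(side=10.0, spacing=1.2, wall=2, element="C",
                    offset=(0.0, 0.0, 0.0)):
    """Closed box of pseudo-atoms whose van der Waals surfaces bound an
    (analytically known) cubic void of the given side length."""
    r = 1.7
    n = int(np.ceil(side / spacing)) + 1
    grid = np.linspace(0, side, n)
    pts = []
    for axis in range(3):
        offs = ([-r - spacing * k for k in range(wall)]
                + [side + r + spacing * k for k in range(wall)])
        for off in offs:
            for a in grid:
                for b in grid:
                    p = [0.0, 0.0, 0.0]
                    p[axis] = off
                    p[(axis + 1) % 3] = a
                    p[(axis + 2) % 3] = b
                    pts.append(p)
    pts = np.array(pts) + np.asarray(offset)
    return make_structure(pts, elements=[element] * len(pts))


@pytest.fixture(scope="session")
def toy_dimer():
    return make_toy_dimer(SynthSpec(seed=1))


@pytest.fixture
def small_spec():
    """Desk-scale generator conditions for fast unit tests."""
    return SynthSpec(seed=7, n_snapshots=60, k_states=4, library_size=300,
                     n_binders=5, n_residues=30)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
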