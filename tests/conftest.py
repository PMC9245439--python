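import numpy as np
import pytest

from micellometrics import (MicelleSystem, SyntheticMicelleSpec,
                            generate_micelle)
from micellometrics.model import AtomSet


def make_atoms(coords, elements=None, roles=None, chains=None,
               resnames=None, resindices=None, masses=None, names=None,
               box=None) -> AtomSet:
    """Hand-build a small AtomSet with sensible defaults."""
    coords = np.atleast_2d(np.asarray(coords, float))
    n = len(coords)
    return AtomSet(
        coords=coords,
        masses=np.ones(n) if masses is None else np.asarray(masses, float),
        elements=np.array(["C"] * n if elements is None else elements),
        chain_ids=np.zeros(n, int) if chains is None else np.asarray(chains),
        residue_names=np.array(["DEC"] * n if resnames is None
                               else resnames),
        residue_indices=np.arange(n) if resindices is None
        else np.asarray(resindices),
        atom_roles=np.array(["sidechain"] * n if roles is None else roles),
        names=np.array(["SC"] * n if names is None else names),
        box=None if box is None else np.asarray(box, float),
    )


@pytest.fixture(scope="session")
def small_micelle() -> MicelleSystem:
    """A compact 6-chain micelle with a thin hydration shell (fast)."""
    spec = SyntheticMicelleSpec(
        n_chains=6, core_radius=1.0, corona_thickness=1.0,
        water_shell_thickness=0.35, na_condensation_fraction=0.5,
        n_frames=2, seed=11)
    return generate_micelle(spec)


@pytest.fixture(scope="session")
def default_micelle() -> MicelleSystem:
    """The default (largest singly charged) study system."""
    return generate_micelle(SyntheticMicelleSpec(seed=7))
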