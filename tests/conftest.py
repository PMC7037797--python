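import numpy as np
import pytest

from helixcm import HingeSpec, build_ideal_helix
from helixcm.energy import ForceFieldParams


@pytest.fixture(scope="session")
def params():
    return ForceFieldParams.default()


@pytest.fixture(scope="session")
def torsion_only_params():
    """Force field with all nonbonded terms zeroed: energy is purely the
    torsion series attached to the free dihedrals (analytic landscapes)."""
    return ForceFieldParams(
        partial_charges={},
        lj={"C": (0.0, 4.0), "N": (0.0, 3.6), "O": (0.0, 3.4), "S": (0.0, 4.0)},
        torsion_terms={"threefold": [(1.0, 3, 0.0)]},
        dielectric_model=("distance", 1.0),
    )


@pytest.fixture(scope="session")
def hinge_helix():
    """18-residue helix with an SGT helix-bending motif; hinge Thr at
    position 6 (0-based), leaving 11 residues downstream."""
    return build_ideal_helix("AAAASGTAAAAAAAAAAA")


@pytest.fixture(scope="session")
def hinge_spec(hinge_helix):
    return HingeSpec.for_hinge(hinge_helix, 6)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240725)
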