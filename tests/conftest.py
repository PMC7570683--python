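import numpy as np
import pytest

from cdftkit.fields import AtomSite
from cdftkit.synthetic import FixtureSpec, make_fukui_pair


@pytest.fixture(scope="session")
def two_atom_spec() -> FixtureSpec:
    """Two well-separated Gaussian atoms (8 sigma apart) on a 64^3 grid."""
    return FixtureSpec(
        atoms=(
            AtomSite("C", 6.0, (0.0, 0.0, 0.0)),
            AtomSite("N", 7.0, (4.0, 0.0, 0.0)),
        ),
        per_atom_masses=(5.0, 3.0),
        widths=(0.5, 0.5),
        grid_shape=(64, 64, 64),
    )


@pytest.fixture(scope="session")
def fukui_pair(two_atom_spec):
    """(rho_N, rho_N+1, analytic per-atom Fukui masses) with deltas (0.7, 0.3)."""
    return make_fukui_pair(two_atom_spec, (0.7, 0.3))


@pytest.fixture(scope="session")
def ones_field():
    """All-ones values on a 2x2x2 unit grid: integral must be 8."""
    from cdftkit.fields import ScalarField

    return ScalarField(
        origin=np.zeros(3),
        axes=np.eye(3),
        values=np.ones((2, 2, 2)),
        atoms=[AtomSite("H", 1.0, (0.5, 0.5, 0.5))],
        quantity="density",
    )
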