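"""Fukui/DD/Parr field algebra and atomic condensation against analytic oracles."""

import numpy as np
import pytest

from cdftkit.errors import GridMismatchError, InvariantError
from cdftkit.fields import AtomSite, ScalarField
from cdftkit.local_descriptors import (
    condense,
    dual_descriptor,
    fukui_minus,
    fukui_plus,
    fukui_zero,
    integrate,
    parr_dual,
    parr_functions,
)
from cdftkit.synthetic import FixtureSpec, make_density, make_fukui_pair, random_fixture_spec


def test_fukui_plus_integrates_to_one(fukui_pair):
    rho_n, rho_np1, _ = fukui_pair
    f = fukui_plus(rho_np1, rho_n)
    assert f.quantity == "fukui_plus"
    assert integrate(f) == pytest.approx(1.0, abs=1e-3)


def test_fukui_minus_integrates_to_one(fukui_pair):
    rho_n, rho_np1, _ = fukui_pair
    # reuse the pair with roles swapped: rho_np1 plays rho_N, rho_n plays rho_N-1
    f = fukui_minus(rho_np1, rho_n)
    assert f.quantity == "fukui_minus"
    assert integrate(f) == pytest.approx(1.0, abs=1e-3)


def test_identical_densities_give_zero_fukui(fukui_pair):
    rho_n, _, _ = fukui_pair
    assert np.all(fukui_plus(rho_n, rho_n).values == 0.0)


def test_constant_shift_cancels_in_fukui(fukui_pair):
    rho_n, rho_np1, _ = fukui_pair
    shifted_a = rho_np1.with_values(rho_np1.values + 0.25, "density")
    shifted_b = rho_n.with_values(rho_n.values + 0.25, "density")
    f0 = fukui_plus(rho_np1, rho_n)
    f1 = fukui_plus(shifted_a, shifted_b)
    assert np.allclose(f0.values, f1.values, atol=1e-12)


def test_fukui_zero_is_average_and_linear(fukui_pair):
    rho_n, rho_np1, _ = fukui_pair
    fp = fukui_plus(rho_np1, rho_n)
    fm = fukui_minus(rho_np1, rho_n)
    f0 = fukui_zero(fp, fm)
    assert np.allclose(f0.values, fp.values)  # f+ == f- here
    assert integrate(f0) == pytest.approx((integrate(fp) + integrate(fm)) / 2, abs=1e-10)
    ch = {v.quantity: v for v in (condense(fp), condense(fm), condense(f0))}
    mean = [(a + b) / 2 for a, b in zip(ch["fukui_plus"].values, ch["fukui_minus"].values)]
    assert ch["fukui_zero"].values == pytest.approx(mean, abs=1e-10)


def test_dual_descriptor_sign_pattern_and_zero_integral():
    """f- mass on the donor atom, f+ mass on the acceptor: DD>0 on acceptor."""
    atoms = (AtomSite("C", 6.0, (0.0, 0.0, 0.0)), AtomSite("O", 8.0, (5.0, 0.0, 0.0)))
    base = FixtureSpec(atoms=atoms, per_atom_masses=(4.0, 4.0), widths=(0.5, 0.5),
                       grid_shape=(64, 64, 64))
    rho_n, rho_np1, _ = make_fukui_pair(base, (0.0, 1.0))   # acceptor = atom 2
    _, rho_nm1_hi, _ = make_fukui_pair(base, (1.0, 0.0))    # donor = atom 1
    # rho_N-1 = rho_N - donor electron: build by subtracting the delta field
    rho_nm1 = rho_n.with_values(2 * rho_n.values - rho_nm1_hi.values, "density")
    fp = fukui_plus(rho_np1, rho_n)
    fm = fukui_minus(rho_n, rho_nm1)
    dd = dual_descriptor(fp, fm)
    assert dd.quantity == "dual"
    assert integrate(dd) == pytest.approx(0.0, abs=2e-3)
    cv = condense(dd)
    assert cv.values[0] < 0 < cv.values[1]


def test_dual_descriptor_of_equal_fukuis_vanishes(fukui_pair):
    rho_n, rho_np1, _ = fukui_pair
    fp = fukui_plus(rho_np1, rho_n)
    assert np.all(dual_descriptor(fp, fp).values == 0.0)


def test_grid_mismatch_is_rejected(fukui_pair, ones_field):
    rho_n, _, _ = fukui_pair
    with pytest.raises(GridMismatchError):
        fukui_plus(rho_n, ones_field)


def test_parr_functions_diagnostics_and_tags():
    spec = FixtureSpec(
        atoms=(AtomSite("C", 6.0, (0.0, 0.0, 0.0)),),
        per_atom_masses=(1.0,),
        widths=(0.5,),
        grid_shape=(48, 48, 48),
    )
    spin = make_density(spec, quantity="spin_density")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("error")  # a clean doublet must not warn
        p_plus, p_minus = parr_functions(spin, spin)
    assert p_plus.quantity == "parr_plus"
    assert p_minus.quantity == "parr_minus"
    assert integrate(p_plus) == pytest.approx(1.0, abs=1e-3)
    cv = condense(p_plus)
    assert cv.values[0] == pytest.approx(1.0, abs=1e-3)


def test_all_zero_spin_field_warns_but_returns():
    f = ScalarField(np.zeros(3), np.eye(3), np.zeros((4, 4, 4)),
                    atoms=[AtomSite("H", 1.0, (0, 0, 0))], quantity="spin_density")
    with pytest.warns(UserWarning, match="integrates to 0"):
        p_plus, p_minus = parr_functions(f, f)
    assert np.all(p_plus.values == 0.0)


def test_parr_dual_linearity_and_zero_case():
    spec = random_fixture_spec(7, grid_shape=(48, 48, 48))
    spin = make_density(spec, quantity="spin_density")
    pd = parr_dual(spin.with_values(spin.values, "parr_plus"),
                   spin.with_values(spin.values, "parr_minus"))
    assert np.all(pd.values == 0.0)
    other = make_density(random_fixture_spec(7, grid_shape=(48, 48, 48)))
    pd2 = parr_dual(spin.with_values(2 * spin.values, "parr_plus"),
                    spin.with_values(other.values, "parr_minus"))
    assert integrate(pd2) == pytest.approx(2 * integrate(spin) - integrate(other), abs=1e-10)


def test_parr_dual_sign_pattern_matches_dd_on_matched_fixture():
    """Cation spin on the donor atom, anion spin on the acceptor atom: the
    condensed Parr-difference descriptor and the condensed DD of the matched
    Fukui fixture mark the same sites with the same signs."""
    atoms = (AtomSite("C", 6.0, (0.0, 0.0, 0.0)), AtomSite("O", 8.0, (5.0, 0.0, 0.0)))
    widths = (0.5, 0.5)
    spin_cation = make_density(
        FixtureSpec(atoms=atoms, per_atom_masses=(1.0, 0.0), widths=widths,
                    grid_shape=(64, 64, 64), padding=2.0), quantity="spin_density"
    )
    spin_anion = make_density(
        FixtureSpec(atoms=atoms, per_atom_masses=(0.0, 1.0), widths=widths,
                    grid_shape=(64, 64, 64), padding=2.0), quantity="spin_density"
    )
    p_plus, p_minus = parr_functions(spin_cation, spin_anion)
    pd = condense(parr_dual(p_plus, p_minus))
    # matched Fukui fixture: same donor/acceptor placement
    base = FixtureSpec(atoms=atoms, per_atom_masses=(4.0, 4.0), widths=widths,
                       grid_shape=(64, 64, 64), padding=2.0)
    rho_n, rho_np1, _ = make_fukui_pair(base, (0.0, 1.0))
    _, rho_n_plus_donor, _ = make_fukui_pair(base, (1.0, 0.0))
    rho_nm1 = rho_n.with_values(2 * rho_n.values - rho_n_plus_donor.values, "density")
    dd = condense(dual_descriptor(fukui_plus(rho_np1, rho_n), fukui_minus(rho_n, rho_nm1)))
    assert np.sign(pd.values) == pytest.approx(np.sign(dd.values))
    assert pd.values[1] > 0 > pd.values[0]


def test_condense_single_atom_equals_total_integral():
    spec = FixtureSpec(
        atoms=(AtomSite("C", 6.0, (0.0, 0.0, 0.0)),),
        per_atom_masses=(2.5,),
        widths=(0.6,),
        grid_shape=(48, 48, 48),
    )
    f = make_density(spec)
    for scheme in ("hirshfeld", "voronoi"):
        cv = condense(f, scheme)
        assert cv.total() == pytest.approx(f.integrate(), rel=1e-10)


def test_condense_symmetric_atoms_split_equally():
    atoms = (AtomSite("C", 6.0, (-2.0, 0.0, 0.0)), AtomSite("C", 6.0, (2.0, 0.0, 0.0)))
    spec = FixtureSpec(atoms=atoms, per_atom_masses=(1.0, 1.0), widths=(0.5, 0.5),
                       grid_shape=(64, 64, 64))
    f = make_density(spec)
    cv = condense(f)
    assert cv.values[0] == pytest.approx(cv.values[1], abs=1e-10)


def test_condensed_fukui_recovers_analytic_masses(fukui_pair):
    rho_n, rho_np1, analytic = fukui_pair
    f = fukui_plus(rho_np1, rho_n)
    for scheme in ("hirshfeld", "voronoi"):
        cv = condense(f, scheme)
        assert cv.values == pytest.approx(analytic, abs=0.02)
        assert cv.total() == pytest.approx(integrate(f), rel=1e-10)


def test_condense_errors():
    f = ScalarField(np.zeros(3), np.eye(3), np.ones((2, 2, 2)), atoms=[])
    with pytest.raises(InvariantError, match="no atoms"):
        condense(f)
    g = ScalarField(np.zeros(3), np.eye(3), np.ones((2, 2, 2)),
                    atoms=[AtomSite("H", 1.0, (0, 0, 0))])
    with pytest.raises(InvariantError, match="scheme"):
        condense(g, "mulliken")


@pytest.mark.parametrize("seed", range(20))
def test_partition_of_unity_and_oracle_across_random_fixtures(seed):
    """Property over seeded fixtures: both schemes conserve the integral to
    1e-10 relative, and Hirshfeld recovers the analytic per-atom Fukui masses
    within 0.02 at >=4 sigma separation."""
    spec = random_fixture_spec(seed, grid_shape=(40, 40, 40))
    delta = 0.2 + 0.6 * (seed / 19.0)
    rho_n, rho_np1, analytic = make_fukui_pair(spec, (delta, 1.0 - delta))
    f = fukui_plus(rho_np1, rho_n)
    total = integrate(f)
    for scheme in ("hirshfeld", "voronoi"):
        cv = condense(f, scheme)
        assert cv.total() == pytest.approx(total, rel=1e-10)
    assert condense(f, "hirshfeld").values == pytest.approx(analytic, abs=0.02)


def test_voronoi_and_hirshfeld_agree_for_well_separated_atoms():
    atoms = (AtomSite("C", 6.0, (0.0, 0.0, 0.0)), AtomSite("C", 6.0, (6.0, 0.0, 0.0)))
    spec = FixtureSpec(atoms=atoms, per_atom_masses=(3.0, 1.0), widths=(0.5, 0.5),
                       grid_shape=(72, 72, 72))
    f = make_density(spec)
    h = condense(f, "hirshfeld")
    v = condense(f, "voronoi")
    assert h.values == pytest.approx(v.values, abs=0.05)
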