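"""SASA against analytic oracles, interface metrics, polar contacts."""

import math

import numpy as np
import pytest

from s9conf.domains import partition_domains
from s9conf.interface import (
    InterfaceError,
    compute_sasa,
    find_polar_contacts,
    interface_metrics,
    ligand_environment,
)
from s9conf.structure import Atom, Residue, Structure
from s9conf.synth import ToySpec, closure_trajectory, make_toy_structure

PROBE = 1.4
R_C = 1.70  # carbon vdW


def carbon(x, y, z, name="C1"):
    return Atom(name=name, element="C", coord=np.array([x, y, z], float))


def residue_of(atoms, number=1, name="UNK"):
    return Residue("A", number, "", name, atoms)


def test_single_atom_sasa_matches_analytic_sphere():
    res = residue_of([carbon(0, 0, 0)])
    out = compute_sasa([res])
    expected = 4 * math.pi * (R_C + PROBE) ** 2
    assert out.total == pytest.approx(expected, rel=1e-6)  # no occlusion: exact
    assert expected == pytest.approx(120.76, abs=0.01)


def test_distant_atoms_do_not_occlude():
    res = residue_of([carbon(0, 0, 0), carbon(50, 0, 0, "C2")])
    out = compute_sasa([res])
    assert out.total == pytest.approx(2 * 4 * math.pi * (R_C + PROBE) ** 2, rel=1e-6)


@pytest.mark.parametrize("d", [2.0, 3.0, 4.0, 5.0])
def test_two_sphere_overlap_matches_spherical_cap_formula(d):
    """Two equal spheres at center distance d each lose a cap of height
    R - d/2; accessible area = 4*pi*R^2 - 2*pi*R*(R - d/2) per sphere."""
    R = R_C + PROBE
    res = residue_of([carbon(0, 0, 0), carbon(d, 0, 0, "C2")])
    out = compute_sasa([res])
    cap = 2 * math.pi * R * (R - d / 2)
    expected = 2 * (4 * math.pi * R * R - cap)
    assert out.total == pytest.approx(expected, rel=0.01)


def test_sasa_occlusion_monotonic_under_atom_addition():
    rng = np.random.default_rng(8)
    pts = rng.uniform(-4, 4, size=(12, 3))
    base_atoms = [carbon(*p, name=f"C{i}") for i, p in enumerate(pts)]
    base = compute_sasa([residue_of(base_atoms)])
    for trial in range(5):
        extra = carbon(*rng.uniform(-5, 5, 3), name="CX")
        grown = compute_sasa([residue_of(base_atoms + [extra])])
        # area of the original atoms can only shrink
        assert grown.atom_areas[:12].sum() <= base.total + 1e-9


def test_unknown_element_radius_raises():
    bad = Atom(name="FE", element="Fe", coord=np.zeros(3))
    with pytest.raises(InterfaceError, match="Fe"):
        compute_sasa([residue_of([bad])])
    with pytest.raises(InterfaceError, match="empty"):
        compute_sasa([])
    with pytest.raises(InterfaceError, match="probe"):
        compute_sasa([residue_of([carbon(0, 0, 0)])], probe=-1)


def test_sasa_cross_checked_against_biotite():
    """Independent oracle: biotite's Shrake-Rupley on the same atoms, same
    radii and probe, agrees within quadrature error."""
    biotite_struc = pytest.importorskip("biotite.structure")
    rng = np.random.default_rng(4)
    pts = rng.uniform(-5, 5, size=(20, 3))
    atoms = [carbon(*p, name=f"C{i}") for i, p in enumerate(pts)]
    ours = compute_sasa([residue_of(atoms)], points=960)

    arr = biotite_struc.AtomArray(len(pts))
    arr.coord = pts.astype(np.float32)
    arr.chain_id[:] = "A"
    arr.res_id[:] = 1
    arr.res_name[:] = "UNK"
    arr.atom_name[:] = [f"C{i}" for i in range(len(pts))]
    arr.element[:] = "C"
    theirs = biotite_struc.sasa(
        arr, probe_radius=PROBE, point_number=960, vdw_radii="Single"
    ).sum()
    # "Single" radii use C=1.70 as we do
    assert ours.total == pytest.approx(theirs, rel=0.02)


def test_bsa_zero_when_domains_far_apart():
    st, _ = make_toy_structure(ToySpec(separation=40.0, og_ne2=3.0, nd1_od2=3.0))
    part = partition_domains(st, "SpOpB")
    rep = interface_metrics(st, part, points=240)
    assert rep.bsa_percent_catalytic == 0.0
    assert rep.bsa_percent_propeller == 0.0
    assert rep.interface_residue_percent_catalytic == 0.0


def test_closed_pose_buries_more_than_open_pose():
    closed, _ = make_toy_structure(closure_trajectory(0.0))
    opened, _ = make_toy_structure(closure_trajectory(6.0))
    rep_c = interface_metrics(closed, partition_domains(closed, "SpOpB"), points=240)
    rep_o = interface_metrics(opened, partition_domains(opened, "SpOpB"), points=240)
    assert rep_c.bsa_percent_catalytic > rep_o.bsa_percent_catalytic
    assert rep_c.bsa_percent_propeller > rep_o.bsa_percent_propeller
    assert rep_c.interface_residue_percent_catalytic >= rep_o.interface_residue_percent_catalytic


def _arg(number, nh1_xyz):
    nh1 = np.asarray(nh1_xyz, float)
    return Residue("A", number, "", "ARG", [
        Atom("CA", "C", nh1 + [-4, 0, 0]),
        Atom("NH1", "N", nh1),
        Atom("NH2", "N", nh1 + [0.5, 1.8, 0.5]),
    ])


def _glu(number, oe1_xyz):
    oe1 = np.asarray(oe1_xyz, float)
    return Residue("A", number, "", "GLU", [
        Atom("CA", "C", oe1 + [4, 0, 0]),
        Atom("OE1", "O", oe1),
        Atom("OE2", "O", oe1 + [0.4, -1.7, 1.0]),
    ])


def test_planted_salt_bridge_found_exactly_once():
    arg, glu = _arg(10, (0, 0, 0)), _glu(90, (3.0, 0, 0))
    st = Structure(id="sb", chains={"A": [arg, glu]})
    contacts = find_polar_contacts(st, [arg], [glu])
    bridges = [c for c in contacts if c.kind == "salt_bridge"]
    assert len(bridges) == 1
    assert bridges[0].distance == pytest.approx(3.0)
    assert bridges[0].res_a[2] == "NH1" and bridges[0].res_b[2] == "OE1"


def test_no_contacts_beyond_default_cutoffs():
    arg, glu = _arg(10, (0, 0, 0)), _glu(90, (4.6, 0, 0))
    st = Structure(id="far", chains={"A": [arg, glu]})
    assert find_polar_contacts(st, [arg], [glu]) == []


def test_polar_contacts_symmetric_in_groups():
    arg, glu = _arg(10, (0, 0, 0)), _glu(90, (3.2, 0, 0))
    st = Structure(id="sym", chains={"A": [arg, glu]})
    ab = find_polar_contacts(st, [arg], [glu])
    ba = find_polar_contacts(st, [glu], [arg])
    assert {(c.kind, c.distance) for c in ab} == {(c.kind, c.distance) for c in ba}
    assert len(ab) == len(ba)


def test_polar_contact_groups_must_be_disjoint():
    arg = _arg(10, (0, 0, 0))
    st = Structure(id="dup", chains={"A": [arg]})
    with pytest.raises(InterfaceError, match="disjoint"):
        find_polar_contacts(st, [arg], [arg])


def test_ligand_environment_around_active_site():
    st, _ = make_toy_structure(ToySpec(ligand="active_site"))
    nearby = {r.number for r in ligand_environment(st, "TCK", cutoff=4.0)}
    assert 532 in nearby  # the covalently attacked serine sits next door
    far_st, _ = make_toy_structure(ToySpec(ligand="far"))
    assert ligand_environment(far_st, "TCK", cutoff=4.0) == []
    with pytest.raises(InterfaceError, match="not found"):
        ligand_environment(st, "AIP")


def test_ligand_environment_monotone_in_cutoff():
    st, _ = make_toy_structure(ToySpec(ligand="active_site"))
    prev = set()
    for cutoff in (3.0, 3.5, 4.0, 4.5, 5.0):
        cur = {r.number for r in ligand_environment(st, "TCK", cutoff=cutoff)}
        assert prev <= cur
        prev = cur
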