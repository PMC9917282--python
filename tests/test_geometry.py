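"""Triad distances, center-of-mass separation, Kabsch superposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from s9conf.domains import partition_domains
from s9conf.geometry import (
    GeometryError,
    RigidTransform,
    center_of_mass_distance,
    distance,
    kabsch_superpose,
    measure_triad,
    transform_structure,
)
from s9conf.structure import Atom, Residue, Structure
from s9conf.synth import ToySpec, make_toy_structure

coord = st.floats(min_value=-50, max_value=50, allow_nan=False)


def atom_at(x, y, z, name="CA", element="C"):
    return Atom(name=name, element=element, coord=np.array([x, y, z], float))


def test_distance_basics():
    a = atom_at(0, 0, 0)
    assert distance(a, a) == 0.0
    assert distance(a, atom_at(3, 4, 0)) == pytest.approx(5.0)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.tuples(coord, coord, coord), st.tuples(coord, coord, coord), st.tuples(coord, coord, coord))
def test_distance_symmetry_and_triangle_inequality(p, q, r):
    a, b, c = (atom_at(*v) for v in (p, q, r))
    assert distance(a, b) == distance(b, a)
    assert distance(a, c) <= distance(a, b) + distance(b, c) + 1e-9


@pytest.mark.parametrize("og_ne2,nd1_od2", [(3.2, 3.0), (2.8, 3.9), (6.0, 5.0)])
def test_measure_triad_recovers_planted_distances(og_ne2, nd1_od2):
    st_, truth = make_toy_structure(ToySpec(og_ne2=og_ne2, nd1_od2=nd1_od2))
    tri = measure_triad(st_, (532, 617, 652))
    assert tri.og_s_ne2_h == pytest.approx(og_ne2, abs=1e-3)
    assert tri.nd1_h_od2_d == pytest.approx(nd1_od2, abs=1e-3)
    assert tri.nd1_h_od_min_d <= tri.nd1_h_od2_d


def test_serine_mutant_reports_na_for_og_distance():
    st_, _ = make_toy_structure(ToySpec(plant_ser_og=False))
    tri = measure_triad(st_, (532, 617, 652))
    assert tri.serine_mutated
    assert tri.og_s_ne2_h is None
    assert not tri.assembled()
    assert "n/a" in tri.atoms_used["og_s_ne2_h"]


def test_measure_triad_lists_missing_atoms():
    st_, _ = make_toy_structure(ToySpec())
    his = st_.residue("A", 652)
    his.atoms = [a for a in his.atoms if a.name != "ND1"]
    with pytest.raises(GeometryError, match="HIS652:ND1"):
        measure_triad(st_, (532, 617, 652))


def test_triad_distances_invariant_under_rigid_motion():
    st_, _ = make_toy_structure(ToySpec(seed=3))
    before = measure_triad(st_, (532, 617, 652))
    R = Rotation.from_euler("xyz", [21, -35, 57], degrees=True).as_matrix()
    transform_structure(st_, RigidTransform(rotation=R, translation=np.array([5.0, -3.0, 11.0])))
    after = measure_triad(st_, (532, 617, 652))
    for field in ("ca_s_h", "og_s_ne2_h", "ca_h_d", "nd1_h_od2_d"):
        assert getattr(after, field) == pytest.approx(getattr(before, field), abs=1e-6)


def _point_mass_structure(d):
    """Two single-atom 'domains' separated by d along x."""
    res_cat = Residue("A", 500, "", "ALA", [atom_at(0, 0, 0)])
    res_prop = Residue("A", 100, "", "ALA", [atom_at(d, 0, 0)])
    st_ = Structure(id="pm", chains={"A": [res_prop, res_cat]})
    part = partition_domains(
        st_, {"n_loop": (1, 50), "hinge1": (60, 61), "propeller": (62, 200),
              "hinge2": (201, 202), "hydrolase": (203, 600)},
    )
    return st_, part


def test_com_distance_between_planted_point_masses():
    st_, part = _point_mass_structure(25.0)
    assert center_of_mass_distance(st_, part) == pytest.approx(25.0)


def test_com_distance_additive_under_domain_translation():
    from s9conf.geometry import _mass_center

    st_, truth = make_toy_structure(ToySpec(seed=5))
    part = partition_domains(st_, "SpOpB")
    base = center_of_mass_distance(st_, part)
    # rigid +5 A translation of the propeller along the actual COM axis
    axis = _mass_center(part.residues(st_, "propeller")) - _mass_center(
        part.residues(st_, "catalytic")
    )
    axis = 5.0 * axis / np.linalg.norm(axis)
    for res in part.residues(st_, "propeller"):
        for a in res.atoms:
            a.coord = a.coord + axis
    moved = center_of_mass_distance(st_, part)
    assert moved - base == pytest.approx(5.0, abs=1e-9)


def test_com_distance_invariant_under_global_rigid_motion():
    st_, _ = make_toy_structure(ToySpec(seed=5))
    part = partition_domains(st_, "SpOpB")
    base = center_of_mass_distance(st_, part)
    R = Rotation.from_euler("zyx", [10, 80, -30], degrees=True).as_matrix()
    transform_structure(st_, RigidTransform(rotation=R, translation=np.array([-7.0, 2.0, 4.0])))
    assert center_of_mass_distance(st_, part) == pytest.approx(base, abs=1e-9)


def test_com_distance_empty_domain_errors():
    res = Residue("A", 500, "", "ALA", [atom_at(0, 0, 0)])
    st_ = Structure(id="one", chains={"A": [res]})
    part = partition_domains(
        st_, {"n_loop": (400, 450), "hinge1": (460, 461), "propeller": (462, 470),
              "hinge2": (471, 472), "hydrolase": (473, 600)},
    )
    with pytest.raises(Exception, match="empty domain|no residues"):
        center_of_mass_distance(st_, part)


def _pairs(structure, n=None):
    nums = [r.number for r in structure.residues()]
    if n:
        nums = nums[:n]
    return [(("A", k), ("A", k)) for k in nums]


def test_kabsch_self_superposition_is_zero(toy_closed):
    st_, _ = toy_closed
    rmsd, _ = kabsch_superpose(st_, st_, _pairs(st_))
    assert rmsd == pytest.approx(0.0, abs=1e-9)


def test_kabsch_recovers_rigid_motion(toy_closed):
    import copy

    st_, _ = toy_closed
    moved = copy.deepcopy(st_)
    R = Rotation.from_euler("xyz", [33, 120, -75], degrees=True).as_matrix()
    transform_structure(moved, RigidTransform(rotation=R, translation=np.array([12.0, -4.0, 8.0])))
    rmsd, tf = kabsch_superpose(moved, st_, _pairs(st_))
    assert rmsd == pytest.approx(0.0, abs=1e-6)
    assert np.allclose(tf.rotation, R.T, atol=1e-6)


def test_kabsch_agrees_with_independent_quaternion_solver():
    rng = np.random.default_rng(11)
    P = rng.normal(size=(12, 3)) * 8
    R_true = Rotation.from_euler("xyz", [40, -60, 15], degrees=True)
    Q = R_true.apply(P) + np.array([3.0, 1.0, -2.0]) + rng.normal(size=(12, 3)) * 0.3

    def as_structure(coords, offset=0):
        residues = [
            Residue("A", i + 1 + offset, "", "ALA", [atom_at(*c)]) for i, c in enumerate(coords)
        ]
        return Structure(id="pts", chains={"A": residues})

    sm, stgt = as_structure(P), as_structure(Q)
    pairs = [(("A", i + 1), ("A", i + 1)) for i in range(12)]
    rmsd, tf = kabsch_superpose(sm, stgt, pairs)

    # independent route: quaternion-based alignment of the centered clouds
    rot, rssd = Rotation.align_vectors(Q - Q.mean(axis=0), P - P.mean(axis=0))
    assert rmsd == pytest.approx(rssd / np.sqrt(len(P)), abs=1e-6)
    assert np.allclose(tf.rotation, rot.as_matrix(), atol=1e-6)


def test_kabsch_rejects_degenerate_input():
    line = [atom_at(i, 0, 0) for i in range(5)]
    residues = [Residue("A", i + 1, "", "ALA", [a]) for i, a in enumerate(line)]
    st_ = Structure(id="line", chains={"A": residues})
    pairs = [(("A", i + 1), ("A", i + 1)) for i in range(5)]
    with pytest.raises(GeometryError, match="degenerate|collinear"):
        kabsch_superpose(st_, st_, pairs)
    with pytest.raises(GeometryError, match="at least 3"):
        kabsch_superpose(st_, st_, pairs[:2])
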