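"""Triad geometry, domain center-of-mass separation, and Kabsch superposition.

Four distances discriminate the assembled from the disassembled catalytic
triad in S9 peptidases: the Ser-His and His-Asp Calpha separations, and the
functional-atom distances Ser OG - His NE2 (the proton-transfer pair of the
nucleophilic attack) and His ND1 - Asp OD1/OD2 (the charge-relay pair). In the
closed state both functional distances sit at hydrogen-bond range (~2.8-3.5 A);
opening moves OG-NE2 beyond 18 A.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from s9conf.structure import Atom, Residue, Structure, StructureError

# Atomic masses (u) of elements found in heavy-atom protein models.
ATOMIC_MASS = {
    "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "SE": 78.971, "P": 30.974,
}

# Default assembled-triad cutoffs; see classify.Thresholds for the config block.
OG_NE2_ASSEMBLED_MAX = 4.5
ND1_OD_ASSEMBLED_MAX = 4.0


class GeometryError(Exception):
    pass


def distance(a: Atom, b: Atom) -> float:
    """Euclidean distance in Angstrom."""
    return float(np.linalg.norm(a.coord - b.coord))


@dataclasses.dataclass
class TriadGeometry:
    """The four per-structure triad distances (Angstrom).

    ``og_s_ne2_h`` is None when the nucleophile serine carries no OG (an S->A
    mutant), mirroring the "n/a" such structures print. ``nd1_h_od2_d`` uses
    OD2 specifically; ``nd1_h_od_min_d`` takes the nearer of OD1/OD2 — the two
    carboxylate oxygens are crystallographically ambiguous, so both readings
    are kept.
    """

    ca_s_h: float
    og_s_ne2_h: float | None
    ca_h_d: float
    nd1_h_od2_d: float
    nd1_h_od_min_d: float
    atoms_used: dict[str, str]
    serine_mutated: bool = False

    def assembled(
        self,
        og_ne2_max: float = OG_NE2_ASSEMBLED_MAX,
        nd1_od_max: float = ND1_OD_ASSEMBLED_MAX,
    ) -> bool:
        """Both functional-atom pairs within hydrogen-bonding reach."""
        if self.og_s_ne2_h is None:
            return False
        return self.og_s_ne2_h <= og_ne2_max and self.nd1_h_od_min_d <= nd1_od_max


def measure_triad(
    structure: Structure,
    triad: tuple[int, int, int],
    chain: str | None = None,
) -> TriadGeometry:
    """Measure the catalytic-triad distances.

    ``triad`` gives author residue numbers as (Ser, Asp, His). A missing Ser
    OG is tolerated (S->A mutants) and flagged; any other missing atom is an
    error listing the absences.
    """
    chain = chain or structure.first_chain()
    s_num, d_num, h_num = triad
    ser = structure.residue(chain, s_num)
    asp = structure.residue(chain, d_num)
    his = structure.residue(chain, h_num)

    missing = []
    for res, names in ((ser, ["CA"]), (his, ["CA", "NE2", "ND1"]), (asp, ["CA", "OD1", "OD2"])):
        for n in names:
            if not res.has_atom(n):
                missing.append(f"{res.name}{res.number}:{n}")
    if missing:
        raise GeometryError("triad atoms missing: " + ", ".join(missing))

    has_og = ser.has_atom("OG")
    ne2, nd1 = his.atom("NE2"), his.atom("ND1")
    od1, od2 = asp.atom("OD1"), asp.atom("OD2")

    d_od1 = distance(nd1, od1)
    d_od2 = distance(nd1, od2)
    atoms_used = {
        "ca_s_h": "CA-CA",
        "og_s_ne2_h": "OG-NE2" if has_og else "n/a (no OG)",
        "ca_h_d": "CA-CA",
        "nd1_h_od2_d": "ND1-OD2",
        "nd1_h_od_min_d": "ND1-OD1" if d_od1 < d_od2 else "ND1-OD2",
    }
    return TriadGeometry(
        ca_s_h=distance(ser.atom("CA"), his.atom("CA")),
        og_s_ne2_h=distance(ser.atom("OG"), ne2) if has_og else None,
        ca_h_d=distance(his.atom("CA"), asp.atom("CA")),
        nd1_h_od2_d=d_od2,
        nd1_h_od_min_d=min(d_od1, d_od2),
        atoms_used=atoms_used,
        serine_mutated=not has_og,
    )


def _mass_center(residues: list[Residue]) -> np.ndarray:
    coords, masses = [], []
    for res in residues:
        for a in res.atoms:
            coords.append(a.coord)
            masses.append(ATOMIC_MASS.get(a.element.upper(), 12.011))
    if not coords:
        raise GeometryError("empty domain: no atoms for center of mass")
    coords = np.asarray(coords)
    masses = np.asarray(masses)
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def center_of_mass_distance(structure: Structure, partition) -> float:
    """Separation of the mass-weighted heavy-atom centers of the catalytic
    domain (N-terminal loop + hydrolase fold) and the beta-propeller.

    Hinge residues belong to neither center. ~30 A in closed S9 structures,
    ~37 A in open ones.
    """
    cat = partition.residues(structure, "catalytic")
    prop = partition.residues(structure, "propeller")
    return float(np.linalg.norm(_mass_center(cat) - _mass_center(prop)))


@dataclasses.dataclass
class RigidTransform:
    rotation: np.ndarray  # 3x3
    translation: np.ndarray  # 3-vector

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(
    mobile: Structure,
    target: Structure,
    pairs: list[tuple[tuple[str, int], tuple[str, int]]],
    atom_name: str = "CA",
) -> tuple[float, RigidTransform]:
    """Optimal least-squares superposition over paired residues (Kabsch/SVD).

    ``pairs`` lists ((mobile_chain, mobile_resnum), (target_chain,
    target_resnum)); the named atom (Calpha by default) of each pair is used.
    Returns the RMSD after superposition and the transform mapping mobile onto
    target coordinates.
    """
    if len(pairs) < 3:
        raise GeometryError("need at least 3 residue pairs")
    P = np.array([mobile.residue(c, n).atom(atom_name).coord for (c, n), _ in pairs])
    Q = np.array([target.residue(c, n).atom(atom_name).coord for _, (c, n) in pairs])

    p_mean, q_mean = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - p_mean, Q - q_mean
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    # collinear/degenerate point sets leave the rotation under-determined
    if S[1] < 1e-8 * max(S[0], 1.0):
        raise GeometryError("degenerate (collinear) point set: rotation not determined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = q_mean - R @ p_mean
    moved = P0 @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q0) ** 2, axis=1))))
    return rmsd, RigidTransform(rotation=R, translation=t)


def transform_structure(structure: Structure, transform: RigidTransform) -> None:
    """Apply a rigid transform to every atom in place (hetero included)."""
    for _, atom in structure.atoms(include_hetero=True):
        atom.coord = transform.apply(atom.coord[None, :])[0]
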