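"""Solvent accessibility and interdomain interface census.

Solvent-accessible surface area (SASA) is computed with an in-house
Shrake-Rupley sphere sampling: each atom is inflated by the probe radius and a
fixed deterministic set of test points on its sphere is checked for occlusion
by neighbouring inflated atoms. The buried-surface percentage of a domain is
the fraction of its isolated SASA lost in the assembled two-domain structure —
the quantity that separates closed (~14-17%) from open (~7-9%) S9 peptidase
conformations.

Polar contacts use heavy-atom distance criteria only: at typical crystal
resolutions hydrogens are absent, so a hydrogen bond is operationally an N/O
to N/O pair within 3.5 A, and a salt bridge a basic-nitrogen to
carboxylate-oxygen pair within 4.0 A.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from s9conf.structure import Residue, Structure

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "SE": 1.90, "P": 1.80}
DEFAULT_PROBE = 1.4
DEFAULT_POINTS = 960
INTERFACE_BURIED_MIN = 0.1  # A^2 buried for a residue to count as interfacial

HBOND_CUTOFF = 3.5
SALT_BRIDGE_CUTOFF = 4.0

# side-chain charge carriers for the salt-bridge criterion
BASIC_ATOMS = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}
ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


class InterfaceError(Exception):
    pass


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _radius(element: str) -> float:
    try:
        return VDW_RADII[element.upper()]
    except KeyError:
        raise InterfaceError(f"no van der Waals radius for element {element!r}") from None


@dataclasses.dataclass
class SasaResult:
    atom_areas: np.ndarray                 # A^2, aligned with ``atoms``
    atoms: list[tuple[Residue, str]]       # (residue, atom name) per entry
    residue_areas: dict[tuple[str, int, str], float]
    total: float


def _gather(residues: Iterable[Residue]):
    atoms, coords, radii = [], [], []
    for res in residues:
        for a in res.atoms:
            atoms.append((res, a.name))
            coords.append(a.coord)
            radii.append(_radius(a.element))
    return atoms, np.asarray(coords, dtype=float), np.asarray(radii, dtype=float)


def compute_sasa(
    residues: Iterable[Residue] | Structure,
    probe: float = DEFAULT_PROBE,
    points: int = DEFAULT_POINTS,
) -> SasaResult:
    """Shrake-Rupley accessible surface of the given residue set.

    The selection is treated as the whole system: atoms outside it do not
    occlude. Pass a :class:`Structure` to use all protein residues plus
    retained hetero groups.
    """
    if isinstance(residues, Structure):
        residues = [r for r in residues.residues()] + list(residues.hetero)
    residues = list(residues)
    if not residues:
        raise InterfaceError("empty selection")
    if probe <= 0:
        raise InterfaceError("probe radius must be positive")
    atoms, coords, radii = _gather(residues)
    sphere = _fibonacci_sphere(points)
    inflated = radii + probe
    tree = cKDTree(coords)
    max_reach = 2.0 * inflated.max()
    areas = np.zeros(len(atoms))
    for i in range(len(atoms)):
        ri = inflated[i]
        test = coords[i] + ri * sphere
        neigh = [j for j in tree.query_ball_point(coords[i], ri + inflated.max()) if j != i]
        if neigh:
            d2 = ((test[:, None, :] - coords[neigh][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (inflated[neigh] ** 2)[None, :]).any(axis=1)
            accessible = int((~buried).sum())
        else:
            accessible = points
        areas[i] = 4.0 * math.pi * ri * ri * accessible / points
    residue_areas: dict[tuple[str, int, str], float] = {}
    for (res, _), a in zip(atoms, areas):
        residue_areas[res.key] = residue_areas.get(res.key, 0.0) + a
    return SasaResult(atom_areas=areas, atoms=atoms, residue_areas=residue_areas, total=float(areas.sum()))


@dataclasses.dataclass
class PolarContact:
    kind: str                      # "hbond" | "salt_bridge"
    res_a: tuple[str, int, str]    # residue name, number, atom name
    res_b: tuple[str, int, str]
    distance: float
    interdomain: bool = True

    def involves(self, resnum_a: int, resnum_b: int) -> bool:
        nums = {self.res_a[1], self.res_b[1]}
        return nums == {resnum_a, resnum_b}


@dataclasses.dataclass
class InterfaceReport:
    bsa_percent_catalytic: float
    bsa_percent_propeller: float
    interface_residue_percent_catalytic: float
    interface_residue_percent_propeller: float
    hbonds: list[PolarContact]
    salt_bridges: list[PolarContact]

    @property
    def hbond_count(self) -> int:
        return len(self.hbonds)

    @property
    def salt_bridge_count(self) -> int:
        return len(self.salt_bridges)


def _polar_atoms(res: Residue):
    for a in res.atoms:
        if a.element.upper() in ("N", "O"):
            yield a


def find_polar_contacts(
    structure: Structure,
    group_a: Sequence[Residue],
    group_b: Sequence[Residue],
    hbond_cutoff: float = HBOND_CUTOFF,
    sb_cutoff: float = SALT_BRIDGE_CUTOFF,
) -> list[PolarContact]:
    """Cross-group hydrogen bonds and salt bridges.

    One contact is reported per (residue pair, kind), carrying its
    minimal-distance atom pair. The two groups must be disjoint.
    """
    keys_a = {r.key for r in group_a}
    if keys_a & {r.key for r in group_b}:
        raise InterfaceError("groups must be disjoint")

    def collect(group):
        recs, coords = [], []
        for res in group:
            for a in _polar_atoms(res):
                recs.append((res, a))
                coords.append(a.coord)
        return recs, np.asarray(coords, dtype=float).reshape(-1, 3)

    recs_a, xyz_a = collect(group_a)
    recs_b, xyz_b = collect(group_b)
    if not recs_a or not recs_b:
        return []
    max_cut = max(hbond_cutoff, sb_cutoff)
    pairs = cKDTree(xyz_a).query_ball_tree(cKDTree(xyz_b), max_cut)
    best: dict[tuple, PolarContact] = {}
    for ia, hits in enumerate(pairs):
        ra, aa = recs_a[ia]
        for ib in hits:
            rb, ab = recs_b[ib]
            d = float(np.linalg.norm(aa.coord - ab.coord))
            kinds = []
            if d <= hbond_cutoff:
                kinds.append("hbond")
            a_basic = aa.name in BASIC_ATOMS.get(ra.name, ())
            a_acid = aa.name in ACIDIC_ATOMS.get(ra.name, ())
            b_basic = ab.name in BASIC_ATOMS.get(rb.name, ())
            b_acid = ab.name in ACIDIC_ATOMS.get(rb.name, ())
            if d <= sb_cutoff and ((a_basic and b_acid) or (a_acid and b_basic)):
                kinds.append("salt_bridge")
            for kind in kinds:
                key = (ra.key, rb.key, kind)
                if key not in best or d < best[key].distance:
                    best[key] = PolarContact(
                        kind=kind,
                        res_a=(ra.name, ra.number, aa.name),
                        res_b=(rb.name, rb.number, ab.name),
                        distance=d,
                    )
    return sorted(best.values(), key=lambda c: (c.res_a[1], c.res_b[1], c.kind))


def interface_metrics(
    structure: Structure,
    partition,
    probe: float = DEFAULT_PROBE,
    points: int = DEFAULT_POINTS,
    buried_min: float = INTERFACE_BURIED_MIN,
    hbond_cutoff: float = HBOND_CUTOFF,
    sb_cutoff: float = SALT_BRIDGE_CUTOFF,
) -> InterfaceReport:
    """Buried-surface and interface-residue percentages plus the polar-contact
    census between the catalytic domain (N-loop + hydrolase) and the
    propeller. Hinge residues belong to neither side.
    """
    cat = partition.residues(structure, "catalytic")
    prop = partition.residues(structure, "propeller")

    iso_cat = compute_sasa(cat, probe, points)
    iso_prop = compute_sasa(prop, probe, points)
    together = compute_sasa(list(cat) + list(prop), probe, points)

    def stats(iso: SasaResult, members: list[Residue]):
        keys = [r.key for r in members]
        buried_total = 0.0
        n_interface = 0
        for k in keys:
            b = iso.residue_areas.get(k, 0.0) - together.residue_areas.get(k, 0.0)
            buried_total += max(b, 0.0)
            if b > buried_min:
                n_interface += 1
        bsa_pct = 100.0 * buried_total / iso.total if iso.total > 0 else 0.0
        res_pct = 100.0 * n_interface / len(keys)
        return bsa_pct, res_pct

    bsa_cat, resp_cat = stats(iso_cat, cat)
    bsa_prop, resp_prop = stats(iso_prop, prop)

    contacts = find_polar_contacts(structure, cat, prop, hbond_cutoff, sb_cutoff)
    return InterfaceReport(
        bsa_percent_catalytic=bsa_cat,
        bsa_percent_propeller=bsa_prop,
        interface_residue_percent_catalytic=resp_cat,
        interface_residue_percent_propeller=resp_prop,
        hbonds=[c for c in contacts if c.kind == "hbond"],
        salt_bridges=[c for c in contacts if c.kind == "salt_bridge"],
    )


def ligand_environment(
    structure: Structure,
    ligand_id: str | tuple[str, int],
    cutoff: float = 4.0,
) -> list[Residue]:
    """Protein residues with any heavy atom within ``cutoff`` of any ligand
    heavy atom (the 4-A inhibitor surroundings of binding-site figures).
    """
    if isinstance(ligand_id, str):
        ligands = [r for r in structure.hetero if r.name == ligand_id]
    else:
        cid, num = ligand_id
        ligands = [r for r in structure.hetero if r.chain_id == cid and r.number == num]
    if not ligands:
        raise InterfaceError(f"ligand {ligand_id!r} not found")
    lig_coords = np.array([a.coord for r in ligands for a in r.atoms])
    tree = cKDTree(lig_coords)
    out = []
    for res in structure.residues():
        coords = np.array([a.coord for a in res.atoms])
        if tree.query(coords, k=1)[0].min() <= cutoff:
            out.append(res)
    return out
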