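"""Hierarchical protein-structure model with PDB input/output.

The public coordinate system is author residue numbering throughout: every
residue identifier printed in structure reports (S532, H652, E172, ...) refers
to the number in the deposited PDB, never to a sequential index. Parsing is
delegated to gemmi; this module owns the in-memory model the rest of the
package navigates.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}

WATER_NAMES = {"HOH", "WAT", "DOD"}


class StructureError(Exception):
    """Raised for parse failures and failed atom/residue lookups."""


@dataclasses.dataclass
class Atom:
    """A heavy atom with PDB naming.

    Coordinates are in Angstrom. ``altloc`` is None once alternate locations
    have been collapsed (the reader keeps the highest-occupancy conformer).
    """

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str | None = None
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")
        if not self.element:
            raise StructureError(f"atom {self.name}: empty element")


@dataclasses.dataclass
class Residue:
    chain_id: str
    number: int
    icode: str
    name: str
    atoms: list[Atom]
    is_hetero: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise StructureError(
            f"atom {name!r} not found in {self.name} {self.chain_id}{self.number}{self.icode.strip()}"
        )

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclasses.dataclass
class Structure:
    """Protein chains plus retained hetero groups (ligands, no waters)."""

    id: str
    chains: dict[str, list[Residue]]
    hetero: list[Residue] = dataclasses.field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        if not any(self.chains.values()):
            raise StructureError("no protein chains")
        seen: set[tuple[str, int, str]] = set()
        for res in self.residues():
            if res.key in seen:
                raise StructureError(f"duplicate residue {res.key}")
            seen.add(res.key)

    def residues(self, chain: str | None = None) -> Iterator[Residue]:
        """Protein residues, in chain then author order."""
        for cid, reslist in self.chains.items():
            if chain is not None and cid != chain:
                continue
            yield from reslist

    def first_chain(self) -> str:
        return next(iter(self.chains))

    def residue(self, chain: str, number: int, icode: str = "") -> Residue:
        for res in self.chains.get(chain, []):
            if res.number == number and res.icode.strip() == icode.strip():
                return res
        raise StructureError(f"residue {chain}/{number}{icode.strip()} not found in {self.id}")

    def sequence(self, chain: str | None = None) -> str:
        chain = chain or self.first_chain()
        return "".join(r.one_letter for r in self.chains[chain])

    def atoms(self, include_hetero: bool = False) -> Iterator[tuple[Residue, Atom]]:
        for res in self.residues():
            for a in res.atoms:
                yield res, a
        if include_hetero:
            for res in self.hetero:
                for a in res.atoms:
                    yield res, a


def _collapse_altlocs(raw: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc letter."""
    by_name: dict[str, Atom] = {}
    for atom in raw:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
            continue
        better = atom.occupancy > prev.occupancy or (
            atom.occupancy == prev.occupancy and (atom.altloc or "~") < (prev.altloc or "~")
        )
        if better:
            by_name[atom.name] = atom
    out = []
    for atom in by_name.values():
        atom = dataclasses.replace(atom, altloc=None)
        out.append(atom)
    return out


def read_structure(
    path: str | Path,
    format: str = "pdb",
    keep_waters: bool = False,
    model_index: int = 0,
) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Highest-occupancy alternate locations are retained, waters are dropped by
    default, hydrogens are discarded, and author numbering is preserved.
    Non-water heteroatom groups (e.g. a covalent inhibitor) are kept on
    ``Structure.hetero``.
    """
    if format != "pdb":
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    if not path.exists():
        raise StructureError(f"file not found: {path}")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError("no protein chains")
    st.setup_entities()
    model = st[model_index]

    chains: dict[str, list[Residue]] = {}
    hetero: list[Residue] = []
    for chain in model:
        for res in chain:
            raw_atoms = []
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                raw_atoms.append(
                    Atom(
                        name=atom.name,
                        element=atom.element.name,
                        coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=min(1.0, max(0.0, atom.occ)),
                        altloc=atom.altloc if atom.altloc != "\x00" else None,
                        b_factor=atom.b_iso,
                    )
                )
            if not raw_atoms:
                continue
            atoms = _collapse_altlocs(raw_atoms)
            resname = res.name.strip()
            is_water = resname in WATER_NAMES
            if is_water and not keep_waters:
                continue
            is_protein = resname in THREE_TO_ONE
            residue = Residue(
                chain_id=chain.name,
                number=res.seqid.num,
                icode=(res.seqid.icode or "").strip(),
                name=resname,
                atoms=atoms,
                is_hetero=not is_protein,
            )
            if is_protein:
                chains.setdefault(chain.name, []).append(residue)
            else:
                hetero.append(residue)
    if not chains:
        raise StructureError("no protein chains")
    return Structure(id=st.name or path.stem, chains=chains, hetero=hetero, source=str(path))


_PDB_ATOM = (
    "{record:<6}{serial:>5} {name:<4}{altloc:1}{resname:>3} {chain:1}"
    "{resnum:>4}{icode:1}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2}\n"
)


def _format_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: one/two-letter elements are right/left aligned differently
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 and len(name) <= 3:
        return f" {name:<3}"
    return f"{name:<4}"


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write ATOM/HETATM/TER/END records; coordinates at PDB precision (3 dp)."""
    path = Path(path)
    serial = 0
    lines: list[str] = []
    for cid, reslist in structure.chains.items():
        for res in reslist:
            for a in res.atoms:
                serial += 1
                lines.append(
                    _PDB_ATOM.format(
                        record="ATOM",
                        serial=serial,
                        name=_format_atom_name(a.name, a.element),
                        altloc=" ",
                        resname=res.name,
                        chain=cid,
                        resnum=res.number,
                        icode=res.icode or " ",
                        x=a.coord[0],
                        y=a.coord[1],
                        z=a.coord[2],
                        occ=a.occupancy,
                        b=a.b_factor,
                        element=a.element.upper(),
                    )
                )
        serial += 1
        lines.append(f"TER   {serial:>5}\n")
    for res in structure.hetero:
        for a in res.atoms:
            serial += 1
            lines.append(
                _PDB_ATOM.format(
                    record="HETATM",
                    serial=serial,
                    name=_format_atom_name(a.name, a.element),
                    altloc=" ",
                    resname=res.name,
                    chain=res.chain_id,
                    resnum=res.number,
                    icode=res.icode or " ",
                    x=a.coord[0],
                    y=a.coord[1],
                    z=a.coord[2],
                    occ=a.occupancy,
                    b=a.b_factor,
                    element=a.element.upper(),
                )
            )
    lines.append("END\n")
    path.write_text("".join(lines))


def get_atom(structure: Structure, chain: str, resnum: int, atom_name: str) -> Atom:
    """Look up a named atom by author numbering.

    Ambiguous carboxylate/guanidinium atoms are not resolved here: ask for OD1
    or OD2 (etc.) explicitly.
    """
    return structure.residue(chain, resnum).atom(atom_name)
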