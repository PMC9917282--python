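"""Seeded generators for every input class the pipeline consumes.

Everything here plants its ground truth and returns it alongside the data, so
tests can close the loop: toy two-domain structures with a Ser/His/Asp triad
at controlled functional-atom distances and an interdomain stabilization
network (Glu-Arg salt bridge or RR-SQ contact web), sequence sets derived from
the packaged references with known group labels and a lineage table, and
pseudo-first-order inactivation curves from stated Ki/k2.

The toy structures are deliberately not physical proteins: each domain is a
ball of alanine-like residues on a jittered grid (rigid, compact, with a
realistic ~26 A center-of-mass separation at contact), and the functional
side-chain atoms are placed by explicit coordinates. Only inter-atomic
distances and occlusion matter to the downstream measurements, and those are
exact by construction. All cross-domain planted vectors run along +x, the
domain-separation axis, so increasing the separation by s lengthens every
interdomain planted distance by exactly s while intradomain geometry is
untouched.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from s9conf.domains import reference_sequence
from s9conf.kinetics import InactivationSeries
from s9conf.structure import Atom, Residue, Structure

AAS = "ACDEFGHIKLMNPQRSTVWY"

# Domain geometry: each rigid body is an oblate ellipsoid of alanine-like
# residues, flattened along the separation axis so the two domains meet over
# a broad face (as the catalytic and propeller discs do). Dimensions are set
# so that at contact (separation 0) the catalytic domain buries ~15% of its
# surface — the scale crystal structures show for the closed state — decaying
# through the 10% intermediate/open boundary over a few Angstrom of opening.
XSEMI = 6.5       # semi-axis along the separation axis (A)
YSEMI = 13.0      # transverse semi-axes (A)
GRID_SPACING = 4.2
BASE_CENTER_DISTANCE = 2 * XSEMI + 0.5

MIN_PLANTED_DISTANCE = 2.4  # steric floor for planted atom pairs


class SynthError(Exception):
    pass


@dataclasses.dataclass
class ToySpec:
    """Recipe for a planted two-domain toy structure.

    separation: extra domain separation (A) beyond the contact pose; 0 is the
    closed-like pose. og_ne2 / nd1_od2: planted triad functional distances.
    network: interdomain stabilization to plant ("SB1", "RRSQ", or "none").
    ligand: None, "active_site" (a TCK-like hetero group next to the triad),
    or "far" (10 A off the protein surface).
    """

    separation: float = 0.0
    og_ne2: float = 2.8
    nd1_od2: float = 3.0
    network: str = "RRSQ"
    plant_ser_og: bool = True
    ligand: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.separation < 0:
            raise SynthError("separation must be >= 0")
        for d in (self.og_ne2, self.nd1_od2):
            if d < MIN_PLANTED_DISTANCE:
                raise SynthError(
                    f"planted distance {d} below the {MIN_PLANTED_DISTANCE} A steric floor"
                )
        if self.network not in ("SB1", "RRSQ", "none"):
            raise SynthError(f"unknown network {self.network!r}")


def _grid_ball(center: np.ndarray, rng: np.random.Generator) -> list[np.ndarray]:
    pts = []
    n = int(max(XSEMI, YSEMI) // GRID_SPACING) + 1
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            for k in range(-n, n + 1):
                p = np.array([i, j, k], dtype=float) * GRID_SPACING
                if (p[0] / XSEMI) ** 2 + (p[1] / YSEMI) ** 2 + (p[2] / YSEMI) ** 2 <= 1.0:
                    pts.append(center + p + rng.uniform(-0.3, 0.3, 3))
    return pts


def _ala_residue(chain: str, number: int, center: np.ndarray) -> Residue:
    offs = {
        "N": np.array([-1.2, 0.8, 0.0]),
        "CA": np.array([0.0, 0.0, 0.0]),
        "C": np.array([1.3, 0.6, 0.0]),
        "O": np.array([1.5, 1.8, 0.2]),
        "CB": np.array([-0.4, -1.0, 1.1]),
    }
    elem = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
    atoms = [Atom(name=n, element=elem[n], coord=center + o) for n, o in offs.items()]
    return Residue(chain_id=chain, number=number, icode="", name="ALA", atoms=atoms)


def _residue_from_atoms(chain: str, number: int, name: str, atom_spec: dict[str, np.ndarray]) -> Residue:
    elem = lambda n: n[0] if n[0] in "NOC" else "C"  # noqa: E731 - toy atoms are N/O/C only
    atoms = [Atom(name=n, element=elem(n), coord=c) for n, c in atom_spec.items()]
    return Residue(chain_id=chain, number=number, icode="", name=name, atoms=atoms)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def make_toy_structure(spec: ToySpec) -> tuple[Structure, dict]:
    """Build the planted two-domain toy and its machine-readable truth record.

    The catalytic ball sits at the origin (residues split between the
    N-terminal loop, numbers 15+, and the hydrolase fold, numbers 430+); the
    propeller ball sits on +x (numbers 160+). Numbering follows the SpOpB
    preset so partition_domains(..., "SpOpB") and an identity ReferenceMap
    apply directly. The triad and network residues carry the SpOpB author
    numbers (S532/D617/H652; 149-151, 618-621).
    """
    rng = np.random.default_rng(spec.seed)
    sep = spec.separation
    shift = np.array([sep, 0.0, 0.0])
    chain = "A"

    cat_center = np.zeros(3)
    prop_center = np.array([BASE_CENTER_DISTANCE, 0.0, 0.0]) + shift

    residues: list[Residue] = []
    reserved = {149, 150, 151, 532, 617, 618, 619, 621, 652}

    def numbers(start):
        n = start
        while True:
            if n not in reserved:
                yield n
            n += 1

    cat_points = _grid_ball(cat_center, rng)
    n_nloop = min(30, len(cat_points) // 3)
    nums = numbers(15)
    for p in cat_points[:n_nloop]:
        residues.append(_ala_residue(chain, next(nums), p))
    nums = numbers(430)
    for p in cat_points[n_nloop:]:
        residues.append(_ala_residue(chain, next(nums), p))
    nums = numbers(160)
    for p in _grid_ball(prop_center, rng):
        number = next(nums)
        if number > 406:
            raise SynthError("propeller ball too large for the preset numbering range")
        residues.append(_ala_residue(chain, number, p))

    # --- catalytic triad (all catalytic-domain residues), planted distances.
    # Disassembly stretches the His away laterally (the H-loop swings to the
    # domain periphery), never toward the propeller.
    og = np.array([XSEMI - 0.5, 0.0, 4.0])
    ne2 = og + spec.og_ne2 * _unit([-0.35, 0.55, 0.76])
    nd1 = ne2 + 2.2 * _unit([0.45, 0.9, 0.0])
    od2 = nd1 + np.array([0.0, spec.nd1_od2, 0.0])
    od1 = od2 + 2.2 * _unit([0.0, 0.7, 0.7])

    ser_atoms = {
        "N": og + np.array([-2.8, 0.6, -1.2]),
        "CA": og + np.array([-2.0, 0.0, -1.6]),
        "C": og + np.array([-2.2, -1.2, -2.4]),
        "O": og + np.array([-1.6, -2.2, -2.6]),
        "CB": og + np.array([-1.0, 0.4, -0.8]),
    }
    if spec.plant_ser_og:
        ser_atoms["OG"] = og
    residues.append(_residue_from_atoms(chain, 532, "SER", ser_atoms))

    his_ca = (ne2 + nd1) / 2 + np.array([0.0, 0.4, 2.6])
    residues.append(
        _residue_from_atoms(
            chain, 652, "HIS",
            {
                "N": his_ca + np.array([-1.3, 0.6, 0.6]),
                "CA": his_ca,
                "C": his_ca + np.array([1.3, 0.7, 0.4]),
                "O": his_ca + np.array([2.2, 0.2, 1.2]),
                "CB": his_ca + np.array([0.2, -0.6, -1.3]),
                "CG": (ne2 + nd1) / 2 + np.array([0.0, 0.0, 1.2]),
                "ND1": nd1,
                "NE2": ne2,
            },
        )
    )
    asp_ca = od2 + np.array([0.0, 1.6, 1.8])
    residues.append(
        _residue_from_atoms(
            chain, 617, "ASP",
            {
                "N": asp_ca + np.array([-1.3, 0.7, 0.3]),
                "CA": asp_ca,
                "C": asp_ca + np.array([1.4, 0.5, 0.2]),
                "O": asp_ca + np.array([1.8, 1.6, 0.6]),
                "CB": asp_ca + np.array([-0.2, -0.9, -1.1]),
                "CG": (od1 + od2) / 2 + np.array([0.0, 0.8, 0.4]),
                "OD1": od1,
                "OD2": od2,
            },
        )
    )

    truth = {
        "separation": sep,
        "og_ne2": spec.og_ne2 if spec.plant_ser_og else None,
        "nd1_od2": spec.nd1_od2,
        "network": spec.network,
        "seed": spec.seed,
    }

    # --- stabilization network across the gap (propeller side rides with
    # the ball: every cross vector is +x, so contacts stretch by exactly sep)
    y0 = -8.0
    if spec.network == "SB1":
        nh2 = np.array([XSEMI - 0.5, y0, 0.0])
        oe1 = nh2 + np.array([3.4 + sep, 0.0, 0.0])
        residues.append(
            _residue_from_atoms(
                chain, 619, "ARG",
                {
                    "N": nh2 + np.array([-4.6, 0.8, 0.4]),
                    "CA": nh2 + np.array([-3.8, 0.0, 0.0]),
                    "C": nh2 + np.array([-4.4, -1.2, -0.6]),
                    "O": nh2 + np.array([-5.4, -1.2, -1.2]),
                    "CB": nh2 + np.array([-2.4, 0.4, 0.6]),
                    "NE": nh2 + np.array([-1.6, -0.6, 0.2]),
                    "NH1": nh2 + np.array([-0.4, 1.8, 0.0]),
                    "NH2": nh2,
                },
            )
        )
        residues.append(
            _residue_from_atoms(
                chain, 151, "GLU",
                {
                    "N": oe1 + np.array([3.6, 0.9, 0.4]),
                    "CA": oe1 + np.array([2.9, 0.0, 0.0]),
                    "C": oe1 + np.array([3.6, -1.1, -0.7]),
                    "O": oe1 + np.array([4.6, -1.0, -1.3]),
                    "CB": oe1 + np.array([1.6, 0.4, 0.5]),
                    "OE1": oe1,
                    "OE2": oe1 + np.array([0.4, -1.7, 1.2]),
                },
            )
        )
        truth["sb1_distance"] = 3.4 + sep
        truth["planted_mode"] = "salt_bridge_SB1" if sep < 0.6 else "undetermined"
    elif spec.network == "RRSQ":
        ne2_q = np.array([XSEMI - 0.5, y0, 0.0])                # Q619 NE2
        oe1_q = ne2_q + 2.2 * _unit([0.0, 1.1, 1.9])            # Q619 OE1
        og_s = oe1_q + np.array([0.0, 2.6, 0.0])                # S618 OG
        oe1_q621 = np.array([XSEMI - 0.5, y0 - 3.0, 0.0])       # Q621 OE1
        nh1_r151 = ne2_q + np.array([3.7 + sep, 0.0, 0.0])      # R151 NH1
        o_r150 = og_s + np.array([3.3 + sep, 0.0, 0.0])         # R150 O
        nh1_r150 = oe1_q621 + np.array([3.1 + sep, 0.0, 0.0])   # R150 NH1
        residues.append(
            _residue_from_atoms(
                chain, 618, "SER",
                {
                    "N": og_s + np.array([-2.6, 0.8, -0.6]),
                    "CA": og_s + np.array([-1.9, 0.0, -1.0]),
                    "C": og_s + np.array([-2.4, -1.2, -1.7]),
                    "O": og_s + np.array([-3.4, -1.1, -2.4]),
                    "CB": og_s + np.array([-0.9, 0.5, -0.4]),
                    "OG": og_s,
                },
            )
        )
        residues.append(
            _residue_from_atoms(
                chain, 619, "GLN",
                {
                    "N": ne2_q + np.array([-4.2, 0.9, 0.3]),
                    "CA": ne2_q + np.array([-3.4, 0.0, 0.0]),
                    "C": ne2_q + np.array([-4.0, -1.2, -0.6]),
                    "O": ne2_q + np.array([-5.0, -1.2, -1.2]),
                    "CB": ne2_q + np.array([-2.2, 0.4, 0.5]),
                    "CD": (ne2_q + oe1_q) / 2 + np.array([-0.9, 0.0, 0.0]),
                    "NE2": ne2_q,
                    "OE1": oe1_q,
                },
            )
        )
        residues.append(
            _residue_from_atoms(
                chain, 621, "GLN",
                {
                    "N": oe1_q621 + np.array([-4.2, -0.9, 0.3]),
                    "CA": oe1_q621 + np.array([-3.4, 0.0, 0.0]),
                    "C": oe1_q621 + np.array([-4.0, 1.2, -0.6]),
                    "O": oe1_q621 + np.array([-5.0, 1.2, -1.2]),
                    "CB": oe1_q621 + np.array([-2.2, -0.4, 0.5]),
                    "NE2": oe1_q621 + np.array([0.3, -1.8, 1.1]),
                    "OE1": oe1_q621,
                },
            )
        )
        residues.append(
            _residue_from_atoms(
                chain, 150, "ARG",
                {
                    "N": o_r150 + np.array([2.4, -0.8, 0.5]),
                    "CA": o_r150 + np.array([1.6, -1.4, 0.0]),
                    "C": o_r150 + np.array([0.6, -0.6, -0.4]),
                    "O": o_r150,
                    "CB": o_r150 + np.array([2.4, -2.4, -0.8]),
                    "NE": nh1_r150 + np.array([1.4, 0.8, 0.2]),
                    "NH1": nh1_r150,
                    "NH2": nh1_r150 + np.array([0.6, -1.2, 1.5]),
                },
            )
        )
        residues.append(
            _residue_from_atoms(
                chain, 151, "ARG",
                {
                    "N": nh1_r151 + np.array([3.8, 0.9, 0.4]),
                    "CA": nh1_r151 + np.array([3.0, 0.0, 0.0]),
                    "C": nh1_r151 + np.array([3.6, -1.2, -0.6]),
                    "O": nh1_r151 + np.array([4.6, -1.2, -1.2]),
                    "CB": nh1_r151 + np.array([1.8, 0.4, 0.5]),
                    "NE": nh1_r151 + np.array([1.0, -0.8, 0.3]),
                    "NH1": nh1_r151,
                    "NH2": nh1_r151 + np.array([0.4, 1.4, 1.4]),
                },
            )
        )
        truth["rrsq_distances"] = {
            "R151~Q619": 3.7 + sep,
            "S618~Q619": 2.6,
            "S618~R150bb": 3.3 + sep,
            "R150~Q621": 3.1 + sep,
        }
        n_hits = sum(d <= 4.0 for d in truth["rrsq_distances"].values())
        truth["planted_mode"] = "complementary_surface" if n_hits >= 2 else "undetermined"
    else:
        truth["planted_mode"] = "undetermined"

    hetero = []
    if spec.ligand is not None:
        if spec.ligand == "active_site":
            lig_center = og + np.array([1.2, -1.0, 1.4])
        elif spec.ligand == "far":
            lig_center = np.array([XSEMI, 18.0 + YSEMI, 0.0])
        else:
            raise SynthError(f"unknown ligand placement {spec.ligand!r}")
        hetero.append(
            _residue_from_atoms(
                chain, 801, "TCK",
                {
                    "C1": lig_center,
                    "C2": lig_center + np.array([1.4, 0.3, 0.2]),
                    "N1": lig_center + np.array([0.3, 1.3, -0.4]),
                    "O1": lig_center + np.array([-0.9, -0.8, 0.9]),
                    "S1": lig_center + np.array([2.2, -1.0, -0.8]),
                },
            )
        )

    residues.sort(key=lambda r: r.number)
    structure = Structure(
        id=f"toy_sep{sep:g}_{spec.network}", chains={chain: residues}, hetero=hetero
    )
    truth["n_residues"] = len(residues)
    truth["com_distance_expected"] = BASE_CENTER_DISTANCE + sep
    return structure, truth


def closure_trajectory(delta: float, network: str = "RRSQ", seed: int = 0) -> ToySpec:
    """Couple triad disassembly to domain opening, as the closure mechanism
    does: at delta = 0 the pose is closed (assembled triad, packed domains);
    increasing delta stretches the functional-atom distances and the
    separation together, passing through intermediate and ending open.
    """
    if delta < 0:
        raise SynthError("delta must be >= 0")
    return ToySpec(
        separation=delta,
        og_ne2=2.8 + 1.8 * delta,
        nd1_od2=3.0 + 1.0 * delta,
        network=network,
        seed=seed,
    )


def write_toy(structure: Structure, truth: dict, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the toy PDB and its truth record (JSON) side by side."""
    from s9conf.structure import write_structure

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb = out_dir / f"{structure.id}.pdb"
    write_structure(structure, pdb)
    truth_path = out_dir / f"{structure.id}.truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    return pdb, truth_path


# ---------------------------------------------------------------------------
# sequence sets

_TAXON_PROFILES = {
    # emulates the reported lineage bias: SpOpB-like dominates FCB/Acido and
    # Gammaproteobacteria, TbOpB-like dominates Terrabacteria and
    # Alphaproteobacteria
    "SpOpB_like": (("FCB group", 0.35), ("Acidobacteria", 0.2), ("Proteobacteria", 0.45)),
    "TbOpB_like": (("Terrabacteria", 0.5), ("Proteobacteria", 0.4), ("Bacteria incertae sedis", 0.1)),
    "other": (("Proteobacteria", 0.6), ("PVC group", 0.4)),
    "short": (("Proteobacteria", 0.5), ("Terrabacteria", 0.3), ("FCB group", 0.2)),
}
_PROTEO_CLASSES = {
    "SpOpB_like": (("Gammaproteobacteria", 0.8), ("Betaproteobacteria", 0.2)),
    "TbOpB_like": (("Alphaproteobacteria", 0.8), ("Gammaproteobacteria", 0.2)),
    "other": (("Gammaproteobacteria", 1.0),),
    "short": (("Gammaproteobacteria", 1.0),),
}

# anchor positions that stay fixed under off-anchor mutation, per base reference
_SP_FIXED = (150, 151, 618, 619, 621, 532, 617, 652)
_TB_FIXED = (171, 172, 649, 650, 652, 563, 648, 683)


def _mutate(seq: list[str], rate: float, fixed: set[int], rng: np.random.Generator) -> None:
    for i in range(len(seq)):
        if (i + 1) in fixed:
            continue
        if rng.random() < rate:
            choices = [a for a in AAS if a != seq[i]]
            seq[i] = choices[rng.integers(len(choices))]


def make_sequence_set(
    n_per_group: dict[str, int],
    mutation_rate: float = 0.05,
    seed: int = 0,
):
    """Generate labelled OpB-like sequences plus a lineage table.

    Returns (records, taxonomy, truth): records is a list of (id, sequence),
    taxonomy a DataFrame with columns id/superphylum/class/order, truth a dict
    id -> planted group. Group-defining anchors are held fixed; mutations are
    substitutions elsewhere at ``mutation_rate``. "other" sequences carry
    non-matching anchor residues (K at the propeller anchor, M at the D-loop
    anchor); "short" sequences are truncations below 500 residues.
    """
    if not 0.0 <= mutation_rate <= 0.3:
        raise SynthError("mutation_rate must be in [0, 0.3]")
    rng = np.random.default_rng(seed)
    sp_ref = reference_sequence("SpOpB")
    tb_ref = reference_sequence("TbOpB")

    records: list[tuple[str, str]] = []
    truth: dict[str, str] = {}
    tax_rows = []

    def pick(profile):
        names = [n for n, _ in profile]
        probs = np.array([p for _, p in profile])
        return names[rng.choice(len(names), p=probs / probs.sum())]

    for group, n in n_per_group.items():
        if group not in _TAXON_PROFILES:
            raise SynthError(f"unknown group {group!r}")
        for i in range(n):
            sid = f"{group[:2].lower()}{i:05d}"
            if group == "TbOpB_like":
                seq = list(tb_ref)
                _mutate(seq, mutation_rate, set(_TB_FIXED), rng)
            elif group == "short":
                length = int(rng.integers(320, 500))
                seq = list(sp_ref[:length])
                _mutate(seq, mutation_rate, set(), rng)
            else:
                seq = list(sp_ref)
                _mutate(seq, mutation_rate, set(_SP_FIXED), rng)
                if group == "other":
                    seq[150] = "K"   # 151-anchor: neither R nor E/D
                    seq[618] = "M"   # 619-anchor: neither Q nor R
            records.append((sid, "".join(seq)))
            truth[sid] = group
            superphylum = pick(_TAXON_PROFILES[group])
            klass = (
                pick(_PROTEO_CLASSES[group]) if superphylum == "Proteobacteria" else ""
            )
            tax_rows.append(
                {"id": sid, "superphylum": superphylum, "class": klass,
                 "order": f"{klass or superphylum}_order{int(rng.integers(1, 4))}"}
            )

    import pandas as pd

    return records, pd.DataFrame(tax_rows), truth


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# inactivation curves


def simulate_inactivation(
    Ki_mM: float,
    k2_per_min: float,
    concentrations_uM: list[float],
    times_min: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[InactivationSeries]:
    """Pseudo-first-order inactivation curves from the two-step mechanism.

    activity(t) = exp(-k' t) with k' = k2 [I] / (Ki + [I]) (Ki converted to
    uM). ``noise_sd`` adds multiplicative lognormal noise; activities are
    clipped into (0, 1] so every series remains a valid fraction-of-initial
    time course.
    """
    if Ki_mM <= 0 or k2_per_min <= 0:
        raise SynthError("Ki and k2 must be positive")
    rng = np.random.default_rng(seed)
    Ki_uM = Ki_mM * 1000.0
    times = np.asarray(times_min, dtype=float)
    out = []
    for conc in concentrations_uM:
        k_prime = k2_per_min * conc / (Ki_uM + conc)
        activity = np.exp(-k_prime * times)
        if noise_sd > 0:
            activity = activity * rng.lognormal(0.0, noise_sd, size=times.shape)
            activity = np.clip(activity, 1e-9, 1.0)
        out.append(InactivationSeries(conc_uM=conc, times_min=times, activity=activity))
    return out
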