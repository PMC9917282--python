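"""Conformational-state and D-loop stabilization-mode classification.

State rule. "Closed" requires an assembled triad (both functional-atom
distances at hydrogen-bond range). With the triad apart, the domains may still
pack together — "intermediate" — or separate — "open"; the two are split on
the buried-surface percentage of the catalytic domain, which sits near 12% in
intermediate and below 9% in open crystal forms, so the default boundary is
10%. The split is a quantization of qualitative structural criteria, not a
published threshold, and is config-overridable; reports carry the thresholds
used.

Mode rule. In the closed state the D-loop (carrying the catalytic Asp) is held
by the facing propeller loop in one of two ways: a single interdomain salt
bridge between a propeller Glu/Asp and a D-loop Arg (TbOpB-like, "SB1"), or
complementary charged surfaces built from a propeller Arg pair facing the
Ser/Gln residues after the catalytic Asp (SpOpB-like, "RR-SQ"). Anchors are
resolved through reference numbering, so the same classifier runs on
crystal structures and on predicted models of any OpB homolog.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from s9conf.domains import DomainPartition, ReferenceMap, SPOPB_ANCHORS
from s9conf.geometry import TriadGeometry, distance
from s9conf.interface import InterfaceReport
from s9conf.structure import Residue, Structure, StructureError


class ClassifyError(Exception):
    pass


@dataclasses.dataclass
class Thresholds:
    """Every numeric cutoff of the state/mode calls, in one overridable block.

    og_ne2_assembled_max / nd1_od_assembled_max: hydrogen-bond-range cutoffs
    for the assembled triad (closed-state values sit at 2.8-3.5 A, open-state
    at >8.8 A, so the margin is wide on both sides).
    bsa_intermediate_min (%): catalytic-domain buried-surface boundary between
    intermediate and open.
    mutant_ca_closed_max (A): Ser-His Calpha fallback when the nucleophile
    serine is mutated (closed structures show 7.9-8.3 A, open/intermediate
    17.4-18.5 A).
    """

    og_ne2_assembled_max: float = 4.5
    nd1_od_assembled_max: float = 4.0
    bsa_intermediate_min: float = 10.0
    mutant_ca_closed_max: float = 10.0
    contact_cutoff: float = 4.0
    hbond_cutoff: float = 3.5
    sb_cutoff: float = 4.0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class ConformationCall:
    state: str                      # closed | intermediate | open
    triad: TriadGeometry
    com_distance: float
    interface: InterfaceReport
    thresholds: Thresholds
    mutant_inference: bool = False

    def summary(self) -> dict:
        return {
            "state": self.state,
            "mutant_inference": self.mutant_inference,
            "ca_S_H": self.triad.ca_s_h,
            "og_S_ne2_H": self.triad.og_s_ne2_h,
            "ca_H_D": self.triad.ca_h_d,
            "nd1_H_od2_D": self.triad.nd1_h_od2_d,
            "nd1_H_od_min_D": self.triad.nd1_h_od_min_d,
            "com_distance": self.com_distance,
            "bsa_percent_cat": self.interface.bsa_percent_catalytic,
            "bsa_percent_prop": self.interface.bsa_percent_propeller,
            "interface_residue_percent_cat": self.interface.interface_residue_percent_catalytic,
            "interface_residue_percent_prop": self.interface.interface_residue_percent_propeller,
            "hbond_count": self.interface.hbond_count,
            "salt_bridge_count": self.interface.salt_bridge_count,
            "thresholds": self.thresholds.as_dict(),
        }


def classify_state(
    triad: TriadGeometry,
    com_distance: float,
    interface: InterfaceReport,
    thresholds: Thresholds | None = None,
) -> ConformationCall:
    """Call closed / intermediate / open from triad geometry and interface
    packing (all inputs must come from the same structure)."""
    th = thresholds or Thresholds()
    mutant_inference = False
    if triad.serine_mutated:
        # no OG: decide on Calpha separation alone and flag the inference
        mutant_inference = True
        assembled = (
            triad.ca_s_h <= th.mutant_ca_closed_max
            and triad.nd1_h_od_min_d <= th.nd1_od_assembled_max
        )
    else:
        assembled = triad.assembled(th.og_ne2_assembled_max, th.nd1_od_assembled_max)
    if assembled:
        state = "closed"
    elif interface.bsa_percent_catalytic >= th.bsa_intermediate_min:
        state = "intermediate"
    else:
        state = "open"
    return ConformationCall(
        state=state,
        triad=triad,
        com_distance=com_distance,
        interface=interface,
        thresholds=th,
        mutant_inference=mutant_inference,
    )


@dataclasses.dataclass
class StabilizationMode:
    mode: str                        # salt_bridge_SB1 | complementary_surface | undetermined
    evidence: list                   # PolarContact-like evidence tuples
    anchors_observed: dict[str, str]  # anchor name -> "R151" style identity


def _min_atom_distance(res_a: Residue, res_b: Residue, names_a, names_b) -> float | None:
    ds = []
    for na in names_a:
        if not res_a.has_atom(na):
            continue
        for nb in names_b:
            if not res_b.has_atom(nb):
                continue
            ds.append(distance(res_a.atom(na), res_b.atom(nb)))
    return min(ds) if ds else None


_SIDECHAIN_POLAR = {
    "ARG": ("NH1", "NH2", "NE"),
    "GLN": ("NE2", "OE1"),
    "GLU": ("OE1", "OE2"),
    "ASP": ("OD1", "OD2"),
    "SER": ("OG",),
    "THR": ("OG1",),
}


def classify_stabilization_mode(
    structure: Structure,
    refmap: ReferenceMap,
    partition: DomainPartition | None = None,
    thresholds: Thresholds | None = None,
    chain: str | None = None,
) -> StabilizationMode:
    """Call the D-loop stabilization mode from the anchor residues.

    SB1: the 151-equivalent is Glu/Asp, the 619-equivalent Arg, and their
    side chains form a salt bridge within the cutoff.
    Complementary surface: the 151-equivalent is Arg, the 619-equivalent Gln,
    and at least two contacts of the RR-SQ network (R151-Q619 side chains,
    S618-Q619 side chains, S618 side chain to R150 backbone O, R150-Q621 side
    chains) lie within the cutoff.
    """
    if refmap.reference_id != "SpOpB":
        raise ClassifyError(
            "stabilization-mode anchors are defined in SpOpB numbering; "
            "supply a ReferenceMap against the SpOpB reference"
        )
    th = thresholds or Thresholds()
    chain = chain or structure.first_chain()

    def resolve(anchor_key: str) -> Residue | None:
        target_num = refmap.anchor(SPOPB_ANCHORS[anchor_key])
        if target_num is None:
            return None
        try:
            return structure.residue(chain, target_num)
        except StructureError:
            return None

    r151 = resolve("propeller")
    q619 = resolve("dloop")
    if r151 is None or q619 is None:
        raise ClassifyError(
            "anchors not resolvable: the 151-/619-equivalent positions are "
            "unmapped or not modeled"
        )
    r150 = resolve("propeller_pre")
    s618 = resolve("dloop_pre")
    q621 = resolve("alpha11")

    anchors = {
        "150_equiv": f"{r150.one_letter}{r150.number}" if r150 else "unresolved",
        "151_equiv": f"{r151.one_letter}{r151.number}",
        "618_equiv": f"{s618.one_letter}{s618.number}" if s618 else "unresolved",
        "619_equiv": f"{q619.one_letter}{q619.number}",
        "621_equiv": f"{q621.one_letter}{q621.number}" if q621 else "unresolved",
    }
    evidence = []

    def sidechain(res: Residue):
        return _SIDECHAIN_POLAR.get(res.name, ())

    if r151.name in ("GLU", "ASP") and q619.name == "ARG":
        d = _min_atom_distance(r151, q619, sidechain(r151), sidechain(q619))
        if d is not None and d <= th.sb_cutoff:
            evidence.append(("salt_bridge", anchors["151_equiv"], anchors["619_equiv"], round(d, 2)))
            return StabilizationMode("salt_bridge_SB1", evidence, anchors)

    if r151.name == "ARG" and q619.name == "GLN":
        network = [
            ("R151~Q619", r151, q619, sidechain(r151), sidechain(q619)),
        ]
        if s618 is not None:
            network.append(("S618~Q619", s618, q619, sidechain(s618), sidechain(q619)))
            if r150 is not None:
                network.append(("S618~R150bb", s618, r150, sidechain(s618), ("O",)))
        if r150 is not None and q621 is not None:
            network.append(("R150~Q621", r150, q621, sidechain(r150), sidechain(q621)))
        hits = 0
        for label, ra, rb, na, nb in network:
            d = _min_atom_distance(ra, rb, na, nb)
            if d is not None and d <= th.contact_cutoff:
                hits += 1
                evidence.append((label, f"{ra.one_letter}{ra.number}", f"{rb.one_letter}{rb.number}", round(d, 2)))
        if hits >= 2:
            return StabilizationMode("complementary_surface", evidence, anchors)

    return StabilizationMode("undetermined", evidence, anchors)
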