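"""Domain partitioning and reference-anchored residue numbering.

Position bookkeeping across oligopeptidase B homologs is done by pairwise
global alignment against one of two packaged reference sequences (SpOpB from
Serratia proteamaculans, TbOpB from Trypanosoma brucei), so that statements
like "the residue equivalent to SpOpB R151" resolve in any homolog. The
packaged sequences are synthetic stand-ins built to carry the documented
catalytic and anchor residues at the literature author positions (see
data/README_data.md); they are adequate for anchor mapping and for driving the
synthetic generators, but are not the UniProt entries.

Anchor positions (SpOpB numbering): the R/E loop of propeller blade 2 carries
S149/R150/R151; the D-loop and adjoining alpha11 helix carry the catalytic
D617 and S618/Q619/Q621. In TbOpB numbering R151 corresponds to E172 and Q619
to R650; the catalytic triad S532/D617/H652 corresponds to S563/D648/H683.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from s9conf.structure import Structure

# SpOpB-numbering anchors used by the stabilization-mode and sequence-group
# classifiers.
SPOPB_ANCHORS = {
    "propeller_pre": 150,   # R150 (RR pair, first)
    "propeller": 151,       # R151 in SpOpB / E172 in TbOpB — group-defining
    "catalytic_D": 617,
    "dloop_pre": 618,       # S618 (SQ pair, first)
    "dloop": 619,           # Q619 in SpOpB / R650 in TbOpB — group-defining
    "alpha11": 621,         # Q621
    "catalytic_S": 532,
    "catalytic_H": 652,
}

_PRESETS = {
    # hinge1 71-77 (IPQQEH peptide); hinge2 bounds reconstructed from the
    # blade-7/hinge-2 contact residues K407, N408, T410, N413.
    "SpOpB": {"hinge1": (71, 77), "propeller": (78, 406), "hinge2": (407, 413)},
    # TbOpB bounds follow from mapping the SpOpB boundaries through the
    # packaged pairwise alignment (+21 before the propeller, +31 after it).
    "TbOpB": {"hinge1": (92, 98), "propeller": (99, 437), "hinge2": (438, 444)},
}


class DomainError(Exception):
    pass


@dataclasses.dataclass
class DomainPartition:
    """Disjoint residue-number intervals covering one chain.

    ``catalytic`` is the union n_loop + hydrolase: the catalytic domain of S9
    peptidases is split in sequence by the inserted propeller.
    """

    n_loop: tuple[int, int]
    hinge1: tuple[int, int]
    propeller: tuple[int, int]
    hinge2: tuple[int, int]
    hydrolase: tuple[int, int]
    blades: dict[int, tuple[int, int]] | None = None
    chain: str | None = None

    def __post_init__(self) -> None:
        ivs = [self.n_loop, self.hinge1, self.propeller, self.hinge2, self.hydrolase]
        for lo, hi in ivs:
            if lo > hi:
                raise DomainError(f"empty interval ({lo}, {hi})")
        for (a_lo, a_hi), (b_lo, b_hi) in zip(ivs, ivs[1:]):
            if a_hi >= b_lo:
                raise DomainError("intervals must be disjoint and ordered")

    def domain_of(self, resnum: int) -> str | None:
        for name in ("n_loop", "hinge1", "propeller", "hinge2", "hydrolase"):
            lo, hi = getattr(self, name)
            if lo <= resnum <= hi:
                return name
        return None

    def residues(self, structure: Structure, domain: str, chain: str | None = None):
        """Residues of one domain; ``catalytic`` = n_loop + hydrolase."""
        chain = chain or self.chain or structure.first_chain()
        if domain == "catalytic":
            wanted = {"n_loop", "hydrolase"}
        else:
            wanted = {domain}
        out = [r for r in structure.chains[chain] if self.domain_of(r.number) in wanted]
        if not out:
            raise DomainError(f"domain {domain!r} holds no residues of chain {chain}")
        return out


def partition_domains(
    structure: Structure,
    preset_or_ranges: str | dict = "SpOpB",
    chain: str | None = None,
) -> DomainPartition:
    """Partition a structure into N-loop / hinge1 / propeller / hinge2 /
    hydrolase.

    Either a named preset ("SpOpB", "TbOpB") or an explicit dict with keys
    ``hinge1``, ``propeller``, ``hinge2`` (and optionally ``n_loop``,
    ``hydrolase``) may be given; the terminal intervals default to everything
    before hinge1 / after hinge2 among the modeled residues.
    """
    chain = chain or structure.first_chain()
    numbers = sorted(r.number for r in structure.chains[chain])
    lo_mod, hi_mod = numbers[0], numbers[-1]

    if isinstance(preset_or_ranges, str):
        if preset_or_ranges not in _PRESETS:
            raise DomainError(
                f"unknown preset {preset_or_ranges!r}; available: {sorted(_PRESETS)}"
            )
        ranges = dict(_PRESETS[preset_or_ranges])
    else:
        ranges = dict(preset_or_ranges)

    h1, prop, h2 = ranges["hinge1"], ranges["propeller"], ranges["hinge2"]
    n_loop = ranges.get("n_loop", (lo_mod, h1[0] - 1))
    hydro = ranges.get("hydrolase", (h2[1] + 1, hi_mod))

    part = DomainPartition(
        n_loop=tuple(n_loop), hinge1=tuple(h1), propeller=tuple(prop),
        hinge2=tuple(h2), hydrolase=tuple(hydro),
        blades=ranges.get("blades"), chain=chain,
    )
    uncovered = [n for n in numbers if part.domain_of(n) is None]
    if uncovered:
        raise DomainError(
            f"partition does not cover modeled residues (first misses: {uncovered[:5]})"
        )
    return part


@dataclasses.dataclass
class ReferenceMap:
    """Residue-number mapping from a reference to a target sequence.

    ``mapping[ref_resnum] -> target_resnum or None`` (gap). Non-gap entries
    are injective and increasing by construction (they come from one alignment
    path).
    """

    target_id: str
    reference_id: str
    mapping: dict[int, int | None]
    identity_percent: float
    unreliable: bool = False

    def anchor(self, ref_resnum: int) -> int | None:
        if ref_resnum not in self.mapping:
            raise DomainError(
                f"reference position {ref_resnum} outside the {self.reference_id} reference"
            )
        return self.mapping[ref_resnum]

    @classmethod
    def identity(cls, reference_id: str, length: int, target_id: str = "self") -> "ReferenceMap":
        """Self-map for structures already in reference numbering."""
        return cls(
            target_id=target_id,
            reference_id=reference_id,
            mapping={i: i for i in range(1, length + 1)},
            identity_percent=100.0,
        )


def reference_sequence(reference: str) -> str:
    """The packaged (synthetic stand-in) reference sequence, numbered 1..len."""
    fname = {"SpOpB": "spopb_reference_synthetic.fasta",
             "TbOpB": "tbopb_reference_synthetic.fasta"}.get(reference)
    if fname is None:
        raise DomainError(f"unknown reference {reference!r}; available: SpOpB, TbOpB")
    with resources.files("s9conf").joinpath("data", fname).open() as fh:
        record = next(SeqIO.parse(fh, "fasta"))
    return str(record.seq)


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -10.0
    al.extend_gap_score = -0.5
    # end-gap-free global alignment: terminal overhangs are not penalized
    al.end_insertion_score = 0.0
    al.end_deletion_score = 0.0
    al.mode = "global"
    return al


def map_numbering(
    target_sequence: str,
    reference: str = "SpOpB",
    target_id: str = "target",
    target_numbers: list[int] | None = None,
) -> ReferenceMap:
    """Map reference residue numbers onto a target sequence by global
    alignment (BLOSUM62, gap open 10, extend 0.5, free end gaps).

    ``target_numbers`` supplies author numbering for the target (defaults to
    1..len). Identity below 15% sets the ``unreliable`` flag rather than
    raising: a distant homolog may still have usable anchors, but the caller
    is warned.
    """
    if len(target_sequence) < 50:
        raise DomainError("target sequence shorter than 50 residues")
    bad = set(target_sequence.upper()) - set("ACDEFGHIKLMNPQRSTVWYBZXUO")
    if bad:
        raise DomainError(f"non-amino-acid characters in target sequence: {sorted(bad)}")
    ref_seq = reference_sequence(reference)
    if target_numbers is None:
        target_numbers = list(range(1, len(target_sequence) + 1))
    if len(target_numbers) != len(target_sequence):
        raise DomainError("target_numbers length must match the sequence")

    aln = _aligner().align(ref_seq, target_sequence.upper())[0]
    mapping: dict[int, int | None] = {i: None for i in range(1, len(ref_seq) + 1)}
    matches = 0
    aligned_cols = 0
    for (r_lo, r_hi), (t_lo, t_hi) in zip(*aln.aligned):
        for k in range(r_hi - r_lo):
            ri, ti = r_lo + k, t_lo + k
            mapping[ri + 1] = target_numbers[ti]
            aligned_cols += 1
            if ref_seq[ri] == target_sequence[ti].upper():
                matches += 1
    # identity over the full reference length: robust against gap-fragmented
    # alignments of unrelated sequences inflating per-column identity
    identity = 100.0 * matches / len(ref_seq)
    return ReferenceMap(
        target_id=target_id,
        reference_id=reference,
        mapping=mapping,
        identity_percent=identity,
        unreliable=identity < 15.0,
    )
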