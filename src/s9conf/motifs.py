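"""Sequence-group classification of oligopeptidase B and column summaries.

Bacterial OpBs divide on two alignment-anchored positions — the propeller
R/E-loop position (SpOpB 151) and the D-loop position after the catalytic Asp
(SpOpB 619). An Arg-Gln combination marks the SpOpB-like group (complementary
RR-SQ surfaces); Glu-or-Asp with Arg marks the TbOpB-like group (interdomain
salt bridge). Sequences under 500 residues do not span both positions and are
binned "short" without alignment; anything else (including anchors falling in
alignment gaps, counted separately) is "other".
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import pandas as pd

from s9conf.domains import DomainError, SPOPB_ANCHORS, map_numbering

SHORT_LENGTH = 500
GROUPS = ("SpOpB_like", "TbOpB_like", "other", "short")

_AMBIGUOUS = set("BZXUO")


class MotifError(Exception):
    pass


@dataclasses.dataclass
class MotifCall:
    sequence_id: str
    length: int
    group: str
    anchor_propeller: str | None = None   # residue at the 151-equivalent
    anchor_dloop: str | None = None       # residue at the 619-equivalent
    aux_150: str | None = None
    aux_618: str | None = None
    aux_621: str | None = None
    unresolved_anchor: bool = False
    identity_percent: float | None = None


def classify_sequence(seq: str, sequence_id: str = "seq") -> MotifCall:
    """Classify one protein sequence into SpOpB-like / TbOpB-like / other /
    short by reading the two anchor positions through alignment to the SpOpB
    reference."""
    seq = seq.strip().upper()
    bad = set(seq) - set("ACDEFGHIKLMNPQRSTVWYBZXUO")
    if bad:
        raise MotifError(f"{sequence_id}: non-amino-acid characters {sorted(bad)}")
    if len(seq) < SHORT_LENGTH:
        return MotifCall(sequence_id=sequence_id, length=len(seq), group="short")

    refmap = map_numbering(seq, "SpOpB", target_id=sequence_id)

    def at(anchor_key: str) -> str | None:
        pos = refmap.anchor(SPOPB_ANCHORS[anchor_key])
        return seq[pos - 1] if pos is not None else None

    a_prop, a_dloop = at("propeller"), at("dloop")
    call = MotifCall(
        sequence_id=sequence_id,
        length=len(seq),
        group="other",
        anchor_propeller=a_prop,
        anchor_dloop=a_dloop,
        aux_150=at("propeller_pre"),
        aux_618=at("dloop_pre"),
        aux_621=at("alpha11"),
        identity_percent=refmap.identity_percent,
    )
    if a_prop is None or a_dloop is None:
        call.unresolved_anchor = True
        return call
    if a_prop in _AMBIGUOUS or a_dloop in _AMBIGUOUS:
        return call
    if a_prop == "R" and a_dloop == "Q":
        call.group = "SpOpB_like"
    elif a_prop in ("E", "D") and a_dloop == "R":
        call.group = "TbOpB_like"
    return call


@dataclasses.dataclass
class GroupTally:
    taxon: str
    counts: dict[str, int]
    fractions: dict[str, float]
    total: int


def tally_groups(
    calls: list[MotifCall],
    taxonomy: pd.DataFrame | None = None,
    level: str = "all",
) -> list[GroupTally]:
    """Per-taxon counts and fractions of the four groups at a taxonomy rank.

    ``taxonomy`` is a lineage table indexed by (or containing a column) ``id``
    with one column per rank; sequences missing from it fall into
    "unassigned". ``level="all"`` tallies the whole input; an overall "all"
    row is always included.
    """
    if not calls:
        return []
    if level == "all" or taxonomy is None:
        buckets = {"all": list(calls)}
    else:
        tax = taxonomy.set_index("id") if "id" in taxonomy.columns else taxonomy
        if level not in tax.columns:
            raise MotifError(f"unknown rank {level!r}; available: {list(tax.columns)}")
        buckets = {}
        for call in calls:
            taxon = (
                str(tax.loc[call.sequence_id, level])
                if call.sequence_id in tax.index
                else "unassigned"
            )
            buckets.setdefault(taxon, []).append(call)
        buckets["all"] = list(calls)
    out = []
    for taxon in sorted(k for k in buckets if k != "all") + ["all"]:
        members = buckets[taxon]
        counts = Counter(c.group for c in members)
        total = len(members)
        out.append(
            GroupTally(
                taxon=taxon,
                counts={g: counts.get(g, 0) for g in GROUPS},
                fractions={g: counts.get(g, 0) / total for g in GROUPS},
                total=total,
            )
        )
    return out


def tally_frame(tallies: list[GroupTally]) -> pd.DataFrame:
    rows = []
    for t in tallies:
        row = {"taxon": t.taxon, "n": t.total}
        for g in GROUPS:
            row[g] = t.counts[g]
            row[f"{g}_frac"] = t.fractions[g]
        rows.append(row)
    return pd.DataFrame(rows)


def consensus_and_frequencies(
    aligned_block: list[str],
    positions: list[int] | None = None,
) -> tuple[str, pd.DataFrame]:
    """Plurality consensus and per-column residue frequencies of an aligned
    block (equal-length rows; 1-based ``positions`` restrict the columns).

    Gaps are excluded from the plurality vote unless they exceed half the
    column; frequencies are normalized per column over all symbols including
    the gap. The frequency table is what a sequence-logo renderer consumes
    (letter height proportional to frequency).
    """
    if not aligned_block:
        raise MotifError("empty block")
    width = len(aligned_block[0])
    if any(len(row) != width for row in aligned_block):
        raise MotifError("ragged block: rows differ in length")
    cols = positions or list(range(1, width + 1))
    if any(not 1 <= p <= width for p in cols):
        raise MotifError("positions outside the block width")

    consensus = []
    freq_rows = {}
    n = len(aligned_block)
    for p in cols:
        column = [row[p - 1].upper() for row in aligned_block]
        counts = Counter(column)
        gap_count = counts.get("-", 0)
        if gap_count > n / 2:
            consensus.append("-")
        else:
            residues = {k: v for k, v in counts.items() if k != "-"}
            # deterministic tie-break: count desc, then alphabetical
            consensus.append(min(residues, key=lambda k: (-residues[k], k)))
        freq_rows[p] = {sym: cnt / n for sym, cnt in counts.items()}
    table = pd.DataFrame(freq_rows).fillna(0.0).T
    table.index.name = "position"
    return "".join(consensus), table
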