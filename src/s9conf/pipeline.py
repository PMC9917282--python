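"""End-to-end orchestration: structure, sequence, and kinetics reports.

Each runner consumes file paths, executes the corresponding analysis modules,
and writes machine-readable reports (JSON per structure plus a combined TSV
whose rows mirror the standard comparison-table metrics). Every report embeds
the full threshold block for provenance. Logging goes to stderr; results only
to files/stdout.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path

import pandas as pd

from s9conf.classify import Thresholds, classify_state, classify_stabilization_mode, ClassifyError
from s9conf.domains import ReferenceMap, SPOPB_ANCHORS, map_numbering, partition_domains
from s9conf.geometry import center_of_mass_distance, measure_triad
from s9conf.interface import interface_metrics
from s9conf.kinetics import analyze_inactivation, read_series_csv
from s9conf.motifs import classify_sequence, tally_frame, tally_groups
from s9conf.structure import read_structure

log = logging.getLogger("s9conf")

TABLE_ROWS = [
    ("conformation", "state"),
    ("stabilization_mode", "mode"),
    ("ca_S_H_A", "ca_S_H"),
    ("og_S_ne2_H_A", "og_S_ne2_H"),
    ("ca_H_D_A", "ca_H_D"),
    ("nd1_H_od2_D_A", "nd1_H_od2_D"),
    ("center_of_mass_distance_A", "com_distance"),
    ("bsa_percent_cat", "bsa_percent_cat"),
    ("bsa_percent_prop", "bsa_percent_prop"),
    ("interface_residue_percent_cat", "interface_residue_percent_cat"),
    ("interface_residue_percent_prop", "interface_residue_percent_prop"),
    ("hydrogen_bonds", "hbond_count"),
    ("salt_bridges", "salt_bridge_count"),
]


class PipelineError(Exception):
    pass


@dataclasses.dataclass
class RunConfig:
    inputs: list[str]
    preset: str = "SpOpB"
    chain: str | None = None
    out_dir: str = "."
    thresholds: Thresholds = dataclasses.field(default_factory=Thresholds)
    sasa_points: int = 960
    seed: int = 0


def analyze_structure(
    path: str | Path,
    preset: str = "SpOpB",
    chain: str | None = None,
    thresholds: Thresholds | None = None,
    sasa_points: int = 960,
) -> dict:
    """Classify one structure: triad geometry, COM separation, interface
    metrics, conformational state, and stabilization mode.

    Anchor numbering is resolved by aligning the chain sequence to the SpOpB
    reference; structures already in SpOpB numbering (the preset case) behave
    identically because the self-alignment is the identity.
    """
    th = thresholds or Thresholds()
    structure = read_structure(path)
    chain = chain or structure.first_chain()
    partition = partition_domains(structure, preset, chain=chain)

    numbers = [r.number for r in structure.chains[chain]]
    seq = structure.sequence(chain)
    if preset == "SpOpB":
        # toys and SpOpB-numbered models: positions are already reference
        refmap = ReferenceMap.identity("SpOpB", max(numbers), target_id=structure.id)
    else:
        refmap = map_numbering(seq, "SpOpB", target_id=structure.id, target_numbers=numbers)

    triad_nums = tuple(
        refmap.anchor(SPOPB_ANCHORS[k]) for k in ("catalytic_S", "catalytic_D", "catalytic_H")
    )
    if any(n is None for n in triad_nums):
        raise PipelineError(f"{structure.id}: catalytic triad not resolvable through numbering")

    triad = measure_triad(structure, triad_nums, chain=chain)
    com = center_of_mass_distance(structure, partition)
    interface = interface_metrics(
        structure, partition, points=sasa_points,
        hbond_cutoff=th.hbond_cutoff, sb_cutoff=th.sb_cutoff,
    )
    call = classify_state(triad, com, interface, th)
    try:
        mode = classify_stabilization_mode(structure, refmap, partition, th, chain=chain)
        mode_record = {"mode": mode.mode, "evidence": mode.evidence, "anchors": mode.anchors_observed}
    except ClassifyError as exc:
        mode_record = {"mode": "undetermined", "error": str(exc)}

    record = call.summary()
    record["id"] = structure.id
    record["path"] = str(path)
    record["triad_residues"] = list(triad_nums)
    record["stabilization"] = mode_record
    record["mode"] = mode_record["mode"]
    return record


def run_structure_report(
    paths: list[str | Path],
    out_dir: str | Path,
    preset: str = "SpOpB",
    chain: str | None = None,
    thresholds: Thresholds | None = None,
    sasa_points: int = 960,
) -> pd.DataFrame:
    """Per-structure JSON reports plus one combined TSV (metric rows, one
    column per structure). Individual failures are recorded and the run
    continues; it raises only if every input fails."""
    if not paths:
        raise PipelineError("no input structures given")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, failures = [], []
    for p in paths:
        try:
            rec = analyze_structure(p, preset=preset, chain=chain,
                                    thresholds=thresholds, sasa_points=sasa_points)
            records.append(rec)
            (out_dir / f"{rec['id']}.json").write_text(json.dumps(rec, indent=1, default=str) + "\n")
        except Exception as exc:  # noqa: BLE001 - per-structure isolation is the contract
            log.error("failed on %s: %s", p, exc)
            failures.append((str(p), str(exc)))
    if not records:
        raise PipelineError(f"all structures failed: {failures}")
    table = pd.DataFrame(
        {rec["id"]: {row: rec.get(key) for row, key in TABLE_ROWS} for rec in records}
    )
    table.index.name = "metric"
    table.to_csv(out_dir / "structure_report.tsv", sep="\t")
    if failures:
        (out_dir / "failures.json").write_text(json.dumps(failures, indent=1) + "\n")
    return table


def run_sequence_report(
    fasta: str | Path,
    out_dir: str | Path,
    taxonomy: str | Path | None = None,
    rank: str = "superphylum",
) -> pd.DataFrame:
    """Classify every sequence in a FASTA and tally groups by taxonomy rank.

    Without a taxonomy table the tally is at the "all" rank only (with a
    warning). Writes calls TSV and tally TSV; returns the tally frame.
    """
    from Bio import SeqIO

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    calls = [
        classify_sequence(str(rec.seq), rec.id) for rec in SeqIO.parse(str(fasta), "fasta")
    ]
    if not calls:
        raise PipelineError(f"no sequences in {fasta}")
    calls_df = pd.DataFrame(
        {
            "id": c.sequence_id,
            "length": c.length,
            "anchor_151": c.anchor_propeller,
            "anchor_619": c.anchor_dloop,
            "aux_150": c.aux_150,
            "aux_618": c.aux_618,
            "aux_621": c.aux_621,
            "group": c.group,
            "unresolved_anchor": c.unresolved_anchor,
        }
        for c in calls
    )
    calls_df.to_csv(out_dir / "motif_calls.tsv", sep="\t", index=False)

    tax_df = None
    if taxonomy is not None:
        tax_df = pd.read_csv(taxonomy, sep="\t")
    else:
        log.warning("no taxonomy table: tallying at rank 'all' only")
        rank = "all"
    tallies = tally_groups(calls, tax_df, level=rank)
    frame = tally_frame(tallies)
    frame.to_csv(out_dir / f"group_tally_{rank}.tsv", sep="\t", index=False)
    return frame


def run_kinetics_report(csv: str | Path, out_dir: str | Path) -> dict:
    """Kitz-Wilson fit of inactivation time courses from CSV; writes the fit
    report JSON and returns it as a dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series = read_series_csv(csv)
    fit = analyze_inactivation(series)
    report = fit.as_dict()
    report["units"] = {"Ki": "mM", "k2": "min^-1", "concentrations": "uM"}
    (out_dir / "kinetics_report.json").write_text(json.dumps(report, indent=1) + "\n")
    return report


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(stream=sys.stderr, level=getattr(logging, level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
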