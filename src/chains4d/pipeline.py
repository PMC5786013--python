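"""End-to-end orchestration: cluster -> type -> connect -> map -> assign."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import aa_typing, atom_assignment, chain_mapping, spin_systems
from .assignment_table import AssignmentTable
from .chain_mapping import MappingState, Round, write_mapping_report
from .shift_statistics import StatsLibrary
from .spectra_io import (Peak4D, RootPeak, Sequence, format_peak_label,
                         write_assigned_peaklists, write_xeasy_shifts)
from .spin_systems import AAIG, Tolerances

log = logging.getLogger(__name__)


@dataclass
class RunResult:
    sequence: Sequence
    aaigs: dict[str, AAIG]
    orphans: list[Peak4D]
    predictions: dict[str, list[aa_typing.AATypePrediction]]
    connectivities: list[chain_mapping.Connectivity]
    state: MappingState
    table: AssignmentTable
    noesy_annotation: atom_assignment.NoesyAnnotation | None = None
    tocsy_peaks: list[Peak4D] = field(default_factory=list)
    noesy_peaks: list[Peak4D] = field(default_factory=list)

    def write_outputs(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_xeasy_shifts(self.table, out / "shifts.prot", self.sequence)
        write_mapping_report(self.state, out / "mapping.tsv")
        write_assignment_report(self.table, out / "assignments.tsv")
        if self.tocsy_peaks:
            write_assigned_peaklists(
                self.tocsy_peaks,
                tocsy_peak_labels(self.state, self.aaigs, self.table,
                                  self.sequence),
                out / "tocsy_assigned.list")
        if self.noesy_peaks and self.noesy_annotation is not None:
            write_assigned_peaklists(
                self.noesy_peaks,
                self.noesy_annotation.peak_labels(self.aaigs, self.sequence),
                out / "noesy_assigned.list")


def write_assignment_report(table: AssignmentTable, path: str | Path) -> None:
    """TSV report with provenance and scores for every assigned shift."""
    with open(path, "w") as fh:
        fh.write("residue\tatom\tshift\tnucleus\tprovenance\tscore\n")
        for e in table.entries():
            fh.write(f"{e.residue}\t{e.atom}\t{e.shift:.3f}\t{e.nucleus}\t"
                     f"{e.provenance}\t{e.score:.6g}\n")


def read_assignment_report(path: str | Path) -> AssignmentTable:
    from .assignment_table import ShiftAssignment
    table = AssignmentTable()
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            res, atom, shift, nucleus, prov, score = line.rstrip("\n").split("\t")
            table.add(ShiftAssignment(int(res), atom, float(shift), nucleus,
                                      prov, float(score)))
    return table


def tocsy_peak_labels(state: MappingState, aaigs: dict[str, AAIG],
                      table: AssignmentTable, sequence: Sequence,
                      tol: Tolerances = Tolerances()) -> dict[int, str]:
    """Annotate TOCSY peaks of mapped spin systems from the table."""
    labels: dict[int, str] = {}
    for pos in sorted(state.assigned):
        prev = pos - 1
        if prev < sequence.first:
            continue
        aaig = aaigs[state.assigned[pos]]
        targets = atom_assignment._residue_ch_atoms(
            table, prev, sequence.residue(prev))
        for pair in aaig.tocsy:
            if pair.peak_index < 0:
                continue
            best = None
            for carbon, proton, c, h in targets:
                dc, dh = abs(pair.c - c), abs(pair.h - h)
                if dc <= tol.tol_c and dh <= tol.tol_h:
                    d = (dc / tol.tol_c) ** 2 + (dh / tol.tol_h) ** 2
                    if best is None or d < best[0]:
                        best = (d, carbon, proton)
            if best is not None:
                labels[pair.peak_index] = format_peak_label(
                    sequence.residue(prev), prev, best[1], best[2])
    return labels


def run_tocsy_noesy(
    sequence: Sequence,
    roots: list[RootPeak],
    tocsy_peaks: list[Peak4D],
    noesy_peaks: list[Peak4D],
    stats: StatsLibrary,
    tol: Tolerances = Tolerances(),
    schedule: tuple[Round, ...] = chain_mapping.DEFAULT_SCHEDULE,
    intensity_threshold: float = atom_assignment.DEFAULT_INTENSITY_THRESHOLD,
    percentile: float = atom_assignment.DEFAULT_PERCENTILE,
    methylene_tol: float = aa_typing.DEFAULT_METHYLENE_TOL,
) -> RunResult:
    """The full TOCSY-NOESY assignment protocol."""
    aaig_list, orphans = spin_systems.cluster_peaks(
        tocsy_peaks, noesy_peaks, roots, tol)
    aaigs = {a.label: a for a in aaig_list}
    log.info("clustered %d spin systems (%d orphan peaks)",
             len(aaigs), len(orphans))

    prior = aa_typing.tocsy_prior(sequence)
    predictions = {
        label: aa_typing.predict_aa_types(aaigs[label], sequence, stats,
                                          methylene_tol, prior=prior)
        for label in sorted(aaigs)
    }
    log.info("typed %d spin systems",
             sum(1 for p in predictions.values() if p))

    min_occ = min(r.min_occupancy for r in schedule)
    connectivities = chain_mapping.compute_connectivities(
        aaig_list, tol, min_occupancy=min_occ)
    log.info("%d candidate connectivities (occupancy >= %.2f)",
             len(connectivities), min_occ)

    state = chain_mapping.Mapper(aaig_list, predictions, connectivities,
                                 sequence, schedule).run()
    log.info("mapped %d of %d spin systems", len(state.assigned), len(aaigs))

    table = atom_assignment.assign_all_tocsy(state, aaigs, stats,
                                             methylene_tol)
    annotation = atom_assignment.transfer_to_noesy(state, aaigs, table, tol)
    added = atom_assignment.extend_from_common_noes(
        state, aaigs, table, stats, annotation, tol,
        intensity_threshold, percentile, methylene_tol)
    log.info("common-NOE extension added %d entries", len(added))

    return RunResult(sequence, aaigs, orphans, predictions, connectivities,
                     state, table, annotation, tocsy_peaks, noesy_peaks)
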