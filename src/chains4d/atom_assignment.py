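"""Per-atom chemical-shift assignment once spin systems are mapped.

Three stages populate the assignment table:

1. *TOCSY typing.*  For every mapped spin system the amino-acid type of
   the residue it describes (the one preceding its amide) is fixed by the
   mapping, so the best placement of its TOCSY CH pairs onto that
   residue's carbon types yields the atom assignments directly.  Pairs
   whose carbon frequencies agree within the methylene threshold share
   one methylene carbon (carbon shift averaged, both protons kept).
2. *NOESY transfer.*  Walking the sequence backwards, every NOESY peak
   matching a known shift of the residue on its own root is labeled
   intraresidue, then remaining peaks matching the preceding residue are
   labeled sequential.  This produces annotated peak lists and marks
   which NOESY peaks are still unexplained.
3. *Common-NOE extension.*  Atoms missing from TOCSY are recovered from
   NOESY alone: the aliphatic atoms of residue i give NOE cross-peaks to
   both its own amide (intraresidue) and the next residue's amide
   (sequential), so unexplained peaks shared by the two spin systems are
   candidate observations of residue i's missing atoms.  Candidates are
   scored as density x (100 x normalized_intensity^2), must clear the
   80th-percentile density filter of their candidate atom type, and the
   highest score (score product for a methylene pair) wins.  Peaks weaker
   than 10% of their spin system's strongest peak are left out.

The NOESY-only scenario applies stage 3 with *every* aliphatic atom
missing, given externally fixed amide assignments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import topology
from .aa_typing import DEFAULT_METHYLENE_TOL, _best_placement, _density_matrix
from .assignment_table import AssignmentTable, ShiftAssignment
from .chain_mapping import MappingState
from .shift_statistics import StatsLibrary
from .spectra_io import Peak4D, RootPeak, Sequence, format_peak_label
from .spin_systems import AAIG, CHPair, Tolerances, cluster_peaks

log = logging.getLogger(__name__)

DEFAULT_INTENSITY_THRESHOLD = 0.1
DEFAULT_PERCENTILE = 80.0


# ---------------------------------------------------------------------------
# TOCSY typing
# ---------------------------------------------------------------------------

def assign_tocsy_atoms(
    aaig: AAIG,
    residue: int,
    residue_type: str,
    stats: StatsLibrary,
    methylene_tol: float = DEFAULT_METHYLENE_TOL,
) -> list[ShiftAssignment]:
    """Atom assignments of residue ``residue`` (type fixed by the mapping)
    from one spin system's TOCSY pairs."""
    pairs = aaig.tocsy
    if not pairs:
        return []
    dens = _density_matrix(pairs, residue_type, stats)
    prob, combo = _best_placement(pairs, residue_type, dens, methylene_tol)
    if combo is None or prob <= 0.0:
        log.warning("residue %s%d (AAIG %s): no valid TOCSY atom placement",
                    residue_type, residue, aaig.label)
        return []
    types = {t.name: t for t in topology.carbon_types(residue_type)}
    cols = {t.name: j for j, t in
            enumerate(topology.carbon_types(residue_type))}
    out = []
    for carbon, idxs in combo.assignment:
        ct = types[carbon]
        score = float(np.prod([dens[i, cols[carbon]] for i in idxs]))
        chosen = [pairs[i] for i in idxs]
        c_value = sum(p.c for p in chosen) / len(chosen)
        out.append(ShiftAssignment(residue, carbon, c_value, "C",
                                   "TOCSY", score))
        protons = ct.proton_names()
        if len(chosen) == 1:
            out.append(ShiftAssignment(residue, protons[0], chosen[0].h,
                                       "H", "TOCSY", score))
        else:
            hs = sorted((p.h for p in chosen), reverse=True)
            for name, h in zip(protons, hs):
                out.append(ShiftAssignment(residue, name, h, "H",
                                           "TOCSY", score))
    return out


def assign_all_tocsy(
    state: MappingState,
    aaigs: dict[str, AAIG],
    stats: StatsLibrary,
    methylene_tol: float = DEFAULT_METHYLENE_TOL,
) -> AssignmentTable:
    """TOCSY-derived assignments plus amide roots for all mapped spin
    systems."""
    table = AssignmentTable()
    seq = state.sequence
    for pos in sorted(state.assigned):
        aaig = aaigs[state.assigned[pos]]
        table.add(ShiftAssignment(pos, "N", aaig.root_n15, "N", "root"))
        table.add(ShiftAssignment(pos, "HN", aaig.root_hn, "H", "root"))
        prev = pos - 1
        if prev < seq.first:
            continue
        for entry in assign_tocsy_atoms(aaig, prev, seq.residue(prev),
                                        stats, methylene_tol):
            table.add(entry, on_conflict="merge")
    return table


# ---------------------------------------------------------------------------
# NOESY transfer
# ---------------------------------------------------------------------------

@dataclass
class NoesyAnnotation:
    """Labels for NOESY peaks plus the set still unexplained."""

    labels: dict[tuple[str, int], tuple[str, int, str, str]] = field(
        default_factory=dict)   # (aaig, pair idx) -> (kind, residue, C, H)
    used: set[tuple[str, int]] = field(default_factory=set)
    claim_dist: dict[tuple[str, int], float] = field(default_factory=dict)
    extension_used: set[tuple[str, int]] = field(default_factory=set)

    def available(self, key: tuple[str, int],
                  loose_claims: float | None = None) -> bool:
        """Is a peak free to explain a missing atom?

        Transfer claims are geometric nearest matches; a claim far from
        its target (scaled distance above ``loose_claims``) may be a
        coincidental grab of an unassigned atom's peak and is offered
        back to the extension stage.
        """
        if key in self.extension_used:
            return False
        if key not in self.used:
            return True
        return (loose_claims is not None
                and self.claim_dist.get(key, 0.0) > loose_claims)

    def peak_labels(self, aaigs: dict[str, AAIG],
                    sequence: Sequence) -> dict[int, str]:
        """Map source-peak indices to Sparky labels."""
        out = {}
        for (label, k), (_kind, res, carbon, proton) in self.labels.items():
            idx = aaigs[label].noesy[k].peak_index
            if idx >= 0:
                out[idx] = format_peak_label(sequence.residue(res), res,
                                             carbon, proton)
        return out


def _residue_ch_atoms(table: AssignmentTable, residue: int,
                      residue_type: str) -> list[tuple[str, str, float, float]]:
    """Known (carbon, proton, c, h) observables of one residue."""
    atoms = table.atoms_of(residue)
    out = []
    for ct in topology.carbon_types(residue_type):
        c_entry = atoms.get(ct.name)
        if c_entry is None:
            continue
        for proton in ct.proton_names():
            h_entry = atoms.get(proton)
            if h_entry is not None:
                out.append((ct.name, proton, c_entry.shift, h_entry.shift))
    return out


def transfer_to_noesy(
    state: MappingState,
    aaigs: dict[str, AAIG],
    table: AssignmentTable,
    tol: Tolerances = Tolerances(),
) -> NoesyAnnotation:
    """Label NOESY peaks from the assignment table, last residue first:
    intraresidue matches (residue i on root i) take precedence, then
    sequential matches (residue i-1); one label per peak, closest match
    wins."""
    seq = state.sequence
    ann = NoesyAnnotation()
    for pos in sorted(state.assigned, reverse=True):
        aaig = aaigs[state.assigned[pos]]
        pool = [(k, p) for k, p in enumerate(aaig.noesy)]
        for kind, res in (("intra", pos), ("sequential", pos - 1)):
            if res < seq.first:
                continue
            targets = _residue_ch_atoms(table, res, seq.residue(res))
            if not targets:
                continue
            taken = ann.used
            # greedy nearest match, peaks and atoms each used once per kind
            cands = []
            for k, p in pool:
                if (aaig.label, k) in taken:
                    continue
                for carbon, proton, c, h in targets:
                    dc, dh = abs(p.c - c), abs(p.h - h)
                    if dc <= tol.tol_c and dh <= tol.tol_h:
                        d = math.sqrt((dc / tol.tol_c) ** 2
                                      + (dh / tol.tol_h) ** 2)
                        cands.append((d, k, carbon, proton))
            used_atoms: set[tuple[str, str]] = set()
            for d, k, carbon, proton in sorted(cands):
                if (aaig.label, k) in ann.used or (carbon, proton) in used_atoms:
                    continue
                ann.labels[(aaig.label, k)] = (kind, res, carbon, proton)
                ann.used.add((aaig.label, k))
                ann.claim_dist[(aaig.label, k)] = d
                used_atoms.add((carbon, proton))
    return ann


# ---------------------------------------------------------------------------
# common-NOE extension
# ---------------------------------------------------------------------------

def _normalized_intensities(aaig: AAIG) -> list[float]:
    peak_max = max((abs(p.intensity) for p in aaig.noesy), default=0.0)
    if peak_max <= 0:
        return [0.0] * len(aaig.noesy)
    return [abs(p.intensity) / peak_max for p in aaig.noesy]


def extend_from_common_noes(
    state: MappingState,
    aaigs: dict[str, AAIG],
    table: AssignmentTable,
    stats: StatsLibrary,
    annotation: NoesyAnnotation | None = None,
    tol: Tolerances = Tolerances(),
    intensity_threshold: float = DEFAULT_INTENSITY_THRESHOLD,
    percentile: float = DEFAULT_PERCENTILE,
    methylene_tol: float = DEFAULT_METHYLENE_TOL,
    loose_claims: float | None = 0.6,
) -> list[ShiftAssignment]:
    """Recover missing atom assignments from common NOEs.

    Scans the sequence backwards; for every residue i whose spin system
    and successor spin system are both mapped, unexplained NOESY peaks of
    root i are matched against unexplained peaks of root i+1.  Matches
    are candidate observations of residue i's missing atoms, scored as
    density x (100 x normalized_intensity^2) after the percentile filter.
    Added entries are also written into ``table``.
    """
    if annotation is None:
        annotation = NoesyAnnotation()
    seq = state.sequence
    added: list[ShiftAssignment] = []
    norm_cache = {lab: _normalized_intensities(a)
                  for lab, a in aaigs.items()}

    for pos in sorted(state.assigned, reverse=True):
        nxt = pos + 1
        if nxt not in state.assigned:
            continue
        res_type = seq.residue(pos)
        own = aaigs[state.assigned[pos]]
        succ = aaigs[state.assigned[nxt]]

        missing = [ct for ct in topology.carbon_types(res_type)
                   if (pos, ct.name) not in table]
        if not missing:
            continue

        own_norm = norm_cache[own.label]
        succ_norm = norm_cache[succ.label]
        # the intensity threshold applies to the residue's own peaks (the
        # ones an assignment would be derived from); the successor's peak
        # only corroborates commonality and may be weak
        own_pool = [(k, p) for k, p in enumerate(own.noesy)
                    if annotation.available((own.label, k), loose_claims)
                    and own_norm[k] >= intensity_threshold]
        succ_pool = [(k, p) for k, p in enumerate(succ.noesy)
                     if annotation.available((succ.label, k), loose_claims)]
        if not own_pool or not succ_pool:
            continue

        # common NOEs: peaks of root i also seen from root i+1
        common = []
        for k, p in own_pool:
            partners = [(m, q) for m, q in succ_pool
                        if abs(p.c - q.c) <= tol.tol_c
                        and abs(p.h - q.h) <= tol.tol_h]
            if partners:
                m, _ = min(partners, key=lambda t: (
                    abs(p.c - t[1].c) / tol.tol_c
                    + abs(p.h - t[1].h) / tol.tol_h))
                common.append((k, p, m))
        if not common:
            continue

        # score every (peak, missing type) candidate
        scored = []
        for ct in missing:
            dmap = stats[(res_type, ct.name)]
            cutoff = dmap.percentile_cutoff(percentile, reference="grid")
            for k, p, m in common:
                dens = dmap.density_at(p.h, p.c)
                if dens < cutoff:
                    continue
                score = dens * (100.0 * own_norm[k] ** 2)
                scored.append((score, ct.name, k, m))
        scored.sort(key=lambda t: (-t[0], t[1], t[2]))

        chosen: dict[str, list[int]] = {}
        used_peaks: set[int] = set()
        for score, carbon, k, m in scored:
            ct = next(c for c in missing if c.name == carbon)
            slot = chosen.get(carbon, [])
            if k in used_peaks or len(slot) >= ct.n_peaks:
                continue
            if slot and abs(own.noesy[slot[0]].c - own.noesy[k].c) > methylene_tol:
                continue
            chosen.setdefault(carbon, []).append(k)
            used_peaks.add(k)

        for carbon in sorted(chosen):
            ct = next(c for c in missing if c.name == carbon)
            idxs = chosen[carbon]
            pairs = [own.noesy[k] for k in idxs]
            dmap = stats[(res_type, carbon)]
            score = math.prod(
                float(dmap.density_at(p.h, p.c)) * 100.0 * own_norm[k] ** 2
                for k, p in zip(idxs, pairs))
            c_value = sum(p.c for p in pairs) / len(pairs)
            entries = [ShiftAssignment(pos, carbon, c_value, "C",
                                       "NOESY-common", score)]
            protons = ct.proton_names()
            if len(pairs) == 1:
                entries.append(ShiftAssignment(pos, protons[0], pairs[0].h,
                                               "H", "NOESY-common", score))
            else:
                hs = sorted((p.h for p in pairs), reverse=True)
                for name, h in zip(protons, hs):
                    entries.append(ShiftAssignment(pos, name, h, "H",
                                                   "NOESY-common", score))
            for e in entries:
                table.add(e, on_conflict="merge")
            added.extend(entries)
            # mark both observations of each assigned atom as explained
            for k in idxs:
                annotation.extension_used.add((own.label, k))
            for k, p, m in common:
                if k in idxs:
                    annotation.extension_used.add((succ.label, m))
    return added


# ---------------------------------------------------------------------------
# NOESY-only scenario
# ---------------------------------------------------------------------------

def run_noesy_only(
    sequence: Sequence,
    nh_assignments: dict[int, tuple[float, float]],
    noesy_peaks: list[Peak4D],
    stats: StatsLibrary,
    tol: Tolerances = Tolerances(),
    intensity_threshold: float = DEFAULT_INTENSITY_THRESHOLD,
    percentile: float = DEFAULT_PERCENTILE,
    methylene_tol: float = DEFAULT_METHYLENE_TOL,
) -> tuple[AssignmentTable, MappingState]:
    """Sidechain assignment from the NOESY spectrum alone, given fixed
    amide (15N, 1H) assignments per position."""
    for pos, _ in nh_assignments.items():
        if not sequence.first <= pos <= sequence.last:
            raise ValueError(f"NH assignment at {pos} outside sequence")
        if sequence.residue(pos) == "P":
            raise ValueError(f"NH assignment on proline at position {pos}")
    roots = [RootPeak(n15=n, hn=hn, label=f"R{pos}")
             for pos, (n, hn) in sorted(nh_assignments.items())]
    aaig_list, _ = cluster_peaks([], noesy_peaks, roots, tol)
    aaigs = {a.label: a for a in aaig_list}

    state = MappingState(sequence)
    for i, pos in enumerate(sorted(nh_assignments)):
        state.assign(pos, f"R{pos}", 0, 0.0)

    table = AssignmentTable()
    for pos in sorted(nh_assignments):
        n, hn = nh_assignments[pos]
        table.add(ShiftAssignment(pos, "N", n, "N", "root"))
        table.add(ShiftAssignment(pos, "HN", hn, "H", "root"))

    extend_from_common_noes(state, aaigs, table, stats,
                            tol=tol, intensity_threshold=intensity_threshold,
                            percentile=percentile,
                            methylene_tol=methylene_tol)
    return table, state


def build_shift_table(*tables: AssignmentTable) -> AssignmentTable:
    """Merge assignment tables; on conflict the more reliable provenance
    (root > TOCSY > NOESY) wins and the conflict is logged."""
    merged = AssignmentTable()
    for t in tables:
        for e in t.entries():
            merged.add(e, on_conflict="merge")
    for kept, dropped in merged.conflicts:
        log.info("conflict at residue %d %s: kept %s value, dropped %s",
                 kept.residue, kept.atom, kept.provenance, dropped.provenance)
    return merged
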