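"""Atom-level assignment: TOCSY typing, NOESY transfer, common-NOE
extension and the NOESY-only scenario."""

import numpy as np
import pytest

import chains4d
from chains4d import topology
from chains4d.assignment_table import AssignmentTable, ShiftAssignment
from chains4d.atom_assignment import (NoesyAnnotation, assign_all_tocsy,
                                      assign_tocsy_atoms, build_shift_table,
                                      extend_from_common_noes, run_noesy_only,
                                      transfer_to_noesy,
                                      _normalized_intensities)
from chains4d.chain_mapping import MappingState
from chains4d.spectra_io import Sequence
from chains4d.spin_systems import AAIG, CHPair, Tolerances


def mode(stats, aa, atom):
    dmap = stats[(aa, atom)]
    i = int(np.argmax(dmap.point_densities()))
    return float(dmap.c_data[i]), float(dmap.h_data[i])


def truth_state(truth):
    """MappingState built directly from generator ground truth."""
    state = MappingState(truth.sequence)
    for pos in truth.root_positions():
        state.assign(pos, truth.label_of[pos], 0, 1.0)
    return state


class TestTocsyTyping:
    def test_alanine_pattern_at_modes(self, stats):
        ca_c, ca_h = mode(stats, "A", "CA")
        cb_c, cb_h = mode(stats, "A", "CB")
        aaig = AAIG("x", 118, 8.2, tocsy=[CHPair(ca_c, ca_h),
                                          CHPair(cb_c, cb_h)])
        entries = {e.atom: e for e in
                   assign_tocsy_atoms(aaig, 5, "A", stats)}
        assert entries["CA"].shift == pytest.approx(ca_c)
        assert entries["HA"].shift == pytest.approx(ca_h)
        assert entries["CB"].shift == pytest.approx(cb_c)
        assert entries["HB"].shift == pytest.approx(cb_h)
        assert all(e.provenance == "TOCSY" for e in entries.values())

    def test_glycine_methylene_grouped(self, stats):
        c, h = mode(stats, "G", "CA")
        aaig = AAIG("x", 118, 8.2, tocsy=[CHPair(c, h + 0.1),
                                          CHPair(c + 0.1, h - 0.1)])
        entries = {e.atom: e for e in
                   assign_tocsy_atoms(aaig, 3, "G", stats)}
        assert entries["CA"].shift == pytest.approx(c + 0.05)
        assert entries["HA2"].shift == pytest.approx(h + 0.1)
        assert entries["HA3"].shift == pytest.approx(h - 0.1)

    def test_full_protein_at_modes_types_every_residue(self, stats):
        cfg = chains4d.SyntheticConfig(
            n_residues=30, seed=1, shift_source="modes",
            p_tocsy_missing=0.0, p_noise_peaks=0.0, sigma_c=0.0,
            sigma_h=0.0, sigma_n=0.0, sigma_hn=0.0)
        truth, roots, tocsy, noesy = chains4d.generate_dataset(cfg, stats)
        aaigs, _ = chains4d.cluster_peaks(tocsy, noesy, roots)
        state = truth_state(truth)
        table = assign_all_tocsy(state, {a.label: a for a in aaigs}, stats)
        for pos in truth.root_positions():
            prev = pos - 1
            aa = truth.sequence.residue(prev)
            atoms = table.atoms_of(prev)
            swap = dict(zip(topology.PROCHIRAL_PAIRS.get(aa, ()),
                            reversed(topology.PROCHIRAL_PAIRS.get(aa, ()))))
            for ct in topology.carbon_types(aa):
                entry = atoms.get(ct.name)
                if entry is None:
                    # mode-centered prochiral methyls collide into one
                    # peak at clustering; the partner must then be typed
                    assert ct.name in swap and atoms.get(swap[ct.name]), \
                        (prev, aa, ct.name)
                    continue
                # prochiral methyl pairs (Leu CD1/CD2, Val CG1/CG2) carry
                # no stereo information and may swap
                allowed = {truth.shifts[(prev, ct.name)]}
                if ct.name in swap:
                    allowed.add(truth.shifts[(prev, swap[ct.name])])
                assert any(entry.shift == pytest.approx(v, abs=1e-9)
                           for v in allowed), (prev, aa, ct.name)

    def test_empty_tocsy_no_entries(self, stats):
        assert assign_tocsy_atoms(AAIG("x", 118, 8.2), 5, "A", stats) == []


class TestTransfer:
    @pytest.fixture(scope="class")
    def run(self, stats):
        cfg = chains4d.SyntheticConfig(
            n_residues=30, seed=1, p_tocsy_missing=0.0, p_noise_peaks=0.0,
            sigma_c=0.0, sigma_h=0.0, sigma_n=0.0, sigma_hn=0.0)
        truth, roots, tocsy, noesy = chains4d.generate_dataset(cfg, stats)
        aaigs, _ = chains4d.cluster_peaks(tocsy, noesy, roots)
        aaig_map = {a.label: a for a in aaigs}
        state = truth_state(truth)
        table = assign_all_tocsy(state, aaig_map, stats)
        ann = transfer_to_noesy(state, aaig_map, table, Tolerances())
        return truth, state, aaig_map, table, ann

    def test_intraresidue_peaks_traced(self, run):
        """On noise-free data nearly all planted intraresidue NOEs whose
        residue was typed must be labeled intraresidue."""
        truth, state, aaigs, table, ann = run
        planted = labeled = 0
        for label, aaig in aaigs.items():
            pos = truth.position_of[label]
            for k, pair in enumerate(aaig.noesy):
                origin = truth.peak_origin["NOESY"][pair.peak_index]
                if origin[0] != "intra":
                    continue
                if not table.atoms_of(origin[2]):
                    continue    # residue itself had no typed shifts
                planted += 1
                got = ann.labels.get((label, k))
                if got is not None and got[0] == "intra" \
                   and got[1] == origin[2]:
                    labeled += 1
        assert planted > 100
        assert labeled / planted >= 0.95

    def test_one_label_per_peak(self, run):
        truth, state, aaigs, table, ann = run
        assert set(ann.labels) == ann.used

    def test_empty_noesy_aaig_no_labels(self, stats):
        state = MappingState(Sequence("MKVLE"))
        state.assign(2, "x", 0, 1.0)
        table = AssignmentTable()
        table.add(ShiftAssignment(2, "CA", 56.0, "C", "TOCSY"))
        table.add(ShiftAssignment(2, "HA", 4.2, "H", "TOCSY"))
        ann = transfer_to_noesy(state, {"x": AAIG("x", 118, 8.2)}, table)
        assert ann.labels == {}


class TestExtension:
    def build_scenario(self, stats, intensity=5.0):
        """Residue 2 (Ala) missing CB; its CB peak present in both its own
        spin system (intra) and the successor's (sequential)."""
        seq = Sequence("AAAA")
        cb_c, cb_h = mode(stats, "A", "CB")
        ca_c, ca_h = mode(stats, "A", "CA")
        own = AAIG("r2", 118, 8.2, noesy=[
            CHPair(ca_c, ca_h, intensity=10.0),        # explained (CA)
            CHPair(cb_c, cb_h, intensity=intensity),   # the missing CB
        ])
        succ = AAIG("r3", 119, 8.3, noesy=[
            CHPair(cb_c, cb_h, intensity=3.0),         # common NOE partner
            CHPair(ca_c, ca_h, intensity=8.0),
        ])
        state = MappingState(seq)
        state.assign(2, "r2", 0, 1.0)
        state.assign(3, "r3", 0, 1.0)
        table = AssignmentTable()
        table.add(ShiftAssignment(2, "CA", ca_c, "C", "TOCSY"))
        table.add(ShiftAssignment(2, "HA", ca_h, "H", "TOCSY"))
        return state, {"r2": own, "r3": succ}, table, (cb_c, cb_h)

    def test_missing_atom_recovered_with_printed_score(self, stats):
        state, aaigs, table, (cb_c, cb_h) = self.build_scenario(stats)
        ann = transfer_to_noesy(state, aaigs, table)
        added = extend_from_common_noes(state, aaigs, table, stats, ann)
        entry = table.get(2, "CB")
        assert entry is not None and entry.provenance == "NOESY-common"
        assert entry.shift == pytest.approx(cb_c)
        # score = density * (100 * normalized_intensity^2)
        dens = float(stats[("A", "CB")].density_at(cb_h, cb_c))
        assert entry.score == pytest.approx(dens * 100 * (5.0 / 10.0) ** 2,
                                            rel=1e-9)
        assert table.get(2, "HB").shift == pytest.approx(cb_h)

    def test_weak_peak_excluded_by_intensity_threshold(self, stats):
        state, aaigs, table, _ = self.build_scenario(stats, intensity=0.5)
        # normalized = 0.5 / 10.0 = 0.05 < 0.1
        ann = transfer_to_noesy(state, aaigs, table)
        extend_from_common_noes(state, aaigs, table, stats, ann)
        assert table.get(2, "CB") is None

    def test_no_common_partner_no_assignment(self, stats):
        state, aaigs, table, _ = self.build_scenario(stats)
        aaigs["r3"].noesy = []     # successor has nothing to corroborate
        ann = transfer_to_noesy(state, aaigs, table)
        extend_from_common_noes(state, aaigs, table, stats, ann)
        assert table.get(2, "CB") is None

    def test_normalization_is_per_spin_system(self):
        aaig = AAIG("x", 118, 8.2, noesy=[CHPair(20, 1, intensity=-8.0),
                                          CHPair(21, 2, intensity=2.0)])
        assert _normalized_intensities(aaig) == [1.0, 0.25]


class TestNoesyOnly:
    def test_noise_free_accuracy(self, stats):
        cfg = chains4d.SyntheticConfig(
            n_residues=60, seed=1, p_tocsy_missing=0.0, p_noise_peaks=0.0,
            sigma_c=0.0, sigma_h=0.0, sigma_n=0.0, sigma_hn=0.0)
        truth, roots, tocsy, noesy = chains4d.generate_dataset(cfg, stats)
        nh = {pos: (truth.shifts[(pos, "N")], truth.shifts[(pos, "HN")])
              for pos in truth.root_positions()}
        table, state = run_noesy_only(truth.sequence, nh, noesy, stats)
        metrics = chains4d.evaluate(table, state, truth)
        assert metrics["atom_assigned"] > 100
        assert metrics["atom_correct"] / metrics["atom_assigned"] >= 0.95

    def test_empty_noesy_only_roots(self, stats):
        seq = Sequence("MKVLE")
        table, state = run_noesy_only(seq, {2: (118.0, 8.2)}, [], stats)
        assert {e.atom for e in table.entries()} == {"N", "HN"}

    def test_nh_on_proline_rejected(self, stats):
        seq = Sequence("MPVLE")
        with pytest.raises(ValueError, match="proline"):
            run_noesy_only(seq, {2: (118.0, 8.2)}, [], stats)

    def test_deterministic(self, stats):
        cfg = chains4d.SyntheticConfig(n_residues=25, seed=9)
        truth, roots, tocsy, noesy = chains4d.generate_dataset(cfg, stats)
        nh = {pos: (truth.shifts[(pos, "N")], truth.shifts[(pos, "HN")])
              for pos in truth.root_positions()}
        t1, _ = run_noesy_only(truth.sequence, nh, noesy, stats)
        t2, _ = run_noesy_only(truth.sequence, nh, noesy, stats)
        assert t1.entries() == t2.entries()


class TestMergedTable:
    def test_disjoint_union(self):
        a, b = AssignmentTable(), AssignmentTable()
        a.add(ShiftAssignment(1, "CA", 53.0, "C", "TOCSY"))
        b.add(ShiftAssignment(2, "CA", 56.0, "C", "NOESY-common"))
        merged = build_shift_table(a, b)
        assert len(merged) == 2 and not merged.conflicts

    def test_conflict_tocsy_wins_and_logged(self):
        a, b = AssignmentTable(), AssignmentTable()
        a.add(ShiftAssignment(1, "CA", 53.0, "C", "NOESY-common"))
        b.add(ShiftAssignment(1, "CA", 56.0, "C", "TOCSY"))
        merged = build_shift_table(a, b)
        assert merged.get(1, "CA").provenance == "TOCSY"
        assert merged.get(1, "CA").shift == 56.0
        assert len(merged.conflicts) == 1
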