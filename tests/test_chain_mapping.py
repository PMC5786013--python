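"""Connectivities, chains, alignment, contigs and consensus."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

import chains4d
from chains4d.chain_mapping import (Chain, Connectivity, MappingState,
                                    PeptideAlignment, align_peptide,
                                    assemble_contigs, build_chains,
                                    chains_to_peptides, compute_connectivities,
                                    confidence_scores, consensus_assign,
                                    nw_score, s_align_score,
                                    score_assignments, GAP_SCORE, _BLOSUM90)
from chains4d.aa_typing import AATypePrediction
from chains4d.spectra_io import Sequence
from chains4d.spin_systems import AAIG, CHPair, Tolerances


def aaig(label, tocsy=(), noesy=()):
    return AAIG(label, 118.0, 8.2,
                tocsy=[CHPair(c, h, origin="TOCSY") for c, h in tocsy],
                noesy=[CHPair(c, h, origin="NOESY") for c, h in noesy])


class TestConnectivities:
    def test_full_containment_occupancy_one(self):
        donor = aaig("d", tocsy=[(30.0, 1.5), (19.0, 1.3)])
        acceptor = aaig("a", noesy=[(30.0, 1.5), (19.0, 1.3), (55.0, 4.2)])
        conns = compute_connectivities([donor, acceptor])
        assert len(conns) == 1
        c = conns[0]
        assert (c.tocsy_aaig, c.noesy_aaig) == ("d", "a")
        assert c.occupancy == 1.0

    def test_half_matched_occupancy(self):
        donor = aaig("d", tocsy=[(30.0, 1.5), (19.0, 1.3), (55.0, 4.2),
                                 (40.0, 2.6)])
        acceptor = aaig("a", noesy=[(30.0, 1.5), (19.0, 1.3)])
        c = compute_connectivities([donor, acceptor])[0]
        assert c.matched == 2 and c.total == 4
        assert c.occupancy == 0.5

    def test_single_coincidental_match_rejected(self):
        donor = aaig("d", tocsy=[(30.0, 1.5), (19.0, 1.3), (55.0, 4.2)])
        acceptor = aaig("a", noesy=[(30.0, 1.5)])
        assert compute_connectivities([donor, acceptor]) == []

    def test_complete_small_donor_accepted(self):
        donor = aaig("d", tocsy=[(45.0, 3.9)])
        acceptor = aaig("a", noesy=[(45.0, 3.9), (20.0, 1.1)])
        c = compute_connectivities([donor, acceptor])[0]
        assert c.occupancy == 1.0 and c.matched == 1

    def test_self_pair_excluded(self):
        both = aaig("x", tocsy=[(30.0, 1.5), (19.0, 1.3)],
                    noesy=[(30.0, 1.5), (19.0, 1.3)])
        other = aaig("y", noesy=[(1.0, 1.0)])
        assert compute_connectivities([both, other]) == []

    def test_true_neighbours_recovered_on_synthetic_data(self, stats):
        cfg = chains4d.SyntheticConfig(n_residues=40, seed=6)
        truth, roots, tocsy, noesy = chains4d.generate_dataset(cfg, stats)
        aaigs, _ = chains4d.cluster_peaks(tocsy, noesy, roots)
        conns = compute_connectivities(aaigs, min_occupancy=0.5)
        have = {(c.noesy_aaig, c.tocsy_aaig) for c in conns}
        for pos in truth.root_positions():
            if pos + 1 in truth.label_of:
                assert (truth.label_of[pos], truth.label_of[pos + 1]) in have


class TestChains:
    def C(self, u, v, occ=1.0, total=10):
        return Connectivity(v, u, matched=int(round(occ * total)),
                            total=total)

    def test_linear_graph(self):
        conns = [self.C("A", "B"), self.C("B", "C")]
        chains = {c.aaigs: c.p_chain for c in build_chains(conns, l_max=6)}
        assert chains == {("A", "B"): 1.0, ("B", "C"): 1.0,
                          ("A", "B", "C"): 1.0}

    def test_single_link_probability(self):
        conns = [self.C("A", "B", occ=0.7)]
        (chain,) = build_chains(conns, l_max=6)
        assert chain.p_chain == pytest.approx(0.7)

    def test_probability_is_product_of_occupancies(self):
        conns = [self.C("A", "B", occ=0.9), self.C("B", "C", occ=0.6)]
        by = {c.aaigs: c for c in build_chains(conns, l_max=3)}
        assert by[("A", "B", "C")].p_chain == pytest.approx(0.54)

    @pytest.mark.parametrize("seed", range(6))
    def test_path_enumeration_matches_networkx(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        nodes = [f"n{i}" for i in range(n)]
        conns = []
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for u, v in itertools.permutations(nodes, 2):
            if rng.random() < 0.25:
                conns.append(self.C(u, v, occ=1.0))
                g.add_edge(u, v)
        l_max = 5
        mine = {c.aaigs for c in build_chains(conns, l_max=l_max)}
        ref = set()
        for s, t in itertools.permutations(nodes, 2):
            for path in nx.all_simple_paths(g, s, t, cutoff=l_max - 1):
                if 2 <= len(path) <= l_max:
                    ref.add(tuple(path))
        assert mine == ref


class TestPeptides:
    def preds(self, spec):
        """spec: {label: [(aa, posterior), ...]}"""
        out = {}
        for label, lst in spec.items():
            posts = np.array([p for _, p in lst], dtype=float)
            sd = posts.std()
            z = (posts - posts.mean()) / sd if sd > 0 else posts * 0
            out[label] = [AATypePrediction(aa, p, 0.05, p, None, float(zi))
                          for (aa, p), zi in zip(lst, z)]
        return out

    def test_single_prediction_single_peptide(self):
        chain = Chain(("a", "b"), 1.0)
        preds = self.preds({"a": [("M", 1.0)], "b": [("K", 1.0)]})
        assert chains_to_peptides(chain, preds, -math.inf) == [("MK", 1.0)]

    def test_two_by_two_gives_four(self):
        chain = Chain(("a", "b"), 1.0)
        preds = self.preds({"a": [("M", 0.6), ("L", 0.4)],
                            "b": [("K", 0.7), ("R", 0.3)]})
        peptides = chains_to_peptides(chain, preds, -math.inf)
        assert len(peptides) == 4
        assert peptides[0] == ("MK", pytest.approx(0.42))

    def test_cap_matches_sort_oracle(self):
        chain = Chain(("a", "b", "c"), 1.0)
        preds = self.preds({
            "a": [("M", 0.5), ("L", 0.3), ("V", 0.2)],
            "b": [("K", 0.6), ("R", 0.4)],
            "c": [("A", 0.7), ("G", 0.3)],
        })
        full = chains_to_peptides(chain, preds, -math.inf, cap=1000)
        capped = chains_to_peptides(chain, preds, -math.inf, cap=5)
        assert capped == sorted(full, key=lambda t: (-t[1], t[0]))[:5]


class TestAlignment:
    def test_unique_substring_single_placement(self):
        seq = Sequence("MKVLEDRATS")
        (al,) = align_peptide("VLED", seq)
        assert al.start == 3
        assert al.positions == (4, 5, 6, 7)

    def test_absent_peptide_no_placement(self):
        assert align_peptide("WWWW", Sequence("MKVLEDRATS")) == []

    def test_trailing_placement_needs_room_for_spin_system(self):
        # last letter may not be the final residue: its spin system would
        # sit past the sequence end
        assert align_peptide("ATS", Sequence("MKVLEDRATS")) == []
        assert len(align_peptide("RAT", Sequence("MKVLEDRATS"))) == 1

    def test_s_align_in_unit_interval(self):
        s = s_align_score("MKVL")
        assert 0.0 < s <= 1.0
        raw = sum(_BLOSUM90[a, a] for a in "MKVL")
        assert s == pytest.approx(1 / (1 + math.exp(-raw / 4)))

    @pytest.mark.parametrize("seed", range(5))
    def test_nw_score_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        alphabet = list("ARNDCQEGHILKMFPSTWYV")
        a = "".join(rng.choice(alphabet, rng.integers(2, 5)))
        b = "".join(rng.choice(alphabet, rng.integers(5, 11)))

        def enumerate_best(i, j):
            if i == len(a):
                return GAP_SCORE * (len(b) - j)
            if j == len(b):
                return GAP_SCORE * (len(a) - i)
            return max(
                _BLOSUM90[a[i], b[j]] + enumerate_best(i + 1, j + 1),
                GAP_SCORE + enumerate_best(i + 1, j),
                GAP_SCORE + enumerate_best(i, j + 1))

        assert nw_score(a, b) == pytest.approx(enumerate_best(0, 0))


class TestScoring:
    def make_alignment(self, posteriors, p_chain=1.0, labels=("a", "b")):
        chain = Chain(tuple(labels), p_chain)
        return PeptideAlignment(chain, "MK"[:len(labels)], 1, 0.8,
                                tuple(posteriors))

    def test_unit_factors(self):
        al = PeptideAlignment(Chain(("a",), 1.0), "M", 1, 1.0, (1.0,))
        assert score_assignments(al) == {(2, "a"): 1.0}

    def test_zero_factor_zeroes_score(self):
        al = PeptideAlignment(Chain(("a",), 0.0), "M", 1, 1.0, (1.0,))
        assert score_assignments(al)[(2, "a")] == 0.0

    def test_hand_computed_product(self):
        al = PeptideAlignment(Chain(("a",), 0.4), "M", 1, 0.8, (0.5,))
        assert score_assignments(al)[(2, "a")] == pytest.approx(0.16)

    def test_confidence_single_chain(self):
        al = self.make_alignment((0.5, 0.6), p_chain=0.9)
        scored = [score_assignments(al)]
        assert confidence_scores(scored) == scored[0]

    def test_confidence_duplicated_chain_doubles(self):
        al = self.make_alignment((0.5, 0.6), p_chain=0.9)
        once = confidence_scores([score_assignments(al)])
        twice = confidence_scores([score_assignments(al)] * 2)
        for key in once:
            assert twice[key] == pytest.approx(2 * once[key])

    def test_confidence_matches_summation_oracle(self, rng):
        scored = []
        for _ in range(20):
            pos = int(rng.integers(1, 5))
            label = str(rng.choice(["a", "b", "c"]))
            scored.append({(pos, label): float(rng.random())})
        cs = confidence_scores(scored)
        for key, value in cs.items():
            assert value == pytest.approx(
                sum(d.get(key, 0.0) for d in scored))


def AL(labels, start, peptide=None):
    L = len(labels)
    return PeptideAlignment(Chain(tuple(labels), 1.0),
                            peptide or "A" * L, start, 1.0, (1.0,) * L)


class TestContigs:
    def test_textbook_merge(self):
        aligned = [AL("ABC", 1), AL("BCD", 2)]
        (contig,) = assemble_contigs(aligned)
        assert contig.aaigs == ("A", "B", "C", "D")
        assert contig.start == 2

    def test_lone_chain_discarded(self):
        assert assemble_contigs([AL("ABC", 1), AL("XYZ", 7)]) == []

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError):
            assemble_contigs([AL("ABC", 1), AL("BC", 2)])

    def test_repeated_aaig_terminates_contig(self):
        aligned = [AL("ABC", 1), AL("BCA", 2)]
        assert assemble_contigs(aligned) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_merge_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # chains over unique per-position labels: no repeat complications
        L = 3
        n_pos = 9
        labels = {p: f"s{p}" for p in range(1, n_pos + 1)}
        aligned = []
        for start in range(1, n_pos - L + 1):
            if rng.random() < 0.65:
                aligned.append(AL([labels[start + k] for k in range(L)],
                                  start))
        mine = {(c.aaigs, c.start) for c in assemble_contigs(aligned)}

        # oracle: merge pairs to closure, keep maximal elements
        items = {(a.chain.aaigs, a.start) for a in aligned}
        closed = set(items)
        changed = True
        while changed:
            changed = False
            for (xa, xs), (ya, ys) in itertools.permutations(closed, 2):
                if ys == xs + len(xa) - L + 1 and xa[-(L - 1):] == ya[:L - 1]:
                    merged = (xa + ya[L - 1:], xs)
                    if merged not in closed:
                        closed.add(merged)
                        changed = True
                        break
        maximal = {(a, s) for (a, s) in closed - items
                   if not any((a2, s2) != (a, s)
                              and len(a2) > len(a)
                              and s2 <= s and s2 + len(a2) >= s + len(a)
                              and a2[s - s2:s - s2 + len(a)] == a
                              for (a2, s2) in closed)}
        expected = {(a, s + 1) for a, s in maximal}
        assert mine == expected


class TestConsensus:
    """Toy overlap-layout-consensus scenarios: positions are assigned only
    where all contig-member chains agree and the winner's confidence is a
    strict maximum."""

    def run(self, aligned, extra_scores=()):
        cs = confidence_scores([score_assignments(a) for a in aligned]
                               + list(extra_scores))
        state = MappingState(Sequence("A" * 30))
        return consensus_assign(aligned, cs, state)

    def test_agreeing_contig_assigns_all_positions(self):
        aligned = [AL("ABC", 1), AL("BCD", 2)]
        got = self.run(aligned)
        assert {pos: lab for pos, (lab, _) in got.items()} == \
            {2: "A", 3: "B", 4: "C", 5: "D"}

    def test_disagreeing_contigs_leave_position_unassigned(self):
        aligned = [AL("ABC", 1), AL("BCD", 2),      # propose C at 4
                   AL("XYZ", 2), AL("YZW", 3)]      # propose Y at 4
        got = self.run(aligned)
        positions = {pos: lab for pos, (lab, _) in got.items()}
        assert 4 not in positions
        assert positions[2] == "A" and positions[6] == "W"

    def test_lone_chain_never_assigns(self):
        assert self.run([AL("ABC", 1)]) == {}

    def test_confidence_tie_blocks_assignment(self):
        aligned = [AL("ABC", 1), AL("BCD", 2)]
        # a lone competing chain also proposes R at position 3
        lone = AL("QRS", 1)
        cs = confidence_scores([score_assignments(a)
                                for a in aligned + [lone]])
        cs[(3, "R")] = cs[(3, "B")]   # force the tie
        cs[(2, "Q")] = 0.5            # Q loses at 2, A still wins there
        state = MappingState(Sequence("A" * 30))
        got = consensus_assign(aligned + [lone], cs, state)
        assert 3 not in got
        assert 2 in got

    def test_duplicate_winner_assigned_nowhere(self):
        aligned = [AL("ABC", 1), AL("BCD", 2),
                   AL("ABC", 11), AL("BCD", 12)]
        got = self.run(aligned)
        assert got == {}

    def test_assigned_positions_are_skipped(self):
        aligned = [AL("ABC", 1), AL("BCD", 2)]
        cs = confidence_scores([score_assignments(a) for a in aligned])
        state = MappingState(Sequence("A" * 30))
        state.assign(2, "A", 0, 1.0)
        got = consensus_assign(aligned, cs, state)
        assert 2 not in got and 3 in got


class TestIterativeMapping:
    def test_monotone_growth_and_no_revocation(self, stats):
        cfg = chains4d.SyntheticConfig(n_residues=40, seed=2)
        truth, roots, tocsy, noesy = chains4d.generate_dataset(cfg, stats)
        from chains4d import aa_typing
        from chains4d.chain_mapping import (DEFAULT_SCHEDULE, Mapper,
                                            compute_connectivities)
        aaigs, _ = chains4d.cluster_peaks(tocsy, noesy, roots)
        prior = aa_typing.tocsy_prior(truth.sequence)
        preds = {a.label: aa_typing.predict_aa_types(a, truth.sequence,
                                                     stats, prior=prior)
                 for a in aaigs}
        conns = compute_connectivities(aaigs, min_occupancy=0.3)
        mapper = Mapper(aaigs, preds, conns, truth.sequence)
        snapshots = []
        for i, rnd in enumerate(DEFAULT_SCHEDULE, 1):
            mapper.run_round(rnd, i)
            snapshots.append(dict(mapper.state.assigned))
        for before, after in zip(snapshots, snapshots[1:]):
            assert set(before) <= set(after)
            for pos, label in before.items():
                assert after[pos] == label
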