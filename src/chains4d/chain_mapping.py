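"""Sequential mapping of spin systems onto the protein sequence.

The mapping proceeds in four conceptual steps, iterated with
progressively looser parameters:

1. *Connectivities.*  A TOCSY spin system describes residue i-1; a NOESY
   spin system rooted on residue i-1's own amide contains residue i-1's
   intraresidue CH resonances.  Matching every TOCSY spin system's CH
   frequencies against every other spin system's NOESY content (excluding
   the one sharing its root) therefore reveals candidate predecessor
   relations, graded by the occupancy rate: matched / total TOCSY
   frequencies.
2. *Chains.*  Directed paths of consecutive connectivities, up to length
   6; each chain X carries P(X) = product of the occupancies of its
   links.
3. *Peptides and alignment.*  Each chain is translated into candidate
   peptides using the retained amino-acid-type predictions of its
   members and placed on the sequence; only mismatch-free, ungapped
   placements survive.  The placement score S_align is the
   logistic-normalized BLOSUM90 similarity of the placement, and each
   (position, spin system) pair receives the weighted score
   S(X) = P(AA|CCS) * P(X) * S_align, accumulated over chains into a
   confidence score C_s.
4. *Overlap-layout-consensus.*  Aligned chains of length L overlapping by
   exactly L-1 members merge into contigs; chains without any overlap
   partner are considered spurious and dropped.  A position is assigned
   only when every contig covering it proposes the same spin system and
   that spin system holds the strictly highest confidence score there.
   Assignments are never revoked; each successive round eliminates
   predictions and connectivities inconsistent with them and re-runs the
   procedure with shorter chains (minimum length 3) and looser cutoffs.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .aa_typing import AATypePrediction, zscore_filter
from .spectra_io import Sequence
from .spin_systems import AAIG, Tolerances

log = logging.getLogger(__name__)

MAX_CHAIN_LENGTH = 6   # longer chains cost memory without adding fidelity
MIN_CHAIN_LENGTH = 3
DEFAULT_PEPTIDE_CAP = 2000


# ---------------------------------------------------------------------------
# connectivities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Connectivity:
    """Candidate predecessor relation between two spin systems.

    ``noesy_aaig`` is the candidate *predecessor* of ``tocsy_aaig``: the
    donor's TOCSY frequencies (residue i-1) were found inside the
    acceptor's NOESY content, so the acceptor's root sits on residue i-1.
    """

    tocsy_aaig: str
    noesy_aaig: str
    matched: int
    total: int

    @property
    def occupancy(self) -> float:
        return self.matched / self.total


def compute_connectivities(
    aaigs: list[AAIG],
    tol: Tolerances = Tolerances(),
    min_occupancy: float = 0.0,
    min_matched: int = 2,
) -> list[Connectivity]:
    """All ordered (donor TOCSY, acceptor NOESY) relations with
    occupancy >= ``min_occupancy``; self-pairs excluded.

    A single coincidental frequency match is weak evidence of a
    sequential contact, so relations must match at least ``min_matched``
    donor frequencies — unless they match the donor completely (small
    donors, e.g. glycine patterns, cannot offer more frequencies).
    """
    if len(aaigs) < 2:
        raise ValueError("need at least two spin systems")
    aaigs = sorted(aaigs, key=lambda a: a.label)

    donors = [a for a in aaigs if a.tocsy]
    acceptors = [a for a in aaigs if a.noesy]
    if not donors or not acceptors:
        return []

    t_c = np.concatenate([[p.c for p in a.tocsy] for a in donors])
    t_h = np.concatenate([[p.h for p in a.tocsy] for a in donors])
    n_c = np.concatenate([[p.c for p in a.noesy] for a in acceptors])
    n_h = np.concatenate([[p.h for p in a.noesy] for a in acceptors])
    t_sizes = [len(a.tocsy) for a in donors]
    n_sizes = [len(a.noesy) for a in acceptors]
    t_off = np.concatenate([[0], np.cumsum(t_sizes)[:-1]]).astype(int)
    n_off = np.concatenate([[0], np.cumsum(n_sizes)[:-1]]).astype(int)

    hit = (np.abs(t_c[:, None] - n_c[None, :]) <= tol.tol_c) & \
          (np.abs(t_h[:, None] - n_h[None, :]) <= tol.tol_h)
    # per (tocsy frequency, acceptor): was the frequency matched at all?
    per_acceptor = np.add.reduceat(hit, n_off, axis=1) > 0
    # per (donor, acceptor): number of matched donor frequencies
    matched = np.add.reduceat(per_acceptor.astype(int), t_off, axis=0)

    out = []
    for i, d in enumerate(donors):
        total = t_sizes[i]
        for j, a in enumerate(acceptors):
            if a.label == d.label:
                continue
            m = int(matched[i, j])
            if m == 0 or (m < min_matched and m < total):
                continue
            if m / total >= min_occupancy:
                out.append(Connectivity(d.label, a.label, m, total))
    return out


# ---------------------------------------------------------------------------
# chains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Chain:
    """An ordered N-to-C path of spin systems through the connectivity
    graph, with its occurrence probability (product of link occupancies)."""

    aaigs: tuple[str, ...]
    p_chain: float

    def __len__(self):
        return len(self.aaigs)


def build_chains(
    connectivities: list[Connectivity],
    l_max: int = MAX_CHAIN_LENGTH,
    l_min: int = 2,
) -> list[Chain]:
    """All simple paths of 2..l_max nodes in the connectivity digraph.

    Edges run from predecessor (acceptor NOESY spin system) to successor
    (donor TOCSY spin system), so chain order follows the sequence.
    """
    if l_max < 2:
        raise ValueError("l_max must be >= 2")
    adj: dict[str, list[tuple[str, float]]] = {}
    nodes = set()
    for c in connectivities:
        adj.setdefault(c.noesy_aaig, []).append((c.tocsy_aaig, c.occupancy))
        nodes.add(c.noesy_aaig)
        nodes.add(c.tocsy_aaig)
    for lst in adj.values():
        lst.sort()

    chains: list[Chain] = []
    path: list[str] = []
    on_path: set[str] = set()

    def dfs(u: str, prob: float):
        path.append(u)
        on_path.add(u)
        if l_min <= len(path) <= l_max:
            chains.append(Chain(tuple(path), prob))
        if len(path) < l_max:
            for v, occ in adj.get(u, ()):
                if v not in on_path:
                    dfs(v, prob * occ)
        on_path.remove(u)
        path.pop()

    for start in sorted(nodes):
        dfs(start, 1.0)
    return chains


# ---------------------------------------------------------------------------
# peptides and alignment
# ---------------------------------------------------------------------------

def chains_to_peptides(
    chain: Chain,
    predictions: dict[str, list[AATypePrediction]],
    zscore_cutoff: float = -math.inf,
    cap: int = DEFAULT_PEPTIDE_CAP,
) -> list[tuple[str, float]]:
    """Candidate peptides for one chain: the Cartesian product of the
    z-filtered predictions of its members, as (peptide, posterior product)
    sorted by decreasing product and capped at ``cap``."""
    retained = []
    for label in chain.aaigs:
        preds = zscore_filter(predictions.get(label, []), zscore_cutoff)
        if not preds:
            return []
        retained.append(preds)
    combos = itertools.product(*retained)
    peptides = [("".join(p.amino_acid for p in combo),
                 math.prod(p.posterior for p in combo))
                for combo in combos]
    peptides.sort(key=lambda t: (-t[1], t[0]))
    return peptides[:cap]


_BLOSUM90 = substitution_matrices.load("BLOSUM90")
GAP_SCORE = -10.0   # linear gap penalty for the global aligner


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _BLOSUM90
    aligner.mode = "global"
    aligner.open_gap_score = GAP_SCORE
    aligner.extend_gap_score = GAP_SCORE
    return aligner


_ALIGNER = _make_aligner()


def nw_score(a: str, b: str) -> float:
    """Optimal Needleman-Wunsch global alignment score of two peptide
    strings under BLOSUM90 with a linear gap penalty."""
    return float(_ALIGNER.score(a, b))


@lru_cache(maxsize=None)
def _self_similarity(peptide: str) -> float:
    # NW score of a peptide against its own exact placement window
    return nw_score(peptide, peptide)


def s_align_score(peptide: str) -> float:
    """Logistic-normalized BLOSUM90 similarity of a mismatch-free
    placement, in (0, 1]: logistic(raw / L)."""
    raw = _self_similarity(peptide)
    return 1.0 / (1.0 + math.exp(-raw / len(peptide)))


@dataclass(frozen=True)
class PeptideAlignment:
    """One surviving (mismatch-free, ungapped) placement of a chain.

    ``start`` is the sequence position of the first peptide letter; the
    chain's k-th spin system (0-based) then sits on position
    ``start + k + 1`` (a spin system's TOCSY letter describes the residue
    preceding its amide).
    """

    chain: Chain
    peptide: str
    start: int
    s_align: float
    posteriors: tuple[float, ...]   # per-letter P(AA|CCS)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(self.start + k + 1 for k in range(len(self.peptide)))


def align_peptide(
    peptide: str,
    sequence: Sequence,
    chain: Chain | None = None,
    posteriors: tuple[float, ...] | None = None,
) -> list[PeptideAlignment]:
    """All mismatch-free ungapped placements of a peptide.

    With only exact placements retained, the surviving placements are the
    optimal ungapped global alignments of the peptide against each window;
    their BLOSUM90 score is computed through the Needleman-Wunsch aligner.
    Placements must leave room for the spin systems (one past each
    letter), so the last letter stops one short of the sequence end.
    """
    L = len(peptide)
    if L > len(sequence):
        raise ValueError("peptide longer than sequence")
    if chain is None:
        chain = Chain(tuple(f"?{k}" for k in range(L)), 1.0)
    if posteriors is None:
        posteriors = tuple(1.0 for _ in range(L))
    s_align = s_align_score(peptide)
    out = []
    res = sequence.residues
    start = res.find(peptide)
    while start != -1:
        pos0 = sequence.first + start        # sequence position of letter 0
        if pos0 + L <= sequence.last:        # room for the trailing AAIG
            out.append(PeptideAlignment(chain, peptide, pos0, s_align,
                                        posteriors))
        start = res.find(peptide, start + 1)
    return out


def score_assignments(alignment: PeptideAlignment,
                      p_chain: float | None = None) -> dict[tuple[int, str], float]:
    """Weighted assignment scores S(X) = P(AA|CCS) * P(X) * S_align for
    every (position, spin system) of one aligned chain."""
    if p_chain is None:
        p_chain = alignment.chain.p_chain
    out = {}
    for k, label in enumerate(alignment.chain.aaigs):
        pos = alignment.start + k + 1
        out[(pos, label)] = alignment.posteriors[k] * p_chain * alignment.s_align
    return out


def confidence_scores(
    scored: list[dict[tuple[int, str], float]],
) -> dict[tuple[int, str], float]:
    """Confidence C_s per (position, spin system): sum of S(X) over all
    chains proposing that spin system there."""
    cs: dict[tuple[int, str], float] = {}
    for d in scored:
        for key, s in d.items():
            cs[key] = cs.get(key, 0.0) + s
    return cs


# ---------------------------------------------------------------------------
# contig assembly (overlap-layout-consensus)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contig:
    """A maximal merge of aligned chains overlapping by exactly L-1."""

    aaigs: tuple[str, ...]
    start: int                       # position of the first member AAIG
    members: tuple[int, ...]         # indices into the aligned-chain list


def assemble_contigs(aligned: list[PeptideAlignment]) -> list[Contig]:
    """Merge aligned chains of one length into contigs.

    Two aligned chains overlap when the second starts one position later
    and shares its first L-1 spin systems with the other's last L-1.
    Contigs are maximal merge paths; extension stops when an already
    incorporated spin system reappears.  Chains with no overlap partner
    are spurious and yield no contig.
    """
    if not aligned:
        return []
    lengths = {len(a.chain) for a in aligned}
    if len(lengths) != 1:
        raise ValueError("contig assembly requires chains of equal length")

    succ: dict[int, list[int]] = {i: [] for i in range(len(aligned))}
    pred_count = dict.fromkeys(range(len(aligned)), 0)
    by_start: dict[int, list[int]] = {}
    for i, a in enumerate(aligned):
        by_start.setdefault(a.start, []).append(i)
    for i, a in enumerate(aligned):
        for j in by_start.get(a.start + 1, ()):
            b = aligned[j]
            if a.chain.aaigs[1:] == b.chain.aaigs[:-1]:
                succ[i].append(j)
                pred_count[j] += 1

    contigs: list[Contig] = []
    seen: set[tuple[tuple[str, ...], int]] = set()

    def extend(path: list[int], members: set[str]):
        i = path[-1]
        grew = False
        for j in succ[i]:
            new_aaig = aligned[j].chain.aaigs[-1]
            if new_aaig in members:      # would revisit: terminate here
                continue
            members.add(new_aaig)
            path.append(j)
            extend(path, members)
            path.pop()
            members.remove(new_aaig)
            grew = True
        if not grew and len(path) > 1:
            first = aligned[path[0]]
            aaigs = first.chain.aaigs + tuple(
                aligned[j].chain.aaigs[-1] for j in path[1:])
            key = (aaigs, first.start + 1)
            if key not in seen:
                seen.add(key)
                contigs.append(Contig(aaigs, first.start + 1, tuple(path)))

    for i in sorted(succ):
        if pred_count[i] == 0 and succ[i]:
            extend([i], set(aligned[i].chain.aaigs))
    return contigs


def _partnered(aligned: list[PeptideAlignment]) -> list[bool]:
    """Which aligned chains have an L-1 overlap partner (contig members)."""
    partnered = [False] * len(aligned)
    index: dict[int, list[int]] = {}
    for i, a in enumerate(aligned):
        index.setdefault(a.start, []).append(i)
    for i, a in enumerate(aligned):
        for j in index.get(a.start + 1, ()):
            if a.chain.aaigs[1:] == aligned[j].chain.aaigs[:-1]:
                partnered[i] = True
                partnered[j] = True
    return partnered


def consensus_assign(
    aligned: list[PeptideAlignment],
    cs: dict[tuple[int, str], float],
    state: "MappingState",
) -> dict[int, tuple[str, float]]:
    """New assignments under the two consensus conditions.

    A position is assigned its proposed spin system iff (a) every contig
    covering the position proposes that same spin system (equivalently:
    every partnered aligned chain there agrees — every contig member has
    an overlap partner, and contig proposals at a position are exactly the
    proposals of its member chains), and (b) it holds the strictly
    highest confidence score among all spin systems proposed there by any
    aligned chain.  Ties leave the position unassigned, and a spin system
    proposed as winner at two positions is assigned to neither
    (bidirectional exclusivity).
    """
    partnered = _partnered(aligned)
    proposals: dict[int, set[str]] = {}
    pool: dict[int, set[str]] = {}
    for i, a in enumerate(aligned):
        for k, label in enumerate(a.chain.aaigs):
            pos = a.start + k + 1
            proposals.setdefault(pos, set()).add(label)
            if partnered[i]:
                pool.setdefault(pos, set()).add(label)

    candidates: dict[int, tuple[str, float]] = {}
    for pos in sorted(pool):
        if pos in state.assigned:
            continue
        if len(pool[pos]) != 1:
            continue                     # contigs disagree
        label = next(iter(pool[pos]))
        if label in state.by_label:
            continue
        best = cs[(pos, label)]
        others = [cs[(pos, other)] for other in proposals[pos]
                  if other != label]
        if others and max(others) >= best:
            continue                     # not the strict C_s maximum
        candidates[pos] = (label, best)

    label_counts: dict[str, int] = {}
    for label, _ in candidates.values():
        label_counts[label] = label_counts.get(label, 0) + 1
    return {pos: (label, score) for pos, (label, score) in candidates.items()
            if label_counts[label] == 1}


# ---------------------------------------------------------------------------
# iterative mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Round:
    """One iteration's restraining parameters."""

    length: int
    zscore_cutoff: float
    min_occupancy: float


#: First round extracts long chains under stringent cutoffs; later rounds
#: loosen gradually down to the minimum chain length of 3.
DEFAULT_SCHEDULE = (
    Round(6, 0.0, 0.5),
    Round(5, -0.5, 0.4),
    Round(4, -1.0, 0.3),
    Round(3, -1.0, 0.3),
)


@dataclass
class MappingState:
    """Injective position <-> spin-system mapping plus iteration history."""

    sequence: Sequence
    assigned: dict[int, str] = field(default_factory=dict)
    by_label: dict[str, int] = field(default_factory=dict)
    round_assigned: dict[int, int] = field(default_factory=dict)
    confidence: dict[int, float] = field(default_factory=dict)

    def assign(self, pos: int, label: str, round_no: int, cs: float) -> None:
        if pos in self.assigned or label in self.by_label:
            raise RuntimeError("internal error: mapping would lose "
                               "injectivity or revoke an assignment")
        self.assigned[pos] = label
        self.by_label[label] = pos
        self.round_assigned[pos] = round_no
        self.confidence[pos] = cs


class Mapper:
    """Runs the iterative restraining schedule over one dataset."""

    def __init__(
        self,
        aaigs: list[AAIG],
        predictions: dict[str, list[AATypePrediction]],
        connectivities: list[Connectivity],
        sequence: Sequence,
        schedule: tuple[Round, ...] = DEFAULT_SCHEDULE,
    ):
        self.aaigs = {a.label: a for a in aaigs}
        self.predictions = predictions
        self.connectivities = list(connectivities)
        self.sequence = sequence
        self.schedule = schedule
        self.state = MappingState(sequence)

    # -- consistency helpers -------------------------------------------
    def _position_allowed(self, pos: int, label: str) -> bool:
        seq = self.sequence
        if not (seq.first + 1 <= pos <= seq.last):
            return False
        if seq.residue(pos) == "P":
            return False
        ass = self.state.assigned.get(pos)
        if ass is not None and ass != label:
            return False
        lab_pos = self.state.by_label.get(label)
        if lab_pos is not None and lab_pos != pos:
            return False
        return True

    def _retained_types(self, zscore_cutoff: float) -> dict[str, dict[str, float]]:
        """Per spin system: candidate residue type -> posterior, after the
        Z filter and the restraints from already mapped neighbours."""
        out: dict[str, dict[str, float]] = {}
        for label in sorted(self.aaigs):
            pos = self.state.by_label.get(label)
            if pos is not None:
                # pinned: the spin system's TOCSY letter is the residue
                # preceding its mapped position
                out[label] = {self.sequence.residue(pos - 1): 1.0}
                continue
            kept = zscore_filter(self.predictions.get(label, []),
                                 zscore_cutoff)
            types: dict[str, float] = {}
            for p in kept:
                types[p.amino_acid] = max(types.get(p.amino_acid, 0.0),
                                          p.posterior)
            if types:
                out[label] = types
        return out

    def _live_connectivities(self, min_occupancy: float) -> list[Connectivity]:
        seq = self.sequence
        live = []
        for c in self.connectivities:
            if c.occupancy < min_occupancy:
                continue
            # edge: noesy_aaig at position p, tocsy_aaig at p + 1
            p_pred = self.state.by_label.get(c.noesy_aaig)
            p_succ = self.state.by_label.get(c.tocsy_aaig)
            if p_pred is not None and p_succ is not None:
                if p_succ != p_pred + 1:
                    continue
            elif p_pred is not None:
                nxt = p_pred + 1
                if nxt > seq.last or seq.residue(nxt) == "P":
                    continue
                if self.state.assigned.get(nxt) not in (None, c.tocsy_aaig):
                    continue
            elif p_succ is not None:
                prv = p_succ - 1
                if prv <= seq.first or seq.residue(prv) == "P":
                    continue
                if self.state.assigned.get(prv) not in (None, c.noesy_aaig):
                    continue
            live.append(c)
        return live

    # -- one round ------------------------------------------------------
    def _align_chains(self, chains: list[Chain],
                      retained: dict[str, dict[str, float]]) -> list[PeptideAlignment]:
        """Mismatch-free placements of every chain, walked directly along
        the sequence (equivalent to enumerating candidate peptides and
        aligning each: a placement survives iff every member retains the
        sequence's letter as a candidate type)."""
        seq = self.sequence
        res = seq.residues
        aligned = []
        for chain in chains:
            types = [retained.get(label) for label in chain.aaigs]
            if any(t is None for t in types):
                continue
            L = len(chain)
            for start0 in range(0, len(res) - L):
                pos0 = seq.first + start0
                ok = True
                for k, label in enumerate(chain.aaigs):
                    letter = res[start0 + k]
                    if letter not in types[k] or \
                       not self._position_allowed(pos0 + k + 1, label):
                        ok = False
                        break
                if ok:
                    peptide = res[start0:start0 + L]
                    aligned.append(PeptideAlignment(
                        chain, peptide, pos0, s_align_score(peptide),
                        tuple(types[k][peptide[k]] for k in range(L))))
        return aligned

    def run_round(self, rnd: Round, round_no: int) -> int:
        retained = self._retained_types(rnd.zscore_cutoff)
        live = self._live_connectivities(rnd.min_occupancy)
        chains = build_chains(live, l_max=rnd.length, l_min=rnd.length)
        aligned = self._align_chains(chains, retained)
        if not aligned:
            return 0
        cs = confidence_scores([score_assignments(a) for a in aligned])
        candidates = consensus_assign(aligned, cs, self.state)
        for pos in sorted(candidates):
            label, score = candidates[pos]
            self.state.assign(pos, label, round_no, score)
        return len(candidates)

    def run(self) -> MappingState:
        round_no = 0
        for rnd in self.schedule:
            round_no += 1
            added = self.run_round(rnd, round_no)
            log.info("round %d (L=%d, z>=%.1f, occ>=%.2f): %d new "
                     "assignments (%d total)", round_no, rnd.length,
                     rnd.zscore_cutoff, rnd.min_occupancy, added,
                     len(self.state.assigned))
        # repeat the final (loosest, shortest) round to a fixed point
        final = self.schedule[-1]
        while True:
            round_no += 1
            added = self.run_round(final, round_no)
            log.info("round %d (repeat L=%d): %d new assignments",
                     round_no, final.length, added)
            if added == 0:
                break
        return self.state


def iterate_mapping(
    aaigs: list[AAIG],
    predictions: dict[str, list[AATypePrediction]],
    connectivities: list[Connectivity],
    sequence: Sequence,
    schedule: tuple[Round, ...] = DEFAULT_SCHEDULE,
) -> MappingState:
    """Run the full iterative mapping schedule; see :class:`Mapper`."""
    return Mapper(aaigs, predictions, connectivities, sequence,
                  schedule).run()


def write_mapping_report(state: MappingState, path: str | Path) -> None:
    """TSV report: position, residue, spin system, confidence, round."""
    with open(path, "w") as fh:
        fh.write("position\tresidue\taaig\tconfidence\tround\n")
        for pos in sorted(state.assigned):
            fh.write(f"{pos}\t{state.sequence.residue(pos)}\t"
                     f"{state.assigned[pos]}\t"
                     f"{state.confidence[pos]:.6g}\t"
                     f"{state.round_assigned[pos]}\n")
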