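"""Bayesian amino-acid-type prediction from correlated 13C-1H shifts.

A TOCSY spin system carries the aliphatic CH resonances of the residue
preceding its amide (i-1).  For each candidate amino-acid type AA the
likelihood P(CCS|AA) of the observed set of correlated chemical shifts
(CCS) is the *best* injective placement of the CH pairs onto the
candidate's carbon types, scored as the product of per-pair densities
from the 2D shift-statistics maps.  Two pairs whose carbon frequencies
differ by at most the methylene threshold (default 0.2 ppm) may jointly
occupy one methylene carbon; the group then contributes the logarithmic
average (geometric mean) of the two individual densities.  If the spin
system holds more CH pairs than the candidate can accommodate, the
likelihood is zero.

Posteriors follow Bayes' rule with a sequence-composition prior taken
over the residues that precede a non-proline residue — exactly the
population a TOCSY spin system can report on (prolines contribute no
amide root of their own, so residue types are only ever observed through
their successor's spin system).

The ranked predictions are standardized to Z-scores on the natural-log
posteriors; downstream mapping rounds retain predictions above a Z
cutoff (always keeping the top-ranked one).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from . import topology
from .shift_statistics import StatsLibrary
from .spin_systems import AAIG, CHPair
from .spectra_io import Sequence

log = logging.getLogger(__name__)

DEFAULT_METHYLENE_TOL = 0.2   # ppm 13C; grouping threshold for CH2 partners

#: densities below this are treated as exact zeros (Gaussian tail underflow)
_ZERO = 1e-300


@dataclass(frozen=True)
class AtomCombination:
    """One injective placement of CH pairs onto a residue's carbon types.

    ``assignment`` maps carbon name -> tuple of pair indices (length 2
    only for a grouped methylene).
    """

    amino_acid: str
    assignment: tuple[tuple[str, tuple[int, ...]], ...]

    def pairs_of(self, carbon: str) -> tuple[int, ...]:
        for name, idxs in self.assignment:
            if name == carbon:
                return idxs
        return ()


@dataclass(frozen=True)
class AATypePrediction:
    amino_acid: str
    p_ccs_given_aa: float
    prior: float
    posterior: float
    combination: AtomCombination | None
    zscore: float = 0.0


# ---------------------------------------------------------------------------
# combination enumeration and likelihood
# ---------------------------------------------------------------------------

def enumerate_combinations(
    pairs: list[CHPair],
    aa: str,
    methylene_tol: float = DEFAULT_METHYLENE_TOL,
) -> list[AtomCombination]:
    """All injective placements of ``pairs`` onto the carbon types of
    ``aa``; empty when the residue cannot accommodate them all."""
    out: list[AtomCombination] = []
    for placement in _placements(pairs, aa, methylene_tol):
        out.append(_to_combination(aa, placement))
    return out


def _placements(pairs, aa, methylene_tol):
    """Yield placements as dict carbon -> list of pair indices."""
    types = topology.carbon_types(aa)
    if len(pairs) > topology.max_ch_peaks(aa):
        return
    state: dict[str, list[int]] = {t.name: [] for t in types}

    def rec(i):
        if i == len(pairs):
            yield {k: list(v) for k, v in state.items() if v}
            return
        for t in types:
            slot = state[t.name]
            if t.is_methylene:
                if len(slot) >= 2:
                    continue
                if slot and abs(pairs[slot[0]].c - pairs[i].c) > methylene_tol:
                    continue
            elif slot:
                continue
            slot.append(i)
            yield from rec(i + 1)
            slot.pop()

    yield from rec(0)


def _to_combination(aa, placement) -> AtomCombination:
    order = [t.name for t in topology.carbon_types(aa)]
    items = tuple((name, tuple(placement[name]))
                  for name in order if name in placement)
    return AtomCombination(aa, items)


def combination_probability(combo: AtomCombination,
                            densities: np.ndarray,
                            carbon_index: dict[str, int]) -> float:
    """Product of per-pair densities, geometric mean within a methylene
    group.  ``densities[i, j]`` is pair i's density on carbon type j."""
    prob = 1.0
    for carbon, idxs in combo.assignment:
        j = carbon_index[carbon]
        if len(idxs) == 1:
            prob *= densities[idxs[0], j]
        else:
            prob *= math.sqrt(densities[idxs[0], j] * densities[idxs[1], j])
    return prob


def p_ccs_given_aa(
    pairs: list[CHPair],
    aa: str,
    stats: StatsLibrary,
    methylene_tol: float = DEFAULT_METHYLENE_TOL,
) -> tuple[float, AtomCombination | None]:
    """Likelihood of the observed CH pairs under amino-acid type ``aa``.

    Maximizes the combination probability over all placements
    (branch-and-bound with zero pruning); ties are resolved in favour of
    the first placement in deterministic carbon order, which prefers
    backbone CA/CB assignments.
    """
    dens = _density_matrix(pairs, aa, stats)
    return _best_placement(pairs, aa, dens, methylene_tol)


def _density_matrix(pairs, aa, stats) -> np.ndarray:
    types = topology.carbon_types(aa)
    h = np.array([p.h for p in pairs])
    c = np.array([p.c for p in pairs])
    cols = []
    for t in types:
        cols.append(stats[(aa, t.name)].density_at(h, c))
    return np.column_stack(cols) if cols else np.zeros((len(pairs), 0))


def _best_placement(pairs, aa, dens, methylene_tol):
    """Max-product placement search over the density matrix."""
    types = topology.carbon_types(aa)
    if len(pairs) > topology.max_ch_peaks(aa):
        return 0.0, None
    if not pairs:
        return 0.0, None
    n = len(pairs)
    best = [0.0, None]
    state: dict[str, list[int]] = {t.name: [] for t in types}

    def rec(i, prob):
        if prob <= _ZERO:
            return
        if i == n:
            if prob > best[0]:
                best[0] = prob
                best[1] = {k: list(v) for k, v in state.items() if v}
            return
        for j, t in enumerate(types):
            slot = state[t.name]
            d = dens[i, j]
            if d <= _ZERO:
                continue
            if t.is_methylene:
                if len(slot) >= 2:
                    continue
                if slot and abs(pairs[slot[0]].c - pairs[i].c) > methylene_tol:
                    continue
                if slot:
                    # closing a group: replace p1*p2 by sqrt(p1*p2)
                    d_prev = dens[slot[0], j]
                    factor = math.sqrt(d_prev * d) / d_prev
                else:
                    factor = d
            elif slot:
                continue
            else:
                factor = d
            slot.append(i)
            rec(i + 1, prob * factor)
            slot.pop()

    rec(0, 1.0)
    if best[1] is None:
        return 0.0, None
    return best[0], _to_combination(aa, best[1])


# ---------------------------------------------------------------------------
# posterior prediction
# ---------------------------------------------------------------------------

def tocsy_prior(sequence: Sequence) -> dict[str, float]:
    """Composition prior over residues that precede a non-proline.

    These are exactly the residues a TOCSY spin system can describe: the
    spin system sits on the amide of residue i (which must not be proline)
    and reports on residue i-1.
    """
    counts: dict[str, int] = {}
    for pos in range(sequence.first + 1, sequence.last + 1):
        if sequence.residue(pos) == "P":
            continue
        prev = sequence.residue(pos - 1)
        counts[prev] = counts.get(prev, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence yields no observable TOCSY residues")
    return {aa: c / total for aa, c in counts.items()}


def predict_aa_types(
    aaig: AAIG,
    sequence: Sequence,
    stats: StatsLibrary,
    methylene_tol: float = DEFAULT_METHYLENE_TOL,
    prior: dict[str, float] | None = None,
) -> list[AATypePrediction]:
    """Ranked amino-acid-type posteriors for one TOCSY spin system."""
    if prior is None:
        prior = tocsy_prior(sequence)
    pairs = aaig.tocsy
    if not pairs:
        return []

    # one vectorized density pass over every map in the library
    h = np.array([p.h for p in pairs])
    c = np.array([p.c for p in pairs])
    all_dens = stats.densities(h, c)

    raw: list[tuple[str, float, AtomCombination | None]] = []
    for aa in topology.AA1:
        if prior.get(aa, 0.0) <= 0.0:
            raw.append((aa, 0.0, None))
            continue
        types = topology.carbon_types(aa)
        dens = np.column_stack([all_dens[(aa, t.name)] for t in types])
        p, combo = _best_placement(pairs, aa, dens, methylene_tol)
        raw.append((aa, p, combo))

    weights = {aa: p * prior.get(aa, 0.0) for aa, p, _ in raw}
    total = sum(weights.values())
    if total <= 0.0:
        log.warning("AAIG %s: all amino-acid types have zero support "
                    "(abnormal shifts?)", aaig.label)
        return []

    preds = [
        AATypePrediction(aa, p, prior.get(aa, 0.0), weights[aa] / total, combo)
        for aa, p, combo in raw if weights[aa] > 0.0
    ]
    preds.sort(key=lambda pr: (-pr.posterior, pr.amino_acid))

    # standardize on the posteriors themselves: the log scale's dynamic
    # range (tens of orders of magnitude) would make negligible
    # candidates look above-average
    post = np.array([pr.posterior for pr in preds])
    sd = float(post.std())
    z = (post - float(post.mean())) / sd if sd > 0 else np.zeros_like(post)
    return [AATypePrediction(pr.amino_acid, pr.p_ccs_given_aa, pr.prior,
                             pr.posterior, pr.combination, float(zi))
            for pr, zi in zip(preds, z)]


def zscore_filter(predictions: list[AATypePrediction],
                  cutoff: float) -> list[AATypePrediction]:
    """Retain predictions with zscore >= cutoff; the top-ranked one is
    always kept."""
    if not predictions:
        return []
    kept = [pr for pr in predictions if pr.zscore >= cutoff]
    if not kept:
        kept = [predictions[0]]
    if predictions[0] not in kept:
        kept.insert(0, predictions[0])
    return kept
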