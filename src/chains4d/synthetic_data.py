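"""Ground-truth-labeled synthetic 4D TOCSY/NOESY datasets.

The generator emulates exactly the statistical structure the assignment
algorithm exploits:

* per-spin-system TOCSY patterns holding the aliphatic CH resonances of
  the preceding residue, with configurable random peak dropout;
* NOESY spin systems holding intraresidue CH correlations (present with
  probability 0.99) and sequential ones (0.89), with additional
  atom-type-specific sequential dropouts for the long, mobile sidechain
  ends (Lys delta/epsilon, Arg delta, Met epsilon, and more mildly Leu
  gamma and Ile gamma1) that are known to lose sequential NOEs;
* Gaussian shift jitter per peak — except that the two proton peaks of a
  methylene share one carbon jitter within a spectrum, since they stem
  from a single 13C resonance;
* spurious peaks drawn uniformly over the occupied shift ranges;
* log-normal NOESY intensities with a x3 boost for intraresidue methyls,
  which give characteristically strong amide NOEs.

No long-range NOEs are generated: the assignment algorithm only exploits
intraresidue and sequential correlations, and real long-range peaks act
as noise, which the spurious-peak rate models.

True shifts are drawn from the same density maps the classifier scores
against; amides come from configured Gaussians with a minimum root
separation (overlapped amide roots are a flagged failure mode, not a
clustering benchmark).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import topology
from .assignment_table import AssignmentTable
from .chain_mapping import MappingState
from .shift_statistics import StatsLibrary
from .spectra_io import Peak4D, RootPeak, Sequence

#: sequential-NOE presence for dropout-prone sidechain ends, replacing
#: the global sequential rate
SEQUENTIAL_DROPOUT_TYPES: dict[tuple[str, str], float] = {
    ("K", "CD"): 0.60, ("K", "CE"): 0.60,
    ("R", "CD"): 0.60, ("M", "CE"): 0.60,
    ("L", "CG"): 0.75, ("I", "CG1"): 0.75,
}

AMIDE_N_MEAN, AMIDE_N_SD = 118.8, 4.5
AMIDE_HN_MEAN, AMIDE_HN_SD = 8.3, 0.55
#: minimum root separation (ppm): redrawn if within both windows
ROOT_MIN_SEP_N, ROOT_MIN_SEP_HN = 0.4, 0.08


@dataclass(frozen=True)
class SyntheticConfig:
    n_residues: int = 120
    seed: int = 1
    sigma_c: float = 0.1       # 13C jitter, ppm
    sigma_h: float = 0.01      # 1H jitter, ppm
    sigma_n: float = 0.05      # 15N jitter, ppm
    sigma_hn: float = 0.005    # amide 1H jitter, ppm
    p_tocsy_missing: float = 0.10
    p_noise_peaks: float = 0.05
    p_noe_intra: float = 0.99
    p_noe_seq: float = 0.89
    proline_fraction: float | None = None
    #: "kde": true shifts drawn from the density maps (realistic spread,
    #: including intrinsically ambiguous draws where distributions
    #: overlap); "modes": true shifts at each map's density mode (the
    #: unambiguous perfect-data limit)
    shift_source: str = "kde"
    intensity_sigma: float = 0.7          # log-normal spread
    methyl_intra_boost: float = 3.0
    sequential_dropout: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(SEQUENTIAL_DROPOUT_TYPES))

    def __post_init__(self):
        for p in (self.p_tocsy_missing, self.p_noise_peaks,
                  self.p_noe_intra, self.p_noe_seq):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if min(self.sigma_c, self.sigma_h, self.sigma_n, self.sigma_hn) < 0:
            raise ValueError("jitter sigmas must be >= 0")


@dataclass
class GroundTruth:
    sequence: Sequence
    shifts: dict[tuple[int, str], float]          # (position, atom) -> ppm
    position_of: dict[str, int]                   # AAIG label -> position
    label_of: dict[int, str]                      # position -> AAIG label
    peak_origin: dict[str, list[tuple]]           # spectrum -> per-peak origin

    def root_positions(self) -> list[int]:
        return sorted(self.label_of)

    def aliphatic_atoms(self, pos: int) -> list[topology.CarbonType]:
        return list(topology.carbon_types(self.sequence.residue(pos)))


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_sequence(n: int, seed: int | np.random.Generator,
                    proline_fraction: float | None = None) -> Sequence:
    """Random sequence from the average-composition table."""
    if n < 2:
        raise ValueError("need at least 2 residues")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    aas = sorted(topology.COMPOSITION)
    weights = np.array([topology.COMPOSITION[a] for a in aas], dtype=float)
    if proline_fraction is not None:
        i_p = aas.index("P")
        weights = weights / weights.sum()
        scale = (1.0 - proline_fraction) / (1.0 - weights[i_p])
        weights *= scale
        weights[i_p] = proline_fraction
    weights = weights / weights.sum()
    residues = "".join(rng.choice(aas, size=n, p=weights))
    return Sequence(residues)


def _map_mode(dmap) -> tuple[float, float]:
    """(h, c) of the map's highest-density data point."""
    i = int(np.argmax(dmap.point_densities()))
    return float(dmap.h_data[i]), float(dmap.c_data[i])


def sample_true_shifts(sequence: Sequence, stats: StatsLibrary,
                       seed: int | np.random.Generator,
                       shift_source: str = "kde") -> GroundTruth:
    """Draw every atom's true shifts; amides get well-separated roots."""
    if shift_source not in ("kde", "modes"):
        raise ValueError(f"unknown shift source {shift_source!r}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    shifts: dict[tuple[int, str], float] = {}
    for pos in sequence.positions():
        aa = sequence.residue(pos)
        for ct in topology.carbon_types(aa):
            dmap = stats[(aa, ct.name)]
            if ct.is_methylene:
                if shift_source == "modes":
                    h_mode, c = _map_mode(dmap)
                    h1, h2 = h_mode + 0.08, h_mode - 0.08
                else:
                    (h1, c), (h2, _) = dmap.sample(rng, 2)
                shifts[(pos, ct.name)] = c
                p2, p3 = ct.proton_names()
                shifts[(pos, p2)] = max(h1, h2)
                shifts[(pos, p3)] = min(h1, h2)
            else:
                if shift_source == "modes":
                    h, c = _map_mode(dmap)
                else:
                    (h, c), = dmap.sample(rng, 1)
                shifts[(pos, ct.name)] = c
                shifts[(pos, ct.proton_names()[0])] = h

    root_positions = [pos for pos in sequence.positions()
                      if pos > sequence.first and sequence.residue(pos) != "P"]
    placed: list[tuple[float, float]] = []
    for pos in root_positions:
        while True:
            n = rng.normal(AMIDE_N_MEAN, AMIDE_N_SD)
            hn = rng.normal(AMIDE_HN_MEAN, AMIDE_HN_SD)
            if all(abs(n - n0) >= ROOT_MIN_SEP_N
                   or abs(hn - hn0) >= ROOT_MIN_SEP_HN
                   for n0, hn0 in placed):
                break
        placed.append((n, hn))
        shifts[(pos, "N")] = n
        shifts[(pos, "HN")] = hn

    labels = [f"X{k + 1:03d}" for k in range(len(root_positions))]
    order = rng.permutation(len(root_positions))
    position_of = {labels[int(j)]: root_positions[i]
                   for i, j in enumerate(order)}
    label_of = {pos: lab for lab, pos in position_of.items()}
    return GroundTruth(sequence, shifts, position_of, label_of,
                       peak_origin={})


# ---------------------------------------------------------------------------
# peak-list generation
# ---------------------------------------------------------------------------

def _residue_ch_peaks(truth: GroundTruth, pos: int):
    """(carbon, proton, c_true, h_true) observables of residue pos."""
    aa = truth.sequence.residue(pos)
    for ct in topology.carbon_types(aa):
        c = truth.shifts[(pos, ct.name)]
        for proton in ct.proton_names():
            yield ct, proton, c, truth.shifts[(pos, proton)]


def generate_peaklists(
    truth: GroundTruth,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[RootPeak], list[Peak4D], list[Peak4D]]:
    """Emit root, TOCSY and NOESY peak lists with jitter, dropout, noise
    and intensities; per-peak origins are recorded on
    ``truth.peak_origin``."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    seq = truth.sequence

    roots = [RootPeak(truth.shifts[(pos, "N")], truth.shifts[(pos, "HN")],
                      truth.label_of[pos])
             for pos in truth.root_positions()]

    # one carbon jitter per (spectrum, residue, carbon): the two protons
    # of a methylene share a single 13C resonance within a spectrum
    c_jit: dict[tuple[str, int, str], float] = {}

    def jittered_c(spectrum: str, pos: int, carbon: str, c_true: float) -> float:
        key = (spectrum, pos, carbon)
        if key not in c_jit:
            c_jit[key] = rng.normal(0.0, config.sigma_c)
        return c_true + c_jit[key]

    def amide(pos):
        return (truth.shifts[(pos, "N")] + rng.normal(0.0, config.sigma_n),
                truth.shifts[(pos, "HN")] + rng.normal(0.0, config.sigma_hn))

    tocsy: list[Peak4D] = []
    noesy: list[Peak4D] = []
    t_origin: list[tuple] = []
    n_origin: list[tuple] = []

    for pos in truth.root_positions():
        prev = pos - 1
        # TOCSY: aliphatic CH of the preceding residue
        for ct, proton, c_true, h_true in _residue_ch_peaks(truth, prev):
            if rng.random() < config.p_tocsy_missing:
                continue
            n15, hn = amide(pos)
            tocsy.append(Peak4D(
                h_ali=h_true + rng.normal(0.0, config.sigma_h),
                c_ali=jittered_c("TOCSY", prev, ct.name, c_true),
                n15=n15, hn=hn, intensity=1.0, source="TOCSY"))
            t_origin.append(("tocsy", pos, prev, ct.name, proton))

        # NOESY: intraresidue (i) and sequential (i-1) CH
        for kind, res, p_keep in (("intra", pos, config.p_noe_intra),
                                  ("sequential", prev, config.p_noe_seq)):
            aa = seq.residue(res)
            for ct, proton, c_true, h_true in _residue_ch_peaks(truth, res):
                keep = p_keep
                if kind == "sequential":
                    keep = config.sequential_dropout.get((aa, ct.name),
                                                         p_keep)
                if rng.random() >= keep:
                    continue
                intensity = rng.lognormal(0.0, config.intensity_sigma)
                if kind == "intra" and ct.is_methyl:
                    intensity *= config.methyl_intra_boost
                n15, hn = amide(pos)
                noesy.append(Peak4D(
                    h_ali=h_true + rng.normal(0.0, config.sigma_h),
                    c_ali=jittered_c("NOESY", res, ct.name, c_true),
                    n15=n15, hn=hn, intensity=intensity,
                    source="NOESY_HCNH"))
                n_origin.append((kind, pos, res, ct.name, proton))

    # spurious peaks, uniform over the occupied ranges
    for peaks, origin, spectrum in ((tocsy, t_origin, "TOCSY"),
                                    (noesy, n_origin, "NOESY")):
        if not peaks or config.p_noise_peaks <= 0:
            continue
        n_noise = int(round(config.p_noise_peaks * len(peaks)))
        arr = np.array([[p.h_ali, p.c_ali, p.n15, p.hn] for p in peaks])
        lo, hi = arr.min(axis=0), arr.max(axis=0)
        for _ in range(n_noise):
            h, c, n15, hn = rng.uniform(lo, hi)
            intensity = 1.0 if spectrum == "TOCSY" else \
                rng.lognormal(0.0, config.intensity_sigma)
            peaks.append(Peak4D(h, c, n15, hn, intensity,
                                source="TOCSY" if spectrum == "TOCSY"
                                else "NOESY_HCNH"))
            origin.append(("noise",))

    # shuffle peak order (the pipeline must not depend on it)
    for peaks, origin in ((tocsy, t_origin), (noesy, n_origin)):
        perm = rng.permutation(len(peaks))
        peaks[:] = [peaks[i] for i in perm]
        origin[:] = [origin[i] for i in perm]

    truth.peak_origin = {"TOCSY": t_origin, "NOESY": n_origin}
    return roots, tocsy, noesy


def generate_dataset(
    config: SyntheticConfig,
    stats: StatsLibrary,
) -> tuple[GroundTruth, list[RootPeak], list[Peak4D], list[Peak4D]]:
    """Sequence, true shifts and peak lists in one deterministic call."""
    rng = np.random.default_rng(config.seed)
    seq = sample_sequence(config.n_residues, rng, config.proline_fraction)
    truth = sample_true_shifts(seq, stats, rng, config.shift_source)
    roots, tocsy, noesy = generate_peaklists(truth, config, rng)
    return truth, roots, tocsy, noesy


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def reachable_positions(truth: GroundTruth, min_run: int = 4) -> set[int]:
    """Root positions inside connectivity runs long enough for
    overlap-layout-consensus mapping.

    A run is a maximal stretch of consecutive root positions; contigs
    need two overlapping chains of at least the minimum chain length 3,
    so runs shorter than 4 are structurally unreachable.
    """
    roots = truth.root_positions()
    runs: list[list[int]] = []
    for pos in roots:
        if runs and runs[-1][-1] == pos - 1:
            runs[-1].append(pos)
        else:
            runs.append([pos])
    return {p for run in runs if len(run) >= min_run for p in run}


def _residue_truth_variants(truth: GroundTruth, pos: int):
    """Truth shift dictionaries for a residue, one per allowed prochiral
    orientation (methyl pairs of Leu/Val are not stereo-assigned)."""
    aa = truth.sequence.residue(pos)
    base = {}
    for ct in topology.carbon_types(aa):
        base[ct.name] = truth.shifts[(pos, ct.name)]
        for proton in ct.proton_names():
            base[proton] = truth.shifts[(pos, proton)]
    variants = [base]
    pair = topology.PROCHIRAL_PAIRS.get(aa)
    if pair:
        a, b = pair
        swapped = dict(base)
        swapped[a], swapped[b] = base[b], base[a]
        ha, hb = "H" + a[1:], "H" + b[1:]
        swapped[ha], swapped[hb] = base[hb], base[ha]
        variants.append(swapped)
    return variants


def evaluate(
    table: AssignmentTable,
    state: MappingState,
    truth: GroundTruth,
    tol_c: float = 0.4,
    tol_h: float = 0.04,
) -> dict:
    """Score a run against ground truth.

    A carbon type counts as correctly assigned when its carbon and all
    its assigned protons match the true values within tolerance, under
    the best prochiral orientation.  Mapping completeness is measured
    over the structurally reachable positions; mapping errors over all
    assigned positions.
    """
    # ---- mapping ----
    reachable = reachable_positions(truth)
    mapped = set(state.assigned)
    errors = {pos for pos, lab in state.assigned.items()
              if truth.label_of.get(pos) != lab}
    completeness = (len(mapped & reachable) / len(reachable)
                    if reachable else 0.0)

    # ---- atoms ----
    atom_stats = {"assigned": 0, "correct": 0, "errors": 0}
    methyl_stats = {"assigned": 0, "correct": 0, "errors": 0}
    recovery = {"missing": 0, "assigned": 0, "correct": 0}
    per_provenance: dict[str, int] = {}

    for pos in truth.sequence.positions():
        aa = truth.sequence.residue(pos)
        atoms = table.atoms_of(pos)
        variants = _residue_truth_variants(truth, pos)

        def type_ok(ct, tvals):
            c_entry = atoms.get(ct.name)
            if c_entry is None or abs(c_entry.shift - tvals[ct.name]) > tol_c:
                return False
            protons = [p for p in ct.proton_names() if p in atoms]
            if not protons:
                return False
            if ct.is_methylene:
                # methylene protons carry no stereo assignment: each
                # predicted proton must match a distinct true partner
                pred = [atoms[p].shift for p in protons]
                true = [tvals[p] for p in ct.proton_names()]
                if len(pred) == 1:
                    return any(abs(pred[0] - t) <= tol_h for t in true)
                direct = all(abs(a - b) <= tol_h
                             for a, b in zip(sorted(pred), sorted(true)))
                return direct
            return all(abs(atoms[p].shift - tvals[p]) <= tol_h
                       for p in protons)

        for ct in topology.carbon_types(aa):
            entry = atoms.get(ct.name)
            if entry is None:
                if pos in mapped and pos + 1 <= truth.sequence.last:
                    pass
                continue
            atom_stats["assigned"] += 1
            per_provenance[entry.provenance] = \
                per_provenance.get(entry.provenance, 0) + 1
            ok = any(type_ok(ct, tv) for tv in variants)
            key = "correct" if ok else "errors"
            atom_stats[key] += 1
            if ct.is_methyl:
                methyl_stats["assigned"] += 1
                methyl_stats[key] += 1
            if entry.provenance == "NOESY-common":
                recovery["assigned"] += 1
                recovery["correct"] += ok

        # extension denominator, the "additionally assignable" atoms:
        # true types lacking a TOCSY-derived entry that the common-NOE
        # stage could reach — both flanking spin systems mapped, and both
        # the intraresidue and the sequential NOE observation present in
        # the peak lists (atoms with no data cannot be recovered by any
        # method)
        succ = pos + 1
        if pos in mapped and succ in mapped:
            noesy_origin = truth.peak_origin.get("NOESY", ())
            for ct in topology.carbon_types(aa):
                e = atoms.get(ct.name)
                if e is not None and e.provenance == "TOCSY":
                    continue
                if noesy_origin:
                    intra_seen = any(
                        o[0] == "intra" and o[1] == pos and o[3] == ct.name
                        for o in noesy_origin)
                    seq_seen = any(
                        o[0] == "sequential" and o[1] == succ
                        and o[3] == ct.name for o in noesy_origin)
                    if not (intra_seen and seq_seen):
                        continue
                recovery["missing"] += 1

    n_true_types = sum(len(topology.carbon_types(truth.sequence.residue(p)))
                       for p in truth.sequence.positions())

    def rate(num, den):
        return num / den if den else 0.0

    return {
        "n_residues": len(truth.sequence),
        "n_reachable": len(reachable),
        "n_mapped": len(mapped),
        "mapping_completeness": rate(len(mapped & reachable), len(reachable)),
        "mapping_errors": len(errors),
        "atom_assigned": atom_stats["assigned"],
        "atom_correct": atom_stats["correct"],
        "atom_errors": atom_stats["errors"],
        "atom_error_rate": rate(atom_stats["errors"], atom_stats["assigned"]),
        "atom_completeness": rate(atom_stats["assigned"], n_true_types),
        "methyl_assigned": methyl_stats["assigned"],
        "methyl_errors": methyl_stats["errors"],
        "methyl_error_rate": rate(methyl_stats["errors"],
                                  methyl_stats["assigned"]),
        "recovery_missing": recovery["missing"],
        "recovery_assigned": recovery["assigned"],
        "recovery_correct": recovery["correct"],
        "recovery_rate": rate(recovery["assigned"], recovery["missing"]),
        "recovery_error_rate": rate(
            recovery["assigned"] - recovery["correct"], recovery["assigned"]),
        "assigned_by_provenance": dict(sorted(per_provenance.items())),
    }
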