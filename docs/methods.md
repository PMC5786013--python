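# Methods

This note records the model, the parameter defaults and their
rationale, the numerical choices, and what the synthetic benchmarks do
and do not demonstrate.

## Shift statistics

Amino-acid typing rests on per-(residue type, carbon type) joint
densities of correlated ¹³C–¹H chemical shifts, estimated with a 2D
Gaussian kernel over reference shift pairs.  Bandwidths follow Scott's
rule, h = n^(−1/6), multiplied by the per-dimension sample standard
deviation so they carry ppm units; a single-record map falls back to
the visualization bin sizes (0.04 ppm ¹H, 0.2 ppm ¹³C).  Evaluation is
always the exact kernel sum; the binned grid exists for normalization
checks, percentile references and plotting only.

The repository ships a *synthetic parametric table*
(`data/shift_params.tsv`): one Gaussian per carbon type with means and
standard deviations consistent with published BMRB ranges.  The default
library samples 200 reference records per type from it with a fixed
seed, playing the role of a fixed public statistics table.  Real
record-level tables (TSV: amino_acid, atom_type, c_shift, h_shift) are
read through the same interface.  Aromatic CH, sidechain amides and
re-referencing corrections are out of scope.

`percentile_cutoff(q)` supports two reference sets.  The default ranks
the density values at the map's own data points (cutoff such that q% of
them lie at or above it) — a rank among plausible observations.  The
`"grid"` reference ranks the binned map's density values instead, which
only excludes the map's low-density fringe.  The common-NOE extension
uses the grid reference: its filter exists to reject *implausible*
candidate atom types, and the data-point rank would reject ~20% of
genuine candidates by construction (more, in fact, because data-point
densities are biased upward by their own kernel), capping recovery below
any useful level.

## Spin-system clustering

Peaks attach to the nearest root in scaled (N/HN) distance, within the
matching tolerances; defaults tol_HN = 0.04, tol_N = 0.2, tol_H = 0.04,
tol_C = 0.4 ppm reflect typical digital resolution of non-uniformly
sampled 4D spectra and are configurable everywhere.  Nearest-root
assignment (not first-match) makes clustering independent of peak
order.  Near-duplicate CH pairs within one spin system merge, keeping
the strongest peak.  Roots closer than half-tolerance in both
dimensions are flagged as degenerate, not split.

## Typing

The likelihood P(CCS|AA) is the maximum over injective placements of
the observed CH pairs onto the candidate's carbon types; two pairs with
¹³C differing by ≤0.2 ppm may share one methylene carbon, contributing
the geometric mean (logarithmic average) of their densities.  A residue
offering fewer CH slots than observed pairs has likelihood zero.  The
search is a depth-first branch-and-bound with zero pruning (densities
below 1e-300 prune the branch); ties prefer placements filling
backbone CA/CB first, deterministically.

The prior P(AA) is the composition of residues *preceding a
non-proline* — exactly the population a TOCSY spin system can report,
since prolines contribute no amide root.  Posteriors follow Bayes'
rule over the supported types.

Retained predictions per mapping round are controlled by a Z-score
cutoff.  Z is computed on the posteriors themselves, not their
logarithms: posteriors span tens of orders of magnitude, and on the log
scale the long tail of negligible candidates drags the mean so far down
that junk types (posterior ~1e-6) standardize above zero and flood the
retained sets — measured on the 120-residue benchmark this blocked the
consensus rule badly enough to cost ~20% mapping coverage and introduce
errors.  The top-ranked prediction is always retained.

## Connectivities and chains

A sequential candidate (donor TOCSY spin system → acceptor NOESY spin
system) is graded by occupancy = matched/total donor frequencies.  A
relation must additionally match at least two donor frequencies *or*
match the donor completely.  Rationale: a single coincidental frequency
match is weak evidence, and small donors (glycine patterns: one carbon)
produce chance occupancies of 0.5–1.0 at appreciable rates; without the
rule the loosest rounds saw ~70 spurious relations per 120-residue
dataset (vs ~10 with it), flooding the short-chain rounds with junk
contigs that block consensus.

Chains are all simple paths of 2..6 nodes in the connectivity digraph
(length capped at six for memory), with occurrence probability
P(X) = Π occupancies — occupancy is used directly as the link
probability, since only monotonicity matters.

## Alignment and consensus

Each chain is translated to peptides from its members' retained types;
only mismatch-free, ungapped placements on the sequence survive, which
the mapper finds by walking the sequence directly (equivalent to
enumerating the peptide product, but never materializing it — the
peptide cap in `chains_to_peptides` therefore never engages in the
pipeline).  The placement's BLOSUM90 score is computed through a
Needleman–Wunsch global aligner (Biopython, linear gap penalty −10) and
normalized as S_align = logistic(raw/L) ∈ (0,1] so that Eq.-style
factors are commensurate.  S(X) = P(AA|CCS)·P(X)·S_align per
(position, spin system), summed over chains into C_s.

Consensus: a position is assigned iff (a) every contig covering it —
equivalently every aligned chain possessing an L−1 overlap partner —
proposes the same spin system, and (b) that spin system's C_s is the
*strict* maximum among all proposals there; ties and double-winners
leave positions unassigned (the method prioritizes a near-zero error
rate over coverage).  Chains without overlap partners are spurious and
discarded.  Contig extension terminates when a spin system reappears.

The default iteration schedule is
(L=6, z≥0.0, occ≥0.5) → (5, −0.5, 0.4) → (4, −1.0, 0.3) → (3, −1.0,
0.3), with the last round repeated to a fixed point.  After each round,
mapped spin systems pin their TOCSY letter to the sequence, and
connectivities or placements inconsistent with the mapping are
eliminated.  Assignments are never revoked.

Structural reach: a run of consecutive root positions supports a contig
only if it holds at least two overlapping chains of the minimum length
3, i.e. runs of fewer than 4 mappable positions (short proline-flanked
stretches, chain termini) are unreachable by construction.  Mapping
completeness is therefore reported over reachable positions; the raw
count is also available.

## Atom assignment

TOCSY typing with the residue type fixed by the mapping reuses the
placement search; grouped methylene partners share the averaged carbon
shift, protons ordered by decreasing shift (no stereo assignment is
implied).  Transfer to NOESY walks the sequence backwards, matching
intraresidue peaks first, then sequential ones; each peak takes at most
one label (closest scaled distance wins) and each atom one peak per
pass.

Common-NOE extension, also walking backwards: unexplained peaks of the
residue's own spin system are matched against unexplained peaks of the
successor's; matches are candidate observations of the residue's
missing atoms, scored as density × (100 × normalized intensity²), with
the percentile filter (grid reference, q=80) applied first.  Peak
intensities are normalized per spin system by the maximum absolute
intensity, and the 0.1 threshold applies to the residue's *own* peaks —
the ones an assignment is derived from; the successor's peak only
corroborates commonality and may be weak.  Peaks claimed by the
transfer stage at a loose match distance (>0.6 of the scaled tolerance)
are offered back to the extension as candidates: a nearest-match claim
can coincidentally grab the peak of an atom missing from TOCSY when the
true owner's competitor peak is absent, and on the benchmarks ~30% of
recoverable atoms were lost this way before re-admission.  Methylene
groups may take two peaks (¹³C within the grouping threshold), scored
by the product.  Conflicting table entries resolve by provenance:
root > TOCSY > NOESY (through-bond TOCSY assignments have a much lower
intrinsic error rate than through-space inferences).

The NOESY-only mode runs the same extension with *every* aliphatic atom
missing, on spin systems built from externally supplied amide
assignments.

## Synthetic data

The generator emits, per non-proline non-terminal residue: TOCSY peaks
for each aliphatic CH of the preceding residue (dropped with
p_tocsy_missing, default 0.10); NOESY peaks for the residue's own CH
(kept with p_noe_intra = 0.99) and the preceding residue's CH (kept
with p_noe_seq = 0.89, further reduced to 0.60 for Lys δ/ε, Arg δ,
Met ε and 0.75 for Leu γ, Ile γ1 — the sidechain ends known to lose
sequential NOEs); spurious peaks uniform over the occupied ranges at
rate p_noise_peaks (default 0.05, also standing in for real long-range
NOEs, which are deliberately not modeled — the assignment logic only
exploits intra/sequential contacts, and anything else acts as noise).

True shifts are drawn from the same density maps the classifier scores
against; amide roots come from N(118.8, 4.5) × N(8.3, 0.55) ppm with a
minimum separation (0.4 ppm ¹⁵N or 0.08 ppm ¹H_N) — truly overlapped
roots are a flagged failure mode of the method, not something the
generator benchmarks.  Jitter defaults: σ_C = 0.1, σ_H = 0.01,
σ_N = 0.05, σ_HN = 0.005 ppm, applied per peak — except that the two
proton peaks of a methylene share one carbon jitter within a spectrum,
because they arise from a single ¹³C resonance; with independent carbon
jitter ~16% of methylene peak pairs would spuriously exceed the 0.2 ppm
grouping threshold, contradicting how methylenes present in real
spectra.  NOESY intensities are log-normal (σ = 0.7) with a ×3 boost
for intraresidue methyls, which give characteristically strong amide
NOEs.  A `shift_source="modes"` option places every true shift at its
map's density mode — the unambiguous limit used for typing tests; it
cannot be used for mapping benchmarks, because identical per-type
shifts destroy the uniqueness that sequential matching relies on.

What the generator does *not* emulate: conformation-dependent secondary
shifts (true shifts are independent draws, so within-residue shift
correlations are absent), long-range NOEs with spatial structure,
spectral artifacts, and amide overlap.  Independent draws make
neighbouring atom types *harder* to distinguish than in real proteins
(a real Arg with an unusually high CB tends to have a coherently
shifted CG); the residual ~1% aliphatic error rate on the benchmarks is
dominated by exactly such statistically inverted draws — cases where
the likelihood-maximizing placement is genuinely the wrong one and no
shift-based method could decide otherwise.  Passing benchmarks
therefore demonstrate the pipeline's bookkeeping and decision rules
under realistic noise, not performance on any particular real protein.

## Evaluation

A carbon type counts as correct when its carbon and all assigned
protons match the truth within the matching tolerances, with methylene
protons compared up to permutation (they carry no stereo assignment)
and the prochiral methyl pairs Leu CD1/CD2 and Val CG1/CG2 allowed to
swap.  Mapping completeness is measured over reachable positions;
mapping errors over all assigned ones.  Common-NOE recovery is reported
over the "additionally assignable" atoms: those missing a TOCSY-derived
entry whose flanking spin systems are mapped and whose intraresidue and
sequential observations exist in the peak lists — atoms with no data
cannot be recovered by any method and would only measure the generator.

## Problem sizes

The shipped benchmarks use 120-residue proteins (three to five seeds
per scenario) and a 200-sample-per-type statistics library; a full
pipeline run takes well under a second, the whole test suite under a
minute, chosen to keep the feedback loop tight while being large enough
for stable rates.

## Known limitations

* No aromatic CH, sidechain NH₂ or stereo-specific assignments.
* Overlapped amide roots are flagged, not resolved.
* Proline-flanked runs shorter than four root positions cannot be
  mapped by the consensus scheme.
* The statistics table is parametric-synthetic; for real data a
  VASCO/BMRB-derived record table should be supplied.
* The NOESY-only mode assigns only atoms observable as common NOEs;
  residues preceding prolines or at the C-terminus are out of reach.
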