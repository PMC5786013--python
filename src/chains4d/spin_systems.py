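"""Clustering of 4D peaks into spin systems (AAIGs) via root resonances.

Every backbone amide gives one root 15N-1H resonance.  All 4D TOCSY and
NOESY cross-peaks sharing that root (within tolerance) form the amide's
Amino Acid Index Group (AAIG): the TOCSY members are the aliphatic CH
resonances of the *preceding* residue (i-1), the NOESY members are CH
moieties spatially close to the amide (dominated by intraresidue i and
sequential i-1 contacts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .spectra_io import Peak4D, RootPeak

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Tolerances:
    """Shift-matching tolerances (ppm).

    Defaults reflect typical digital resolution of non-uniformly sampled
    4D spectra; all are configurable.
    """

    tol_hn: float = 0.04
    tol_n15: float = 0.2
    tol_h: float = 0.04
    tol_c: float = 0.4

    def __post_init__(self):
        if min(self.tol_hn, self.tol_n15, self.tol_h, self.tol_c) <= 0:
            raise ValueError("all tolerances must be positive")


@dataclass(frozen=True)
class CHPair:
    """One aliphatic 13C-1H resonance pair inside an AAIG."""

    c: float
    h: float
    intensity: float = 1.0
    origin: str = "NOESY"      # "TOCSY" | "NOESY"
    peak_index: int = -1       # index into the source peak list


@dataclass
class AAIG:
    """A spin system: root amide resonance plus its TOCSY/NOESY CH pairs."""

    label: str
    root_n15: float
    root_hn: float
    tocsy: list[CHPair] = field(default_factory=list)
    noesy: list[CHPair] = field(default_factory=list)


def match_ch(a: CHPair, b: CHPair, tol: Tolerances) -> bool:
    """True iff two CH pairs coincide within tolerance (closed boundary)."""
    return abs(a.c - b.c) <= tol.tol_c and abs(a.h - b.h) <= tol.tol_h


def _merge_duplicates(pairs: list[CHPair], tol: Tolerances) -> list[CHPair]:
    """Collapse near-duplicate CH pairs, keeping the strongest peak.

    Duplicates arise from noise or from peaks split across planes; within
    an AAIG two pairs within tolerance carry the same information.
    """
    kept: list[CHPair] = []
    for p in sorted(pairs, key=lambda p: (-abs(p.intensity), p.c, p.h)):
        if not any(match_ch(p, q, tol) for q in kept):
            kept.append(p)
    return sorted(kept, key=lambda p: (p.c, p.h))


def cluster_peaks(
    tocsy: list[Peak4D],
    noesy: list[Peak4D],
    roots: list[RootPeak],
    tol: Tolerances = Tolerances(),
) -> tuple[list[AAIG], list[Peak4D]]:
    """Attach every 4D peak to the nearest root within tolerance.

    Assignment is by scaled (Mahalanobis-like) distance in the (N, HN)
    plane so the result does not depend on peak order.  Peaks matching no
    root are returned as orphans.  Every root yields an AAIG, possibly
    with an empty TOCSY set.

    Returns ``(aaigs, orphans)``.
    """
    if not roots:
        raise ValueError("at least one root resonance is required")

    _warn_degenerate_roots(roots, tol)

    root_n = np.array([r.n15 for r in roots])
    root_hn = np.array([r.hn for r in roots])
    aaigs = [AAIG(r.label, r.n15, r.hn) for r in roots]
    orphans: list[Peak4D] = []

    for source, peaks in (("TOCSY", tocsy), ("NOESY", noesy)):
        if not peaks:
            continue
        pn = np.array([p.n15 for p in peaks])
        phn = np.array([p.hn for p in peaks])
        # scaled squared distance to every root
        dn = (pn[:, None] - root_n[None, :]) / tol.tol_n15
        dhn = (phn[:, None] - root_hn[None, :]) / tol.tol_hn
        d2 = dn * dn + dhn * dhn
        nearest = np.argmin(d2, axis=1)
        within = (np.abs(pn[:, None] - root_n[None, :]) <= tol.tol_n15) & \
                 (np.abs(phn[:, None] - root_hn[None, :]) <= tol.tol_hn)
        for i, p in enumerate(peaks):
            j = int(nearest[i])
            if not within[i, j]:
                # nearest root may be outside the box while another is in:
                candidates = np.flatnonzero(within[i])
                if candidates.size == 0:
                    orphans.append(p)
                    continue
                j = int(candidates[np.argmin(d2[i, candidates])])
            pair = CHPair(c=p.c_ali, h=p.h_ali, intensity=p.intensity,
                          origin=source, peak_index=i)
            (aaigs[j].tocsy if source == "TOCSY" else aaigs[j].noesy).append(pair)

    for a in aaigs:
        a.tocsy = _merge_duplicates(a.tocsy, tol)
        a.noesy = _merge_duplicates(a.noesy, tol)

    if orphans:
        log.info("clustering: %d orphan peaks matched no root", len(orphans))
    return aaigs, orphans


def _warn_degenerate_roots(roots: list[RootPeak], tol: Tolerances) -> None:
    n = np.array([r.n15 for r in roots])
    hn = np.array([r.hn for r in roots])
    close_n = np.abs(n[:, None] - n[None, :]) < 0.5 * tol.tol_n15
    close_hn = np.abs(hn[:, None] - hn[None, :]) < 0.5 * tol.tol_hn
    ii, jj = np.nonzero(np.triu(close_n & close_hn, k=1))
    for i, j in zip(ii, jj):
        log.warning("degenerate roots: %s and %s overlap within half "
                    "tolerance", roots[i].label, roots[j].label)
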