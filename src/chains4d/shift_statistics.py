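"""Correlated 13C-1H chemical-shift statistics as 2D kernel densities.

Amino-acid typing from chemical shifts needs, for every aliphatic carbon
type of every residue type, the joint distribution of its (1H, 13C) shift
pair.  Joint ("correlated") densities discriminate far better than the
product of the two 1D marginals, because proton and carbon shifts of one
atom co-vary.  Each map is a Gaussian kernel density estimate over
reference shift pairs (H_i, C_i):

    G(H0, C0) = 1/(2 pi n h_H h_C) * sum_i exp(-1/2 [ (H_i-H0)^2/h_H^2
                                                    + (C_i-C0)^2/h_C^2 ])

with per-dimension bandwidths chosen by Scott's rule, h = n^(-1/6) scaled
by the sample standard deviation of that dimension.

Evaluation is always the exact kernel sum; the binned grid (0.04 ppm 1H x
0.2 ppm 13C) exists for visualization and for normalization checks only.

The repository ships a parametric table (one Gaussian per carbon type,
means/SDs consistent with published BMRB ranges) from which reference
records are sampled, so no external statistics download is required; a
plain record table (TSV: amino_acid, atom_type, c_shift, h_shift) is read
through the same interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from . import topology

#: Fallback bandwidths (ppm) when a map has a single record: the
#: visualization bin sizes.
MIN_BANDWIDTH_H = 0.04
MIN_BANDWIDTH_C = 0.2

DEFAULT_BIN_H = 0.04
DEFAULT_BIN_C = 0.2


@dataclass(frozen=True)
class ShiftRecord:
    """One reference 13C-1H correlated shift observation."""

    amino_acid: str   # one-letter code
    atom_type: str    # carbon name, e.g. "CB"
    c_shift: float    # ppm 13C
    h_shift: float    # ppm 1H

    def __post_init__(self) -> None:
        if self.amino_acid not in topology.ALIPHATIC:
            raise ValueError(f"unknown amino acid {self.amino_acid!r}")
        topology.carbon(self.amino_acid, self.atom_type)
        if not (math.isfinite(self.c_shift) and math.isfinite(self.h_shift)):
            raise ValueError("shift values must be finite")


def scott_bandwidth(n: int) -> float:
    """Scott's rule-of-thumb bandwidth factor, n^(-1/6).

    The factor is dimensionless; callers multiply it by the sample standard
    deviation of each dimension to obtain a bandwidth in ppm.
    """
    if n < 1:
        raise ValueError(f"sample count must be >= 1, got {n}")
    return float(n) ** (-1.0 / 6.0)


@dataclass
class DensityMap2D:
    """Gaussian-kernel density of correlated (1H, 13C) shifts for one
    (amino acid, carbon type)."""

    amino_acid: str
    atom_type: str
    h_data: np.ndarray          # reference 1H shifts, ppm
    c_data: np.ndarray          # reference 13C shifts, ppm
    h_H: float                  # 1H bandwidth, ppm
    h_C: float                  # 13C bandwidth, ppm
    bin_h: float = DEFAULT_BIN_H
    bin_c: float = DEFAULT_BIN_C
    _grid: tuple[np.ndarray, np.ndarray, np.ndarray] | None = field(
        default=None, repr=False)
    _point_densities: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.h_data.size

    @property
    def label(self) -> str:
        return topology.atom_type_label(self.amino_acid, self.atom_type)

    def density_at(self, h, c):
        """Exact kernel-sum density at (h, c); accepts scalars or arrays."""
        h = np.asarray(h, dtype=float)
        c = np.asarray(c, dtype=float)
        dh = (self.h_data - h[..., None]) / self.h_H
        dc = (self.c_data - c[..., None]) / self.h_C
        k = np.exp(-0.5 * (dh * dh + dc * dc)).sum(axis=-1)
        out = k / (2.0 * math.pi * self.n * self.h_H * self.h_C)
        return float(out) if out.ndim == 0 else out

    # -- grid (visualization / normalization checks) --------------------
    def grid(self, pad_bandwidths: float = 6.0):
        """(h_axis, c_axis, density) on the binned grid, padded beyond the
        data range by ``pad_bandwidths`` bandwidths."""
        if self._grid is None:
            h0 = self.h_data.min() - pad_bandwidths * self.h_H
            h1 = self.h_data.max() + pad_bandwidths * self.h_H
            c0 = self.c_data.min() - pad_bandwidths * self.h_C
            c1 = self.c_data.max() + pad_bandwidths * self.h_C
            h_axis = np.arange(h0, h1 + self.bin_h, self.bin_h)
            c_axis = np.arange(c0, c1 + self.bin_c, self.bin_c)
            hh, cc = np.meshgrid(h_axis, c_axis, indexing="ij")
            dens = self.density_at(hh.ravel(), cc.ravel()).reshape(hh.shape)
            self._grid = (h_axis, c_axis, dens)
        return self._grid

    def grid_integral(self) -> float:
        """Midpoint-rule integral of the binned grid (should be ~1)."""
        _, _, dens = self.grid()
        return float(dens.sum() * self.bin_h * self.bin_c)

    # -- percentile filter ----------------------------------------------
    def point_densities(self) -> np.ndarray:
        if self._point_densities is None:
            self._point_densities = self.density_at(self.h_data, self.c_data)
        return self._point_densities

    def percentile_cutoff(self, q: float, reference: str = "points") -> float:
        """Density cutoff of the q-th percentile region.

        With ``reference="points"`` the reference set is the density
        evaluated at the map's own data points: the cutoff is chosen so
        that q% of those densities lie at or above it (a rank among
        observed shifts).  With ``reference="grid"`` the reference set is
        the binned map itself, so the cutoff only excludes the map's
        low-density fringe — the appropriate reading when the filter's
        job is to reject implausible candidates rather than to rank
        plausible ones.  ``density_at(x) >= cutoff`` classifies x as
        inside the q-th percentile region.
        """
        if not 0.0 < q < 100.0:
            raise ValueError(f"percentile must be in (0, 100), got {q}")
        if reference == "points":
            ref = self.point_densities()
        elif reference == "grid":
            ref = self.grid()[2].ravel()
        else:
            raise ValueError(f"unknown reference {reference!r}")
        return float(np.percentile(ref, 100.0 - q))

    # -- sampling (used by the synthetic-data generator) ----------------
    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Draw (h, c) pairs from the KDE (data point + kernel noise)."""
        idx = rng.integers(0, self.n, size=size)
        h = self.h_data[idx] + rng.normal(0.0, self.h_H, size=size)
        c = self.c_data[idx] + rng.normal(0.0, self.h_C, size=size)
        return np.column_stack([h, c])


def build_density_map(
    records: list[ShiftRecord],
    bandwidth_rule: str = "scott",
    bin_h: float = DEFAULT_BIN_H,
    bin_c: float = DEFAULT_BIN_C,
) -> DensityMap2D:
    """Build one density map from homogeneous records."""
    if not records:
        raise ValueError("cannot build a density map from zero records")
    keys = {(r.amino_acid, r.atom_type) for r in records}
    if len(keys) != 1:
        raise ValueError(f"records mix several (aa, atom) keys: {keys}")
    aa, atom = next(iter(keys))
    h = np.array([r.h_shift for r in records], dtype=float)
    c = np.array([r.c_shift for r in records], dtype=float)
    n = h.size
    if bandwidth_rule != "scott":
        raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
    if n == 1:
        h_H, h_C = MIN_BANDWIDTH_H, MIN_BANDWIDTH_C
    else:
        f = scott_bandwidth(n)
        h_H = max(f * float(h.std(ddof=1)), MIN_BANDWIDTH_H)
        h_C = max(f * float(c.std(ddof=1)), MIN_BANDWIDTH_C)
    return DensityMap2D(aa, atom, h, c, h_H, h_C, bin_h=bin_h, bin_c=bin_c)


class StatsLibrary:
    """Collection of density maps, one per (amino acid, carbon type)."""

    def __init__(self, maps: dict[tuple[str, str], DensityMap2D]):
        # every aliphatic carbon of every residue type, exactly once
        expected = {(aa, ct.name)
                    for aa, cts in topology.ALIPHATIC.items() for ct in cts}
        missing = expected - set(maps)
        extra = set(maps) - expected
        if missing or extra:
            raise ValueError(
                f"library incomplete: missing={sorted(missing)} "
                f"extra={sorted(extra)}")
        self.maps = dict(sorted(maps.items()))
        self._cache = None

    def __getitem__(self, key: tuple[str, str]) -> DensityMap2D:
        return self.maps[key]

    def maps_for(self, aa: str) -> list[DensityMap2D]:
        return [self.maps[(aa, ct.name)]
                for ct in topology.carbon_types(aa)]

    def _eval_cache(self):
        if self._cache is None:
            keys = list(self.maps)
            h = np.concatenate([self.maps[k].h_data for k in keys])
            c = np.concatenate([self.maps[k].c_data for k in keys])
            hH = np.concatenate([
                np.full(self.maps[k].n, self.maps[k].h_H) for k in keys])
            hC = np.concatenate([
                np.full(self.maps[k].n, self.maps[k].h_C) for k in keys])
            sizes = np.array([self.maps[k].n for k in keys])
            offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
            scale = np.array([
                1.0 / (2.0 * math.pi * self.maps[k].n
                       * self.maps[k].h_H * self.maps[k].h_C)
                for k in keys])
            self._cache = (keys, h, c, hH, hC, offsets, scale)
        return self._cache

    def densities(self, h_queries, c_queries) -> dict[tuple[str, str], np.ndarray]:
        """Evaluate every map at every query point in one vectorized pass.

        Returns ``{(aa, carbon): array of len(queries)}``; equivalent to
        calling :meth:`DensityMap2D.density_at` per map but much faster for
        the typing loop, which scores each spin system against all maps.
        """
        keys, h, c, hH, hC, offsets, scale = self._eval_cache()
        hq = np.asarray(h_queries, dtype=float)[:, None]
        cq = np.asarray(c_queries, dtype=float)[:, None]
        dh = (h[None, :] - hq) / hH[None, :]
        dc = (c[None, :] - cq) / hC[None, :]
        kern = np.exp(-0.5 * (dh * dh + dc * dc))
        sums = np.add.reduceat(kern, offsets, axis=1)
        sums *= scale[None, :]
        return {k: sums[:, i] for i, k in enumerate(keys)}


# ---------------------------------------------------------------------------
# readers / default library
# ---------------------------------------------------------------------------

def read_shift_records(path: str | Path) -> list[ShiftRecord]:
    """Read a record table: TSV columns amino_acid, atom_type, c_shift,
    h_shift; ``#`` comment lines and an optional header row are skipped."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "amino_acid":
                continue
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, "
                    f"got {len(parts)}")
            aa, atom, c_s, h_s = parts
            try:
                records.append(ShiftRecord(aa, atom, float(c_s), float(h_s)))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return records


def library_from_records(records: list[ShiftRecord]) -> StatsLibrary:
    groups: dict[tuple[str, str], list[ShiftRecord]] = {}
    for r in records:
        groups.setdefault((r.amino_acid, r.atom_type), []).append(r)
    return StatsLibrary({k: build_density_map(v) for k, v in groups.items()})


def read_param_table(path: str | Path | None = None) -> dict[tuple[str, str], tuple[float, float, float, float]]:
    """Read the parametric table: aa, atom, mean_c, sd_c, mean_h, sd_h."""
    if path is None:
        ref = resources.files("chains4d.data").joinpath("shift_params.tsv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    params = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ValueError(
                f"param table line {lineno}: expected 6 columns, got {len(parts)}")
        aa, atom, mc, sc, mh, sh = parts
        params[(aa, atom)] = (float(mc), float(sc), float(mh), float(sh))
    return params


def default_library(n_per_type: int = 200, seed: int = 7,
                    params_path: str | Path | None = None) -> StatsLibrary:
    """Sample reference records from the parametric table and build maps.

    The library plays the role of a fixed reference statistics table: its
    seed is independent of the analysis seed and defaults to a constant so
    that every run scores shifts against the same maps.
    """
    if n_per_type < 1:
        raise ValueError("n_per_type must be >= 1")
    params = read_param_table(params_path)
    rng = np.random.default_rng(seed)
    maps = {}
    for (aa, atom) in sorted(params):
        mc, sc, mh, sh = params[(aa, atom)]
        c = rng.normal(mc, sc, size=n_per_type)
        h = rng.normal(mh, sh, size=n_per_type)
        recs = [ShiftRecord(aa, atom, ci, hi) for ci, hi in zip(c, h)]
        maps[(aa, atom)] = build_density_map(recs)
    return StatsLibrary(maps)
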