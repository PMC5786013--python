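"""Readers and writers for the plain-text NMR formats the pipeline speaks.

* Sparky peak lists (.list): whitespace-separated; first column an
  assignment label, then one shift column per axis in a declared order,
  last numeric column the peak intensity (optional, defaults to 1.0).
* Single-record FASTA for the protein sequence.
* XEASY .prot chemical-shift tables (index, shift, error, atom, residue).
* Annotated Sparky lists with the label column rewritten from an
  assignment table, for visual verification of the results.

All parse errors carry the file name and line number.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from . import topology
from .assignment_table import XEASY_ERRORS, AssignmentTable, ShiftAssignment

#: canonical axis order of a Peak4D: aliphatic 1H, aliphatic 13C, 15N, amide 1H
CANONICAL_AXES = ("h", "c", "n", "hn")


class ParseError(ValueError):
    pass


@dataclass(frozen=True)
class Peak4D:
    """One 4D cross-peak: aliphatic CH correlated to a backbone amide."""

    h_ali: float
    c_ali: float
    n15: float
    hn: float
    intensity: float = 1.0
    source: str = "NOESY_HCNH"   # "TOCSY" | "NOESY_HCNH"
    label: str = "?-?-?-?"


@dataclass(frozen=True)
class RootPeak:
    """One 15N-1H root (HSQC) resonance identifying a spin system."""

    n15: float
    hn: float
    label: str


@dataclass(frozen=True)
class Sequence:
    """Protein sequence with 1-based numbering plus a configurable offset."""

    residues: str
    offset: int = 0   # residue number of position 1 is offset + 1

    def __post_init__(self):
        if len(self.residues) < 2:
            raise ValueError("sequence must have at least 2 residues")
        bad = set(self.residues) - set(topology.AA1)
        if bad:
            raise ValueError(f"non-standard residue codes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def first(self) -> int:
        return self.offset + 1

    @property
    def last(self) -> int:
        return self.offset + len(self.residues)

    def positions(self) -> range:
        return range(self.first, self.last + 1)

    def residue(self, pos: int) -> str:
        if not self.first <= pos <= self.last:
            raise IndexError(f"position {pos} outside sequence "
                             f"[{self.first}, {self.last}]")
        return self.residues[pos - 1 - self.offset]


# ---------------------------------------------------------------------------
# Sparky peak lists
# ---------------------------------------------------------------------------

def _is_header(tokens: list[str]) -> bool:
    return tokens[0].lower() in ("assignment",) or not any(
        _is_number(t) for t in tokens)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_sparky_peaks(
    path: str | Path,
    axis_order: tuple[str, ...] = CANONICAL_AXES,
    source: str = "NOESY_HCNH",
) -> list[Peak4D]:
    """Read a 4D Sparky list into canonical Peak4D records.

    ``axis_order`` names the w1..w4 columns with the canonical axis keys
    ``("h", "c", "n", "hn")`` in the file's order.
    """
    if sorted(axis_order) != sorted(CANONICAL_AXES):
        raise ValueError(f"axis_order must be a permutation of "
                         f"{CANONICAL_AXES}, got {axis_order}")
    peaks = []
    for lineno, tokens in _data_lines(path):
        if len(tokens) not in (5, 6):
            raise ParseError(
                f"{path}:{lineno}: expected label + 4 shifts "
                f"[+ intensity], got {len(tokens)} columns")
        label = tokens[0]
        try:
            values = [float(t) for t in tokens[1:]]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric shift: {exc}") from None
        shifts = dict(zip(axis_order, values[:4]))
        intensity = values[4] if len(values) == 5 else 1.0
        peaks.append(Peak4D(h_ali=shifts["h"], c_ali=shifts["c"],
                            n15=shifts["n"], hn=shifts["hn"],
                            intensity=intensity, source=source, label=label))
    return peaks


def read_sparky_roots(path: str | Path,
                      axis_order: tuple[str, str] = ("n", "hn")) -> list[RootPeak]:
    """Read a 2D root (15N-1H HSQC) Sparky list."""
    if sorted(axis_order) != ["hn", "n"]:
        raise ValueError(f"axis_order must be a permutation of ('n','hn')")
    roots = []
    seen = set()
    for lineno, tokens in _data_lines(path):
        if len(tokens) < 3:
            raise ParseError(f"{path}:{lineno}: expected label + 2 shifts")
        label = tokens[0]
        try:
            values = [float(t) for t in tokens[1:3]]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric shift: {exc}") from None
        if label in seen:
            raise ParseError(f"{path}:{lineno}: duplicate root label {label!r}")
        seen.add(label)
        shifts = dict(zip(axis_order, values))
        roots.append(RootPeak(n15=shifts["n"], hn=shifts["hn"], label=label))
    return roots


def _data_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if not tokens or line.lstrip().startswith("#"):
                continue
            if lineno == 1 and _is_header(tokens):
                continue
            yield lineno, tokens


def write_sparky_peaks(peaks: list[Peak4D], path: str | Path,
                       axis_order: tuple[str, ...] = CANONICAL_AXES) -> None:
    with open(path, "w") as fh:
        fh.write("      Assignment        w1        w2        w3        w4"
                 "   Data Height\n\n")
        for p in peaks:
            shifts = {"h": p.h_ali, "c": p.c_ali, "n": p.n15, "hn": p.hn}
            cols = "".join(f"{shifts[a]:10.3f}" for a in axis_order)
            fh.write(f"{p.label:>16s}{cols}{p.intensity:14.5g}\n")


def write_sparky_roots(roots: list[RootPeak], path: str | Path,
                       axis_order: tuple[str, str] = ("n", "hn")) -> None:
    with open(path, "w") as fh:
        fh.write("      Assignment        w1        w2\n\n")
        for r in roots:
            shifts = {"n": r.n15, "hn": r.hn}
            cols = "".join(f"{shifts[a]:10.3f}" for a in axis_order)
            fh.write(f"{r.label:>16s}{cols}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, offset: int = 0) -> Sequence:
    """Read a single-record FASTA file into a Sequence."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise ParseError(f"{path}: expected exactly one record, "
                         f"found {len(records)}")
    return Sequence(str(records[0].seq).upper(), offset=offset)


def write_fasta(sequence: Sequence, path: str | Path, name: str = "seq") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        res = sequence.residues
        for i in range(0, len(res), 60):
            fh.write(res[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# XEASY .prot
# ---------------------------------------------------------------------------

def write_xeasy_shifts(table: AssignmentTable, path: str | Path,
                       sequence: Sequence | None = None) -> None:
    """Write an XEASY .prot shift table.

    Columns: running index, shift (ppm), error, atom name, residue number;
    ordering is deterministic (residue, canonical atom order).
    """
    entries = table.entries()
    if sequence is not None:
        for e in entries:
            if not sequence.first <= e.residue <= sequence.last:
                raise ValueError(f"residue {e.residue} outside sequence")
    with open(path, "w") as fh:
        for i, e in enumerate(entries, 1):
            err = XEASY_ERRORS[e.nucleus]
            fh.write(f"{i:4d} {e.shift:8.3f} {err:6.3f} "
                     f"{e.atom:<5s} {e.residue:4d}\n")


def read_xeasy_shifts(path: str | Path,
                      provenance: str = "TOCSY") -> AssignmentTable:
    """Read an XEASY .prot table back (provenance is not stored in the
    format and must be supplied)."""
    table = AssignmentTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if not tokens or line.startswith("#"):
                continue
            if len(tokens) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns")
            try:
                shift = float(tokens[1])
                residue = int(tokens[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            atom = tokens[3]
            nucleus = "N" if atom == "N" else atom[0]
            table.add(ShiftAssignment(residue, atom, shift, nucleus,
                                      provenance))
    return table


# ---------------------------------------------------------------------------
# annotated peak lists
# ---------------------------------------------------------------------------

#: label grammar for assigned peaks: ``<aa><residue><carbon>-<proton>``,
#: e.g. ``K33CD-HD2``; unassigned peaks keep ``?-?-?-?``.
LABEL_RE = re.compile(r"^([A-Z])(\d+)(C[A-Z0-9]*)-(H[A-Z0-9]*)$")


def format_peak_label(aa: str, residue: int, carbon: str, proton: str) -> str:
    return f"{aa}{residue}{carbon}-{proton}"


def parse_peak_label(label: str) -> tuple[str, int, str, str] | None:
    """Inverse of :func:`format_peak_label`; None for unassigned labels."""
    m = LABEL_RE.match(label)
    if m is None:
        return None
    aa, residue, carbon, proton = m.groups()
    return aa, int(residue), carbon, proton


def write_assigned_peaklists(
    peaks: list[Peak4D],
    labels: dict[int, str],
    path: str | Path,
    axis_order: tuple[str, ...] = CANONICAL_AXES,
) -> None:
    """Write a Sparky list with labels rewritten from ``labels``
    (peak index -> label); unlabeled peaks keep ``?-?-?-?``."""
    relabeled = [
        Peak4D(p.h_ali, p.c_ali, p.n15, p.hn, p.intensity, p.source,
               labels.get(i, "?-?-?-?"))
        for i, p in enumerate(peaks)
    ]
    write_sparky_peaks(relabeled, path, axis_order=axis_order)
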