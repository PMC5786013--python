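"""Chemical-shift assignment table: residue/atom -> shift with provenance."""

from __future__ import annotations

from dataclasses import dataclass

from . import topology

#: Where an assigned shift came from.
PROVENANCES = ("root", "TOCSY", "NOESY-intra", "NOESY-common")

#: Default XEASY error-column values per nucleus.
XEASY_ERRORS = {"C": 0.2, "H": 0.02, "N": 0.2}


@dataclass(frozen=True)
class ShiftAssignment:
    residue: int        # sequence position (1-based + offset)
    atom: str           # atom name, e.g. "CA", "HB2", "N", "HN"
    shift: float        # ppm
    nucleus: str        # "C" | "H" | "N"
    provenance: str
    score: float = 0.0

    def __post_init__(self):
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.nucleus not in ("C", "H", "N"):
            raise ValueError(f"unknown nucleus {self.nucleus!r}")


def _atom_sort_key(atom: str) -> tuple:
    """Canonical within-residue atom order: N, HN, then backbone-out
    carbons each followed by their protons."""
    order = ["N", "HN",
             "CA", "HA", "HA2", "HA3",
             "CB", "HB", "HB2", "HB3",
             "CG", "HG", "HG2", "HG3",
             "CG1", "HG1", "HG12", "HG13",
             "CG2", "HG21",
             "CD", "HD2", "HD3",
             "CD1", "HD1", "CD2",
             "CE", "HE", "HE2", "HE3"]
    try:
        return (0, order.index(atom))
    except ValueError:
        return (1, atom)


class AssignmentTable:
    """One shift per (residue, atom), with provenance and score.

    Merging follows source reliability: through-bond TOCSY assignments
    override through-space (NOESY) ones on conflict; conflicts are
    recorded on :attr:`conflicts`.
    """

    #: higher value wins a merge conflict
    _PRIORITY = {"root": 3, "TOCSY": 2, "NOESY-intra": 1, "NOESY-common": 0}

    def __init__(self):
        self._entries: dict[tuple[int, str], ShiftAssignment] = {}
        self.conflicts: list[tuple[ShiftAssignment, ShiftAssignment]] = []

    def __len__(self):
        return len(self._entries)

    def __contains__(self, key: tuple[int, str]) -> bool:
        return key in self._entries

    def get(self, residue: int, atom: str) -> ShiftAssignment | None:
        return self._entries.get((residue, atom))

    def add(self, entry: ShiftAssignment, on_conflict: str = "error") -> None:
        key = (entry.residue, entry.atom)
        old = self._entries.get(key)
        if old is None:
            self._entries[key] = entry
            return
        if on_conflict == "error":
            raise ValueError(f"duplicate assignment for residue "
                             f"{entry.residue} atom {entry.atom}")
        # priority merge: keep the more reliable provenance
        kept, dropped = ((old, entry)
                         if self._PRIORITY[old.provenance]
                         >= self._PRIORITY[entry.provenance]
                         else (entry, old))
        self._entries[key] = kept
        self.conflicts.append((kept, dropped))

    def entries(self) -> list[ShiftAssignment]:
        """All assignments, ordered by residue then canonical atom order."""
        return [self._entries[k] for k in
                sorted(self._entries, key=lambda k: (k[0], _atom_sort_key(k[1])))]

    def residues(self) -> list[int]:
        return sorted({r for r, _ in self._entries})

    def atoms_of(self, residue: int) -> dict[str, ShiftAssignment]:
        return {a: e for (r, a), e in self._entries.items() if r == residue}

    def merged_with(self, other: "AssignmentTable") -> "AssignmentTable":
        out = AssignmentTable()
        for e in self.entries():
            out.add(e)
        for e in other.entries():
            out.add(e, on_conflict="merge")
        return out


def validate_against_sequence(table: AssignmentTable, sequence) -> None:
    """Check residue numbers and atom names against a Sequence."""
    for e in table.entries():
        aa = sequence.residue(e.residue)
        if e.atom in ("N", "HN"):
            if aa == "P":
                raise ValueError(f"amide entry on proline at {e.residue}")
            continue
        valid = set()
        for ct in topology.carbon_types(aa):
            valid.add(ct.name)
            valid.update(ct.proton_names())
        if e.atom not in valid:
            raise ValueError(
                f"atom {e.atom} is not valid for residue {aa}{e.residue}")
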