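"""Aliphatic CH topology of the 20 standard amino acids.

Every assignment decision in the package is phrased in terms of the
aliphatic carbon "atom types" of a residue (CA, CB, CG1, ...).  A carbon
type is one of three proton multiplicities:

* ``CH``   — a methine carbon carrying one proton (e.g. Val CB),
* ``CH2``  — a methylene carrying two (generally inequivalent) protons,
* ``CH3``  — a methyl whose three equivalent protons give one CH cross-peak.

A methylene can therefore contribute up to two cross-peaks to a spectrum,
methines and methyls one each.  Aromatic CH and sidechain NH2 groups are
outside the scope of the aliphatic assignment problem and are not listed.
"""

from __future__ import annotations

from dataclasses import dataclass

AA1 = "ACDEFGHIKLMNPQRSTVWY"
AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


@dataclass(frozen=True)
class CarbonType:
    """One aliphatic carbon position of a residue type."""

    name: str           # carbon name, e.g. "CB"
    multiplicity: str   # "CH" | "CH2" | "CH3"

    @property
    def is_methylene(self) -> bool:
        return self.multiplicity == "CH2"

    @property
    def is_methyl(self) -> bool:
        return self.multiplicity == "CH3"

    @property
    def n_peaks(self) -> int:
        """Maximum number of distinct CH cross-peaks this carbon yields."""
        return 2 if self.is_methylene else 1

    def proton_names(self) -> tuple[str, ...]:
        """Proton name(s) paired with this carbon, IUPAC-style.

        Methylene protons get suffixes 2/3 (HB2/HB3, Gly HA2/HA3,
        Ile HG12/HG13); methyls and methines use the bare stem.
        """
        stem = "H" + self.name[1:]
        if self.is_methylene:
            if self.name == "CG1":      # Ile CG1 -> HG12/HG13
                return (stem + "2", stem + "3")
            return (stem + "2", stem + "3")
        return (stem,)


# Aliphatic CH carbons per amino acid, backbone first.  Proline is included:
# it has no amide root of its own, but its aliphatic atoms are observed in
# the TOCSY spin system of the following residue.
ALIPHATIC: dict[str, tuple[CarbonType, ...]] = {
    "A": (CarbonType("CA", "CH"), CarbonType("CB", "CH3")),
    "R": (CarbonType("CA", "CH"), CarbonType("CB", "CH2"),
          CarbonType("CG", "CH2"), CarbonType("CD", "CH2")),
    "N": (CarbonType("CA", "CH"), CarbonType("CB", "CH2")),
    "D": (CarbonType("CA", "CH"), CarbonType("CB", "CH2")),
    "C": (CarbonType("CA", "CH"), CarbonType("CB", "CH2")),
    "Q": (CarbonType("CA", "CH"), CarbonType("CB", "CH2"),
          CarbonType("CG", "CH2")),
    "E": (CarbonType("CA", "CH"), CarbonType("CB", "CH2"),
          CarbonType("CG", "CH2")),
    "G": (CarbonType("CA", "CH2"),),
    "H": (CarbonType("CA", "CH"), CarbonType("CB", "CH2")),
    "I": (CarbonType("CA", "CH"), CarbonType("CB", "CH"),
          CarbonType("CG1", "CH2"), CarbonType("CG2", "CH3"),
          CarbonType("CD1", "CH3")),
    "L": (CarbonType("CA", "CH"), CarbonType("CB", "CH2"),
          CarbonType("CG", "CH"), CarbonType("CD1", "CH3"),
          CarbonType("CD2", "CH3")),
    "K": (CarbonType("CA", "CH"), CarbonType("CB", "CH2"),
          CarbonType("CG", "CH2"), CarbonType("CD", "CH2"),
          CarbonType("CE", "CH2")),
    "M": (CarbonType("CA", "CH"), CarbonType("CB", "CH2"),
          CarbonType("CG", "CH2"), CarbonType("CE", "CH3")),
    "F": (CarbonType("CA", "CH"), CarbonType("CB", "CH2")),
    "P": (CarbonType("CA", "CH"), CarbonType("CB", "CH2"),
          CarbonType("CG", "CH2"), CarbonType("CD", "CH2")),
    "S": (CarbonType("CA", "CH"), CarbonType("CB", "CH2")),
    "T": (CarbonType("CA", "CH"), CarbonType("CB", "CH"),
          CarbonType("CG2", "CH3")),
    "W": (CarbonType("CA", "CH"), CarbonType("CB", "CH2")),
    "Y": (CarbonType("CA", "CH"), CarbonType("CB", "CH2")),
    "V": (CarbonType("CA", "CH"), CarbonType("CB", "CH"),
          CarbonType("CG1", "CH3"), CarbonType("CG2", "CH3")),
}

# Prochiral pairs whose chemical-shift distributions overlap almost
# completely; assignments swapped within a pair are not stereo errors.
PROCHIRAL_PAIRS: dict[str, tuple[str, str]] = {
    "L": ("CD1", "CD2"),
    "V": ("CG1", "CG2"),
}


def carbon_types(aa: str) -> tuple[CarbonType, ...]:
    """Aliphatic carbon types of a one-letter residue code."""
    try:
        return ALIPHATIC[aa]
    except KeyError:
        raise ValueError(f"unknown amino acid code {aa!r}") from None


def carbon(aa: str, name: str) -> CarbonType:
    for ct in carbon_types(aa):
        if ct.name == name:
            return ct
    raise ValueError(f"{name} is not an aliphatic carbon of {aa}")


def max_ch_peaks(aa: str) -> int:
    """Maximum number of aliphatic CH cross-peaks a residue can yield."""
    return sum(ct.n_peaks for ct in carbon_types(aa))


def atom_type_label(aa: str, carbon_name: str) -> str:
    """Canonical ``C*-H*`` label for one carbon type, e.g. ``CB-HB``."""
    ct = carbon(aa, carbon_name)
    return f"{ct.name}-H{ct.name[1:]}"


# Average amino-acid composition of globular proteins (frequency, %),
# used by the synthetic sequence sampler.
COMPOSITION: dict[str, float] = {
    "A": 8.3, "R": 5.5, "N": 4.1, "D": 5.5, "C": 1.4, "Q": 3.9, "E": 6.8,
    "G": 7.1, "H": 2.3, "I": 5.9, "L": 9.7, "K": 5.8, "M": 2.4, "F": 3.9,
    "P": 4.7, "S": 6.6, "T": 5.3, "W": 1.1, "Y": 2.9, "V": 6.9,
}
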