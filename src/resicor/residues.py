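"""Residue identifiers.

A residue is addressed by its three-letter amino-acid code and sequence number,
written as the code immediately followed by the number (``TYR341``). This is
the labelling used in per-residue MM-PBSA decomposition tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

from .errors import ParseError

#: The 20 standard amino acids, three-letter codes, upper case.
AMINO_ACIDS_3 = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)

_RESIDUE_RE = re.compile(r"^([A-Z]{3})([0-9]+)$")


@dataclass(frozen=True, order=True)
class ResidueID:
    """A residue label: three-letter code + positive sequence number.

    Ordering is alphabetical by code, then ascending number; this is the
    deterministic tie-break order used throughout the package.
    """

    name: str
    number: int

    def __post_init__(self) -> None:
        if self.name not in AMINO_ACIDS_3:
            raise ParseError(
                f"{self.name!r} is not a standard three-letter amino-acid code"
            )
        if not isinstance(self.number, int) or self.number < 1:
            raise ParseError(f"residue number must be a positive integer, got {self.number!r}")

    @classmethod
    def parse(cls, label: str) -> "ResidueID":
        """Parse a canonical label such as ``"TYR341"``."""
        m = _RESIDUE_RE.match(label.strip().upper())
        if m is None:
            raise ParseError(f"cannot parse residue label {label!r} (expected e.g. 'TYR341')")
        return cls(m.group(1), int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.name}{self.number}"


def parse_residues(labels: Iterable[str]) -> tuple[ResidueID, ...]:
    """Parse an iterable of labels, preserving order."""
    return tuple(ResidueID.parse(lab) for lab in labels)


def sorted_residues(residues: Iterable[ResidueID]) -> tuple[ResidueID, ...]:
    """Residues in the package's canonical (name, number) order."""
    return tuple(sorted(residues))
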