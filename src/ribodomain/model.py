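"""Core residue/atom data model shared by every stage of the pipeline.

All geometry modules consume :class:`StructureModel`, a flat, format-agnostic
view of one coordinate model: RNA nucleotides (with author numbering preserved
exactly as in the source file) plus free ions.  Nucleotides are referenced
throughout the package by ``(chain_id, author_number)`` tuples, called *refs*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

#: residue-name -> parent base for common modified ribonucleotides
MODIFIED_BASE_PARENTS = {
    "PSU": "U", "H2U": "U", "4SU": "U", "5MU": "U", "OMU": "U", "UR3": "U",
    "3MU": "U", "70U": "U", "DHU": "U",
    "5MC": "C", "OMC": "C", "4OC": "C", "M4C": "C", "5IC": "C",
    "1MA": "A", "2MA": "A", "A2M": "A", "MA6": "A", "6MZ": "A", "T6A": "A",
    "1MG": "G", "2MG": "G", "M2G": "G", "7MG": "G", "OMG": "G", "G7M": "G",
    "QUO": "G", "YG": "G",
}

STANDARD_BASES = {"A", "C", "G", "U"}

#: elements accepted as free ions (Mg is the one the analysis uses)
ALLOWED_IONS = {"MG", "NA", "K", "ZN", "MN", "CA", "FE"}

NucRef = tuple  # (chain_id: str, author_number: int)


@dataclass(frozen=True)
class Atom:
    """A single atom: PDB-style name, element symbol and Cartesian position in Å."""

    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "coord", np.asarray(self.coord, dtype=float))
        if not np.all(np.isfinite(self.coord)) or self.coord.shape != (3,):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")


@dataclass
class NucleotideRecord:
    """One RNA residue with its atoms.

    ``base_type`` is the parent base (A/C/G/U) used for pairing logic; if the
    residue is a modified nucleotide the original three-letter code is kept in
    ``mod_code``.
    """

    chain_id: str
    author_number: int
    base_type: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""
    mod_code: Optional[str] = None

    @property
    def ref(self) -> NucRef:
        return (self.chain_id, self.author_number)

    @property
    def is_modified(self) -> bool:
        return self.mod_code is not None

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> Optional[np.ndarray]:
        a = self.atom(name)
        return None if a is None else a.coord


@dataclass
class IonRecord:
    """A free (non-covalent) ion; Mg²⁺ is the species the domain analysis uses."""

    element: str
    coord: np.ndarray
    id: str

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.element.upper() not in ALLOWED_IONS:
            raise ValueError(f"ion element {self.element!r} not in allowed set")


@dataclass
class StructureModel:
    """One coordinate model: ordered RNA nucleotides plus ions."""

    nucleotides: list[NucleotideRecord]
    ions: list[IonRecord] = field(default_factory=list)
    source: str = ""

    def __post_init__(self):
        seen = set()
        for nt in self.nucleotides:
            key = (nt.chain_id, nt.author_number, nt.insertion_code)
            if key in seen:
                raise ValueError(f"duplicate residue {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.nucleotides)

    def __iter__(self) -> Iterator[NucleotideRecord]:
        return iter(self.nucleotides)

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for nt in self.nucleotides:
            if nt.chain_id not in out:
                out.append(nt.chain_id)
        return out

    def get(self, ref: NucRef) -> NucleotideRecord:
        for nt in self.nucleotides:
            if nt.ref == tuple(ref):
                return nt
        raise KeyError(f"no residue {ref}")

    def by_ref(self) -> dict:
        return {nt.ref: nt for nt in self.nucleotides}
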