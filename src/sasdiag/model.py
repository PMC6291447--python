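"""Domain types shared across the package.

The structural types are a deliberately thin view of a crystal model:
author numbering and insertion codes are kept verbatim, het-groups are
classified once at parse time, and everything downstream keys residues by
``(chain_id, seq_num, insertion_code)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .tables import BACKBONE_ATOMS, STANDARD_AA1

#: A residue key: (chain_id, author seq_num, insertion_code).
ResidueKey = tuple[str, int, str]


@dataclass(frozen=True)
class Atom:
    """A single atom with coordinates in Å and its B-factor in Å²."""

    name: str
    element: str
    coords: tuple[float, float, float]
    b_factor: float = 0.0

    @property
    def is_heavy(self) -> bool:
        return self.element not in ("H", "D")


@dataclass
class Residue:
    """A polymer residue, ligand or solvent molecule.

    ``aa`` is the one-letter code for polymer residues and the PDB het
    code (e.g. ``"GNP"``) otherwise. ``seq_num`` is the author residue
    number and may be non-contiguous.
    """

    chain_id: str
    seq_num: int
    insertion_code: str
    aa: str
    atoms: list[Atom]
    kind: str  # "polymer" | "ligand" | "solvent"

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_num, self.insertion_code)

    @property
    def is_polymer(self) -> bool:
        return self.kind == "polymer"

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def sidechain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy and a.name not in BACKBONE_ATOMS]

    def mean_bfactor(self) -> float:
        heavy = self.heavy_atoms()
        if not heavy:
            return 0.0
        return float(np.mean([a.b_factor for a in heavy]))


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_polymer]

    def sequence(self) -> str:
        """Observed one-letter sequence of the polymer residues, in order."""
        return "".join(r.aa for r in self.polymer_residues())


@dataclass
class Structure:
    """A parsed crystal model: polymer chains plus classified het-groups."""

    structure_id: str
    chains: list[Chain]
    het_groups: list[Residue] = field(default_factory=list)
    resolution: Optional[float] = None

    def polymer_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.polymer_residues()]

    def ligands(self) -> list[Residue]:
        return [r for r in self.het_groups if r.kind == "ligand"]

    def get_chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.structure_id}")

    def residues(self) -> Iterator[Residue]:
        """All polymer residues across chains, then het-groups."""
        for c in self.chains:
            yield from c.residues
        yield from self.het_groups

    def find_residue(self, key: ResidueKey) -> Residue:
        for r in self.residues():
            if r.key == key:
                return r
        raise KeyError(f"residue {key} not in structure {self.structure_id}")


@dataclass(frozen=True)
class StructureMeta:
    """Selection metadata for one candidate structure.

    ``covered_range`` is a half-open 1-based interval on the reference
    sequence, so coverage length is simply ``end - start``.
    """

    structure_id: str
    covered_range: tuple[int, int]
    resolution: Optional[float] = None
    ligand_codes: frozenset[str] = frozenset()
    partner_chains: frozenset[str] = frozenset()

    @property
    def coverage(self) -> int:
        start, end = self.covered_range
        if end < start:
            raise ValueError(f"invalid covered_range {self.covered_range}")
        return end - start


@dataclass
class SeqMap:
    """Partial mapping reference position (1-based) -> structure residue key."""

    ref_to_structure: dict[int, ResidueKey]
    identity: float
    mismatches: frozenset[int] = frozenset()

    def __contains__(self, ref_pos: int) -> bool:
        return ref_pos in self.ref_to_structure

    def __getitem__(self, ref_pos: int) -> ResidueKey:
        return self.ref_to_structure[ref_pos]


@dataclass(frozen=True)
class Variant:
    """A single amino acid substitution on the reference sequence."""

    wt_aa: str
    position: int
    mut_aa: str
    source: str = "user"  # "user" | "humsavar" | "clinvar"
    clinical_label: Optional[str] = None
    ddg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.wt_aa not in STANDARD_AA1 or self.mut_aa not in STANDARD_AA1:
            raise ValueError(f"non-standard amino acid in {self.short()}")
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"synonymous substitution {self.short()}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    def short(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.wt_aa, self.position, self.mut_aa)
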