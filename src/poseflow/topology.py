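"""Atom-level topology with role and sub-role flags.

The pipeline needs to know three things about every atom: whether it belongs
to the protein or the ligand, which protein atoms form the backbone used for
rigid superposition, and which ligand atoms are heavy atoms (the RMSD metric
and the occupancy grid both run on ligand heavy atoms only).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = ["AtomRecord", "Topology"]

_ROLES = ("protein", "ligand")
_FLAGS = ("backbone", "heavy", "-")


@dataclass(frozen=True)
class AtomRecord:
    """One atom: index, name, role and sub-role flag.

    ``backbone`` is meaningful for protein atoms, ``heavy`` for ligand atoms.
    """

    index: int
    name: str
    role: str
    backbone: bool = False
    heavy: bool = False

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"atom {self.index}: role must be one of {_ROLES}, got {self.role!r}")


class Topology:
    """Ordered collection of :class:`AtomRecord` shared by every trajectory.

    Invariants enforced on construction:

    * atom indices are unique and contiguous from 0;
    * at least 3 protein backbone atoms (a rigid least-squares fit on fewer
      points is degenerate);
    * at least 1 ligand heavy atom.
    """

    def __init__(self, atoms: Iterable[AtomRecord]):
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        indices = [a.index for a in self.atoms]
        if indices != list(range(len(self.atoms))):
            raise ValueError("atom indices must be unique and contiguous from 0")
        self.backbone_indices = np.array(
            [a.index for a in self.atoms if a.role == "protein" and a.backbone], dtype=int
        )
        self.protein_indices = np.array([a.index for a in self.atoms if a.role == "protein"], dtype=int)
        self.ligand_indices = np.array([a.index for a in self.atoms if a.role == "ligand"], dtype=int)
        self.ligand_heavy_indices = np.array(
            [a.index for a in self.atoms if a.role == "ligand" and a.heavy], dtype=int
        )
        if len(self.backbone_indices) < 3:
            raise ValueError(
                f"need at least 3 protein backbone atoms for superposition, got {len(self.backbone_indices)}"
            )
        if len(self.ligand_heavy_indices) < 1:
            raise ValueError("need at least 1 ligand heavy atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_protein(self) -> int:
        return len(self.protein_indices)

    @property
    def n_ligand(self) -> int:
        return len(self.ligand_indices)

    @property
    def n_ligand_heavy(self) -> int:
        return len(self.ligand_heavy_indices)

    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    def __len__(self) -> int:
        return self.n_atoms

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return self.atoms == other.atoms

    def __hash__(self) -> int:
        return hash(self.atoms)

    # ------------------------------------------------------------------
    # plain-text selection file: one atom per line,
    #   <index> <name> <role> <flag>
    # where flag is "backbone" (protein), "heavy" (ligand) or "-".
    # ------------------------------------------------------------------
    @classmethod
    def from_file(cls, path: str | Path) -> "Topology":
        atoms: list[AtomRecord] = []
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns (index name role flag), got {len(parts)}")
            idx, name, role, flag = parts
            if flag not in _FLAGS:
                raise ValueError(f"{path}:{lineno}: flag must be one of {_FLAGS}, got {flag!r}")
            atoms.append(
                AtomRecord(
                    index=int(idx),
                    name=name,
                    role=role,
                    backbone=(flag == "backbone"),
                    heavy=(flag == "heavy"),
                )
            )
        if not atoms:
            raise ValueError(f"{path}: empty topology file")
        return cls(atoms)

    def to_file(self, path: str | Path) -> None:
        lines = ["# index name role flag"]
        for a in self.atoms:
            flag = "backbone" if (a.role == "protein" and a.backbone) else "heavy" if (a.role == "ligand" and a.heavy) else "-"
            lines.append(f"{a.index} {a.name} {a.role} {flag}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def simple(cls, n_backbone: int, n_ligand_heavy: int, n_protein_other: int = 0) -> "Topology":
        """Convenience constructor for synthetic systems: ``n_backbone``
        protein backbone atoms, ``n_protein_other`` non-backbone protein
        atoms, then ``n_ligand_heavy`` ligand heavy atoms."""
        atoms: list[AtomRecord] = []
        i = 0
        for _ in range(n_backbone):
            atoms.append(AtomRecord(i, "CA", "protein", backbone=True))
            i += 1
        for _ in range(n_protein_other):
            atoms.append(AtomRecord(i, "CB", "protein", backbone=False))
            i += 1
        for _ in range(n_ligand_heavy):
            atoms.append(AtomRecord(i, "C1", "ligand", heavy=True))
            i += 1
        return cls(atoms)
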