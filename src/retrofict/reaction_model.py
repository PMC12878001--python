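"""Atom-mapped reactions: parsing, canonicalization, roles, dedup keys.

A reaction line is the USPTO-style ``reactants>agents>products`` SMILES with
integer atom maps linking reactant atoms to their images in the product.
Precursors are partitioned into *starting materials* (SM), which contribute
mapped atoms to the product, and *reagents* (R), which do not. Two dedup
views are used throughout: ``SM → P`` (ignoring conditions) and
``SM + R → P`` (exact reaction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, TextIO

from rdkit import Chem
from rdkit import RDLogger

from .errors import (
    MalformedRecordError,
    ReactionParseError,
    RolePartitionError,
)

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Molecule",
    "MappedReaction",
    "KeyMode",
    "ReactionKey",
    "canonical_smiles",
    "parse_reaction",
    "partition_roles",
    "strip_maps",
    "reaction_key",
    "read_reactions",
    "write_jsonl",
]


def _mol_from_smiles(text: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise ReactionParseError(f"unparsable SMILES: {text!r}")
    return mol


def canonical_smiles(text: str, *, stereo: bool = True) -> str:
    """Canonical (RDKit) SMILES of *text*; idempotent."""
    mol = _mol_from_smiles(text)
    if not stereo:
        Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class Molecule:
    """A single species, stored as canonical SMILES.

    ``map_numbers`` lists the atom-map integer of each atom in the order the
    atoms appear in ``smiles`` (0 = unmapped); ``None`` for unmapped species.
    """

    smiles: str
    map_numbers: tuple[int, ...] | None = None

    @classmethod
    def from_smiles(cls, text: str) -> "Molecule":
        mol = _mol_from_smiles(text)
        smi = Chem.MolToSmiles(mol)
        # Re-parse so map_numbers follow the canonical atom output order.
        out = Chem.MolFromSmiles(smi)
        maps = tuple(a.GetAtomMapNum() for a in out.GetAtoms())
        return cls(smiles=smi, map_numbers=maps if any(maps) else None)

    @classmethod
    def from_mol(cls, mol: Chem.Mol) -> "Molecule":
        return cls.from_smiles(Chem.MolToSmiles(mol))

    def to_mol(self) -> Chem.Mol:
        return _mol_from_smiles(self.smiles)

    @property
    def maps(self) -> frozenset[int]:
        """Nonzero atom-map numbers carried by this species."""
        if not self.map_numbers:
            return frozenset()
        return frozenset(m for m in self.map_numbers if m)

    @property
    def plain(self) -> str:
        """Canonical SMILES with all atom maps removed."""
        if self.map_numbers is None:
            return self.smiles
        mol = self.to_mol()
        for atom in mol.GetAtoms():
            atom.SetAtomMapNum(0)
        return Chem.MolToSmiles(mol)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.smiles


def strip_maps(mol: Molecule) -> Molecule:
    """Remove all atom maps and re-canonicalize. Idempotent."""
    return Molecule(smiles=mol.plain, map_numbers=None)


class KeyMode(str, Enum):
    """Reaction view used for deduplication keys."""

    SM_P = "sm_p"  # starting materials -> product, conditions ignored
    SMRP = "smrp"  # starting materials + reagents -> product


@dataclass(frozen=True)
class ReactionKey:
    mode: KeyMode
    key: str


@dataclass(frozen=True)
class MappedReaction:
    """One atom-mapped reaction with roles partitioned.

    Invariants: exactly one product species; 2–10 precursors in total;
    every nonzero product map occurs once and is covered by SM atoms.
    """

    starting_materials: tuple[Molecule, ...]
    reagents: tuple[Molecule, ...]
    product: Molecule
    source_id: str = ""

    @property
    def precursors(self) -> tuple[Molecule, ...]:
        return self.starting_materials + self.reagents

    def sm_plain_set(self) -> tuple[str, ...]:
        """Sorted map-stripped canonical SM SMILES (the recorded SM-set)."""
        return tuple(sorted(m.plain for m in self.starting_materials))


def _validate(rxn: MappedReaction, line_no: int | None = None) -> MappedReaction:
    n_prec = len(rxn.precursors)
    if not 2 <= n_prec <= 10:
        raise MalformedRecordError(
            f"{n_prec} precursor species (need 2-10)", line_no=line_no
        )
    seen: set[int] = set()
    for m in rxn.product.maps:
        if m in seen:  # pragma: no cover - maps frozenset already unique
            raise MalformedRecordError(f"duplicate product map {m}", line_no=line_no)
        seen.add(m)
    counts: dict[int, int] = {}
    for m in rxn.product.map_numbers or ():
        if m:
            counts[m] = counts.get(m, 0) + 1
    dupes = [m for m, c in counts.items() if c > 1]
    if dupes:
        raise MalformedRecordError(
            f"product map numbers used more than once: {sorted(dupes)}",
            line_no=line_no,
        )
    sm_maps: set[int] = set()
    for sp in rxn.starting_materials:
        sm_maps |= sp.maps
    missing = rxn.product.maps - sm_maps
    if missing:
        raise MalformedRecordError(
            f"product maps absent from starting materials: {sorted(missing)}",
            line_no=line_no,
        )
    return rxn


def partition_roles(rxn: MappedReaction) -> MappedReaction:
    """Re-partition precursors into SM and R by map intersection.

    A precursor is a starting material iff at least one of its atom-map
    numbers occurs in the product; otherwise it is a reagent. Deterministic
    and stable under permutation of the input species (each class keeps a
    canonical sort).
    """
    pmaps = rxn.product.maps
    if not pmaps:
        raise RolePartitionError("product has no mapped atoms")
    sm: list[Molecule] = []
    rg: list[Molecule] = []
    for sp in rxn.precursors:
        (sm if sp.maps & pmaps else rg).append(sp)
    if not sm:
        raise RolePartitionError("no precursor maps into the product")
    sm.sort(key=lambda m: m.smiles)
    rg.sort(key=lambda m: m.smiles)
    return replace(
        rxn, starting_materials=tuple(sm), reagents=tuple(rg)
    )


def parse_reaction(
    line: str, source_id: str = "", line_no: int | None = None
) -> MappedReaction:
    """Parse one ``reactants>agents>products`` line into a MappedReaction.

    Species from the first two fields are pooled and re-partitioned into
    SM/R by atom-map intersection with the product, so mis-filed agents are
    corrected. Raises :class:`ReactionParseError` (with the line number) on
    bad SMILES, and :class:`MalformedRecordError` on invariant violations.
    """
    parts = line.strip().split(">")
    if len(parts) != 3:
        raise ReactionParseError(
            "expected 'reactants>agents>products'", line_no=line_no
        )
    reac_f, agent_f, prod_f = parts
    try:
        products = [Molecule.from_smiles(s) for s in prod_f.split(".") if s]
        precursors = [
            Molecule.from_smiles(s)
            for f in (reac_f, agent_f)
            for s in f.split(".")
            if s
        ]
    except ReactionParseError as exc:
        raise ReactionParseError(str(exc), line_no=line_no) from None
    if len(products) != 1:
        raise MalformedRecordError(
            f"{len(products)} product species (need exactly 1)", line_no=line_no
        )
    # Keep one copy of a species listed under both roles (SM priority falls
    # out of map-based partitioning; duplicates within a role are kept).
    seen: set[str] = set()
    unique: list[Molecule] = []
    for sp in precursors:
        if sp.smiles not in seen:
            seen.add(sp.smiles)
            unique.append(sp)
    draft = MappedReaction(
        starting_materials=tuple(unique),
        reagents=(),
        product=products[0],
        source_id=source_id,
    )
    try:
        rxn = partition_roles(draft)
    except RolePartitionError as exc:
        raise MalformedRecordError(str(exc), line_no=line_no) from None
    return _validate(rxn, line_no=line_no)


def reaction_key(rxn: MappedReaction, mode: KeyMode = KeyMode.SMRP) -> ReactionKey:
    """Canonical, map-stripped, fragment-sorted dedup key for a view."""
    mode = KeyMode(mode)
    sm = sorted(m.plain for m in rxn.starting_materials)
    parts = [".".join(sm)]
    if mode is KeyMode.SMRP:
        parts.append(".".join(sorted(m.plain for m in rxn.reagents)))
    parts.append(rxn.product.plain)
    return ReactionKey(mode=mode, key=">".join(parts))


def read_reactions(
    lines: Iterable[str], *, on_error: str = "raise"
) -> Iterator[MappedReaction]:
    """Parse reaction lines; ``on_error='skip'`` drops rejected records."""
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        try:
            yield parse_reaction(line, source_id=str(i), line_no=i)
        except ReactionParseError:
            if on_error == "raise":
                raise


def to_record(rxn: MappedReaction) -> dict:
    return {
        "source_id": rxn.source_id,
        "sm": [m.smiles for m in rxn.starting_materials],
        "reagents": [m.smiles for m in rxn.reagents],
        "product": rxn.product.smiles,
        "keys": {
            "sm_p": reaction_key(rxn, KeyMode.SM_P).key,
            "smrp": reaction_key(rxn, KeyMode.SMRP).key,
        },
    }


def write_jsonl(reactions: Iterable[MappedReaction], fh: TextIO) -> int:
    n = 0
    for rxn in reactions:
        fh.write(json.dumps(to_record(rxn), sort_keys=True) + "\n")
        n += 1
    return n
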