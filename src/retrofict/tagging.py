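"""The SM* representation: "!"-tagged SMILES token sequences.

Starting materials generated by retro template application carry atom maps
locating the atoms whose environment changes in the reaction. Those atoms
are marked in the token stream with a "!" token placed immediately after
the atom token (before any ring-closure digits), yielding the tagged
species SM* consumed by forward validators. Tagging is performed on the
canonical serialization by default so tagged strings are unique.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from rdkit import Chem

from .errors import TaggingError, TokenizationError
from .reaction_model import Molecule
from .template_engine import ChangedAtomSet

__all__ = ["TaggedMolecule", "tokenize", "tag_changed_atoms", "untag"]

TAG = "!"

# Atom-wise SMILES tokenization as used by sequence models: bracket atoms
# are one token, two-letter organic-subset elements stay intact.
_TOKEN_RE = re.compile(
    r"(\[[^\]]*\]|Br|Cl|B|C|N|O|S|P|F|I|b|c|n|o|s|p|@@|@|%\d{2}"
    r"|[()=#\-+\\/:~.*$!]|\d)"
)
_ATOM_TOKEN_RE = re.compile(r"\[[^\]]*\]|Br|Cl|B|C|N|O|S|P|F|I|b|c|n|o|s|p|\*")


def tokenize(smiles: str) -> list[str]:
    """Split SMILES (possibly containing "!" tags) into tokens.

    Joining the tokens reproduces the input exactly; anything that does not
    round-trip (including unclosed brackets) raises
    :class:`~retrofict.errors.TokenizationError`.
    """
    if not smiles:
        return []
    if smiles.count("[") != smiles.count("]"):
        raise TokenizationError(f"unbalanced brackets in {smiles!r}")
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise TokenizationError(f"cannot tokenize {smiles!r}")
    return tokens


def _is_atom_token(tok: str) -> bool:
    return bool(_ATOM_TOKEN_RE.fullmatch(tok))


@dataclass(frozen=True)
class TaggedMolecule:
    """A species' token sequence with "!" tags on changed atoms."""

    tokens: tuple[str, ...]
    tag_positions: frozenset[int]  # indices of "!" tokens
    plain: str  # canonical untagged SMILES

    @property
    def tagged(self) -> str:
        """Compact tagged string."""
        return "".join(self.tokens)

    @property
    def token_line(self) -> str:
        """Space-joined token line (sequence-model convention)."""
        return " ".join(self.tokens)

    @property
    def n_tags(self) -> int:
        return len(self.tag_positions)

    @classmethod
    def from_tagged(cls, text: str) -> "TaggedMolecule":
        """Rebuild from a compact tagged string (or token line)."""
        compact = text.replace(" ", "")
        tokens = tokenize(compact)
        _check_tag_placement(tokens)
        plain = "".join(t for t in tokens if t != TAG)
        mol = Chem.MolFromSmiles(plain)
        if mol is None:
            raise TaggingError(f"untagged SMILES unparsable: {plain!r}")
        return cls(
            tokens=tuple(tokens),
            tag_positions=frozenset(
                i for i, t in enumerate(tokens) if t == TAG
            ),
            plain=Chem.MolToSmiles(mol),
        )


def _check_tag_placement(tokens: list[str] | tuple[str, ...]) -> None:
    for i, tok in enumerate(tokens):
        if tok == TAG:
            if i == 0 or not _is_atom_token(tokens[i - 1]):
                raise TaggingError(
                    f"'!' at position {i} does not follow an atom token"
                )


def tag_changed_atoms(
    sm: list[Molecule] | tuple[Molecule, ...],
    changed: ChangedAtomSet,
    *,
    canonical: bool = True,
) -> list[TaggedMolecule]:
    """Tag changed atoms in each map-annotated SM species.

    Every map number in ``changed.reactant_side`` must be locatable in the
    SM-set, otherwise a :class:`~retrofict.errors.TaggingError` is raised.
    With ``canonical=True`` (default) each species is re-serialized
    canonically before tagging, so the tagged string is unique.
    """
    present: set[int] = set()
    for sp in sm:
        present |= sp.maps
    missing = set(changed.reactant_side) - present
    if missing:
        raise TaggingError(
            f"changed map numbers absent from SM: {sorted(missing)}"
        )
    return [_tag_species(sp, changed.reactant_side, canonical) for sp in sm]


def _tag_species(
    species: Molecule, changed_maps: frozenset[int] | set[int], canonical: bool
) -> TaggedMolecule:
    mol = species.to_mol()
    flags = [a.GetAtomMapNum() in changed_maps for a in mol.GetAtoms()]
    for a in mol.GetAtoms():
        a.SetAtomMapNum(0)
    plain_canonical = Chem.MolToSmiles(mol)
    smiles = plain_canonical if canonical else Chem.MolToSmiles(mol, canonical=False)
    order = list(
        map(int, mol.GetProp("_smilesAtomOutputOrder")[1:-1].split(","))
    )
    tokens = tokenize(smiles)
    out: list[str] = []
    tag_positions: set[int] = set()
    atom_i = 0
    for tok in tokens:
        out.append(tok)
        if _is_atom_token(tok):
            if flags[order[atom_i]]:
                tag_positions.add(len(out))
                out.append(TAG)
            atom_i += 1
    return TaggedMolecule(
        tokens=tuple(out),
        tag_positions=frozenset(tag_positions),
        plain=plain_canonical,
    )


def untag(t: TaggedMolecule | str) -> Molecule:
    """Remove all "!" tags; inverse of :func:`tag_changed_atoms`."""
    if isinstance(t, str):
        t = TaggedMolecule.from_tagged(t)
    else:
        _check_tag_placement(t.tokens)
    plain = "".join(tok for tok in t.tokens if tok != TAG)
    return Molecule.from_smiles(plain)
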