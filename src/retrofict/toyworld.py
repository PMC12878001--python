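"""A self-contained toy chemistry world with known ground truth.

Six hand-coded reaction families — esterification, amide coupling,
Williamson ether synthesis, aryl–aryl (Suzuki-type) coupling, Markovnikov
hydrobromination and syn-dihydroxylation — are applied to an enumerated
substituent library to produce fully atom-mapped reactions whose changed
atoms, SM/R partition and generating template are known at construction.
The tag counts span 2–4 so per-tag-count stratification has several
buckets. The world makes no claim of chemical realism beyond
valence-valid structures; it exists so that every pipeline stage can be
tested without any external reaction corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence
import warnings

import numpy as np
from rdkit import Chem

from ._seeding import derive_seed, stable_hash
from .dataset_ops import ReactionRecord
from .reaction_model import MappedReaction, Molecule, parse_reaction
from .template_engine import ChangedAtomSet, RetroTemplate, extract_template

__all__ = [
    "ToyWorld",
    "GroundTruth",
    "TOY_FAMILIES",
    "enumerate_pool",
    "generate_toy_reactions",
    "perturb_dataset",
]


# --------------------------------------------------------------------------
# substituent library: mapped SMILES fragments whose LAST written atom is
# the attachment point (string concatenation bonds it to the next atom)


def _chain(n: int) -> Callable[[int], tuple[str, int]]:
    def frag(m: int) -> tuple[str, int]:
        if n == 1:
            return f"[CH3:{m}]", 1
        atoms = [f"[CH3:{m}]"] + [f"[CH2:{m + i}]" for i in range(1, n)]
        return "".join(atoms), n

    return frag


def _phenyl(m: int) -> tuple[str, int]:
    return (
        f"[cH:{m}]1[cH:{m+1}][cH:{m+2}][cH:{m+3}][cH:{m+4}][c:{m+5}]1",
        6,
    )


def _tolyl(m: int) -> tuple[str, int]:
    return (
        f"[CH3:{m}][c:{m+1}]1[cH:{m+2}][cH:{m+3}][c:{m+6}]([cH:{m+4}][cH:{m+5}]1)",
        7,
    )


def _benzyl(m: int) -> tuple[str, int]:
    ph, n = _phenyl(m)
    return ph + f"[CH2:{m+n}]", n + 1


def _isopropyl(m: int) -> tuple[str, int]:
    return f"[CH3:{m}][CH:{m+2}]([CH3:{m+1}])", 3


def _anisyl(m: int) -> tuple[str, int]:
    return (
        f"[CH3:{m}][O:{m+1}][c:{m+2}]1[cH:{m+3}][cH:{m+4}]"
        f"[c:{m+7}]([cH:{m+5}][cH:{m+6}]1)",
        8,
    )


def _chlorophenyl(m: int) -> tuple[str, int]:
    return (
        f"[Cl:{m}][c:{m+1}]1[cH:{m+2}][cH:{m+3}][c:{m+6}]([cH:{m+4}][cH:{m+5}]1)",
        7,
    )


ALKYL = {
    "methyl": _chain(1),
    "ethyl": _chain(2),
    "propyl": _chain(3),
    "butyl": _chain(4),
    "pentyl": _chain(5),
    "hexyl": _chain(6),
    "heptyl": _chain(7),
    "octyl": _chain(8),
    "isopropyl": _isopropyl,
    "benzyl": _benzyl,
    "phenyl": _phenyl,
    "tolyl": _tolyl,
}
ARYL = {
    "phenyl": _phenyl,
    "tolyl": _tolyl,
    "anisyl": _anisyl,
    "chlorophenyl": _chlorophenyl,
}


# attachment-FIRST fragments (written after the core atom they bond to)


def _chain_suffix(n: int) -> Callable[[int], tuple[str, int]]:
    def frag(m: int) -> tuple[str, int]:
        if n == 1:
            return f"[CH3:{m}]", 1
        atoms = [f"[CH2:{m + i}]" for i in range(n - 1)] + [f"[CH3:{m + n - 1}]"]
        return "".join(atoms), n

    return frag


def _isopropyl_suffix(m: int) -> tuple[str, int]:
    return f"[CH:{m}]([CH3:{m+1}])[CH3:{m+2}]", 3


def _phenyl_suffix(m: int) -> tuple[str, int]:
    return (
        f"[c:{m}]1[cH:{m+1}][cH:{m+2}][cH:{m+3}][cH:{m+4}][cH:{m+5}]1",
        6,
    )


def _benzyl_suffix(m: int) -> tuple[str, int]:
    ph, n = _phenyl_suffix(m + 1)
    return f"[CH2:{m}]" + ph, n + 1


def _tolyl_suffix(m: int) -> tuple[str, int]:
    return (
        f"[c:{m}]1[cH:{m+1}][cH:{m+2}][c:{m+3}]([CH3:{m+4}])[cH:{m+5}][cH:{m+6}]1",
        7,
    )


ALKYL_SUFFIX = {
    "methyl": _chain_suffix(1),
    "ethyl": _chain_suffix(2),
    "propyl": _chain_suffix(3),
    "butyl": _chain_suffix(4),
    "pentyl": _chain_suffix(5),
    "hexyl": _chain_suffix(6),
    "heptyl": _chain_suffix(7),
    "octyl": _chain_suffix(8),
    "isopropyl": _isopropyl_suffix,
    "benzyl": _benzyl_suffix,
    "phenyl": _phenyl_suffix,
    "tolyl": _tolyl_suffix,
}


# --------------------------------------------------------------------------
# reaction families


@dataclass(frozen=True)
class ToyReaction:
    family: str
    sm: tuple[str, ...]  # mapped SMILES
    reagents: tuple[str, ...]
    product: str  # mapped SMILES
    changed_reactant: frozenset[int]
    changed_product: frozenset[int]
    n_tags: int

    def to_line(self) -> str:
        return (
            ".".join(self.sm)
            + ">"
            + ".".join(self.reagents)
            + ">"
            + self.product
        )

    def to_mapped_reaction(self, source_id: str = "") -> MappedReaction:
        return parse_reaction(self.to_line(), source_id=source_id)


@dataclass(frozen=True)
class GroundTruth:
    family: str
    changed_reactant: frozenset[int]
    changed_product: frozenset[int]
    n_tags: int
    sm_plain: tuple[str, ...]
    reagents: tuple[str, ...]
    product_plain: str


def _product_from_edits(
    sm_smiles: Sequence[str],
    remove_atoms: Sequence[int],
    remove_bonds: Sequence[tuple[int, int]],
    add_bonds: Sequence[tuple[int, int, Chem.BondType]],
    set_bonds: Sequence[tuple[int, int, Chem.BondType]],
    h_updates: dict[int, int],
) -> str:
    """Assemble the mapped product from SM by explicit graph surgery."""
    combined = None
    for smi in sm_smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"bad toy SM fragment: {smi}")
        combined = mol if combined is None else Chem.CombineMols(combined, mol)
    rw = Chem.RWMol(combined)
    by_map = {a.GetAtomMapNum(): a.GetIdx() for a in rw.GetAtoms()}
    for i, j, order in set_bonds:
        rw.GetBondBetweenAtoms(by_map[i], by_map[j]).SetBondType(order)
    for i, j in remove_bonds:
        rw.RemoveBond(by_map[i], by_map[j])
    for i, j, order in add_bonds:
        rw.AddBond(by_map[i], by_map[j], order)
    for mn, h in h_updates.items():
        atom = rw.GetAtomWithIdx(by_map[mn])
        atom.SetNoImplicit(True)
        atom.SetNumExplicitHs(h)
    for mn in sorted(remove_atoms, reverse=True):
        # re-resolve indices after each removal
        idx = {a.GetAtomMapNum(): a.GetIdx() for a in rw.GetAtoms()}[mn]
        rw.RemoveAtom(idx)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


FamilyBuilder = Callable[[str, str], ToyReaction]


def _esterification(r1: str, r2: str) -> ToyReaction:
    f1, n1 = ALKYL[r1](1)
    a, b, c = n1 + 1, n1 + 2, n1 + 3
    f2, n2 = ALKYL[r2](c + 1)
    d = c + n2 + 1
    sm1 = f1 + f"[C:{a}](=[O:{b}])[OH:{c}]"
    sm2 = f2 + f"[OH:{d}]"
    product = _product_from_edits(
        [sm1, sm2],
        remove_atoms=[c],
        remove_bonds=[],
        add_bonds=[(a, d, Chem.BondType.SINGLE)],
        set_bonds=[],
        h_updates={d: 0},
    )
    return ToyReaction(
        family="esterification",
        sm=(sm1, sm2),
        reagents=("OS(=O)(=O)O",),
        product=product,
        changed_reactant=frozenset({a, c, d}),
        changed_product=frozenset({a, d}),
        n_tags=2,
    )


def _amide_coupling(r1: str, r2: str) -> ToyReaction:
    f1, n1 = ALKYL[r1](1)
    a, b, c = n1 + 1, n1 + 2, n1 + 3
    f2, n2 = ALKYL[r2](c + 1)
    d = c + n2 + 1
    sm1 = f1 + f"[C:{a}](=[O:{b}])[OH:{c}]"
    sm2 = f2 + f"[NH2:{d}]"
    product = _product_from_edits(
        [sm1, sm2],
        remove_atoms=[c],
        remove_bonds=[],
        add_bonds=[(a, d, Chem.BondType.SINGLE)],
        set_bonds=[],
        h_updates={d: 1},
    )
    return ToyReaction(
        family="amide_coupling",
        sm=(sm1, sm2),
        reagents=("CC(C)N=C=NC(C)C",),
        product=product,
        changed_reactant=frozenset({a, c, d}),
        changed_product=frozenset({a, d}),
        n_tags=2,
    )


def _williamson_ether(r1: str, r2: str) -> ToyReaction:
    f1, n1 = ALKYL[r1](1)
    a, b = n1 + 1, n1 + 2
    f2, n2 = ALKYL[r2](b + 1)
    c = b + n2 + 1
    sm1 = f1 + f"[CH2:{a}][Br:{b}]"
    sm2 = f2 + f"[OH:{c}]"
    product = _product_from_edits(
        [sm1, sm2],
        remove_atoms=[b],
        remove_bonds=[],
        add_bonds=[(a, c, Chem.BondType.SINGLE)],
        set_bonds=[],
        h_updates={c: 0},
    )
    return ToyReaction(
        family="williamson_ether",
        sm=(sm1, sm2),
        reagents=("O=C(O[Na])O[Na]",),
        product=product,
        changed_reactant=frozenset({a, b, c}),
        changed_product=frozenset({a, c}),
        n_tags=2,
    )


def _aryl_aryl_coupling(r1: str, r2: str) -> ToyReaction:
    f1, n1 = ARYL[r1](1)
    a1 = n1  # attachment carbon carries the last map of the fragment
    b = n1 + 1
    f2, n2 = ARYL[r2](b + 1)
    a2 = b + n2
    c, d, e = a2 + 1, a2 + 2, a2 + 3
    sm1 = f1 + f"[Br:{b}]"
    sm2 = f2 + f"[B:{c}]([OH:{d}])[OH:{e}]"
    product = _product_from_edits(
        [sm1, sm2],
        remove_atoms=[b, c, d, e],
        remove_bonds=[],
        add_bonds=[(a1, a2, Chem.BondType.SINGLE)],
        set_bonds=[],
        h_updates={},
    )
    return ToyReaction(
        family="aryl_aryl_coupling",
        sm=(sm1, sm2),
        reagents=("Cl[Pd]Cl", "c1ccc(P(c2ccccc2)c2ccccc2)cc1"),
        product=product,
        changed_reactant=frozenset({a1, b, a2, c, d, e}),
        changed_product=frozenset({a1, a2}),
        n_tags=2,
    )


def _hydrobromination(r1: str, r2: str) -> ToyReaction:
    # trisubstituted alkene: the Markovnikov orientation is unambiguous,
    # so forward re-application has a unique outcome
    f1, n1 = ALKYL[r1](1)
    x, a, b = n1 + 1, n1 + 2, n1 + 3
    f2, n2 = ALKYL_SUFFIX[r2](b + 1)
    c = b + n2 + 1
    sm1 = f1 + f"[C:{a}]([CH3:{x}])=[CH:{b}]" + f2
    sm2 = f"[BrH:{c}]"
    product = _product_from_edits(
        [sm1, sm2],
        remove_atoms=[],
        remove_bonds=[],
        add_bonds=[(a, c, Chem.BondType.SINGLE)],
        set_bonds=[(a, b, Chem.BondType.SINGLE)],
        h_updates={a: 0, b: 2, c: 0},
    )
    return ToyReaction(
        family="hydrobromination",
        sm=(sm1, sm2),
        reagents=(),
        product=product,
        changed_reactant=frozenset({a, b, c}),
        changed_product=frozenset({a, b, c}),
        n_tags=3,
    )


def _dihydroxylation(r1: str, r2: str) -> ToyReaction:
    f1, n1 = ALKYL[r1](1)
    a, b = n1 + 1, n1 + 2
    f2, n2 = ALKYL_SUFFIX[r2](b + 1)
    c, d = b + n2 + 1, b + n2 + 2
    sm1 = f1 + f"[CH:{a}]=[CH:{b}]" + f2
    sm2 = f"[OH:{c}][OH:{d}]"
    product = _product_from_edits(
        [sm1, sm2],
        remove_atoms=[],
        remove_bonds=[(c, d)],
        add_bonds=[
            (a, c, Chem.BondType.SINGLE),
            (b, d, Chem.BondType.SINGLE),
        ],
        set_bonds=[(a, b, Chem.BondType.SINGLE)],
        h_updates={},
    )
    return ToyReaction(
        family="dihydroxylation",
        sm=(sm1, sm2),
        reagents=("O=[Os](=O)(=O)=O",),
        product=product,
        changed_reactant=frozenset({a, b, c, d}),
        changed_product=frozenset({a, b, c, d}),
        n_tags=4,
    )


@dataclass(frozen=True)
class Family:
    name: str
    builder: FamilyBuilder
    r1_choices: tuple[str, ...]
    r2_choices: tuple[str, ...]  # empty tuple: unary family
    reagents: tuple[str, ...]


_ALKYL_NAMES = tuple(ALKYL)
_ARYL_NAMES = tuple(ARYL)

TOY_FAMILIES: tuple[Family, ...] = (
    Family(
        "esterification", _esterification, _ALKYL_NAMES, _ALKYL_NAMES,
        ("OS(=O)(=O)O",),
    ),
    Family(
        "amide_coupling", _amide_coupling, _ALKYL_NAMES, _ALKYL_NAMES,
        ("CC(C)N=C=NC(C)C",),
    ),
    Family(
        "williamson_ether", _williamson_ether, _ALKYL_NAMES, _ALKYL_NAMES,
        ("O=C(O[Na])O[Na]",),
    ),
    Family(
        "aryl_aryl_coupling", _aryl_aryl_coupling, _ARYL_NAMES, _ARYL_NAMES,
        ("Cl[Pd]Cl", "c1ccc(P(c2ccccc2)c2ccccc2)cc1"),
    ),
    Family(
        "hydrobromination", _hydrobromination, _ALKYL_NAMES, _ALKYL_NAMES,
        (),
    ),
    Family(
        "dihydroxylation", _dihydroxylation, _ALKYL_NAMES, _ALKYL_NAMES,
        ("O=[Os](=O)(=O)=O",),
    ),
)


def _family_combos(family: Family) -> list[tuple[str, str]]:
    if family.r2_choices:
        return [
            (r1, r2)
            for r1 in family.r1_choices
            for r2 in family.r2_choices
        ]
    return [(r1, "") for r1 in family.r1_choices]


@dataclass
class ToyWorld:
    """The toy chemistry universe: families, substituents, and a seed."""

    seed: int = 0
    families: tuple[Family, ...] = TOY_FAMILIES
    _template_cache: dict = field(default_factory=dict, repr=False)

    def exemplar(self, family: Family) -> ToyReaction:
        r1 = family.r1_choices[0]
        r2 = family.r2_choices[0] if family.r2_choices else ""
        return family.builder(r1, r2)

    def templates(self, radius: str = "r1") -> list[RetroTemplate]:
        """Retro templates extracted from one exemplar reaction per family."""
        if radius not in self._template_cache:
            out = []
            for fam in self.families:
                rxn = self.exemplar(fam).to_mapped_reaction(
                    source_id=f"{fam.name}-exemplar"
                )
                out.append(extract_template(rxn, radius))
            self._template_cache[radius] = out
        return list(self._template_cache[radius])

    def template_for(self, family_name: str, radius: str = "r1") -> RetroTemplate:
        for fam, t in zip(self.families, self.templates(radius)):
            if fam.name == family_name:
                return t
        raise KeyError(family_name)

    def reagent_table(self, radius: str = "r1") -> dict[str, list[list[str]]]:
        """Per-template fixed reagent lists for the oracle predictor."""
        table: dict[str, list[list[str]]] = {}
        for fam, t in zip(self.families, self.templates(radius)):
            table[t.template_id] = [list(fam.reagents)] if fam.reagents else []
        return table


def enumerate_pool(world: ToyWorld, n: int) -> list[Molecule]:
    """Deterministic pool of distinct toy products (canonical, unmapped).

    Products from all families are enumerated, deduplicated, sorted and
    then shuffled with the world seed so pool order is seed-stable.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    seen: set[str] = set()
    for fam in world.families:
        for r1, r2 in _family_combos(fam):
            toy = fam.builder(r1, r2)
            mol = Chem.MolFromSmiles(toy.product)
            for atom in mol.GetAtoms():
                atom.SetAtomMapNum(0)
            seen.add(Chem.MolToSmiles(mol))
    pool = sorted(seen)
    rng = np.random.default_rng(derive_seed(world.seed, "pool"))
    rng.shuffle(pool)
    if n > len(pool):
        warnings.warn(
            f"{n} molecules requested, toy space has {len(pool)}",
            stacklevel=2,
        )
        n = len(pool)
    return [Molecule.from_smiles(s) for s in pool[:n]]


def generate_toy_reactions(
    world: ToyWorld, n_per_template: int, seed: int | None = None
) -> list[tuple[MappedReaction, GroundTruth]]:
    """Mapped reactions with ground-truth labels, n per family."""
    seed = world.seed if seed is None else seed
    out: list[tuple[MappedReaction, GroundTruth]] = []
    for fam in world.families:
        combos = _family_combos(fam)
        rng = np.random.default_rng(
            [derive_seed(seed, "reactions"), stable_hash(fam.name)]
        )
        order = rng.permutation(len(combos))
        if n_per_template > len(combos):
            warnings.warn(
                f"family {fam.name}: {n_per_template} requested, "
                f"{len(combos)} available",
                stacklevel=2,
            )
        picks = order[: min(n_per_template, len(combos))]
        for k, ci in enumerate(picks):
            r1, r2 = combos[ci]
            toy = fam.builder(r1, r2)
            rxn = toy.to_mapped_reaction(source_id=f"{fam.name}-{k}")
            truth = GroundTruth(
                family=fam.name,
                changed_reactant=toy.changed_reactant,
                changed_product=toy.changed_product,
                n_tags=toy.n_tags,
                sm_plain=rxn.sm_plain_set(),
                reagents=tuple(sorted(m.plain for m in rxn.reagents)),
                product_plain=rxn.product.plain,
            )
            out.append((rxn, truth))
    return out


def perturb_dataset(
    reactions: Sequence[ReactionRecord],
    overlap_fraction: float,
    seed: int,
    n_condition_variants: int = 0,
) -> tuple[list[ReactionRecord], list[ReactionRecord]]:
    """Construct a dataset pair with known overlap for analysis tests.

    Returns ``(A, B)`` where A is the input and B shares exactly
    ``round(overlap_fraction * n)`` SM + R -> P keys with A, plus
    ``n_condition_variants`` same-SM-different-R records (shared SM -> P
    key, different reagents); the remaining B records are SM/product
    re-pairings sharing no key with A.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    n = len(reactions)
    k = round(overlap_fraction * n)
    if k + n_condition_variants > n:
        raise ValueError("overlap + condition variants exceed dataset size")
    rng = np.random.default_rng(derive_seed(seed, "perturb"))
    order = rng.permutation(n)
    a = list(reactions)
    shared = [a[i] for i in order[:k]]
    rest = [a[i] for i in order[k:]]
    variants = []
    for rec in rest[:n_condition_variants]:
        new_reagents = tuple(sorted(set(rec.reagents) ^ {"ClCCl"}))
        variants.append(
            ReactionRecord.build(
                rec.template_id, rec.sm, new_reagents, rec.product
            )
        )
    chimeras = []
    pool = rest[n_condition_variants:]
    if len(pool) > 1:
        for i, rec in enumerate(pool):
            partner = pool[(i + 1) % len(pool)]
            chimeras.append(
                ReactionRecord.build(
                    rec.template_id, rec.sm, rec.reagents, partner.product
                )
            )
    elif len(pool) == 1:
        rec = pool[0]
        chimeras.append(
            ReactionRecord.build(
                rec.template_id, rec.sm, rec.reagents, rec.product + ".O"
            )
        )
    b = shared + variants + chimeras
    return a, b
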