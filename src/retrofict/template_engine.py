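"""Reaction-center detection, retro-template extraction and application.

An atom *changed* between the two sides of a mapped reaction when its
neighbor multiset (map number, bond order), formal charge or total hydrogen
count differs, or when it exists on one side only. A radius-0 (r0) template
abstracts exactly the changed atoms; a radius-1 (r1) template additionally
keeps their first-shell neighbors. Templates are written as reaction SMARTS
with side-specific atom primitives:

* changed atoms: element, aromaticity, H count, degree, charge;
* shell atoms: element, aromaticity, degree, charge (no H count, which is
  the generality knob the hierarchical correction step exploits).

Applying a template retro (P -> SM) or forward (SM -> P) goes through
RDKit ``RunReactants``; hydrogen counts and charges of the changed atoms
are then re-imposed from the pattern itself so the outcome is exact and
deterministic rather than dependent on RDKit's creation heuristics.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, replace
from functools import lru_cache
from itertools import permutations
from typing import Iterable, Mapping, Sequence

from rdkit import Chem
from rdkit.Chem import AllChem

from ._seeding import stable_hash
from .errors import (
    AmbiguousMappingError,
    NoReactionError,
    TemplateExtractionError,
)
from .reaction_model import MappedReaction, Molecule, strip_maps

logger = logging.getLogger(__name__)

__all__ = [
    "ChangedAtomSet",
    "RetroTemplate",
    "detect_changed_atoms",
    "extract_template",
    "template_hash",
    "correct_templates",
    "match_products",
    "apply_retro",
    "apply_forward",
    "write_templates",
    "read_templates",
]

_BOND_SYM = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


@dataclass(frozen=True)
class ChangedAtomSet:
    """Map numbers of atoms whose environment changed, per side."""

    reactant_side: frozenset[int]
    product_side: frozenset[int]

    def __bool__(self) -> bool:
        return bool(self.reactant_side or self.product_side)


@dataclass(frozen=True)
class RetroTemplate:
    """A retrosynthetic transformation rule, product pattern -> SM patterns."""

    template_id: str
    radius: str  # "r0" | "r1"
    product_pattern: str
    reactant_patterns: tuple[str, ...]
    n_tags: int
    parent_r0_hash: str
    hash: str
    n_examples: int = 1

    @property
    def retro_smarts(self) -> str:
        return f"{self.product_pattern}>>{'.'.join(self.reactant_patterns)}"

    @property
    def forward_smarts(self) -> str:
        return f"{'.'.join(self.reactant_patterns)}>>{self.product_pattern}"

    @property
    def changed_reactant_maps(self) -> frozenset[int]:
        """Template map numbers of SM-side atoms with an environment change.

        By construction the changed product atoms carry maps 1..n_tags and
        reactant-only atoms carry maps absent from the product pattern.
        """
        pmaps = set(_pattern_maps(self.product_pattern))
        out: set[int] = set()
        for pat in self.reactant_patterns:
            for m in _pattern_maps(pat):
                if m <= self.n_tags or m not in pmaps:
                    out.add(m)
        return frozenset(out)

    @property
    def specificity(self) -> int:
        """Total number of atom-query primitives; fewer = more general."""
        n = 0
        for pat in (self.product_pattern, *self.reactant_patterns):
            for body in re.findall(r"\[([^\]]+)\]", pat):
                body = body.split(":")[0]
                n += len([p for p in re.split(r"[;&]", body) if p])
        return n


# --------------------------------------------------------------------------
# changed-atom detection


def _atom_env(atom: Chem.Atom) -> tuple:
    mol = atom.GetOwningMol()
    neigh = sorted(
        (
            n.GetAtomMapNum(),
            mol.GetBondBetweenAtoms(atom.GetIdx(), n.GetIdx()).GetBondTypeAsDouble(),
        )
        for n in atom.GetNeighbors()
    )
    return (neigh, atom.GetFormalCharge(), atom.GetTotalNumHs())


def detect_changed_atoms(rxn: MappedReaction) -> ChangedAtomSet:
    """Compare each mapped atom's environment between SM and product.

    Atoms present on one side only are changed on that side. If an atom's
    environment differs but an unmapped heavy neighbor is involved, the
    center cannot be located reliably and an
    :class:`~retrofict.errors.AmbiguousMappingError` is raised.
    """
    r_atoms: dict[int, Chem.Atom] = {}
    r_mols = [m.to_mol() for m in rxn.starting_materials]
    for mol in r_mols:
        for atom in mol.GetAtoms():
            if atom.GetAtomMapNum():
                r_atoms[atom.GetAtomMapNum()] = atom
    p_mol = rxn.product.to_mol()
    p_atoms = {a.GetAtomMapNum(): a for a in p_mol.GetAtoms() if a.GetAtomMapNum()}

    r_changed: set[int] = set()
    p_changed: set[int] = set()
    for mn in set(r_atoms) | set(p_atoms):
        if mn not in p_atoms:
            r_changed.add(mn)
        elif mn not in r_atoms:
            p_changed.add(mn)
        else:
            env_r = _atom_env(r_atoms[mn])
            env_p = _atom_env(p_atoms[mn])
            if env_r != env_p:
                if any(n == 0 for n, _ in env_r[0]) or any(
                    n == 0 for n, _ in env_p[0]
                ):
                    raise AmbiguousMappingError(
                        f"atom map {mn}: environment change involves an "
                        "unmapped heavy neighbor"
                    )
                r_changed.add(mn)
                p_changed.add(mn)
    return ChangedAtomSet(
        reactant_side=frozenset(r_changed), product_side=frozenset(p_changed)
    )


# --------------------------------------------------------------------------
# SMARTS writing


def _atom_query(atom: Chem.Atom, new_map: int, with_h: bool) -> str:
    parts = [f"#{atom.GetAtomicNum()}", "a" if atom.GetIsAromatic() else "A"]
    if with_h:
        parts.append(f"H{atom.GetTotalNumHs()}")
    parts.append(f"D{atom.GetDegree()}")
    charge = atom.GetFormalCharge()
    parts.append(f"{'+' if charge >= 0 else '-'}{abs(charge)}")
    return "[" + ";".join(parts) + f":{new_map}]"


def _write_fragment_smarts(
    order: Sequence[int],
    labels: Mapping[int, str],
    bonds: Mapping[tuple[int, int], str],
) -> str:
    """Serialize one connected-or-not subgraph to SMARTS.

    ``order`` fixes atom output order (canonical), ``labels`` the atom query
    strings, ``bonds`` the bond symbols keyed by sorted atom-index pairs.
    Handles branches and ring closures; disconnected pieces are joined with
    '.' (the caller adds component parentheses when needed).
    """
    adj: dict[int, list[int]] = {i: [] for i in order}
    for (i, j) in bonds:
        adj[i].append(j)
        adj[j].append(i)
    pos = {a: k for k, a in enumerate(order)}
    for i in adj:
        adj[i].sort(key=pos.__getitem__)

    visit_time: dict[int, int] = {}
    tree: dict[int, list[int]] = {i: [] for i in order}
    ring_pairs: list[tuple[int, int]] = []  # (ancestor, descendant)
    roots: list[int] = []

    def dfs(i: int) -> None:
        visit_time[i] = len(visit_time)
        for j in adj[i]:
            if j not in visit_time:
                tree[i].append(j)
                dfs(j)
            elif visit_time[j] < visit_time[i] and j not in tree_parent_of(i):
                ring_pairs.append((j, i))

    def tree_parent_of(i: int) -> tuple[int, ...]:
        return tuple(p for p, kids in tree.items() if i in kids)

    for a in order:
        if a not in visit_time:
            roots.append(a)
            dfs(a)

    ring_pairs.sort(key=lambda p: (visit_time[p[0]], visit_time[p[1]]))
    digit_of = {pair: d for d, pair in enumerate(ring_pairs, start=1)}
    closures: dict[int, list[tuple[int, int]]] = {i: [] for i in order}
    for pair in ring_pairs:
        closures[pair[0]].append(pair)
        closures[pair[1]].append(pair)

    def bond_sym(i: int, j: int) -> str:
        return bonds[(i, j) if (i, j) in bonds else (j, i)]

    def digit_str(d: int) -> str:
        return str(d) if d < 10 else f"%{d:02d}"

    def emit(i: int) -> str:
        s = labels[i]
        for pair in sorted(closures[i], key=digit_of.__getitem__):
            s += bond_sym(*pair) + digit_str(digit_of[pair])
        kids = tree[i]
        for j in kids[:-1]:
            s += "(" + bond_sym(i, j) + emit(j) + ")"
        if kids:
            j = kids[-1]
            s += bond_sym(i, j) + emit(j)
        return s

    return ".".join(emit(r) for r in roots)


def _subgraph_smarts(
    mol: Chem.Mol,
    atom_ids: Sequence[int],
    new_maps: Mapping[int, int],
    with_h_ids: set[int],
) -> str:
    order = list(atom_ids)
    labels = {
        i: _atom_query(mol.GetAtomWithIdx(i), new_maps[i], with_h=i in with_h_ids)
        for i in order
    }
    selected = set(order)
    bonds: dict[tuple[int, int], str] = {}
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in selected and j in selected:
            bonds[(min(i, j), max(i, j))] = _BOND_SYM[b.GetBondType()]
    smarts = _write_fragment_smarts(order, labels, bonds)
    if "." in smarts:
        smarts = f"({smarts})"
    return smarts


_MAP_RE = re.compile(r":(\d+)\]")
_ATOM_RE = re.compile(r"\[([^\]]+):(\d+)\]")


def _pattern_maps(pattern: str) -> list[int]:
    return [int(m) for m in _MAP_RE.findall(pattern)]


@lru_cache(maxsize=4096)
def _pattern_intents(pattern: str) -> dict[int, tuple[int, int, int]]:
    """map -> (atomic number, H count, charge) for atoms carrying an H primitive."""
    out: dict[int, tuple[int, int, int]] = {}
    for body, mapno in _ATOM_RE.findall(pattern):
        prims = re.split(r"[;&]", body)
        elem = h = charge = None
        for p in prims:
            if p.startswith("#"):
                elem = int(p[1:])
            elif re.fullmatch(r"H\d+", p):
                h = int(p[1:])
            elif re.fullmatch(r"[+-]\d+", p):
                charge = int(p)
        if elem is not None and h is not None:
            out[int(mapno)] = (elem, h, charge or 0)
    return out


def _side_intents(patterns: Iterable[str]) -> dict[int, tuple[int, int, int]]:
    out: dict[int, tuple[int, int, int]] = {}
    for pat in patterns:
        out.update(_pattern_intents(pat))
    return out


# --------------------------------------------------------------------------
# extraction


def _order_extras(
    mol: Chem.Mol, extras: list[int], maps_here: dict[int, int]
) -> list[int]:
    """Deterministic order for reactant-only atoms: BFS out from the mapped
    atoms, ties broken by atom invariants."""
    if not extras:
        return []
    dist = {i: 0 for i in maps_here}
    frontier = list(maps_here)
    remaining = set(extras)
    layers: dict[int, int] = {}
    d = 0
    while frontier and remaining:
        d += 1
        nxt = []
        for i in frontier:
            for n in mol.GetAtomWithIdx(i).GetNeighbors()[:]:
                j = n.GetIdx()
                if j in remaining and j not in layers:
                    layers[j] = d
                    nxt.append(j)
        frontier = nxt
    for j in remaining:  # disconnected leaving atoms (single-atom species)
        layers.setdefault(j, d + 1)

    def key(i: int):
        a = mol.GetAtomWithIdx(i)
        anchor = min(
            (maps_here[n.GetIdx()] for n in a.GetNeighbors() if n.GetIdx() in maps_here),
            default=10**6,
        )
        return (
            layers[i],
            anchor,
            a.GetAtomicNum(),
            a.GetFormalCharge(),
            a.GetTotalNumHs(),
            a.GetDegree(),
            i,
        )

    ordered = []
    for i in sorted(extras, key=key):
        ordered.append(i)
    return ordered


def template_hash(t: RetroTemplate) -> str:
    """Stable digest of the canonical pattern form."""
    return _hash_patterns(t.radius, t.product_pattern, t.reactant_patterns)


def _hash_patterns(radius: str, pp: str, rps: Sequence[str]) -> str:
    text = f"{radius}|{pp}>>{'.'.join(sorted(rps))}"
    return hashlib.sha256(text.encode("utf-8")).hexdigest()[:16]


def extract_template(
    rxn: MappedReaction, radius: str = "r1", *, verify: bool = True
) -> RetroTemplate:
    """Extract a retro template at radius ``"r0"`` or ``"r1"``.

    Atom maps in the pattern are renumbered canonically (changed product
    atoms get 1..n_tags by canonical rank), so atom-renumbered copies of
    the same reaction hash identically. With ``verify=True`` the template
    is self-checked: its retro application to the reaction product must
    regenerate the recorded SM-set.
    """
    if radius not in ("r0", "r1"):
        raise ValueError(f"radius must be 'r0' or 'r1', got {radius!r}")
    changed = detect_changed_atoms(rxn)
    if not changed.product_side:
        raise NoReactionError(
            f"no changed product atoms in reaction {rxn.source_id!r}"
        )

    p_mol = rxn.product.to_mol()
    # Rank product atoms with their reactant-side environment encoded as an
    # isotope label, so symmetric product patterns (e.g. the two ipso
    # carbons of a biaryl) still number their atoms by reaction role and
    # mirror-image source reactions yield identical patterns.
    r_sig: dict[int, int] = {}
    for sm in rxn.starting_materials:
        mol = sm.to_mol()
        for a in mol.GetAtoms():
            if not a.GetAtomMapNum():
                continue
            neigh = sorted(
                (
                    n.GetAtomicNum(),
                    mol.GetBondBetweenAtoms(a.GetIdx(), n.GetIdx())
                    .GetBondTypeAsDouble(),
                    n.GetAtomMapNum() == 0,
                )
                for n in a.GetNeighbors()
            )
            sig = (a.GetFormalCharge(), a.GetTotalNumHs(), tuple(neigh))
            r_sig[a.GetAtomMapNum()] = 1 + stable_hash(repr(sig)) % 9999
    stripped = Chem.Mol(p_mol)
    for a in stripped.GetAtoms():
        mn = a.GetAtomMapNum()
        a.SetAtomMapNum(0)
        a.SetIsotope(r_sig.get(mn, 0))
    rank = list(Chem.CanonicalRankAtoms(stripped, breakTies=True))

    by_map = {a.GetAtomMapNum(): a.GetIdx() for a in p_mol.GetAtoms() if a.GetAtomMapNum()}
    core_ids = sorted(
        (by_map[m] for m in changed.product_side), key=lambda i: rank[i]
    )
    shell_ids: list[int] = []
    if radius == "r1":
        core_set = set(core_ids)
        shell = {
            n.GetIdx()
            for i in core_ids
            for n in p_mol.GetAtomWithIdx(i).GetNeighbors()
            if n.GetIdx() not in core_set
        }
        shell_ids = sorted(shell, key=lambda i: rank[i])

    new_map_p: dict[int, int] = {}
    for k, i in enumerate(core_ids + shell_ids, start=1):
        new_map_p[i] = k
    n_tags = len(core_ids)
    try:
        product_pattern = _subgraph_smarts(
            p_mol, core_ids + shell_ids, new_map_p, with_h_ids=set(core_ids)
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise TemplateExtractionError(
            f"product pattern generation failed for {rxn.source_id!r}: {exc}"
        ) from exc

    # old product map -> new template map, for atoms kept in the pattern
    old_to_new = {
        p_mol.GetAtomWithIdx(i).GetAtomMapNum(): m for i, m in new_map_p.items()
    }
    r_only = changed.reactant_side - set(by_map)

    # species visited in order of their smallest template map so that
    # reactant-only atom numbering is independent of species SMILES sorting
    def _species_min_map(sm: Molecule) -> tuple[int, str]:
        maps = [old_to_new[m] for m in sm.maps if m in old_to_new]
        return (min(maps) if maps else len(new_map_p) + 1, sm.plain)

    species: list[str] = []
    next_map = len(new_map_p) + 1
    for sm in sorted(rxn.starting_materials, key=_species_min_map):
        mol = sm.to_mol()
        sel: list[int] = []
        changed_here: set[int] = set()
        maps_here: dict[int, int] = {}
        extras: list[int] = []
        for a in mol.GetAtoms():
            mn = a.GetAtomMapNum()
            if not mn:
                continue
            if mn in old_to_new:
                sel.append(a.GetIdx())
                maps_here[a.GetIdx()] = old_to_new[mn]
                if mn in changed.reactant_side:
                    changed_here.add(a.GetIdx())
            elif mn in r_only:
                sel.append(a.GetIdx())
                extras.append(a.GetIdx())
                changed_here.add(a.GetIdx())
        if not sel:
            continue
        for i in _order_extras(mol, extras, maps_here):
            maps_here[i] = next_map
            next_map += 1
        sel.sort(key=lambda i: maps_here[i])
        try:
            pat = _subgraph_smarts(mol, sel, maps_here, with_h_ids=changed_here)
        except Exception as exc:  # pragma: no cover - defensive
            raise TemplateExtractionError(
                f"reactant pattern generation failed for {rxn.source_id!r}: {exc}"
            ) from exc
        species.append(pat)
    if not species:
        raise TemplateExtractionError(
            f"no reactant-side pattern atoms for {rxn.source_id!r}"
        )
    reactant_patterns = tuple(sorted(species))

    if radius == "r1":
        parent = extract_template(rxn, "r0", verify=False).hash
    else:
        parent = _hash_patterns("r0", product_pattern, reactant_patterns)

    t = RetroTemplate(
        template_id="",
        radius=radius,
        product_pattern=product_pattern,
        reactant_patterns=reactant_patterns,
        n_tags=n_tags,
        parent_r0_hash=parent,
        hash=_hash_patterns(radius, product_pattern, reactant_patterns),
        n_examples=1,
    )
    t = replace(t, template_id=f"{radius}-{t.hash}")
    if verify:
        expected = rxn.sm_plain_set()
        got = apply_retro(t, strip_maps(rxn.product))
        if expected not in [
            tuple(sorted(m.plain for m in sm_set)) for sm_set in got
        ]:
            raise TemplateExtractionError(
                f"template from {rxn.source_id!r} failed retro self-consistency"
            )
    return t


# --------------------------------------------------------------------------
# application


@lru_cache(maxsize=4096)
def _compiled(smarts: str) -> AllChem.ChemicalReaction:
    rxn = AllChem.ReactionFromSmarts(smarts)
    if rxn is None:  # pragma: no cover - our own patterns always parse
        raise TemplateExtractionError(f"bad reaction SMARTS: {smarts}")
    return rxn


@lru_cache(maxsize=4096)
def _match_queries(product_pattern: str) -> tuple[Chem.Mol, ...]:
    pat = product_pattern
    if pat.startswith("(") and pat.endswith(")"):
        pat = pat[1:-1]
    return tuple(Chem.MolFromSmarts(c) for c in pat.split("."))


def match_products(t: RetroTemplate, pool: Sequence[Molecule]) -> list[Molecule]:
    """Pool molecules with a substructure match of the product pattern."""
    queries = _match_queries(t.product_pattern)
    out = []
    for m in pool:
        mol = m.to_mol()
        if all(mol.HasSubstructMatch(q) for q in queries):
            out.append(m)
    return out


def _repair(mol: Chem.Mol, intents: Mapping[int, tuple[int, int, int]]) -> Chem.Mol:
    """Re-impose H counts/charges recorded for changed atoms, keep maps."""
    for atom in mol.GetAtoms():
        if atom.HasProp("old_mapno"):
            mn = atom.GetIntProp("old_mapno")
            atom.SetAtomMapNum(mn)
            if mn in intents:
                _, h, charge = intents[mn]
                atom.SetNoImplicit(True)
                atom.SetNumExplicitHs(h)
                atom.SetFormalCharge(charge)
    Chem.SanitizeMol(mol)
    return mol


def apply_retro(
    t: RetroTemplate, product: Molecule
) -> list[tuple[Molecule, ...]]:
    """Apply the template in retro direction: product -> SM-sets.

    Returns one map-annotated SM-set per distinct match site; unsanitizable
    outcomes are dropped (and counted in the module logger); duplicate
    SM-sets are collapsed. Output order is deterministic (sorted by the
    map-stripped canonical key of the set).
    """
    rxn = _compiled(t.retro_smarts)
    mol = Chem.MolFromSmiles(product.plain)
    if mol is None:
        return []
    intents = _side_intents(t.reactant_patterns)
    seen: set[tuple[str, ...]] = set()
    out: list[tuple[tuple[str, ...], tuple[Molecule, ...]]] = []
    n_dropped = 0
    for frags in rxn.RunReactants((mol,)):
        try:
            mols = tuple(
                Molecule.from_mol(_repair(f, intents)) for f in frags
            )
        except Exception:
            n_dropped += 1
            continue
        key = tuple(sorted(m.plain for m in mols))
        if key in seen:
            continue
        seen.add(key)
        out.append((key, mols))
    if n_dropped:
        logger.debug(
            "apply_retro(%s): dropped %d unsanitizable outcome(s)",
            t.template_id,
            n_dropped,
        )
    out.sort(key=lambda kv: kv[0])
    return [mols for _, mols in out]


def apply_forward(
    t: RetroTemplate, sm: Sequence[Molecule]
) -> Molecule | None:
    """Apply the inverted template: SM-set -> unique product, else ``None``."""
    if len(sm) != len(t.reactant_patterns):
        return None
    rxn = _compiled(t.forward_smarts)
    intents = _pattern_intents(t.product_pattern)
    mols = [Chem.MolFromSmiles(m.plain) for m in sm]
    if any(m is None for m in mols):
        return None
    products: set[str] = set()
    for perm in set(permutations(range(len(mols)))):
        try:
            results = rxn.RunReactants(tuple(mols[i] for i in perm))
        except Exception:
            continue
        for frags in results:
            if len(frags) != 1:
                continue
            try:
                repaired = _repair(frags[0], intents)
            except Exception:
                continue
            m = Molecule.from_mol(repaired)
            products.add(m.plain)
    if len(products) == 1:
        return Molecule(smiles=products.pop())
    return None


# --------------------------------------------------------------------------
# hierarchical correction


def _covers(t: RetroTemplate, rxn: MappedReaction) -> bool:
    expected = rxn.sm_plain_set()
    for sm_set in apply_retro(t, strip_maps(rxn.product)):
        if tuple(sorted(m.plain for m in sm_set)) == expected:
            return True
    return False


def correct_templates(
    r1_templates: Sequence[RetroTemplate],
    reactions_by_template: Mapping[str, Sequence[MappedReaction]],
) -> list[RetroTemplate]:
    """Merge behaviorally equivalent r1 templates within each r0 group.

    Two templates are equivalent iff each one's retro application reproduces
    the recorded SM-set for every example reaction of the other. Mutually
    equivalent templates are merged (transitively) and rewritten as the most
    general member — fewest specified atom primitives, ties broken by the
    lexicographically smallest pattern — with example counts summed.
    Non-equivalent templates pass through unchanged.
    """
    parent: dict[int, int] = {}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    groups: dict[str, list[int]] = {}
    for idx, t in enumerate(r1_templates):
        parent[idx] = idx
        groups.setdefault(t.parent_r0_hash, []).append(idx)

    for members in groups.values():
        for a_pos, i in enumerate(members):
            for j in members[a_pos + 1 :]:
                if find(i) == find(j):
                    continue
                ti, tj = r1_templates[i], r1_templates[j]
                ex_i = reactions_by_template.get(ti.template_id, ())
                ex_j = reactions_by_template.get(tj.template_id, ())
                if all(_covers(ti, r) for r in ex_j) and all(
                    _covers(tj, r) for r in ex_i
                ):
                    union(i, j)

    classes: dict[int, list[int]] = {}
    for idx in range(len(r1_templates)):
        classes.setdefault(find(idx), []).append(idx)

    merged: list[RetroTemplate] = []
    for members in classes.values():
        ts = [r1_templates[i] for i in members]
        rep = min(
            ts,
            key=lambda t: (
                t.specificity,
                t.product_pattern,
                ".".join(t.reactant_patterns),
            ),
        )
        merged.append(replace(rep, n_examples=sum(t.n_examples for t in ts)))
    merged.sort(key=lambda t: t.template_id)
    return merged


# --------------------------------------------------------------------------
# template table I/O (TSV)

_COLUMNS = [
    "template_id",
    "radius",
    "product_pattern",
    "reactant_patterns",
    "n_tags",
    "parent_r0_hash",
    "hash",
    "n_examples",
]


def write_templates(templates: Sequence[RetroTemplate], path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "template_id": t.template_id,
                "radius": t.radius,
                "product_pattern": t.product_pattern,
                "reactant_patterns": ".".join(t.reactant_patterns),
                "n_tags": t.n_tags,
                "parent_r0_hash": t.parent_r0_hash,
                "hash": t.hash,
                "n_examples": t.n_examples,
            }
            for t in templates
        ],
        columns=_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def _split_top_level(text: str) -> list[str]:
    """Split '.'-joined patterns, respecting component parentheses."""
    parts, depth, cur = [], 0, []
    bracket = 0
    for ch in text:
        if ch == "[":
            bracket += 1
        elif ch == "]":
            bracket -= 1
        if bracket == 0:
            if ch == "(" and not cur:
                depth += 1
            elif ch == ")" and depth:
                depth -= 1
            elif ch == "." and depth == 0:
                parts.append("".join(cur))
                cur = []
                continue
        cur.append(ch)
    parts.append("".join(cur))
    return parts


def read_templates(path) -> list[RetroTemplate]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            RetroTemplate(
                template_id=row.template_id,
                radius=row.radius,
                product_pattern=row.product_pattern,
                reactant_patterns=tuple(
                    _split_top_level(row.reactant_patterns)
                ),
                n_tags=int(row.n_tags),
                parent_r0_hash=row.parent_r0_hash,
                hash=row.hash,
                n_examples=int(row.n_examples),
            )
        )
    return out
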