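"""Dataset operations: equilibration, template-grouped splits, overlap,
novelty, and distribution reporting.

All operations are duck-typed over *records*: any object exposing
``template_id``, ``keys`` (``{"sm_p": ..., "smrp": ...}``), ``sm`` and
``reagents`` (species lists, SMILES text or objects with ``.plain``)
qualifies — both :class:`~retrofict.generation.FictiveReaction` and the
lightweight :class:`ReactionRecord` do.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem

from ._seeding import derive_seed, stable_hash

__all__ = [
    "ReactionRecord",
    "OverlapReport",
    "SplitAssignment",
    "equilibrate",
    "split_by_template",
    "overlap_analysis",
    "novelty_analysis",
    "tag_count_distribution",
    "element_frequency",
    "as_percentage",
]


@dataclass(frozen=True)
class ReactionRecord:
    """Minimal reaction record carrying only what the dataset ops need."""

    template_id: str
    sm: tuple[str, ...]
    reagents: tuple[str, ...]
    product: str
    keys: dict[str, str] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        template_id: str,
        sm: Sequence[str],
        reagents: Sequence[str],
        product: str,
    ) -> "ReactionRecord":
        sm_part = ".".join(sorted(sm))
        r_part = ".".join(sorted(reagents))
        return cls(
            template_id=template_id,
            sm=tuple(sm),
            reagents=tuple(reagents),
            product=product,
            keys={
                "sm_p": f"{sm_part}>{product}",
                "smrp": f"{sm_part}>{r_part}>{product}",
            },
        )

    @classmethod
    def from_mapped_reaction(cls, rxn, template_id: str = "") -> "ReactionRecord":
        return cls.build(
            template_id=template_id,
            sm=[m.plain for m in rxn.starting_materials],
            reagents=[m.plain for m in rxn.reagents],
            product=rxn.product.plain,
        )


def _species_plain(sp) -> str:
    return sp if isinstance(sp, str) else sp.plain


def equilibrate(dataset: Sequence, cap: int, seed: int) -> list:
    """Cap the number of records per template.

    Templates at or under the cap are kept whole; larger groups are
    down-sampled uniformly without replacement with a per-template seed
    derived from ``seed``. Output preserves the input order.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    by_template: dict[str, list[int]] = defaultdict(list)
    for i, rec in enumerate(dataset):
        by_template[rec.template_id].append(i)
    keep: set[int] = set()
    for tid, idxs in by_template.items():
        if len(idxs) <= cap:
            keep.update(idxs)
        else:
            rng = np.random.default_rng(
                [derive_seed(seed, "equilibrate"), stable_hash(tid)]
            )
            keep.update(rng.choice(idxs, size=cap, replace=False).tolist())
    return [rec for i, rec in enumerate(dataset) if i in keep]


@dataclass(frozen=True)
class SplitAssignment:
    """Template -> split assignment with realized reaction-count ratios."""

    assignment: dict[str, str]
    counts: dict[str, int]
    realized_ratios: dict[str, float]

    def split_of(self, template_id: str) -> str:
        return self.assignment[template_id]


def split_by_template(
    dataset: Sequence,
    ratios: Sequence[float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    split_names: Sequence[str] = ("train", "valid", "test"),
) -> SplitAssignment:
    """Greedy template-grouped split (no template straddles splits).

    Templates are taken in descending reaction count (seeded shuffle breaks
    ties) and each is assigned to the currently most-underfilled split, so
    realized ratios deviate from the targets by at most the weight of the
    largest template.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    if len(ratios) != len(split_names):
        raise ValueError("one ratio per split name")
    counts = Counter(rec.template_id for rec in dataset)
    if len(counts) < len(ratios):
        raise ValueError(
            f"{len(counts)} templates cannot fill {len(ratios)} splits"
        )
    total = sum(counts.values())
    rng = np.random.default_rng(derive_seed(seed, "split"))
    tids = list(counts)
    rng.shuffle(tids)
    tids.sort(key=lambda t: -counts[t])  # stable: shuffled order breaks ties

    assigned: dict[str, str] = {}
    filled = {name: 0 for name in split_names}
    for tid in tids:
        deficits = {
            name: ratios[i] * total - filled[name]
            for i, name in enumerate(split_names)
        }
        target = max(split_names, key=lambda n: deficits[n])
        assigned[tid] = target
        filled[target] += counts[tid]
    realized = {name: filled[name] / total for name in split_names}
    return SplitAssignment(
        assignment=assigned,
        counts=dict(filled),
        realized_ratios=realized,
    )


@dataclass(frozen=True)
class OverlapReport:
    """Pairwise dataset overlap in the two reaction views.

    ``shared_sm_p`` / ``shared_smrp`` are key-set intersection sizes
    (symmetric); ``different_conditions`` counts SM -> P keys shared
    without any exact SM + R -> P match. Fractions are per direction,
    relative to each dataset's own key counts.
    """

    shared_sm_p: int
    shared_smrp: int
    different_conditions: int
    frac_a_sm_p: float
    frac_a_smrp: float
    frac_a_diff_cond: float
    frac_b_sm_p: float
    frac_b_smrp: float
    frac_b_diff_cond: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _key_sets(dataset: Iterable, distinct: bool) -> tuple:
    sm_p: list[str] = []
    smrp: list[str] = []
    smrp_to_smp: dict[str, str] = {}
    for rec in dataset:
        kp, kr = rec.keys["sm_p"], rec.keys["smrp"]
        sm_p.append(kp)
        smrp.append(kr)
        smrp_to_smp[kr] = kp
    if distinct:
        return set(sm_p), set(smrp), smrp_to_smp
    return sm_p, smrp, smrp_to_smp


def overlap_analysis(
    a: Sequence, b: Sequence, *, distinct: bool = True
) -> OverlapReport:
    """Shared-reaction analysis between datasets A and B.

    With ``distinct=True`` (default) fractions are over distinct keys;
    ``distinct=False`` counts raw rows in each direction's denominator.
    """
    a_smp, a_smrp, a_proj = _key_sets(a, True)
    b_smp, b_smrp, b_proj = _key_sets(b, True)
    shared_smp_keys = a_smp & b_smp
    shared_smrp_keys = a_smrp & b_smrp
    exact_smp = {a_proj[k] for k in shared_smrp_keys}
    diff_cond_keys = shared_smp_keys - exact_smp

    def _denoms(dataset, smp_keys, smrp_keys):
        if distinct:
            return len(smp_keys), len(smrp_keys)
        rows_smp = [rec.keys["sm_p"] for rec in dataset]
        rows_smrp = [rec.keys["smrp"] for rec in dataset]
        return len(rows_smp), len(rows_smrp)

    def _numers(dataset, smp_keys, smrp_keys):
        if distinct:
            return (
                len(shared_smp_keys),
                len(shared_smrp_keys),
                len(diff_cond_keys),
            )
        n_smp = sum(1 for rec in dataset if rec.keys["sm_p"] in shared_smp_keys)
        n_smrp = sum(
            1 for rec in dataset if rec.keys["smrp"] in shared_smrp_keys
        )
        n_diff = sum(
            1 for rec in dataset if rec.keys["sm_p"] in diff_cond_keys
        )
        return n_smp, n_smrp, n_diff

    na_smp, na_smrp = _denoms(a, a_smp, a_smrp)
    nb_smp, nb_smrp = _denoms(b, b_smp, b_smrp)
    xa_smp, xa_smrp, xa_diff = _numers(a, a_smp, a_smrp)
    xb_smp, xb_smrp, xb_diff = _numers(b, b_smp, b_smrp)

    def _frac(n, d):
        return n / d if d else 0.0

    return OverlapReport(
        shared_sm_p=len(shared_smp_keys),
        shared_smrp=len(shared_smrp_keys),
        different_conditions=len(diff_cond_keys),
        frac_a_sm_p=_frac(xa_smp, na_smp),
        frac_a_smrp=_frac(xa_smrp, na_smrp),
        frac_a_diff_cond=_frac(xa_diff, na_smp),
        frac_b_sm_p=_frac(xb_smp, nb_smp),
        frac_b_smrp=_frac(xb_smrp, nb_smrp),
        frac_b_diff_cond=_frac(xb_diff, nb_smp),
    )


def novelty_analysis(a: Sequence, b: Sequence) -> dict[str, float]:
    """Species-level novelty of A vs reference B and coverage of B by A.

    Computed over distinct canonical map-stripped species, separately for
    starting materials and reagents.
    """

    def _species(dataset, attr):
        out: set[str] = set()
        for rec in dataset:
            out.update(_species_plain(s) for s in getattr(rec, attr))
        return out

    result: dict[str, float] = {}
    for attr, label in (("sm", "sm"), ("reagents", "reagents")):
        a_set, b_set = _species(a, attr), _species(b, attr)
        result[f"novelty_{label}"] = (
            len(a_set - b_set) / len(a_set) if a_set else 0.0
        )
        result[f"coverage_{label}"] = (
            len(b_set & a_set) / len(b_set) if b_set else 0.0
        )
    return result


def tag_count_distribution(items: Sequence) -> dict[int, dict[str, float]]:
    """Histogram of tag counts with percentages (one decimal).

    Accepts templates or records; anything with an ``n_tags`` attribute.
    """
    counts = Counter(item.n_tags for item in items)
    total = sum(counts.values())
    return {
        n: {"count": c, "percent": as_percentage(c, total)}
        for n, c in sorted(counts.items())
    }


def element_frequency(
    dataset: Sequence, elements: Sequence[str]
) -> dict[str, float]:
    """Fraction of reactions with >= 1 reagent species containing each element.

    Matching is on atoms (a Na reagent is not matched by the N of an amine
    or by Sn). Unknown element symbols raise ``ValueError``.
    """
    pt = Chem.GetPeriodicTable()
    nums = {}
    for sym in elements:
        try:
            num = pt.GetAtomicNumber(sym)
        except Exception:
            raise ValueError(f"unknown element symbol: {sym!r}") from None
        if num == 0:
            raise ValueError(f"unknown element symbol: {sym!r}")
        nums[sym] = num
    n_reactions = 0
    hits = Counter()
    for rec in dataset:
        n_reactions += 1
        present: set[int] = set()
        for sp in rec.reagents:
            mol = Chem.MolFromSmiles(_species_plain(sp))
            if mol is None:
                continue
            present.update(a.GetAtomicNum() for a in mol.GetAtoms())
        for sym, num in nums.items():
            if num in present:
                hits[sym] += 1
    if n_reactions == 0:
        return {sym: 0.0 for sym in elements}
    return {sym: hits[sym] / n_reactions for sym in elements}


def as_percentage(numerator: int, denominator: int) -> float:
    """``100 * numerator / denominator`` rounded half-away-from-zero, 1 dp."""
    if denominator == 0:
        raise ValueError("zero denominator")
    sign = -1 if (numerator < 0) != (denominator < 0) else 1
    num, den = abs(numerator), abs(denominator)
    # one-decimal rounding in exact integer arithmetic
    tenths = (2000 * num + den) // (2 * den)
    return sign * tenths / 10.0
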