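"""The fictive-reaction generation campaign.

For each retro template, the molecule pool (split into subsets, visited in
seeded random order) is scanned for molecules matching the template's
product pattern. Each match is turned into candidate starting materials by
retro application, reagents are predicted, the changed atoms are tagged to
form SM*, and a forward validator must regenerate the product with a
confidence strictly above the threshold (default 0.95) for the candidate
to be accepted. The per-template loop stops once the cap (default 5000)
of validated reactions is reached or the pool is exhausted.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seeding import derive_seed, stable_hash
from .errors import CheckpointError, PredictorError
from .reaction_model import KeyMode, Molecule
from .predictors import ForwardValidator, ReagentPredictor
from .tagging import TaggedMolecule, tag_changed_atoms
from .template_engine import (
    ChangedAtomSet,
    RetroTemplate,
    apply_retro,
    match_products,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GenerationConfig",
    "FictiveReaction",
    "TemplateStats",
    "CampaignStats",
    "shard_pool",
    "validate_candidate",
    "generate_for_template",
    "run_campaign",
]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class GenerationConfig:
    cap_per_template: int = 5000
    confidence_threshold: float = 0.95
    n_pool_subsets: int = 1000
    seed: int = 0
    max_reagent_candidates: int = 1

    def __post_init__(self):
        if self.cap_per_template < 1:
            raise ValueError("cap_per_template must be >= 1")
        if not 0.0 < self.confidence_threshold < 1.0:
            raise ValueError("confidence_threshold must be in (0, 1)")
        if self.n_pool_subsets < 1:
            raise ValueError("n_pool_subsets must be >= 1")
        if self.max_reagent_candidates < 1:
            raise ValueError("max_reagent_candidates must be >= 1")

    def fingerprint(self) -> str:
        text = json.dumps(
            {
                "cap": self.cap_per_template,
                "threshold": self.confidence_threshold,
                "subsets": self.n_pool_subsets,
                "seed": self.seed,
                "reagent_k": self.max_reagent_candidates,
            },
            sort_keys=True,
        )
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class FictiveReaction:
    """A generated SM + R -> P record with its validation outcome."""

    template_id: str
    sm: tuple[Molecule, ...]
    sm_star: tuple[TaggedMolecule, ...]
    reagents: tuple[Molecule, ...]
    product: Molecule
    confidence: float
    accepted: bool
    keys: dict[str, str]

    @property
    def key_sm_p(self) -> str:
        return self.keys["sm_p"]

    @property
    def key_smrp(self) -> str:
        return self.keys["smrp"]

    def to_record(self) -> dict:
        return {
            "template_id": self.template_id,
            "sm": [m.plain for m in self.sm],
            "sm_star": [t.token_line for t in self.sm_star],
            "reagents": [m.plain for m in self.reagents],
            "product": self.product.plain,
            "confidence": round(self.confidence, 6),
            "accepted": self.accepted,
            "keys": self.keys,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "FictiveReaction":
        return cls(
            template_id=rec["template_id"],
            sm=tuple(Molecule.from_smiles(s) for s in rec["sm"]),
            sm_star=tuple(
                TaggedMolecule.from_tagged(s) for s in rec["sm_star"]
            ),
            reagents=tuple(Molecule.from_smiles(s) for s in rec["reagents"]),
            product=Molecule.from_smiles(rec["product"]),
            confidence=rec["confidence"],
            accepted=rec["accepted"],
            keys=dict(rec["keys"]),
        )


def _make_keys(
    sm: Sequence[Molecule],
    reagents: Sequence[Molecule],
    product: Molecule,
) -> dict[str, str]:
    sm_part = ".".join(sorted(m.plain for m in sm))
    r_part = ".".join(sorted(m.plain for m in reagents))
    p = product.plain
    return {
        KeyMode.SM_P.value: f"{sm_part}>{p}",
        KeyMode.SMRP.value: f"{sm_part}>{r_part}>{p}",
    }


@dataclass
class TemplateStats:
    candidates: int = 0
    forward_consistent: int = 0
    accepted: int = 0


@dataclass
class CampaignStats:
    per_template: dict[str, TemplateStats] = field(default_factory=dict)

    @property
    def total_candidates(self) -> int:
        return sum(s.candidates for s in self.per_template.values())

    @property
    def total_forward_consistent(self) -> int:
        return sum(s.forward_consistent for s in self.per_template.values())

    @property
    def total_accepted(self) -> int:
        return sum(s.accepted for s in self.per_template.values())

    def to_rows(self) -> list[dict]:
        return [
            {
                "template_id": tid,
                "candidates": s.candidates,
                "forward_consistent": s.forward_consistent,
                "accepted": s.accepted,
            }
            for tid, s in sorted(self.per_template.items())
        ]


def shard_pool(
    pool: Sequence[Molecule], n: int, seed: int
) -> list[list[Molecule]]:
    """Deterministic balanced partition of the pool into ``n`` subsets."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(pool):
        warnings.warn(
            f"{n} subsets requested for {len(pool)} molecules; "
            f"using {len(pool)} subsets",
            stacklevel=2,
        )
        n = max(1, len(pool))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pool))
    base, extra = divmod(len(pool), n)
    subsets: list[list[Molecule]] = []
    start = 0
    for i in range(n):
        size = base + (1 if i < extra else 0)
        subsets.append([pool[j] for j in perm[start : start + size]])
        start += size
    return subsets


def _gate(
    draft: FictiveReaction,
    validator: ForwardValidator,
    threshold: float,
) -> tuple[FictiveReaction, bool]:
    pred = validator.predict_product(
        draft.sm_star, draft.reagents, template_id=draft.template_id
    )
    consistent = (
        pred.product is not None
        and pred.product.plain == draft.product.plain
    )
    fr = replace(
        draft,
        confidence=pred.confidence,
        accepted=bool(consistent and pred.confidence > threshold),
    )
    return fr, consistent


def validate_candidate(
    draft: FictiveReaction,
    validator: ForwardValidator,
    threshold: float,
) -> FictiveReaction:
    """Run the forward gate on a draft candidate.

    Accepted iff the validator's product (map-stripped canonical) equals
    the target product and its confidence is strictly above the threshold.
    The confidence is recorded either way.
    """
    return _gate(draft, validator, threshold)[0]


def _draft_candidates(
    t: RetroTemplate,
    product: Molecule,
    reagent_predictor: ReagentPredictor,
    config: GenerationConfig,
) -> Iterable[FictiveReaction]:
    changed = ChangedAtomSet(
        reactant_side=t.changed_reactant_maps, product_side=frozenset()
    )
    for sm_set in apply_retro(t, product):
        try:
            predictions = reagent_predictor.predict_reagents(
                sm_set,
                product,
                k=config.max_reagent_candidates,
                template_id=t.template_id,
            )
        except PredictorError as exc:
            logger.warning(
                "reagent prediction failed for template %s: %s",
                t.template_id,
                exc,
            )
            continue
        reagent_choices = [p.reagents for p in predictions] or [()]
        try:
            sm_star = tuple(tag_changed_atoms(list(sm_set), changed))
        except Exception as exc:
            logger.warning(
                "tagging failed for template %s: %s", t.template_id, exc
            )
            continue
        for reagents in reagent_choices:
            yield FictiveReaction(
                template_id=t.template_id,
                sm=tuple(sm_set),
                sm_star=sm_star,
                reagents=tuple(reagents),
                product=Molecule(smiles=product.plain),
                confidence=0.0,
                accepted=False,
                keys=_make_keys(sm_set, reagents, product),
            )


def generate_for_template(
    t: RetroTemplate,
    subsets: Sequence[Sequence[Molecule]],
    reagent_predictor: ReagentPredictor,
    validator: ForwardValidator,
    config: GenerationConfig,
) -> tuple[list[FictiveReaction], TemplateStats]:
    """Scan pool subsets for one template until the cap or exhaustion.

    Subsets are visited in a random order seeded by (campaign seed,
    template id); within a subset, matching products keep pool order.
    Duplicate candidates (same SM + R -> P key) are emitted once and the
    cap counts distinct accepted reactions.
    """
    stats = TemplateStats()
    accepted: list[FictiveReaction] = []
    seen_keys: set[str] = set()
    rng = np.random.default_rng(
        [derive_seed(config.seed, "template-order"), stable_hash(t.template_id)]
    )
    order = rng.permutation(len(subsets))
    for si in order:
        for product in match_products(t, subsets[si]):
            for draft in _draft_candidates(
                t, product, reagent_predictor, config
            ):
                if draft.key_smrp in seen_keys:
                    continue
                seen_keys.add(draft.key_smrp)
                stats.candidates += 1
                try:
                    fr, consistent = _gate(
                        draft, validator, config.confidence_threshold
                    )
                except PredictorError as exc:
                    logger.warning(
                        "validator failed for template %s: %s",
                        t.template_id,
                        exc,
                    )
                    continue
                if consistent:
                    stats.forward_consistent += 1
                if fr.accepted:
                    stats.accepted += 1
                    accepted.append(fr)
                    if stats.accepted >= config.cap_per_template:
                        return accepted, stats
    return accepted, stats


def run_campaign(
    templates: Sequence[RetroTemplate],
    pool: Sequence[Molecule],
    reagent_predictor: ReagentPredictor,
    validator: ForwardValidator,
    config: GenerationConfig,
    checkpoint_dir: str | Path | None = None,
) -> tuple[list[FictiveReaction], CampaignStats]:
    """Run the campaign over all templates; resumable per template.

    With ``checkpoint_dir`` set, each completed template's accepted
    reactions and stats are persisted; a rerun with identical inputs and
    configuration resumes after the last completed template and yields the
    same final dataset. A checkpoint written under a different
    configuration is refused.
    """
    subsets = shard_pool(
        pool, config.n_pool_subsets, derive_seed(config.seed, "shard")
    )
    manifest = None
    ckpt: Path | None = None
    fingerprint = _campaign_fingerprint(config, templates, pool)
    if checkpoint_dir is not None:
        ckpt = Path(checkpoint_dir)
        ckpt.mkdir(parents=True, exist_ok=True)
        manifest_path = ckpt / "manifest.json"
        if manifest_path.exists():
            manifest = json.loads(manifest_path.read_text())
            if (
                manifest.get("version") != CHECKPOINT_VERSION
                or manifest.get("fingerprint") != fingerprint
            ):
                raise CheckpointError(
                    "checkpoint does not match campaign configuration"
                )
        else:
            manifest = {
                "version": CHECKPOINT_VERSION,
                "fingerprint": fingerprint,
                "completed": [],
            }

    dataset: list[FictiveReaction] = []
    stats = CampaignStats()
    for t in sorted(templates, key=lambda t: t.template_id):
        if ckpt is not None and t.template_id in manifest["completed"]:
            reactions, tstats = _load_template_checkpoint(ckpt, t.template_id)
        else:
            reactions, tstats = generate_for_template(
                t, subsets, reagent_predictor, validator, config
            )
            if ckpt is not None:
                _save_template_checkpoint(ckpt, t.template_id, reactions, tstats)
                manifest["completed"].append(t.template_id)
                (ckpt / "manifest.json").write_text(
                    json.dumps(manifest, sort_keys=True)
                )
        dataset.extend(reactions)
        stats.per_template[t.template_id] = tstats
        logger.info(
            "template %s: %d candidates, %d accepted",
            t.template_id,
            tstats.candidates,
            tstats.accepted,
        )
    return dataset, stats


def _campaign_fingerprint(
    config: GenerationConfig,
    templates: Sequence[RetroTemplate],
    pool: Sequence[Molecule],
) -> str:
    h = hashlib.sha256()
    h.update(config.fingerprint().encode())
    for t in sorted(t.template_id for t in templates):
        h.update(t.encode())
    h.update(str(len(pool)).encode())
    for m in pool[:100]:
        h.update(m.smiles.encode())
    return h.hexdigest()[:16]


def _ckpt_file(ckpt: Path, template_id: str) -> Path:
    return ckpt / f"{stable_hash(template_id):010d}.json"


def _save_template_checkpoint(
    ckpt: Path,
    template_id: str,
    reactions: list[FictiveReaction],
    tstats: TemplateStats,
) -> None:
    payload = {
        "template_id": template_id,
        "stats": {
            "candidates": tstats.candidates,
            "forward_consistent": tstats.forward_consistent,
            "accepted": tstats.accepted,
        },
        "reactions": [r.to_record() for r in reactions],
    }
    _ckpt_file(ckpt, template_id).write_text(
        json.dumps(payload, sort_keys=True)
    )


def _load_template_checkpoint(
    ckpt: Path, template_id: str
) -> tuple[list[FictiveReaction], TemplateStats]:
    payload = json.loads(_ckpt_file(ckpt, template_id).read_text())
    stats = TemplateStats(**payload["stats"])
    reactions = [FictiveReaction.from_record(r) for r in payload["reactions"]]
    return reactions, stats


def write_dataset(dataset: Iterable[FictiveReaction], fh) -> int:
    n = 0
    for fr in dataset:
        fh.write(json.dumps(fr.to_record(), sort_keys=True) + "\n")
        n += 1
    return n


def read_dataset(fh) -> list[FictiveReaction]:
    return [
        FictiveReaction.from_record(json.loads(line))
        for line in fh
        if line.strip()
    ]
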