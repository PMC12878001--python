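"""Pluggable prediction contracts and a deterministic template oracle.

Two roles are needed by the generation campaign: a *reagent predictor*
(ranked reagent sets for an SM -> P pair) and a *forward validator* (a
single product plus a confidence score in [0, 1] from tagged SM* and
reagents). Real deployments plug in sequence models through the
line-oriented adapter at the bottom; tests and the bundled toy pipeline use
:class:`TemplateOracle`, a test double that validates against the
generating template only and emits a configured confidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence, runtime_checkable

import numpy as np

from ._seeding import stable_hash
from .errors import ContractError
from .reaction_model import Molecule
from .tagging import TaggedMolecule, untag
from .template_engine import RetroTemplate, apply_forward

__all__ = [
    "ReagentPrediction",
    "ForwardPrediction",
    "OracleConfig",
    "ReagentPredictor",
    "ForwardValidator",
    "TemplateOracle",
    "confidence_from_token_logprobs",
    "format_request",
    "parse_response",
]


@dataclass(frozen=True)
class ReagentPrediction:
    reagents: tuple[Molecule, ...]
    score: float

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ContractError(f"score {self.score} outside [0, 1]")


@dataclass(frozen=True)
class ForwardPrediction:
    product: Molecule | None
    confidence: float

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ContractError(f"confidence {self.confidence} outside [0, 1]")
        if self.product is None and self.confidence != 0.0:
            raise ContractError("missing product requires confidence 0")


@runtime_checkable
class ReagentPredictor(Protocol):
    def predict_reagents(
        self,
        sm: Sequence[Molecule],
        product: Molecule,
        k: int = 1,
        *,
        template_id: str | None = None,
    ) -> list[ReagentPrediction]: ...


@runtime_checkable
class ForwardValidator(Protocol):
    def predict_product(
        self,
        sm_star: Sequence[TaggedMolecule],
        reagents: Sequence[Molecule],
        *,
        template_id: str | None = None,
    ) -> ForwardPrediction: ...


@dataclass(frozen=True)
class OracleConfig:
    """Configuration of the deterministic template oracle.

    ``base_confidence`` is the score reported for forward-consistent
    candidates, optionally jittered by Gaussian noise of sd ``noise_sd``
    (clipped to [0, 1]); the jitter is a deterministic function of
    (seed, input), so reruns and reorderings reproduce it exactly.
    ``reagent_table`` maps template ids to ranked reagent SMILES lists.
    """

    base_confidence: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0
    reagent_table: Mapping[str, Sequence[Sequence[str]]] = field(
        default_factory=dict
    )

    def __post_init__(self):
        if not 0.0 <= self.base_confidence <= 1.0:
            raise ContractError("base_confidence outside [0, 1]")
        if self.noise_sd < 0:
            raise ContractError("noise_sd must be >= 0")


class TemplateOracle:
    """Reagent predictor + forward validator backed by the templates.

    The oracle is a test double, not a chemistry model: it looks reagents
    up in a fixed per-template table and validates SM* by untagging and
    re-applying the *generating* template in the forward direction.
    """

    def __init__(
        self,
        config: OracleConfig,
        templates: Mapping[str, RetroTemplate] | Sequence[RetroTemplate],
    ):
        if not isinstance(templates, Mapping):
            templates = {t.template_id: t for t in templates}
        self.config = config
        self.templates = dict(templates)

    # -- ReagentPredictor ------------------------------------------------
    def predict_reagents(
        self,
        sm: Sequence[Molecule],
        product: Molecule,
        k: int = 1,
        *,
        template_id: str | None = None,
    ) -> list[ReagentPrediction]:
        if k < 1:
            raise ContractError("k must be >= 1")
        entries = self.config.reagent_table.get(template_id or "", [])
        out = []
        for rank, reagent_set in enumerate(entries[:k]):
            out.append(
                ReagentPrediction(
                    reagents=tuple(
                        Molecule.from_smiles(s) for s in reagent_set
                    ),
                    score=1.0 / (rank + 1),
                )
            )
        return out

    # -- ForwardValidator ------------------------------------------------
    def predict_product(
        self,
        sm_star: Sequence[TaggedMolecule],
        reagents: Sequence[Molecule] = (),
        *,
        template_id: str | None = None,
    ) -> ForwardPrediction:
        template = self.templates.get(template_id or "")
        if template is None:
            return ForwardPrediction(product=None, confidence=0.0)
        sm = [untag(t) for t in sm_star]
        product = apply_forward(template, sm)
        if product is None:
            return ForwardPrediction(product=None, confidence=0.0)
        return ForwardPrediction(
            product=product,
            confidence=self._confidence(sm_star, reagents, template_id or ""),
        )

    def _confidence(
        self,
        sm_star: Sequence[TaggedMolecule],
        reagents: Sequence[Molecule],
        template_id: str,
    ) -> float:
        c = self.config.base_confidence
        if self.config.noise_sd > 0:
            key = "|".join(
                [template_id]
                + [t.tagged for t in sm_star]
                + [m.plain for m in reagents]
            )
            rng = np.random.default_rng(
                [self.config.seed, stable_hash(key)]
            )
            c += rng.normal(0.0, self.config.noise_sd)
        return float(min(1.0, max(0.0, c)))


def confidence_from_token_logprobs(logprobs: Sequence[float]) -> float:
    """Confidence of a sequence model output: exp of summed token log-probs.

    This is the product of top-beam token probabilities, clipped to [0, 1].
    """
    if len(logprobs) == 0:
        raise ContractError("empty log-probability list")
    if any(math.isnan(lp) or lp > 0 for lp in logprobs):
        raise ContractError("log-probabilities must be <= 0")
    return float(min(1.0, max(0.0, math.exp(sum(logprobs)))))


# --------------------------------------------------------------------------
# external sequence-model adapter (line-oriented text protocol)

SEP = "[SEP]"


def format_request(
    sm_star: Sequence[TaggedMolecule], reagents: Sequence[Molecule]
) -> str:
    """One input line: tagged SM tokens, ``[SEP]``, reagent tokens."""
    from .tagging import tokenize

    sm_tokens: list[str] = []
    for i, t in enumerate(sm_star):
        if i:
            sm_tokens.append(".")
        sm_tokens.extend(t.tokens)
    reagent_tokens: list[str] = []
    for i, m in enumerate(reagents):
        if i:
            reagent_tokens.append(".")
        reagent_tokens.extend(tokenize(m.plain))
    return " ".join(sm_tokens + [SEP] + reagent_tokens)


def parse_response(line: str) -> ForwardPrediction:
    """One output line: ``product-SMILES<TAB>confidence``."""
    parts = line.rstrip("\n").split("\t")
    if len(parts) != 2:
        raise ContractError(f"bad response line: {line!r}")
    smiles, conf_text = parts
    try:
        confidence = float(conf_text)
    except ValueError:
        raise ContractError(f"bad confidence: {conf_text!r}") from None
    confidence = min(1.0, max(0.0, confidence))
    if not smiles or smiles == "<invalid>":
        return ForwardPrediction(product=None, confidence=0.0)
    try:
        product = Molecule.from_smiles(smiles)
    except Exception:
        return ForwardPrediction(product=None, confidence=0.0)
    return ForwardPrediction(product=product, confidence=confidence)
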