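"""Round-trip accuracy (RTA) and template-averaged RTA (TA-RTA).

A single-step retrosynthesis proposal is counted as a round-trip success
when the forward-predicted product of one of its top-N precursor sets
equals the target product (map-stripped canonical comparison). RTA
averages successes over reactions; TA-RTA first averages within each
template and then takes the unweighted mean over templates, making it
insensitive to how many test records a template has.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from statistics import pstdev
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Prediction",
    "EvalRecord",
    "MetricReport",
    "record_success",
    "round_trip_accuracy",
    "template_averaged_rta",
    "stratify_by_tag_count",
    "compute_metric_report",
    "read_records",
    "write_records",
]


@dataclass(frozen=True)
class Prediction:
    """One ranked precursor proposal with its forward-validation result."""

    precursors: tuple[str, ...]
    product_key: str | None
    confidence: float = 0.0


@dataclass(frozen=True)
class EvalRecord:
    """One test product with its ranked predictions."""

    record_id: str
    template_id: str
    n_tags: int
    target_product_key: str
    predictions: tuple[Prediction, ...] = ()


def record_success(
    rec: EvalRecord, top_n: int, *, require_confidence: float | None = None
) -> bool:
    """True iff any of the first ``top_n`` predictions regenerates the target."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    for pred in rec.predictions[:top_n]:
        if pred.product_key is None:
            continue
        if pred.product_key != rec.target_product_key:
            continue
        if require_confidence is not None and not (
            pred.confidence > require_confidence
        ):
            continue
        return True
    return False


def round_trip_accuracy(
    records: Sequence[EvalRecord],
    top_n: int,
    *,
    require_confidence: float | None = None,
) -> float:
    """Mean round-trip success over all records."""
    if not records:
        raise ValueError("no records")
    wins = sum(
        record_success(r, top_n, require_confidence=require_confidence)
        for r in records
    )
    return wins / len(records)


def template_averaged_rta(
    records: Sequence[EvalRecord],
    top_n: int,
    *,
    require_confidence: float | None = None,
) -> float:
    """Unweighted mean over templates of the per-template success rate."""
    if not records:
        raise ValueError("no records")
    means = _per_template_means(records, top_n, require_confidence)
    return sum(means.values()) / len(means)


def _per_template_means(
    records: Sequence[EvalRecord],
    top_n: int,
    require_confidence: float | None,
) -> dict[str, float]:
    grouped: dict[str, list[bool]] = defaultdict(list)
    for r in records:
        grouped[r.template_id].append(
            record_success(r, top_n, require_confidence=require_confidence)
        )
    return {tid: sum(v) / len(v) for tid, v in grouped.items()}


def stratify_by_tag_count(
    records: Sequence[EvalRecord],
    top_n_list: Sequence[int] = (1,),
    *,
    require_confidence: float | None = None,
) -> pd.DataFrame:
    """RTA / TA-RTA per tag-count bucket and top-N.

    Columns: ``n_tags, top_n, rta, ta_rta, n, n_templates, sd`` where
    ``sd`` is the population standard deviation of the per-template means
    (0 for a single-template bucket). Empty buckets are simply absent.
    """
    buckets: dict[int, list[EvalRecord]] = defaultdict(list)
    for r in records:
        buckets[r.n_tags].append(r)
    rows = []
    for n_tags in sorted(buckets):
        bucket = buckets[n_tags]
        for top_n in top_n_list:
            means = _per_template_means(bucket, top_n, require_confidence)
            vals = list(means.values())
            rows.append(
                {
                    "n_tags": n_tags,
                    "top_n": top_n,
                    "rta": round_trip_accuracy(
                        bucket, top_n, require_confidence=require_confidence
                    ),
                    "ta_rta": sum(vals) / len(vals),
                    "n": len(bucket),
                    "n_templates": len(vals),
                    "sd": pstdev(vals) if len(vals) > 1 else 0.0,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["n_tags", "top_n", "rta", "ta_rta", "n", "n_templates", "sd"],
    )


@dataclass(frozen=True)
class MetricReport:
    """RTA / TA-RTA per top-N plus the per-tag-count table."""

    rta: dict[int, float]
    ta_rta: dict[int, float]
    by_tag_count: pd.DataFrame = field(repr=False)

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": "RTA", **{f"top_{n}": v for n, v in self.rta.items()}},
            {
                "metric": "TA-RTA",
                **{f"top_{n}": v for n, v in self.ta_rta.items()},
            },
        ]
        return pd.DataFrame(rows)


def compute_metric_report(
    records: Sequence[EvalRecord],
    top_n_list: Sequence[int] = (1, 2, 3),
    *,
    require_confidence: float | None = None,
) -> MetricReport:
    rta = {
        n: round_trip_accuracy(records, n, require_confidence=require_confidence)
        for n in top_n_list
    }
    ta = {
        n: template_averaged_rta(
            records, n, require_confidence=require_confidence
        )
        for n in top_n_list
    }
    return MetricReport(
        rta=rta,
        ta_rta=ta,
        by_tag_count=stratify_by_tag_count(
            records, top_n_list, require_confidence=require_confidence
        ),
    )


def write_records(records: Iterable[EvalRecord], fh) -> int:
    n = 0
    for r in records:
        fh.write(
            json.dumps(
                {
                    "record_id": r.record_id,
                    "template_id": r.template_id,
                    "n_tags": r.n_tags,
                    "target_product_key": r.target_product_key,
                    "predictions": [
                        {
                            "precursors": list(p.precursors),
                            "product_key": p.product_key,
                            "confidence": p.confidence,
                        }
                        for p in r.predictions
                    ],
                },
                sort_keys=True,
            )
            + "\n"
        )
        n += 1
    return n


def read_records(fh) -> list[EvalRecord]:
    out = []
    for line in fh:
        if not line.strip():
            continue
        rec = json.loads(line)
        out.append(
            EvalRecord(
                record_id=rec["record_id"],
                template_id=rec["template_id"],
                n_tags=rec["n_tags"],
                target_product_key=rec["target_product_key"],
                predictions=tuple(
                    Prediction(
                        precursors=tuple(p["precursors"]),
                        product_key=p["product_key"],
                        confidence=p["confidence"],
                    )
                    for p in rec["predictions"]
                ),
            )
        )
    return out
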