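"""Weighted evaluation of a candidate system against prioritized needs.

Each need carries a fulfillment score f in [0, 1]; the canonical coarse
scale is 0 (not addressed), 0.5 (partially addressed), 1 (fulfilled).
Weighting fulfillment by the needs' global weights gives a single
[0, 1] compliance score, and the residuals (1 - f) x GW rank the needs
where improvement would buy the most importance — the gap analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .hierarchy import Hierarchy

__all__ = [
    "FULFILLMENT_LABELS",
    "FulfillmentProfile",
    "EvaluationReport",
    "weighted_score",
    "gap_analysis",
]

#: Canonical label -> score mapping for coarse qualitative profiles.
FULFILLMENT_LABELS = {"not_addressed": 0.0, "partial": 0.5, "fulfilled": 1.0}


@dataclass
class FulfillmentProfile:
    """Per-need fulfillment scores for one candidate system."""

    scores: dict[str, float]
    comments: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for need, f in self.scores.items():
            f = float(f)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fulfillment for {need!r} outside [0, 1]: {f}")
            self.scores[need] = f

    @classmethod
    def from_csv(
        cls, path: str | Path, labels: dict[str, float] | None = None
    ) -> "FulfillmentProfile":
        """Read ``need_id,fulfillment[,comment]`` rows.

        ``fulfillment`` may be a number in [0, 1] or one of the canonical
        labels (override the mapping via ``labels``).
        """
        labels = FULFILLMENT_LABELS if labels is None else labels
        df = pd.read_csv(path, dtype=str).fillna("")
        scores, comments = {}, {}
        for lineno, row in enumerate(df.itertuples(index=False), start=2):
            raw = str(row.fulfillment).strip()
            if raw in labels:
                f = labels[raw]
            else:
                try:
                    f = float(raw)
                except ValueError:
                    raise ValueError(
                        f"{path}, line {lineno}: fulfillment {raw!r} is neither "
                        f"a number nor one of {sorted(labels)}"
                    ) from None
            scores[str(row.need_id)] = f
            if getattr(row, "comment", ""):
                comments[str(row.need_id)] = str(row.comment)
        return cls(scores=scores, comments=comments)

    def validate_against(self, h: Hierarchy) -> None:
        leaf_ids = set(h.leaf_ids())
        missing = sorted(leaf_ids - set(self.scores))
        if missing:
            raise ValueError(f"profile missing fulfillment for need(s) {missing}")
        extra = sorted(set(self.scores) - leaf_ids)
        if extra:
            raise ValueError(f"profile scores unknown need(s) {extra}")


@dataclass
class EvaluationReport:
    """Weighted compliance of a system with the prioritized needs.

    ``score`` is sum(f_i x GW_i); ``table`` has one row per need with its
    contribution f x GW and residual (1 - f) x GW, sorted by descending
    residual (ties by GW, then document order).  Score plus total residual
    is 1 by construction whenever GW is normalized.
    """

    score: float
    table: pd.DataFrame

    @property
    def total_residual(self) -> float:
        return float(self.table["residual"].sum())


def weighted_score(
    profile: FulfillmentProfile,
    gw: pd.Series | dict,
    h: Hierarchy | None = None,
) -> EvaluationReport:
    """Score a fulfillment profile against normalized global weights."""
    gw = pd.Series(gw, dtype=float)
    if h is not None:
        profile.validate_against(h)
        gw = gw.reindex(h.leaf_ids())
    missing = sorted(set(gw.index) - set(profile.scores))
    if missing:
        raise ValueError(f"profile missing fulfillment for need(s) {missing}")
    rows = []
    for order, need in enumerate(gw.index):
        f = profile.scores[need]
        rows.append(
            {
                "need": need,
                "gw": float(gw[need]),
                "fulfillment": f,
                "contribution": f * float(gw[need]),
                "residual": (1.0 - f) * float(gw[need]),
                "_order": order,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["residual", "gw", "_order"], ascending=[False, False, True]
    ).drop(columns="_order").reset_index(drop=True)
    return EvaluationReport(score=float(df["contribution"].sum()), table=df)


def gap_analysis(report: EvaluationReport, top_k: int | None = None) -> pd.DataFrame:
    """The needs whose unmet importance (1 - f) x GW is largest.

    Returns the report table restricted to needs with a positive residual,
    optionally truncated to the ``top_k`` leading improvement areas.
    """
    gaps = report.table[report.table["residual"] > 0].reset_index(drop=True)
    if top_k is not None:
        if top_k < 0:
            raise ValueError("top_k must be nonnegative")
        gaps = gaps.head(top_k)
    return gaps
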