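"""Model/Results facade over the AHP pipeline.

:class:`AHPStudy` bundles a hierarchy with a panel's pairwise judgments;
``fit()`` derives every weight (per-respondent and group LW/CW/GW) and
returns an :class:`AHPResults` carrying the estimates, the consistency
diagnostics, and methods for consensus, subgroup comparison, ranking,
system evaluation and a text summary.

>>> from ahp_needs import AHPStudy, simulate
>>> spec = simulate.paper_shaped_panel(seed=1)
>>> panel, judgments = simulate.simulate_judgments(spec)
>>> res = AHPStudy(spec.hierarchy, judgments, panel).fit()
>>> res.global_weights.sum()
1.0...
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import compare as _compare
from . import consensus as _consensus
from . import evaluate as _evaluate
from . import synthesis as _synthesis
from .hierarchy import Hierarchy, load_hierarchy
from .judgments import Judgment, Respondent, read_judgments
from .prioritize import CR_THRESHOLD

__all__ = ["AHPStudy", "AHPResults"]


class AHPStudy:
    """An AHP prioritization study: one hierarchy, one judgment panel.

    Parameters
    ----------
    hierarchy : Hierarchy
        The validated decision tree (goal -> categories -> needs).
    judgments : list of Judgment
        One complete questionnaire per respondent, in long form.
    panel : list of Respondent, optional
        Respondent metadata (group membership); inferred from the
        judgments with group ``"other"`` when omitted.
    """

    def __init__(
        self,
        hierarchy: Hierarchy,
        judgments: list[Judgment],
        panel: list[Respondent] | None = None,
    ):
        self.hierarchy = hierarchy
        self.judgments = judgments
        self.panel = panel

    @classmethod
    def from_files(
        cls,
        hierarchy_path: str | Path,
        judgments_path: str | Path,
        panel_path: str | Path | None = None,
    ) -> "AHPStudy":
        h = load_hierarchy(hierarchy_path)
        panel, judgments = read_judgments(judgments_path, h, panel_path=panel_path)
        return cls(h, judgments, panel)

    def fit(
        self,
        method: str = "eigenvector",
        aggregation: str = "aij",
        cr_threshold: float = CR_THRESHOLD,
        on_violation: str = "warn",
    ) -> "AHPResults":
        """Derive all weights; see :func:`ahp_needs.synthesis.fit_panel`."""
        panel_result = _synthesis.fit_panel(
            self.hierarchy,
            self.judgments,
            self.panel,
            method=method,
            aggregation=aggregation,
            cr_threshold=cr_threshold,
            on_violation=on_violation,
        )
        return AHPResults(self, panel_result)


class AHPResults:
    """Fitted panel weights plus diagnostics and reporting methods."""

    def __init__(self, model: AHPStudy, panel: _synthesis.PanelResult):
        self.model = model
        self.panel = panel

    # -- estimates --------------------------------------------------------

    @property
    def hierarchy(self) -> Hierarchy:
        return self.panel.hierarchy

    @property
    def global_weights(self) -> pd.Series:
        """Consolidated group GW per need (sums to 1)."""
        return self.panel.group_gw

    @property
    def category_weights(self) -> pd.Series:
        """Consolidated group CW per category (sums to 1)."""
        return self.panel.group_cw

    @property
    def local_weights(self) -> dict[str, pd.Series]:
        """Consolidated group LW per internal node."""
        return self.panel.group_local

    @property
    def consistency(self) -> pd.DataFrame:
        """Per-respondent, per-node lambda_max / CI / CR diagnostics."""
        return self.panel.consistency

    def subgroup_medians(self, group: str) -> dict:
        return _synthesis.subgroup_median_weights(self.panel, group)

    def ranking(self) -> pd.DataFrame:
        """Needs ranked by descending group GW."""
        return _synthesis.rank_needs(self.global_weights, self.hierarchy)

    # -- analyses ---------------------------------------------------------

    def consensus(self, aggregation: str = "geometric") -> _consensus.ConsensusReport:
        """Entropy-based group consensus per category and overall."""
        return _consensus.consensus_report(self.panel, aggregation=aggregation)

    def compare_groups(
        self,
        group_a: str = "technical",
        group_b: str = "clinical",
        equal_var: bool = False,
    ) -> _compare.ComparisonResult:
        return _compare.compare_groups(
            self.panel, group_a, group_b, equal_var=equal_var
        )

    def evaluate(
        self, profile: _evaluate.FulfillmentProfile
    ) -> _evaluate.EvaluationReport:
        """Weighted-fulfillment score of a candidate system under these GW."""
        return _evaluate.weighted_score(profile, self.global_weights, self.hierarchy)

    def boxplot_stats(self, group: str | None = None) -> pd.DataFrame:
        """Five-number summaries of the per-respondent GW of each need."""
        table = self.panel.gw_table(group)
        rows = []
        for need, values in table.iterrows():
            bs = _compare.boxplot_stats(values.to_numpy())
            rows.append(
                {
                    "need": need,
                    "median": bs.median,
                    "q1": bs.q1,
                    "q3": bs.q3,
                    "whisker_low": bs.whisker_low,
                    "whisker_high": bs.whisker_high,
                    "n_outliers": len(bs.outliers),
                }
            )
        return pd.DataFrame(rows)

    # -- reporting --------------------------------------------------------

    def needs_table(self) -> pd.DataFrame:
        """One row per need: group GW (LW), subgroup medians where present."""
        h = self.hierarchy
        groups = [g for g in self.panel.groups() if g != "other"]
        med = {g: self.subgroup_medians(g) for g in groups}
        rows = []
        for leaf in h.leaves():
            parent = h.parent(leaf.id)
            row = {
                "need": leaf.id,
                "label": leaf.label,
                "category": parent,
                "group_gw": float(self.global_weights[leaf.id]),
                "group_lw": float(self.local_weights[parent][leaf.id]),
            }
            for g in groups:
                row[f"median_{g}_gw"] = float(med[g]["gw"][leaf.id])
                row[f"median_{g}_lw"] = float(med[g]["leaf_lw"][leaf.id])
            rows.append(row)
        return pd.DataFrame(rows)

    def categories_table(self) -> pd.DataFrame:
        h = self.hierarchy
        groups = [g for g in self.panel.groups() if g != "other"]
        med = {g: self.subgroup_medians(g) for g in groups}
        rows = []
        for cat in h.categories():
            row = {
                "category": cat.id,
                "label": cat.label,
                "cw": float(self.category_weights[cat.id]),
            }
            for g in groups:
                row[f"median_{g}_cw"] = float(med[g]["cw"][cat.id])
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable study summary (weights to 3 decimals)."""
        h = self.hierarchy
        lines = [
            f"AHP study: {h.root.label}",
            f"  respondents: {len(self.panel.respondents)} "
            + str({g: len(c) for g, c in self.panel.groups().items()}),
            f"  method: {self.panel.method}, aggregation: "
            f"{self.panel.aggregation.upper()}",
        ]
        n_bad = int((~self.consistency["acceptable"]).sum())
        lines.append(
            f"  consistency: {n_bad} of {len(self.consistency)} matrices "
            f"above the CR screen"
            + (f" (excluded: {self.panel.excluded})" if self.panel.excluded else "")
        )
        lines.append("")
        lines.append("  Category weights (CW):")
        for cat in h.categories():
            lines.append(
                f"    {self.category_weights[cat.id]:.3f}  {cat.label}"
            )
        lines.append("")
        lines.append("  Needs by global weight (GW, LW within category):")
        ranking = self.ranking()
        for _, row in ranking.iterrows():
            leaf = row["need"]
            parent = h.parent(leaf)
            lw = float(self.local_weights[parent][leaf])
            lines.append(
                f"    {int(row['rank']):2d}. {row['weight']:.3f} ({lw:.3f})  "
                f"{h.node(leaf).label}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<AHPResults: {len(self.panel.respondents)} respondents, "
            f"{len(self.hierarchy.leaves())} needs>"
        )
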