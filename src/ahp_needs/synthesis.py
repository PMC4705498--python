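"""Panel-level synthesis: aggregation, weight propagation, and ranking.

Two aggregation conventions coexist:

* **AIJ** (aggregation of individual judgments): the respondents' matrices
  at each node are combined entry-wise by geometric mean — the only
  aggregation that preserves reciprocity — and one priority vector is
  derived from the consolidated matrix.  This produces the panel's group
  local weights (LW), category weights (CW) and global weights (GW).
* **AIP** (aggregation of individual priorities): per-respondent priority
  vectors are combined element-wise, here by the median, to summarize a
  subgroup (e.g. clinical vs technical experts).  Medians of normalized
  vectors need not sum to one and are deliberately *not* renormalized,
  so subgroup columns remain comparable to per-respondent weights.

Global weights multiply local weights along the root-to-leaf path
(two-level trees: GW = CW x LW), so the leaf GWs under a category sum
exactly to that category's CW.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .hierarchy import Hierarchy, comparison_sets
from .judgments import (
    Judgment,
    JudgmentError,
    JudgmentMatrix,
    Respondent,
    assemble_all_matrices,
)
from .prioritize import CR_THRESHOLD, PriorityResult, derive_priorities

__all__ = [
    "PanelResult",
    "consolidate_judgments",
    "propagate_global_weights",
    "rank_needs",
    "subgroup_median_weights",
    "fit_panel",
]


def consolidate_judgments(matrices: list[JudgmentMatrix]) -> JudgmentMatrix:
    """Entry-wise geometric mean of one-per-respondent matrices (AIJ).

    All matrices must address the same node with the same item order.  The
    result is reciprocal and unit-diagonal by construction; it is
    respondent-order invariant and idempotent on identical inputs.
    """
    if not matrices:
        raise JudgmentError("need at least one matrix to consolidate")
    first = matrices[0]
    for m in matrices[1:]:
        if m.node != first.node or m.items != first.items:
            raise JudgmentError(
                f"cannot consolidate mismatched matrices "
                f"({m.node!r}/{m.items} vs {first.node!r}/{first.items})"
            )
    n = first.order
    entries: dict[tuple[int, int], Fraction] = {}
    for i in range(n):
        for j in range(i + 1, n):
            vals = [m.entry(i, j) for m in matrices]
            if all(v == vals[0] for v in vals):      # exact when unanimous
                g = vals[0]
            else:
                logs = np.log([float(v) for v in vals])
                g = Fraction(float(np.exp(logs.mean())))
            entries[(i, j)] = g
    return JudgmentMatrix(first.node, first.items, entries)


def propagate_global_weights(
    h: Hierarchy, local: dict[str, pd.Series | dict]
) -> pd.Series:
    """Leaf global weights from per-node local weights.

    ``local`` maps each internal node id to its children's normalized
    local weights.  GW(leaf) is the product of local weights along the
    root-to-leaf path; the result sums to 1 (within rounding) whenever
    every local vector does.
    """
    for node in h.internal_nodes():
        if node.id not in local:
            raise KeyError(f"missing local weight vector for node {node.id!r}")
    gw = {}
    for leaf in h.leaves():
        path = h.path_to(leaf.id)
        w = 1.0
        for parent, child in zip(path[:-1], path[1:]):
            vec = local[parent]
            w *= float(vec[child])
        gw[leaf.id] = w
    return pd.Series(gw, name="gw")


def rank_needs(gw: pd.Series | dict, h: Hierarchy | None = None) -> pd.DataFrame:
    """Rank leaves by descending global weight.

    Ties share the minimum rank; display order among ties follows the
    hierarchy's document order (the input order when no hierarchy is
    given), so the ranking is stable and reproducible.
    """
    gw = pd.Series(gw)
    if h is not None:
        gw = gw.reindex(h.leaf_ids())
    doc_order = {k: i for i, k in enumerate(gw.index)}
    order = sorted(gw.index, key=lambda k: (-gw[k], doc_order[k]))
    ranks = gw.rank(method="min", ascending=False).astype(int)
    return pd.DataFrame(
        {
            "need": order,
            "weight": [gw[k] for k in order],
            "rank": [ranks[k] for k in order],
        }
    )


@dataclass
class PanelResult:
    """Every weight the pipeline derives for one panel.

    ``local[code][node]`` are the respondent's local weights at ``node``;
    ``cw`` and ``gw`` index category and leaf weights by respondent code.
    ``group_*`` holds the consolidated (AIJ) panel weights; ``priorities``
    retains the full per-respondent :class:`PriorityResult` diagnostics,
    flattened into the ``consistency`` table.
    """

    hierarchy: Hierarchy
    respondents: list[Respondent]
    local: dict[str, dict[str, pd.Series]]
    cw: dict[str, pd.Series]
    gw: dict[str, pd.Series]
    group_local: dict[str, pd.Series]
    group_cw: pd.Series
    group_gw: pd.Series
    consistency: pd.DataFrame
    method: str
    aggregation: str
    priorities: dict[str, dict[str, PriorityResult]] = field(repr=False, default_factory=dict)
    excluded: list[str] = field(default_factory=list)

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for r in self.respondents:
            out.setdefault(r.group, []).append(r.code)
        return out

    def codes(self, group: str | None = None) -> list[str]:
        if group is None:
            return [r.code for r in self.respondents]
        return [r.code for r in self.respondents if r.group == group]

    def gw_table(self, group: str | None = None) -> pd.DataFrame:
        """Per-respondent GW matrix (leaves x respondents)."""
        codes = self.codes(group)
        return pd.DataFrame({c: self.gw[c] for c in codes})

    def cw_table(self, group: str | None = None) -> pd.DataFrame:
        codes = self.codes(group)
        return pd.DataFrame({c: self.cw[c] for c in codes})

    def lw_table(self, node: str, group: str | None = None) -> pd.DataFrame:
        codes = self.codes(group)
        return pd.DataFrame({c: self.local[c][node] for c in codes})

    def leaf_lw_table(self, group: str | None = None) -> pd.DataFrame:
        """Leaves x respondents matrix of each leaf's local weight."""
        rows = {}
        for leaf in self.hierarchy.leaves():
            parent = self.hierarchy.parent(leaf.id)
            rows[leaf.id] = {
                c: float(self.local[c][parent][leaf.id]) for c in self.codes(group)
            }
        return pd.DataFrame(rows).T


def _fill_trivial_locals(h: Hierarchy, local: dict[str, pd.Series]) -> None:
    # a single-child internal node (only the root can be one) poses no
    # comparison; its child takes local weight 1
    for node in h.internal_nodes():
        if node.id not in local:
            local[node.id] = pd.Series({node.children[0].id: 1.0})


def _respondent_weights(
    h: Hierarchy, node_results: dict[str, PriorityResult]
) -> tuple[dict[str, pd.Series], pd.Series, pd.Series]:
    local = {
        node_id: pd.Series(res.as_dict()) for node_id, res in node_results.items()
    }
    _fill_trivial_locals(h, local)
    cw = local[h.root.id].rename("cw")
    gw = propagate_global_weights(h, local)
    return local, cw, gw


def fit_panel(
    h: Hierarchy,
    judgments: list[Judgment],
    panel: list[Respondent] | None = None,
    method: str = "eigenvector",
    aggregation: str = "aij",
    cr_threshold: float = CR_THRESHOLD,
    on_violation: str = "warn",
) -> PanelResult:
    """Derive all individual and group weights for a panel.

    ``on_violation`` controls how respondents whose matrices exceed the CR
    threshold enter the group synthesis: ``"warn"`` keeps them (with a
    warning), ``"exclude"`` drops them from the consolidated group and
    subgroup summaries while retaining their individual results.
    ``aggregation`` selects the group convention: ``"aij"`` (geometric
    mean of judgments, then one derivation) or ``"aip"`` (arithmetic mean
    of individual priority vectors).
    """
    if on_violation not in ("warn", "exclude"):
        raise ValueError("on_violation must be 'warn' or 'exclude'")
    if aggregation not in ("aij", "aip"):
        raise ValueError("aggregation must be 'aij' or 'aip'")
    matrices = assemble_all_matrices(judgments, h)
    if panel is None:
        panel = [Respondent(code=c, group="other") for c in matrices]
    missing = [r.code for r in panel if r.code not in matrices]
    if missing:
        raise JudgmentError(f"no judgments for respondent(s) {missing}")

    local, cw, gw, priorities = {}, {}, {}, {}
    cons_rows = []
    violators = set()
    for r in panel:
        node_results = {
            node_id: derive_priorities(m, method=method, cr_threshold=cr_threshold)
            for node_id, m in matrices[r.code].items()
        }
        priorities[r.code] = node_results
        for node_id, res in node_results.items():
            cons_rows.append(
                {
                    "respondent": r.code,
                    "node": node_id,
                    "lambda_max": res.lambda_max,
                    "ci": res.ci,
                    "cr": res.cr,
                    "acceptable": res.acceptable,
                }
            )
            if not res.acceptable:
                violators.add(r.code)
        local[r.code], cw[r.code], gw[r.code] = _respondent_weights(h, node_results)

    if violators:
        msg = (
            f"respondent(s) {sorted(violators)} have CR > {cr_threshold:g} "
            f"on at least one matrix"
        )
        if on_violation == "warn":
            warnings.warn(msg + "; kept in group synthesis", stacklevel=2)
    excluded = sorted(violators) if on_violation == "exclude" else []
    pool = [r.code for r in panel if r.code not in excluded]
    if not pool:
        raise JudgmentError("all respondents excluded by the CR screen")

    group_local: dict[str, pd.Series] = {}
    for node_id, _ in comparison_sets(h):
        if aggregation == "aij":
            consolidated = consolidate_judgments(
                [matrices[c][node_id] for c in pool]
            )
            res = derive_priorities(consolidated, method=method,
                                    cr_threshold=cr_threshold)
            group_local[node_id] = pd.Series(res.as_dict())
        else:  # aip: mean of individual priority vectors, renormalized
            stacked = pd.DataFrame({c: local[c][node_id] for c in pool})
            mean = stacked.mean(axis=1)
            group_local[node_id] = mean / mean.sum()
    _fill_trivial_locals(h, group_local)
    group_cw = group_local[h.root.id].rename("cw")
    group_gw = propagate_global_weights(h, group_local)

    return PanelResult(
        hierarchy=h,
        respondents=list(panel),
        local=local,
        cw=cw,
        gw=gw,
        group_local=group_local,
        group_cw=group_cw,
        group_gw=group_gw,
        consistency=pd.DataFrame(cons_rows),
        method=method,
        aggregation=aggregation,
        priorities=priorities,
        excluded=excluded,
    )


def subgroup_median_weights(panel: PanelResult, group: str) -> dict:
    """Element-wise median LW/CW/GW over one respondent group (AIP-median).

    Medians are *not* renormalized: the median of normalized vectors need
    not sum to one, and renormalizing would break comparability with the
    per-respondent weights.  Even group sizes use the midpoint of the two
    central order statistics.
    """
    codes = [c for c in panel.codes(group) if c not in panel.excluded]
    if not codes:
        raise JudgmentError(f"no respondents in group {group!r}")
    lw = {
        node_id: panel.lw_table(node_id)[codes].median(axis=1)
        for node_id, _ in comparison_sets(panel.hierarchy)
    }
    return {
        "lw": lw,
        "cw": panel.cw_table()[codes].median(axis=1),
        "gw": panel.gw_table()[codes].median(axis=1),
        "leaf_lw": panel.leaf_lw_table()[codes].median(axis=1),
        "n": len(codes),
    }
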