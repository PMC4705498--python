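"""Packaged reference data from the published PD-telehealth AHP study.

The study's raw pairwise judgments were never deposited; what survives are
the published result tables: group local/global weights per need, category
weights, the clinical and technical subgroup medians, and the t-test
p-values.  Those printed values are shipped here (3-decimal precision, as
published) so that the arithmetic identities that tie them together —
GW = CW x LW, per-category GW sums, rankings, and the subgroup rank
correlation — can be recomputed and checked, and so that simulated panels
can use the published weights as realistic ground truth.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["pd_study_needs", "pd_study_categories", "pd_study_group_weights"]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("ahp_needs.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def pd_study_needs() -> pd.DataFrame:
    """Published per-need weights: one row per need.

    Columns: ``need_id, category_id, group_gw, group_lw,
    median_technical_gw, median_technical_lw, median_clinical_gw,
    median_clinical_lw, gw_ttest_p, lw_ttest_p``.
    """
    return _read("pd_study_needs.csv")


def pd_study_categories() -> pd.DataFrame:
    """Published category weights and subgroup medians, one row per category."""
    return _read("pd_study_categories.csv")


def pd_study_group_weights() -> dict[str, pd.Series]:
    """Published group local weights as propagation-ready vectors.

    Returns ``{node_id: local weight Series}`` for the goal node (the
    category weights) and each category (the needs' local weights), keyed
    exactly as the packaged hierarchy fixture — the input shape
    :func:`ahp_needs.synthesis.propagate_global_weights` expects.
    """
    from .hierarchy import pd_fixture

    h = pd_fixture()
    needs = pd_study_needs().set_index("need_id")
    cats = pd_study_categories().set_index("category_id")
    local = {h.root.id: cats["cw"].rename("lw")}
    for cat in h.categories():
        ids = [c.id for c in cat.children]
        local[cat.id] = needs.loc[ids, "group_lw"].rename("lw")
    return local
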