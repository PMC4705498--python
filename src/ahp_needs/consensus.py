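"""Shannon-entropy group-consensus (relative homogeneity) index.

Respondents' priority vectors are treated as probability distributions
over criteria.  With alpha entropy H_a (the mean of the individual Shannon
entropies), gamma entropy H_g (the entropy of the normalized element-wise
geometric-mean vector) and beta diversity

    H_b = max(H_g - H_a, 0),

the consensus indicator is

    S = (M - exp(H_b)) / (M - 1),   M = min(N respondents, K criteria),

clamped to [0, 1].  S is 1 when all respondents hold identical priorities
(exp(H_b) = 1) and 0 when priorities are maximally distinct (the true
diversity exp(H_b) reaches its ceiling M).  When the priorities have
disjoint supports the geometric-mean aggregate vanishes identically; this
degenerate case is defined as maximal diversity (S = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "shannon_entropy",
    "group_consensus",
    "consensus_report",
    "ConsensusReport",
]


def shannon_entropy(w, tol: float = 1e-6) -> float:
    """Shannon entropy H = -sum w_i ln w_i of a normalized weight vector.

    Zero weights contribute zero (0 ln 0 := 0).  Inputs whose sum deviates
    from 1 by more than ``tol`` are rejected.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if abs(w.sum() - 1.0) > tol:
        raise ValueError(f"weights must sum to 1 (got {w.sum():.8f})")
    nz = w[w > 0]
    return float(-(nz * np.log(nz)).sum())


def _aggregate(vectors: np.ndarray, how: str) -> np.ndarray | None:
    """Normalized element-wise aggregate across respondents (rows).

    Returns ``None`` for the degenerate geometric case in which every
    element contains a zero (disjoint supports).
    """
    if how == "geometric":
        with np.errstate(divide="ignore"):
            logs = np.where(vectors > 0, np.log(np.where(vectors > 0, vectors, 1.0)),
                            -np.inf)
        g = np.exp(logs.mean(axis=0))          # 0 wherever any respondent has 0
        g[np.isneginf(logs).any(axis=0)] = 0.0
        total = g.sum()
        if total == 0:
            return None
        return g / total
    if how == "arithmetic":
        a = vectors.mean(axis=0)
        return a / a.sum()
    raise ValueError(f"unknown aggregation {how!r}")


def group_consensus(
    vectors,
    m: int | None = None,
    aggregation: str = "geometric",
) -> tuple[float, float, float]:
    """Consensus S plus the alpha and gamma entropies for one panel.

    ``vectors`` is one normalized priority vector per respondent (rows).
    ``m`` overrides the normalization ceiling M = min(N, K).
    Returns ``(S, H_alpha, H_gamma)``.
    """
    rows = [np.asarray(v, dtype=float) for v in vectors]
    if len({r.shape for r in rows}) > 1 or any(r.ndim != 1 for r in rows):
        raise ValueError("respondent vectors must have equal length")
    V = np.asarray(rows, dtype=float)
    n_resp, k = V.shape
    if n_resp < 2:
        raise ValueError("consensus needs at least two respondents")
    if k < 2:
        raise ValueError("consensus needs at least two criteria")
    h_alpha = float(np.mean([shannon_entropy(v) for v in V]))
    M = int(m) if m is not None else min(n_resp, k)
    agg = _aggregate(V, aggregation)
    if agg is None:
        # disjoint supports: maximal diversity by definition
        h_gamma = math.log(k)
        return 0.0, h_alpha, h_gamma
    h_gamma = shannon_entropy(agg, tol=1e-9)
    h_beta = max(h_gamma - h_alpha, 0.0)
    if M <= 1:
        return 1.0, h_alpha, h_gamma
    s = (M - math.exp(h_beta)) / (M - 1)
    return float(min(max(s, 0.0), 1.0)), h_alpha, h_gamma


@dataclass
class ConsensusReport:
    """Per-node, between-categories, and overall consensus of a panel."""

    table: pd.DataFrame   # columns: scope, consensus, h_alpha, h_gamma, k, n

    def __str__(self) -> str:
        out = self.table.copy()
        out["consensus"] = out["consensus"].map(lambda v: f"{v:.3f}")
        return out.to_string(index=False)


def consensus_report(
    panel, aggregation: str = "geometric", m: int | None = None
) -> ConsensusReport:
    """Consensus rows mirroring the per-category / overall report layout.

    One row per internal comparison node (local-weight vectors), one
    "between categories" row (category-weight vectors), and one overall
    row computed on the full global-weight vectors.  ``panel`` is a
    :class:`~ahp_needs.synthesis.PanelResult`.
    """
    h = panel.hierarchy
    codes = [c for c in panel.codes() if c not in panel.excluded]
    rows = []

    def _row(scope: str, table: pd.DataFrame):
        vectors = [table[c].to_numpy() for c in codes]
        s, ha, hg = group_consensus(vectors, m=m, aggregation=aggregation)
        rows.append(
            {
                "scope": scope,
                "consensus": s,
                "h_alpha": ha,
                "h_gamma": hg,
                "k": table.shape[0],
                "n": len(codes),
            }
        )

    for node in h.internal_nodes():
        if node.id == h.root.id:
            continue
        _row(f"{node.label} elements", panel.lw_table(node.id))
    _row("Between categories elements", panel.cw_table())
    _row("Overall (global weights)", panel.gw_table())
    return ConsensusReport(table=pd.DataFrame(rows))
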