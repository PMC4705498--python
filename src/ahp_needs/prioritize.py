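"""Priority derivation and consistency screening for one judgment matrix.

The principal right eigenvector of a positive reciprocal matrix, normalized
to sum one, is the AHP priority vector; the row geometric mean is retained
as an independent derivation (the two coincide exactly on consistent
matrices).  Inconsistency is quantified by

    CI = (lambda_max - n) / (n - 1),        CR = CI / RI(n),

where RI(n) is the expected CI of random reciprocal matrices of order n
(Saaty's classical table) and lambda_max is the principal eigenvalue.
Matrices with CR above 0.10 are flagged for revision; ``suggest_revision``
points at the single entry most at odds with the fitted priorities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .judgments import JudgmentMatrix
from .scale import round_to_saaty

__all__ = [
    "RI_SAATY",
    "CR_THRESHOLD",
    "PriorityResult",
    "RevisionSuggestion",
    "derive_priorities",
    "consistency_ratio",
    "suggest_revision",
]

#: Random consistency index RI(n) for n = 1..10 (classical values).
RI_SAATY: tuple[float, ...] = (0.0, 0.0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45, 1.49)

#: Acceptability threshold on CR ("10% rule").
CR_THRESHOLD: float = 0.10

_POWER_TOL = 1e-12
_POWER_MAXITER = 10_000


class UnsupportedOrderError(ValueError):
    """Matrix order exceeds the random-index table (n > 10)."""


class ConvergenceError(RuntimeError):
    pass


@dataclass
class PriorityResult:
    """Weights and consistency diagnostics for one comparison node."""

    node: str
    items: list[str]
    weights: np.ndarray          # nonnegative, sums to 1
    lambda_max: float
    ci: float
    cr: float
    acceptable: bool
    method: str
    n_iter: int = 0

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.items, self.weights))


@dataclass
class RevisionSuggestion:
    """The entry whose revision would most reduce inconsistency."""

    node: str
    pair: tuple[str, str]
    current: Fraction
    suggested: Fraction


def _check_matrix(m: JudgmentMatrix | np.ndarray) -> tuple[np.ndarray, list[str], str]:
    if isinstance(m, JudgmentMatrix):
        if not m.is_reciprocal():
            raise ValueError(f"matrix at {m.node!r} is not reciprocal")
        return m.array(), m.items, m.node
    A = np.asarray(m, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("judgment matrix must be square")
    if not np.all(A > 0):
        raise ValueError("judgment matrix entries must be positive")
    if not np.allclose(A * A.T, 1.0, rtol=1e-9, atol=0):
        raise ValueError("matrix is not reciprocal (a_ij * a_ji != 1)")
    n = A.shape[0]
    return A, [str(i) for i in range(n)], ""


def _power_iteration(A: np.ndarray) -> tuple[np.ndarray, int]:
    n = A.shape[0]
    w = np.full(n, 1.0 / n)
    for it in range(1, _POWER_MAXITER + 1):
        v = A @ w
        v /= v.sum()
        if np.max(np.abs(v - w)) < _POWER_TOL:
            return v, it
        w = v
    raise ConvergenceError(
        f"power iteration did not converge in {_POWER_MAXITER} iterations"
    )


def derive_priorities(
    m: JudgmentMatrix | np.ndarray,
    method: str = "eigenvector",
    ri_table: tuple[float, ...] = RI_SAATY,
    cr_threshold: float = CR_THRESHOLD,
) -> PriorityResult:
    """Derive the priority vector and consistency diagnostics.

    ``method="eigenvector"`` runs a deterministic power iteration from the
    uniform vector (tolerance 1e-12 on successive normalized iterates,
    capped at 10,000 iterations); ``method="geometric_mean"`` uses the row
    geometric mean, w_i proportional to (prod_j a_ij)^(1/n).  In both
    cases lambda_max is the mean over rows of (A w)_i / w_i.
    """
    A, items, node = _check_matrix(m)
    n = A.shape[0]
    if method == "eigenvector":
        w, n_iter = _power_iteration(A)
    elif method == "geometric_mean":
        w = np.exp(np.log(A).mean(axis=1))
        w /= w.sum()
        n_iter = 0
    else:
        raise ValueError(f"unknown method {method!r}")
    lambda_max = float(np.mean((A @ w) / w))
    ci, cr, acceptable = consistency_ratio(
        n, lambda_max, ri_table=ri_table, cr_threshold=cr_threshold
    )
    return PriorityResult(
        node=node, items=items, weights=w, lambda_max=lambda_max,
        ci=ci, cr=cr, acceptable=acceptable, method=method, n_iter=n_iter,
    )


def consistency_ratio(
    m_or_n,
    lambda_max: float,
    ri_table: tuple[float, ...] = RI_SAATY,
    cr_threshold: float = CR_THRESHOLD,
) -> tuple[float, float, bool]:
    """(CI, CR, acceptable) for a matrix of order n with given lambda_max.

    CR is defined as 0 for n <= 2 (all 2x2 reciprocal matrices are
    consistent).  Orders beyond the RI table (n > 10 for the classical
    table) raise ``UnsupportedOrderError``.
    """
    n = m_or_n.order if isinstance(m_or_n, JudgmentMatrix) else int(m_or_n)
    if n < 2:
        raise ValueError(f"order must be >= 2, got {n}")
    if n > len(ri_table):
        raise UnsupportedOrderError(
            f"order {n} exceeds the random-index table (max {len(ri_table)})"
        )
    if n == 2:
        return 0.0, 0.0, True
    ci = max((lambda_max - n) / (n - 1), 0.0)
    ri = ri_table[n - 1]
    cr = ci / ri
    return ci, cr, cr <= cr_threshold


def suggest_revision(
    m: JudgmentMatrix, cr_threshold: float = CR_THRESHOLD
) -> RevisionSuggestion | None:
    """Locate the judgment most responsible for inconsistency.

    Under the fitted eigenvector w, a perfectly consistent respondent
    would have a_ij = w_i / w_j; the pair maximizing
    ``|log(a_ij * w_j / w_i)|`` deviates most, and the suggested
    replacement is the scale value nearest w_i / w_j in log-space.
    Returns ``None`` (a no-op) when the matrix is already acceptable.
    """
    res = derive_priorities(m, method="eigenvector", cr_threshold=cr_threshold)
    if res.acceptable:
        return None
    A, w = m.array(), res.weights
    best, best_dev = None, -1.0
    for i in range(m.order):
        for j in range(i + 1, m.order):
            dev = abs(math.log(A[i, j] * w[j] / w[i]))
            if dev > best_dev:
                best, best_dev = (i, j), dev
    i, j = best
    return RevisionSuggestion(
        node=m.node,
        pair=(m.items[i], m.items[j]),
        current=m.entry(i, j),
        suggested=round_to_saaty(w[i] / w[j]),
    )
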