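"""Pairwise-judgment elicitation: questionnaires, answers, matrices, and IO.

Respondents answer one question per unordered pair of siblings ("which of
the two is more important, and how much, on an integer 1-9 scale?").
Answers are stored in long form — one row per question — and assembled
into positive reciprocal matrices.  Intensities are kept as integers with
an orientation flag; reciprocals are *derived* (as exact rationals), never
stored as floats, so the reciprocity invariant a_ij * a_ji = 1 holds
exactly.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .hierarchy import Hierarchy, comparison_sets

__all__ = [
    "Respondent",
    "Judgment",
    "JudgmentMatrix",
    "PairwiseQuestion",
    "JudgmentError",
    "generate_questionnaire",
    "assemble_matrix",
    "assemble_all_matrices",
    "read_judgments",
    "write_judgments",
    "read_panel",
    "write_panel",
]

RESPONDENT_GROUPS = ("technical", "clinical", "other")

QUESTION_TEMPLATE = (
    "Comparing {a!r} and {b!r}: which is the most important element and "
    "how much more important is it with respect to the other (1 = equally "
    "important ... 9 = much more important)?"
)


class JudgmentError(ValueError):
    """Raised for malformed, out-of-range, duplicate or missing judgments."""


@dataclass(frozen=True)
class Respondent:
    code: str
    group: str = "other"
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.group not in RESPONDENT_GROUPS:
            raise JudgmentError(
                f"unknown respondent group {self.group!r}; "
                f"expected one of {RESPONDENT_GROUPS}"
            )


@dataclass(frozen=True)
class Judgment:
    """One answered pairwise question.

    ``preferred`` is ``"a"``, ``"b"`` or ``"equal"``; ``intensity`` is the
    integer 1..9, with ``equal`` if and only if the intensity is 1.
    """

    respondent: str
    node: str
    element_a: str
    element_b: str
    preferred: str
    intensity: int

    def __post_init__(self):
        if self.element_a == self.element_b:
            raise JudgmentError(
                f"self-comparison of {self.element_a!r} at node {self.node!r}"
            )
        if self.preferred not in ("a", "b", "equal"):
            raise JudgmentError(f"preferred must be a/b/equal, got {self.preferred!r}")
        if not (isinstance(self.intensity, (int, np.integer)) and 1 <= self.intensity <= 9):
            raise JudgmentError(
                f"intensity must be an integer in 1..9, got {self.intensity!r} "
                f"({self.element_a} vs {self.element_b})"
            )
        if (self.preferred == "equal") != (self.intensity == 1):
            raise JudgmentError(
                "preferred='equal' if and only if intensity=1 "
                f"(got {self.preferred!r} with intensity {self.intensity})"
            )

    @property
    def value_ab(self) -> Fraction:
        """The matrix entry a_{ab} implied by this judgment, exact."""
        if self.preferred == "b":
            return Fraction(1, int(self.intensity))
        return Fraction(int(self.intensity))


@dataclass(frozen=True)
class PairwiseQuestion:
    node: str
    element_a: str
    element_b: str
    text: str


class JudgmentMatrix:
    """A positive reciprocal matrix over the children of one node.

    Entries are exact rationals (``fractions.Fraction``); ``array()``
    yields the float matrix for numerics.  Matrices assembled from
    judgments have entries on the 1-9 scale; consolidated group matrices
    may carry arbitrary positive reals (stored as float-backed Fractions,
    reciprocity still enforced by construction).
    """

    def __init__(self, node: str, items: list[str], entries):
        self.node = node
        self.items = list(items)
        n = len(self.items)
        if n < 2:
            raise JudgmentError(f"matrix at {node!r} needs order >= 2, got {n}")
        M = [[Fraction(1)] * n for _ in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                v = entries[i][j] if not isinstance(entries, dict) else entries[(i, j)]
                v = Fraction(v) if not isinstance(v, Fraction) else v
                if v <= 0:
                    raise JudgmentError(f"nonpositive entry at {node!r}[{i},{j}]")
                M[i][j] = v
                M[j][i] = 1 / v
        self._M = M

    @property
    def order(self) -> int:
        return len(self.items)

    def entry(self, i: int, j: int) -> Fraction:
        return self._M[i][j]

    def array(self) -> np.ndarray:
        return np.array([[float(v) for v in row] for row in self._M], dtype=float)

    def is_reciprocal(self) -> bool:
        n = self.order
        return all(
            self._M[i][j] * self._M[j][i] == 1 for i in range(n) for j in range(n)
        ) and all(self._M[i][i] == 1 for i in range(n))

    def __repr__(self) -> str:
        return f"<JudgmentMatrix node={self.node!r} n={self.order}>"


def generate_questionnaire(h: Hierarchy) -> list[PairwiseQuestion]:
    """All pairwise questions for a hierarchy, in document order.

    One question per unordered child pair per internal node; the PD tree
    yields 10 + 6 + 3 + 6 + 3 + 3 = 31 questions.
    """
    questions = []
    for node_id, child_ids in comparison_sets(h):
        labels = {c: h.node(c).label for c in child_ids}
        for i, a in enumerate(child_ids):
            for b in child_ids[i + 1:]:
                questions.append(
                    PairwiseQuestion(
                        node=node_id,
                        element_a=a,
                        element_b=b,
                        text=QUESTION_TEMPLATE.format(a=labels[a], b=labels[b]),
                    )
                )
    return questions


def assemble_matrix(
    judgments: list[Judgment], node: str, h: Hierarchy
) -> JudgmentMatrix:
    """Build one respondent's reciprocal matrix for ``node``.

    Requires exactly one judgment per unordered child pair; missing or
    duplicated pairs raise, naming the pair.
    """
    children = [c.id for c in h.node(node).children]
    index = {c: i for i, c in enumerate(children)}
    entries: dict[tuple[int, int], Fraction] = {}
    for jd in judgments:
        if jd.node != node:
            continue
        for el in (jd.element_a, jd.element_b):
            if el not in index:
                raise JudgmentError(f"{el!r} is not a child of node {jd.node!r}")
        i, j = index[jd.element_a], index[jd.element_b]
        key, v = ((i, j), jd.value_ab) if i < j else ((j, i), 1 / jd.value_ab)
        if key in entries:
            raise JudgmentError(
                f"duplicate judgment for pair ({jd.element_a!r}, {jd.element_b!r}) "
                f"at node {node!r}"
            )
        entries[key] = v
    n = len(children)
    missing = [
        (children[i], children[j])
        for i in range(n)
        for j in range(i + 1, n)
        if (i, j) not in entries
    ]
    if missing:
        raise JudgmentError(
            f"incomplete questionnaire at node {node!r}: missing pair(s) "
            + ", ".join(f"({a!r}, {b!r})" for a, b in missing)
        )
    return JudgmentMatrix(node, children, entries)


def assemble_all_matrices(
    judgments: list[Judgment], h: Hierarchy
) -> dict[str, dict[str, JudgmentMatrix]]:
    """Nested mapping respondent code -> node id -> JudgmentMatrix."""
    by_resp: dict[str, list[Judgment]] = {}
    for jd in judgments:
        by_resp.setdefault(jd.respondent, []).append(jd)
    return {
        code: {
            node_id: assemble_matrix(jds, node_id, h)
            for node_id, _ in comparison_sets(h)
        }
        for code, jds in by_resp.items()
    }


# -- tabular IO ----------------------------------------------------------

JUDGMENT_COLUMNS = ["respondent", "node", "element_a", "element_b", "preferred", "intensity"]
PANEL_COLUMNS = ["code", "group", "sex", "years_experience", "years_pd", "years_ehealth"]


def write_judgments(
    judgments: list[Judgment],
    path: str | Path | None = None,
    panel: list[Respondent] | None = None,
    panel_path: str | Path | None = None,
) -> str:
    """Write judgments (and optionally the panel) as canonical CSV.

    Returns the judgments CSV text; writes it to ``path`` when given.
    """
    df = pd.DataFrame(
        [
            (j.respondent, j.node, j.element_a, j.element_b, j.preferred, j.intensity)
            for j in judgments
        ],
        columns=JUDGMENT_COLUMNS,
    )
    buf = io.StringIO()
    df.to_csv(buf, index=False, lineterminator="\n")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    if panel is not None and panel_path is not None:
        write_panel(panel, panel_path)
    return text


def write_panel(panel: list[Respondent], path: str | Path) -> str:
    rows = []
    for r in panel:
        md = r.metadata
        rows.append(
            (
                r.code,
                r.group,
                md.get("sex", ""),
                md.get("years_experience", ""),
                md.get("years_pd", ""),
                md.get("years_ehealth", ""),
            )
        )
    df = pd.DataFrame(rows, columns=PANEL_COLUMNS)
    buf = io.StringIO()
    df.to_csv(buf, index=False, lineterminator="\n")
    text = buf.getvalue()
    Path(path).write_text(text, encoding="utf-8")
    return text


def read_panel(path: str | Path) -> list[Respondent]:
    """Read panel metadata CSV (``code,group,...``).

    Unknown groups are mapped to ``"other"`` with a warning; an empty file
    (header only, or zero bytes) yields an empty panel.
    """
    try:
        df = pd.read_csv(path, dtype=str).fillna("")
    except pd.errors.EmptyDataError:
        return []
    panel = []
    seen: set[str] = set()
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        code = str(row.code)
        if code in seen:
            raise JudgmentError(f"{path}, line {lineno}: duplicate respondent code {code!r}")
        seen.add(code)
        group = str(getattr(row, "group", "other")).strip().lower()
        if group not in RESPONDENT_GROUPS:
            warnings.warn(
                f"{path}, line {lineno}: unknown group {group!r} for respondent "
                f"{code!r}; mapped to 'other'",
                stacklevel=2,
            )
            group = "other"
        metadata = {
            k: getattr(row, k)
            for k in PANEL_COLUMNS[2:]
            if hasattr(row, k) and getattr(row, k) != ""
        }
        panel.append(Respondent(code=code, group=group, metadata=metadata))
    return panel


def read_judgments(
    path: str | Path,
    h: Hierarchy | None = None,
    panel_path: str | Path | None = None,
) -> tuple[list[Respondent], list[Judgment]]:
    """Read a long-form judgments CSV (and optionally a panel CSV).

    Without a panel file, respondents are inferred from the judgment rows
    with group ``"other"``.  With a hierarchy, node and element ids are
    validated.  Malformed rows raise with their line number.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return [], []
    missing_cols = [c for c in JUDGMENT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise JudgmentError(f"{path}: missing column(s) {missing_cols}")
    judgments = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            intensity = int(row.intensity)
        except (TypeError, ValueError):
            raise JudgmentError(
                f"{path}, line {lineno}: intensity {row.intensity!r} is not an integer"
            ) from None
        try:
            jd = Judgment(
                respondent=str(row.respondent),
                node=str(row.node),
                element_a=str(row.element_a),
                element_b=str(row.element_b),
                preferred=str(row.preferred),
                intensity=intensity,
            )
        except JudgmentError as exc:
            raise JudgmentError(f"{path}, line {lineno}: {exc}") from None
        if h is not None:
            if jd.node not in h:
                raise JudgmentError(
                    f"{path}, line {lineno}: node {jd.node!r} not in hierarchy"
                )
            child_ids = {c.id for c in h.node(jd.node).children}
            for el in (jd.element_a, jd.element_b):
                if el not in child_ids:
                    raise JudgmentError(
                        f"{path}, line {lineno}: {el!r} is not a child of {jd.node!r}"
                    )
        judgments.append(jd)

    if panel_path is not None:
        panel = read_panel(panel_path)
        known = {r.code for r in panel}
        extra = sorted({j.respondent for j in judgments} - known)
        if extra:
            raise JudgmentError(
                f"{path}: respondent(s) {extra} absent from panel file {panel_path}"
            )
    else:
        codes = list(dict.fromkeys(j.respondent for j in judgments))
        panel = [Respondent(code=c, group="other") for c in codes]
    return panel, judgments
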