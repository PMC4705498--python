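"""Decision hierarchy: goal, categories, and need leaves.

An AHP hierarchy is a rooted tree.  The root is the decision goal; internal
nodes group comparable items (here: need categories); leaves are the items
whose global priorities the analysis ultimately delivers (here: user needs).
Every internal node defines one pairwise-comparison set over its children,
so each internal node must have at least two children.

Files are YAML (canonical) or JSON.  The two-level schema is::

    goal: {id: ..., label: ...}
    categories:
      - id: ...
        label: ...
        needs: [{id: ..., label: ...}, ...]

Deeper trees are expressed by nesting ``needs`` (or the synonym
``children``) inside a need entry; weight propagation is recursive, so
depth is unrestricted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "Node",
    "Hierarchy",
    "HierarchyError",
    "load_hierarchy",
    "write_hierarchy",
    "comparison_sets",
    "pd_fixture",
]


class HierarchyError(ValueError):
    """Raised when a hierarchy file or tree violates the schema invariants."""


@dataclass
class Node:
    """One node of the decision tree.

    Parameters
    ----------
    id : str
        Short stable key, unique across the tree.  Used in judgment files
        and result tables.
    label : str
        Human-readable name, shown in questionnaires and reports.
    children : list of Node
        Ordered children; empty for leaves (needs).
    """

    id: str
    label: str
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        """Yield this node and all descendants in document (pre-)order."""
        yield self
        for child in self.children:
            yield from child.walk()


class Hierarchy:
    """A validated decision hierarchy.

    Validation enforces: unique ids, and >= 2 children for every internal
    node (a pairwise comparison needs at least two items).  Construction
    from nested ``Node`` objects guarantees the tree is connected and
    acyclic.
    """

    def __init__(self, root: Node):
        self.root = root
        self._nodes: dict[str, Node] = {}
        self._parent: dict[str, str | None] = {root.id: None}
        for node in root.walk():
            if node.id in self._nodes:
                raise HierarchyError(f"duplicate node id: {node.id!r}")
            self._nodes[node.id] = node
            for child in node.children:
                self._parent[child.id] = node.id
            # the root may hold a single category (its weight is then 1);
            # any other internal node needs >= 2 children to be comparable
            if node.children and len(node.children) < 2 and node is not root:
                raise HierarchyError(
                    f"category with < 2 children: {node.id!r} "
                    "(pairwise comparison is undefined for a single item)"
                )

    # -- queries ---------------------------------------------------------

    def node(self, node_id: str) -> Node:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise KeyError(f"unknown node id: {node_id!r}") from None

    def parent(self, node_id: str) -> str | None:
        return self._parent[self.node(node_id).id]

    def internal_nodes(self) -> list[Node]:
        """All comparison nodes (root included), in document order."""
        return [n for n in self.root.walk() if not n.is_leaf]

    def leaves(self) -> list[Node]:
        """All needs, in document order."""
        return [n for n in self.root.walk() if n.is_leaf]

    def leaf_ids(self) -> list[str]:
        return [n.id for n in self.leaves()]

    def categories(self) -> list[Node]:
        """Children of the root (the top-level categories)."""
        return list(self.root.children)

    def path_to(self, leaf_id: str) -> list[str]:
        """Node ids from the root down to (and including) ``leaf_id``."""
        path = [leaf_id]
        while (up := self._parent[path[-1]]) is not None:
            path.append(up)
        return path[::-1]

    @property
    def depth(self) -> int:
        def _d(node: Node) -> int:
            return 1 + max((_d(c) for c in node.children), default=-1)

        return _d(self.root)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def __eq__(self, other) -> bool:
        if not isinstance(other, Hierarchy):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def __repr__(self) -> str:
        return (
            f"<Hierarchy {self.root.id!r}: "
            f"{len(self.internal_nodes()) - 1} categories, "
            f"{len(self.leaves())} leaves>"
        )

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        def _branch(node: Node) -> dict:
            d = {"id": node.id, "label": node.label}
            if node.children:
                d["needs"] = [_branch(c) for c in node.children]
            return d

        return {
            "goal": {"id": self.root.id, "label": self.root.label},
            "categories": [_branch(c) for c in self.root.children],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Hierarchy":
        if not isinstance(data, dict) or "goal" not in data:
            raise HierarchyError("hierarchy file must define a 'goal' mapping")
        goal = data["goal"]
        if not isinstance(goal, dict) or "id" not in goal:
            raise HierarchyError("'goal' must be a mapping with an 'id'")

        def _node(entry: dict, where: str) -> Node:
            if not isinstance(entry, dict) or "id" not in entry:
                raise HierarchyError(f"node entry under {where!r} lacks an 'id'")
            kids = entry.get("needs", entry.get("children", [])) or []
            return Node(
                id=str(entry["id"]),
                label=str(entry.get("label", entry["id"])),
                children=[_node(e, entry["id"]) for e in kids],
            )

        root = Node(
            id=str(goal["id"]),
            label=str(goal.get("label", goal["id"])),
            children=[_node(e, "categories") for e in data.get("categories", []) or []],
        )
        return cls(root)


def load_hierarchy(path: str | Path) -> Hierarchy:
    """Read and validate a hierarchy from a YAML or JSON file.

    The format is chosen by extension (``.json`` -> JSON, anything else ->
    YAML; YAML is a superset, so JSON content under a ``.yaml`` name also
    parses).  Validation errors name the offending node id.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise HierarchyError(f"cannot parse {path}: {exc}") from exc
    return Hierarchy.from_dict(data)


def write_hierarchy(h: Hierarchy, path: str | Path) -> Path:
    """Write ``h`` to YAML (default) or JSON, chosen by extension."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(h.to_dict(), indent=2, ensure_ascii=False) + "\n",
                        encoding="utf-8")
    else:
        path.write_text(
            yaml.safe_dump(h.to_dict(), sort_keys=False, allow_unicode=True),
            encoding="utf-8",
        )
    return path


def comparison_sets(h: Hierarchy) -> list[tuple[str, list[str]]]:
    """One (node id, ordered child ids) pair per internal node, root first.

    The root's set compares the categories themselves (their priorities are
    the category weights, CW); each category's set compares its needs.  A
    single-child root poses no comparison and is omitted (its only child
    gets weight 1 during propagation).
    """
    return [
        (n.id, [c.id for c in n.children])
        for n in h.internal_nodes()
        if len(n.children) >= 2
    ]


def n_pairwise_questions(h: Hierarchy) -> int:
    """Total number of pairwise questions: sum of k(k-1)/2 over sets."""
    return sum(len(ids) * (len(ids) - 1) // 2 for _, ids in comparison_sets(h))


def pd_fixture() -> Hierarchy:
    """The packaged Parkinson's-disease telehealth needs hierarchy.

    Five categories — Performance, User experience, Clinical practice,
    Economic, Technical issues — holding 17 needs in total.
    """
    ref = resources.files("ahp_needs.data").joinpath("pd_hierarchy.yaml")
    return Hierarchy.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))
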