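import warnings

import pytest

from ahp_needs.hierarchy import Hierarchy, Node, pd_fixture
from ahp_needs.simulate import paper_shaped_panel, simulate_judgments
from ahp_needs.synthesis import fit_panel


@pytest.fixture(scope="session")
def pd_tree():
    return pd_fixture()


@pytest.fixture
def tiny_tree():
    """Two categories, five needs: smallest multi-category hierarchy."""
    return Hierarchy(
        Node(
            "goal",
            "Goal",
            [
                Node("c1", "Category one", [Node("a", "A"), Node("b", "B")]),
                Node(
                    "c2",
                    "Category two",
                    [Node("x", "X"), Node("y", "Y"), Node("z", "Z")],
                ),
            ],
        )
    )


@pytest.fixture(scope="session")
def paper_panel():
    """One fitted study-shaped synthetic panel (16 experts, PD tree)."""
    spec = paper_shaped_panel(seed=1)
    panel, judgments = simulate_judgments(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = fit_panel(spec.hierarchy, judgments, panel)
    return spec, panel, judgments, result
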