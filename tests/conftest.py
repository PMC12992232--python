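import numpy as np
import pandas as pd
import pytest

from fuzzymcda import (
    ExpertPanel,
    IndicatorHierarchy,
    IndicatorNode,
    jilin_case,
)


@pytest.fixture(scope="session")
def case():
    """The bundled Jilin case study (hierarchy, weights, partial R, scores)."""
    return jilin_case()


@pytest.fixture
def toy_hierarchy():
    """Two criteria with two leaves each, equal weights everywhere."""
    nodes = [
        IndicatorNode("root", "goal", 1),
        IndicatorNode("B1", "criterion 1", 2, "root", 0.5),
        IndicatorNode("B2", "criterion 2", 2, "root", 0.5),
        IndicatorNode("L1", "leaf 1", 3, "B1", 0.5),
        IndicatorNode("L2", "leaf 2", 3, "B1", 0.5),
        IndicatorNode("L3", "leaf 3", 3, "B2", 0.5),
        IndicatorNode("L4", "leaf 4", 3, "B2", 0.5),
    ]
    return IndicatorHierarchy(nodes)


@pytest.fixture
def toy_panel(toy_hierarchy):
    """Five experts, all four leaves answered, grades 1-5."""
    rng = np.random.default_rng(123)
    ratings = pd.DataFrame(
        rng.integers(1, 6, size=(5, 4)).astype(float),
        columns=toy_hierarchy.leaf_ids,
        index=[f"P{i}" for i in range(5)],
    )
    return ExpertPanel(ratings)
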