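import numpy as np
import pytest

from coupcoord import IndexSystem, IndicatorMatrix, IndicatorSpec
from coupcoord.datasets import pingshuo_ahp_config, pingshuo_index


@pytest.fixture(scope="session")
def mine_index() -> IndexSystem:
    """The shipped 2-system / 5-subsystem / 18-indicator hierarchy."""
    return pingshuo_index()


@pytest.fixture(scope="session")
def mine_ahp() -> dict:
    return pingshuo_ahp_config()


@pytest.fixture
def toy_index() -> IndexSystem:
    """Minimal two-system hierarchy: 2 + 2 indicators, one cost column."""
    return IndexSystem(
        systems=("vegetation", "soil"),
        subsystems={"vegetation": ("tree",), "soil": ("basic",)},
        indicators=(
            IndicatorSpec("V1", "cover", "vegetation", "tree"),
            IndicatorSpec("V2", "height", "vegetation", "tree"),
            IndicatorSpec("S1", "som", "soil", "basic"),
            IndicatorSpec("S2", "bulk density", "soil", "basic", direction="cost"),
        ),
    )


@pytest.fixture
def toy_raw(toy_index) -> IndicatorMatrix:
    return IndicatorMatrix(
        plot_ids=("a", "b", "c"),
        indicator_ids=toy_index.indicator_ids,
        values=np.array(
            [
                [1.0, 10.0, 2.0, 1.6],
                [3.0, 30.0, 5.0, 1.2],
                [5.0, 20.0, 8.0, 1.4],
            ]
        ),
        scale="raw",
    )
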