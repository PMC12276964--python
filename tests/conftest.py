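import numpy as np
import pytest

from mapnn.maps import DemographicMap, MapChannel


def make_flat_map(width: int, sigma: float, K: float,
                  mask: np.ndarray | None = None) -> DemographicMap:
    z = np.zeros((width, width), dtype=np.int64)
    return DemographicMap(
        MapChannel(width, np.full((width, width), float(sigma)), z),
        MapChannel(width, np.full((width, width), float(K)), z),
        habitat_mask=mask,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
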