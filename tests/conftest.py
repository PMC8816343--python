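import numpy as np
import pytest

from probcell import AnnotationSet, render_density_map


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_annotations():
    """A handful of well-separated annotations in a 32^3 volume."""
    coords = np.array(
        [
            [8.3, 9.1, 10.7],
            [22.6, 8.4, 21.2],
            [10.1, 24.9, 24.3],
            [25.0, 25.0, 8.0],
        ]
    )
    return AnnotationSet(coords, (32, 32, 32))


@pytest.fixture(scope="session")
def small_kmax_dm(small_annotations):
    return render_density_map(small_annotations, sigma=4.0, compounding="K_max")
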