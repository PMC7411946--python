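import numpy as np
import pytest

from barntrack import BarnMap, Station, DEFAULT_MODEL
from barntrack.io import synthetic_barn


@pytest.fixture(scope="session")
def barn():
    """The packaged synthetic barn, fully built (lookup table + TM)."""
    return synthetic_barn().build(DEFAULT_MODEL)


@pytest.fixture(scope="session")
def yard():
    """A 4 x 5 m waiting-yard arrangement: 0.5 m grid, 7 stations ~2 m apart."""
    ext = (0.0, 4.0, 0.0, 5.0)
    stations = [
        Station(id=f"s{i:02d}", x=float(x), y=float(y), z=3.0)
        for i, (x, y) in enumerate(
            (x, y) for y in (0.5, 2.5, 4.5) for x in (1.0, 3.0)
        )
    ] + [Station(id="s06", x=2.0, y=1.5, z=3.5)]
    return BarnMap(extents=ext, resolution=0.5, stations=stations).build(
        DEFAULT_MODEL
    )


@pytest.fixture
def mini_map():
    """Tiny obstacle-free 4 x 5 m barn with 4 corner-ish stations, 1 m grid."""
    ext = (0.0, 4.0, 0.0, 5.0)
    stations = [
        Station(id="a", x=0.5, y=0.5, z=3.0),
        Station(id="b", x=3.5, y=0.5, z=4.0),
        Station(id="c", x=0.5, y=4.5, z=3.5),
        Station(id="d", x=3.5, y=4.5, z=4.5),
    ]
    return BarnMap(extents=ext, resolution=1.0, stations=stations).build(
        DEFAULT_MODEL
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
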