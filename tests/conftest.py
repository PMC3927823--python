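import numpy as np
import pytest

from specmode.geo import ProjectedPoint


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def pp(x, y):
    return ProjectedPoint(float(x), float(y))


@pytest.fixture
def unit_square_points():
    return [pp(0, 0), pp(1, 0), pp(1, 1), pp(0, 1)]


def write_locality_csv(path, rows, header="species,longitude,latitude"):
    path.write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))
    return path
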