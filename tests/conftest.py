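import numpy as np
import pytest

from osteocea import default_parameters, make_synthetic_life_table


@pytest.fixture
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def life_table():
    return make_synthetic_life_table()


class ScriptedUniforms:
    """Stand-in for a Generator that replays a scripted (n_cycles, 4) uniform
    array: columns are (continuation, hip, vert, death). Values near 1 make
    an event not happen; values near 0 force it."""

    def __init__(self, rows):
        self._rows = np.asarray(rows, dtype=float)

    def random(self, shape):
        n, k = shape
        out = np.full(shape, 0.999999)
        m = min(n, len(self._rows))
        out[:m, :] = self._rows[:m, :k]
        return out


@pytest.fixture
def scripted_rng():
    return ScriptedUniforms
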