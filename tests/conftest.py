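import numpy as np
import pytest

from spindyn import gen_toy_cell


@pytest.fixture
def cubic_cell():
    """10 A cube with an O...O pair constructed 2.80 A apart."""
    return gen_toy_cell((10, 10, 10, 90, 90, 90),
                        [("O", (0.0, 0.0, 0.0)), ("O", (0.28, 0.0, 0.0))])


@pytest.fixture
def magres_text():
    """Minimal MAGRES fixture: two C and two H shielding tensors."""
    return "\n".join([
        "#$magres-abinitio-v1.0",
        "[atoms]",
        "units lattice Angstrom",
        "[/atoms]",
        "[magres]",
        "units ms ppm",
        "ms C 1 10.0 0 0 0 20.0 0 0 0 30.0",
        "ms C 2 150.0 1.0 0 1.0 160.0 0 0 0 170.0",
        "ms H 1 28.0 0 0 0 30.0 0 0 0 32.0",
        "ms H 2 25.0 0 0 0 26.0 0 0 0 27.0",
        "[/magres]",
        "",
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
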