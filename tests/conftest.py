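import numpy as np
import pytest

from gelkit.structure_io import Atom, Box, Frame


@pytest.fixture
def two_atom_frame() -> Frame:
    return Frame(atoms=[Atom("C", (0.0, 0.0, 0.0)), Atom("C", (3.0, 0.0, 0.0))])


@pytest.fixture
def single_sphere_frame() -> Frame:
    return Frame(atoms=[Atom("C", (10.0, 10.0, 10.0))], box=Box((20.0, 20.0, 20.0)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
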