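import numpy as np
import pytest

from inbredkit.pedigree import Pedigree, PedigreeRecord as R


@pytest.fixture
def trio():
    """Two unrelated founders and their offspring."""
    return Pedigree.from_records([R("A"), R("B"), R("C", "A", "B")])


@pytest.fixture
def full_sib_pedigree():
    """Founders A, B; full sibs C, D; X their offspring (F_X = 1/4)."""
    return Pedigree.from_records([
        R("A"), R("B"), R("C", "A", "B"), R("D", "A", "B"), R("X", "C", "D"),
    ])


@pytest.fixture
def full_sib_line():
    """Repeated full-sib matings: F trajectory 0, 1/4, 3/8, 1/2."""
    recs = [R("A0"), R("B0")]
    for t in range(1, 5):
        recs.append(R(f"A{t}", f"A{t-1}", f"B{t-1}"))
        recs.append(R(f"B{t}", f"A{t-1}", f"B{t-1}"))
    return Pedigree.from_records(recs)


@pytest.fixture
def half_sib_pedigree():
    """Shared sire, different unrelated dams; offspring of the half sibs."""
    return Pedigree.from_records([
        R("S"), R("D1"), R("D2"),
        R("H1", "S", "D1"), R("H2", "S", "D2"),
        R("X", "H1", "H2"),
    ])


@pytest.fixture
def cousin_pedigree():
    """First-cousin mating: F = 1/16."""
    return Pedigree.from_records([
        R("GP1"), R("GP2"), R("M1"), R("M2"),
        R("P1", "GP1", "GP2"), R("P2", "GP1", "GP2"),
        R("C1", "P1", "M1"), R("C2", "P2", "M2"),
        R("X", "C1", "C2"),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
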