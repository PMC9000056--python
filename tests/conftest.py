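import numpy as np
import pytest

from timeuse_coda import coda, synthetic
from timeuse_coda.coda import IlrBasis
from timeuse_coda.synthetic import SUBJECT_PARTS, GeneratorConfig, generate_cohort


def random_composition(rng: np.random.Generator, d: int = 4) -> np.ndarray:
    return coda.close(rng.uniform(0.05, 1.0, size=d), total=1440.0)


def random_sbp(rng: np.random.Generator, d: int) -> np.ndarray:
    """A random valid sequential binary partition of d parts."""
    rows = []

    def split(group: list[int]) -> None:
        if len(group) < 2:
            return
        while True:
            mask = rng.integers(0, 2, size=len(group))
            if 0 < mask.sum() < len(group):
                break
        row = np.zeros(d, dtype=int)
        plus = [g for g, m in zip(group, mask) if m]
        minus = [g for g, m in zip(group, mask) if not m]
        row[plus] = 1
        row[minus] = -1
        rows.append(row)
        split(plus)
        split(minus)

    split(list(range(d)))
    return np.array(rows)


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(GeneratorConfig(n_subjects=300, seed=11))


@pytest.fixture(scope="session")
def big_cohort():
    return generate_cohort(GeneratorConfig(n_subjects=2000, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def alt_basis():
    """A balanced (non-pivot) SBP over the subject part order."""
    sbp = np.array(
        [
            [1, 1, -1, -1],
            [1, -1, 0, 0],
            [0, 0, 1, -1],
        ]
    )
    return IlrBasis(parts=SUBJECT_PARTS, sbp=sbp)
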