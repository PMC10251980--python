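import numpy as np
import pytest

from coturnix.pedigree import Pedigree, validate_and_sort


@pytest.fixture(scope="session")
def fullsib_pedigree() -> Pedigree:
    """Two unrelated founders, two full-sib offspring, one inbred
    offspring of the full-sib mating (F = 0.25)."""
    return validate_and_sort(
        [
            (1, 0, 0, "M"),
            (2, 0, 0, "F"),
            (3, 1, 2, "M"),
            (4, 1, 2, "F"),
            (5, 3, 4, "M"),
        ]
    )


@pytest.fixture(scope="session")
def halfsib_pedigree() -> Pedigree:
    """Paternal half sibs and their offspring (F = 0.125)."""
    return validate_and_sort(
        [
            (1, 0, 0, "M"),
            (2, 0, 0, "F"),
            (3, 0, 0, "F"),
            (4, 1, 2, "M"),
            (5, 1, 3, "F"),
            (6, 4, 5, "M"),
        ]
    )


def random_pedigree(n: int, seed: int, p_known: float = 0.8) -> Pedigree:
    """Random valid pedigree: parents drawn among earlier animals."""
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(1, n + 1):
        sire = dam = 0
        if i > 2 and rng.random() < p_known:
            sire, dam = rng.choice(np.arange(1, i), size=2, replace=False)
            if sire == dam:
                dam = 0
        recs.append((i, int(sire), int(dam), "M" if i % 2 else "F"))
    return validate_and_sort(recs)
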