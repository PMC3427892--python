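import numpy as np
import pandas as pd
import pytest

from briefcsid import BRIEF_ITEM_BANK, CohortTable


def brute_force_pair_counts(x: np.ndarray, y: np.ndarray):
    """Subject-enumeration oracle for pairwise Guttman error counts.

    ``x`` is the lower-indexed item.  Difficulty ties treat the
    lower-indexed item as easier.  Returns (n, F, E) on pairwise
    complete cases.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n == 0:
        return 0, 0.0, 0.0
    dx, dy = float((x == 0).mean()), float((y == 0).mean())
    harder, easier = (x, y) if dx > dy else (y, x)
    F = 0
    for h, e in zip(harder, easier):
        if h == 1 and e == 0:
            F += 1
    E = n * (harder == 1).mean() * (easier == 0).mean()
    return n, float(F), float(E)


def random_keyed_matrix(rng: np.random.Generator, n_max: int = 12,
                        p_max: int = 6, missing_prob: float = 0.1) -> np.ndarray:
    n = int(rng.integers(4, n_max + 1))
    p = int(rng.integers(2, p_max + 1))
    probs = rng.uniform(0.1, 0.9, size=p)
    m = (rng.random((n, p)) < probs).astype(float)
    if missing_prob > 0:
        m[rng.random((n, p)) < missing_prob] = np.nan
    return m


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def make_cohort(records: list[dict], items=BRIEF_ITEM_BANK) -> CohortTable:
    return CohortTable(pd.DataFrame(records), items)
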