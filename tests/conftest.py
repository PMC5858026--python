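import numpy as np
import pytest

from hmetad.sdt_core import ConfidenceCounts, MetaDParams


@pytest.fixture(scope="session")
def tutorial_counts() -> ConfidenceCounts:
    """The worked 3-level example: strong S1-biased counts after S1, mirror after S2."""
    return ConfidenceCounts(nR_S1=[100, 50, 20, 10, 5, 1], nR_S2=[3, 7, 8, 12, 27, 89])


def random_metad_params(rng: np.random.Generator, k: int | None = None) -> MetaDParams:
    """A random parameter setting satisfying the criterion-ordering invariant."""
    if k is None:
        k = int(rng.integers(2, 5))
    meta_d = float(rng.uniform(-3.0, 3.0))
    meta_c = float(rng.uniform(-1.0, 1.0))
    inc1 = rng.uniform(0.05, 1.0, k - 1)
    inc2 = rng.uniform(0.05, 1.0, k - 1)
    return MetaDParams(
        meta_d=meta_d,
        meta_c=meta_c,
        cS1=meta_c - np.cumsum(inc1)[::-1],
        cS2=meta_c + np.cumsum(inc2),
    )


def random_counts(rng: np.random.Generator, k: int, n: int = 200) -> ConfidenceCounts:
    """Random non-degenerate counts (no structure implied)."""
    a = rng.multinomial(n, rng.dirichlet(np.ones(2 * k)))
    b = rng.multinomial(n, rng.dirichlet(np.ones(2 * k)))
    return ConfidenceCounts(nR_S1=a, nR_S2=b)
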