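import numpy as np
import pytest

from durleak.leakfit import ComboCounts
from durleak.model import LeakParams, p_second_longer
from durleak.simulate import DISTRACTOR_DURATIONS


def full_design_combos():
    """The 12 ordered distinct distractor pairs of the full design."""
    import itertools

    return list(itertools.permutations(DISTRACTOR_DURATIONS, 2))


@pytest.fixture
def design_combos():
    return full_design_combos()


def counts_from_k(k: float, variant: str = "leaking", n_per: int = 30, rng=None):
    """Combo counts drawn from the forward model at leaking factor k."""
    combos = full_design_combos()
    d1 = np.array([c[0] for c in combos])
    d2 = np.array([c[1] for c in combos])
    params = LeakParams(variant, k)
    phi = np.asarray(p_second_longer(1.0, d1, 1.0, d2, params))
    n = np.full(len(combos), n_per)
    if rng is None:
        m = np.round(n * phi).astype(int)
    else:
        m = rng.binomial(n, phi)
    return ComboCounts(d1=d1, d2=d2, n=n, m=m, t=1.0)
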