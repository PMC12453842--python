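import numpy as np
import pytest

from crowfs.data import FeatureMatrix, apply_zscore, fit_zscore
from crowfs.fitness import make_context
from crowfs.simulate import SyntheticSpec, generate


@pytest.fixture
def small_table() -> FeatureMatrix:
    """Tiny deterministic 6x3 table with two classes."""
    rng = np.random.default_rng(42)
    values = rng.normal(size=(6, 3))
    labels = np.array([0, 1, 0, 1, 0, 1])
    return FeatureMatrix(values=values, labels=labels,
                         feature_names=["a", "b", "c"])


@pytest.fixture(scope="session")
def oracle_problem():
    """10-feature problem (3 informative, effect size 2, n=200) with a
    z-scored table and a fitness context on all ten features — small enough
    to enumerate every non-empty mask."""
    spec = SyntheticSpec(n_samples=200, n_classes=4, n_informative=3,
                         n_redundant=0, n_noise=7, effect_size=2.0, seed=7)
    fm, truth = generate(spec)
    fmz = apply_zscore(fit_zscore(fm), fm)
    ctx = make_context(fmz, np.arange(fm.n_features), seed=7)
    return fmz, truth, ctx


def enumerate_optimum(ctx):
    """Independent exhaustive oracle: best fitness over all non-empty masks."""
    from crowfs.fitness import fitness
    n = ctx.L_t
    best = None
    for bits in range(1, 2 ** n):
        mask = np.array([(bits >> b) & 1 for b in range(n)], dtype=bool)
        f = fitness(ctx, mask)
        if best is None or f.total > best.total:
            best = f
    return best
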