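import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crocpred import GenotypeDataset

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def brute_force_auc(scores, phenotype) -> float:
    """Independent pairwise Mann-Whitney oracle: explicit double loop."""
    scores = np.asarray(scores, dtype=float)
    case = scores[np.asarray(phenotype) == 1]
    ctrl = scores[np.asarray(phenotype) == 0]
    total = 0.0
    for a in case:
        for b in ctrl:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(case) * len(ctrl))


def make_random_dataset(rng, n=40, m=6, maf_low=0.05, maf_high=0.4):
    """A random dataset with both classes guaranteed present."""
    maf = rng.uniform(maf_low, maf_high, size=m)
    geno = rng.binomial(2, maf, size=(n, m)).astype(np.int8)
    phen = rng.integers(0, 2, size=n).astype(np.int8)
    phen[0], phen[1] = 1, 0
    return GenotypeDataset(geno, phen, [f"v{i}" for i in range(m)])


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)
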