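import numpy as np
import pandas as pd
import pytest

from mtsccar import StudyDataset, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_dataset(n=30, p=15, q=10, M=2, C=3, seed=0):
    """Small random (unstructured) study dataset for algebraic checks."""
    rng = np.random.default_rng(seed)
    subj = [f"S{i}" for i in range(n)]
    geno = pd.DataFrame(
        rng.standard_normal((n, p)), index=subj,
        columns=[f"rs{i}" for i in range(p)],
    )
    mods = [
        pd.DataFrame(
            rng.standard_normal((n, q)), index=subj,
            columns=[f"roi{j}" for j in range(q)],
        )
        for _ in range(M)
    ]
    cog = pd.DataFrame(
        rng.standard_normal((n, C)), index=subj,
        columns=[f"score{c}" for c in range(C)],
    )
    return StudyDataset(genotypes=geno, modalities=mods, cognitive=cog)


@pytest.fixture
def small_dataset():
    return random_dataset()


@pytest.fixture(scope="session")
def unit_noise_sim():
    """Reference synthetic design at unit noise (n=90, p=100, q=90, M=2)."""
    return simulate(sigma2=1.0, seed=0)
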