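import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from popgen.variants_io import GenotypeMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

# call-code shorthand used throughout the tests
R, A, H, M = 0, 1, 2, -1


def make_gm(
    calls,
    chrom="chr1",
    positions=None,
    samples=None,
    depth=None,
    gq=None,
    multiallelic=None,
):
    """Build a GenotypeMatrix from a nested list of call codes (sites x samples)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_samples = calls.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10
    if samples is None:
        samples = [f"s{i+1}" for i in range(n_samples)]
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * n_sites,
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": ["A"] * n_sites,
            "alt": ["T"] * n_sites,
            "id": ["."] * n_sites,
            "multiallelic": multiallelic if multiallelic is not None else [False] * n_sites,
        }
    )
    return GenotypeMatrix(
        sites=sites,
        samples=list(samples),
        calls=calls,
        depth=None if depth is None else np.asarray(depth, dtype=np.int32),
        gq=None if gq is None else np.asarray(gq, dtype=np.int32),
    )


@pytest.fixture(scope="session")
def qingke_dataset():
    """One modest qingke-preset simulation shared by read-only tests."""
    from popgen import synthetic_data as sd

    config = sd.preset_qingke(n_loci=40, locus_length=10_000)
    gm, truth = sd.simulate(config, seed=20_240)
    return gm, truth


@pytest.fixture()
def group_indices():
    def _index(gm, truth):
        return {
            g: np.array([i for i, s in enumerate(gm.samples) if truth.labels[s] == g])
            for g in set(truth.labels.values())
        }

    return _index
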