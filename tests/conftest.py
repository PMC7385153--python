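import numpy as np
import pandas as pd
import pytest

from hrdpipe.catalog import CONTEXT_96, TrinucleotideCatalog
from hrdpipe.genome import default_synthetic_genome
from hrdpipe.reference import synthetic_reference_signatures
from hrdpipe.syndata import SimConfig, simulate_cohort

TRUTH_SIG_IDS = ("COSMIC 1", "COSMIC 2", "COSMIC 3", "COSMIC 6")


@pytest.fixture(scope="session")
def reference_sigs():
    return synthetic_reference_signatures()


@pytest.fixture(scope="session")
def truth_profiles(reference_sigs):
    """The four generating profiles used by the default simulator."""
    idx = [reference_sigs.names.index(s) for s in TRUTH_SIG_IDS]
    return reference_sigs.profiles[idx]


@pytest.fixture(scope="session")
def genome():
    return default_synthetic_genome()


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-sample synthetic cohort shared across read-only tests."""
    return simulate_cohort(SimConfig(n_samples=30, seed=11))


def catalog_from_mixtures(weights, n_mutations, profiles, seed):
    """Multinomial draw of context counts for given per-sample weights."""
    rng = np.random.default_rng(seed)
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    n_mutations = np.broadcast_to(np.asarray(n_mutations), (weights.shape[0],))
    rows = [
        rng.multinomial(int(n), w @ profiles / (w @ profiles).sum())
        for w, n in zip(weights, n_mutations)
    ]
    counts = pd.DataFrame(
        np.array(rows),
        index=pd.Index([f"S{i}" for i in range(len(rows))], name="sample"),
        columns=list(CONTEXT_96),
    )
    return TrinucleotideCatalog(counts)


@pytest.fixture(scope="session")
def mixture_catalog_factory():
    return catalog_from_mixtures
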