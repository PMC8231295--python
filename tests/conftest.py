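import numpy as np
import pytest

import daisygen as dg


@pytest.fixture(scope="session")
def structured_ds():
    """3 groups x 3 localities x 8 individuals, moderate divergence."""
    cfg = dg.SimConfig(
        n_groups=3,
        n_localities_per_group=3,
        n_individuals_per_locality=8,
        n_snps=800,
        fst_between_groups=0.3,
        fst_between_localities=0.05,
        inbreeding_fis=0.15,
        missing_rate=0.03,
        seed=101,
    )
    return dg.simulate_structured_genotypes(cfg)


@pytest.fixture(scope="session")
def panmictic_ds():
    """Single unstructured HWE population split over two nominal localities."""
    cfg = dg.SimConfig(
        n_groups=1,
        n_localities_per_group=2,
        n_individuals_per_locality=30,
        n_snps=600,
        fst_between_groups=0.0,
        fst_between_localities=0.0,
        inbreeding_fis=0.0,
        missing_rate=0.0,
        seed=102,
    )
    return dg.simulate_structured_genotypes(cfg)


def make_dataset(calls, localities=None, groups=None):
    """Wrap a raw calls matrix in a GenotypeDataset with minimal metadata."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    return dg.GenotypeDataset(
        calls=calls,
        sample_ids=np.array([f"s{i}" for i in range(n)]),
        locality_labels=np.asarray(localities) if localities is not None else np.array(["loc"] * n),
        group_labels=np.asarray(groups) if groups is not None else np.array([], dtype=str),
        coordinates=np.zeros((n, 2)),
        site_ids=np.array([f"m{j}" for j in range(m)]),
    )
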