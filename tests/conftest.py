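import numpy as np
import pandas as pd
import pytest

from sweepscan.core import (FRESHWATER, MIGRATORY, GenotypeDataset,
                            SampleGrouping)


def make_dataset(dosages, chrom="chr1", positions=None, sample_ids=None,
                 refs=None, alts=None):
    """Build a GenotypeDataset from a samples x sites dosage array."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_samples, n_sites = dosages.shape
    if positions is None:
        positions = list(range(100, 100 + 10 * n_sites, 10))
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_samples)]
    sites = pd.DataFrame({
        "chrom": [chrom] * n_sites,
        "pos": positions,
        "ref": refs if refs is not None else ["A"] * n_sites,
        "alt": alts if alts is not None else ["G"] * n_sites,
    })
    return GenotypeDataset(sample_ids=sample_ids, sites=sites, dosages=dosages)


def make_grouping(ds, n_first_group):
    """First n samples migratory, the rest freshwater."""
    assignment = {}
    for i, s in enumerate(ds.sample_ids):
        assignment[s] = MIGRATORY if i < n_first_group else FRESHWATER
    return SampleGrouping(assignment=assignment)


def random_dataset(rng, n_samples, n_sites, missing_rate=0.0, chrom="chr1"):
    p = rng.uniform(0.05, 0.95, size=n_sites)
    dosages = rng.binomial(2, p, size=(n_samples, n_sites)).astype(np.int8)
    if missing_rate:
        mask = rng.random(dosages.shape) < missing_rate
        dosages[mask] = -1
    positions = np.sort(rng.choice(np.arange(1, 100 * n_sites + 1),
                                   size=n_sites, replace=False))
    return make_dataset(dosages, chrom=chrom, positions=positions.tolist())


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
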