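import numpy as np
import pytest

from hybridzone.datamodel import GenotypeMatrix, Group, LocusMeta, SampleMeta


def make_matrix(calls, groups=None, depth=None, locus_ids=None):
    """Build a GenotypeMatrix from a nested list of calls (-1 = missing)."""
    calls = np.asarray(calls, dtype=np.int16)
    n_samples, n_loci = calls.shape
    groups = groups or [None] * n_samples
    samples = [
        SampleMeta(f"S{i:03d}", group=g) for i, g in enumerate(groups)
    ]
    loci = [
        LocusMeta(locus_ids[j] if locus_ids else f"L{j:03d}")
        for j in range(n_loci)
    ]
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls, depth=depth)


A = Group.PARENTAL_A
B = Group.PARENTAL_B
H = Group.ADMIXED_CANDIDATE


@pytest.fixture(scope="session")
def fixed_panel_dataset():
    """Small simulated dataset with a 50-locus fully diagnostic panel."""
    from hybridzone.simulate import SimConfig, simulate_dataset

    config = SimConfig(
        seed=42,
        n_loci=50,
        frac_fixed=1.0,
        frac_high=0.0,
        n_parental_a=20,
        n_parental_b=20,
        class_counts={"F1": 5, "F2": 5, "BC1_A": 5, "BC1_B": 5},
        missing_rate=0.02,
    )
    return simulate_dataset(config)
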