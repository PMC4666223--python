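import numpy as np
import pytest

from dmrank.io import MethylationDataset, Region, RegionSet


@pytest.fixture
def toy_dataset():
    """4 probes x 4 samples, groups A/B of 2, deterministic betas."""
    rng = np.random.default_rng(42)
    beta = rng.uniform(0.1, 0.9, size=(4, 4))
    return MethylationDataset(
        probe_ids=np.array(["p1", "p2", "p3", "p4"], dtype=object),
        chrom=np.array(["chr1", "chr1", "chr1", "chr2"], dtype=object),
        pos=np.array([100, 200, 300, 50]),
        beta=beta,
        samples=["s1", "s2", "s3", "s4"],
        groups={"s1": "A", "s2": "A", "s3": "B", "s4": "B"},
    )


@pytest.fixture
def toy_regions():
    return RegionSet(
        [
            Region("chr1", 0, 250, "r1"),
            Region("chr1", 250, 500, "r2", gene_name="GENE1"),
            Region("chr2", 0, 100, "r3", gene_name="GENE2"),
        ]
    )


def make_dataset(beta, groups_per_sample, chrom=None, pos=None):
    """Helper: dataset from a beta matrix and a list of group labels."""
    beta = np.asarray(beta, dtype=float)
    n_probes, n_samples = beta.shape
    samples = [f"s{i}" for i in range(n_samples)]
    return MethylationDataset(
        probe_ids=np.array([f"p{i}" for i in range(n_probes)], dtype=object),
        chrom=np.array(chrom if chrom is not None else ["chr1"] * n_probes,
                       dtype=object),
        pos=np.array(pos if pos is not None else np.arange(n_probes) * 100 + 100),
        beta=beta,
        samples=samples,
        groups=dict(zip(samples, groups_per_sample)),
    )
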