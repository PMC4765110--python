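import numpy as np
import pytest

from orthoscreen.cluster_io import Alignment, Cluster, SequenceRecord
from orthoscreen.evolver import generate_pools
from orthoscreen.features import feature_table

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def random_cluster(rng: np.random.Generator, n: int = 3, length: int = 30,
                   cluster_id: str = "c") -> Cluster:
    members = [
        SequenceRecord(id=f"{cluster_id}_s{i}",
                       residues=random_sequence(rng, length + int(rng.integers(0, 5))))
        for i in range(n)
    ]
    return Cluster(cluster_id=cluster_id, members=members)


def pair_alignment(row_a: str, row_b: str) -> Alignment:
    return Alignment(rows=(SequenceRecord("a", row_a), SequenceRecord("b", row_b)))


@pytest.fixture(scope="session")
def tiny_pools():
    """Small generated ground-truth pools (short families, small clusters)."""
    return generate_pools(
        n_h=15,
        n_nh_random=15,
        n_nh_evolved_each=15,
        seed=11,
        size_lambda=5.0,
        root_length_range=(40, 70),
    )


@pytest.fixture(scope="session")
def tiny_feature_table(tiny_pools):
    clusters = [c for pool in tiny_pools.values() for c in pool]
    return feature_table(clusters)
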