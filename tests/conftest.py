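import pandas as pd
import pytest

from decaywood.tables_io import CountMatrix, SampleMetadata, TaxonomyMap
from decaywood.synthetic_data import simulate_decay_study


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """Three samples x four OTUs with easy hand-checkable numbers."""
    df = pd.DataFrame(
        [[3, 5, 0, 2],
         [1, 0, 4, 4],
         [0, 0, 7, 3]],
        index=["s1", "s2", "s3"],
        columns=["otu1", "otu2", "otu3", "otu4"],
    )
    return CountMatrix(df)


@pytest.fixture
def tiny_taxonomy() -> TaxonomyMap:
    return TaxonomyMap({
        "otu1": {"kingdom": "Bacteria", "phylum": "P1", "class": "C1",
                 "order": "O1", "family": "F1", "genus": "Burkholderia"},
        "otu2": {"kingdom": "Bacteria", "phylum": "P1", "class": "C1",
                 "order": "O1", "family": "F1", "genus": "Burkholderia"},
        "otu3": {"kingdom": "Bacteria", "phylum": "P1", "class": "C1",
                 "order": "O2", "family": "F2", "genus": "Pseudomonas"},
        "otu4": {"kingdom": "Bacteria", "phylum": "P1", "class": "C1",
                 "order": "O2", "family": "unclassified",
                 "genus": "unclassified"},
    })


@pytest.fixture
def tiny_metadata() -> SampleMetadata:
    df = pd.DataFrame({
        "wood_density": [0.45, 0.45, 0.2],
        "pH": [4.9, 4.8, 4.1],
        "moisture": [31.0, 32.0, 140.0],
        "c_n_ratio": [1000.0, 980.0, 260.0],
        "ergosterol": [14.0, 15.0, 46.0],
        "replicate_of": ["w1", "w1", "w2"],
    }, index=["s1", "s2", "s3"])
    return SampleMetadata(df)


@pytest.fixture(scope="session")
def small_study():
    """A reduced decay study shared by slower integration tests."""
    return simulate_decay_study(n_parents=10, reps=3, seed=7)


def partitions(n: int, max_part: int | None = None):
    """All integer partitions of n (descending parts)."""
    if max_part is None:
        max_part = n
    if n == 0:
        yield []
        return
    for k in range(min(n, max_part), 0, -1):
        for rest in partitions(n - k, k):
            yield [k] + rest


@pytest.fixture(scope="session")
def partition_fn():
    return partitions
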