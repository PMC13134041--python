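import numpy as np
import pandas as pd
import pytest

from microterroir import FeatureTable, SampleMetadata, TaxonomyTable


def make_table(counts, sample_ids=None, feature_ids=None) -> FeatureTable:
    counts = np.asarray(counts)
    n, m = counts.shape
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n)]
    feature_ids = feature_ids or [f"f{j + 1}" for j in range(m)]
    return FeatureTable(pd.DataFrame(counts, index=sample_ids, columns=feature_ids))


@pytest.fixture
def toy_table() -> FeatureTable:
    return make_table([[3, 0, 1, 5], [1, 2, 0, 5]])


@pytest.fixture
def toy_metadata() -> SampleMetadata:
    df = pd.DataFrame({
        "vineyard": ["A", "A", "B", "B"],
        "cultivar": ["Zin", "Car", "Zin", "Zin"],
        "latitude": [38.0, 38.0001, 38.01, 38.0101],
        "longitude": [-122.0, -122.0, -122.01, -122.0101],
        "row": [1, 2, 1, 2],
        "vine": [1, 1, 1, 1],
    }, index=["s1", "s2", "s3", "s4"])
    return SampleMetadata(df)


@pytest.fixture
def toy_taxonomy() -> TaxonomyTable:
    return TaxonomyTable({
        "f1": "d__Bacteria; p__P1; c__C1; o__O1; f__F1; g__G1; s__S1",
        "f2": "d__Bacteria; p__P2; c__C2; o__O2; f__F2; g__G2; s__S2",
        "f3": "d__Bacteria; p__P3; c__C3; o__O3; f__F3; g__G3; s__S3",
        "f4": "d__Bacteria; p__P4; c__C4; o__O4; f__F4; g__G4; s__S4",
    })
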