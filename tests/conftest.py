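import numpy as np
import pytest

from microsel.compositional import ClrMatrix
from microsel.io import CountTable, SampleMetadata
from microsel.splsda import encode_response


@pytest.fixture
def tiny_table() -> CountTable:
    """3 OTUs x 2 samples with taxonomy."""
    return CountTable(
        sample_ids=["S1", "S2"],
        otu_ids=["OTU1", "OTU2", "OTU3"],
        counts=np.array([[5, 0, 3], [2, 7, 1]]),
        taxonomy={
            "OTU1": "k__Bacteria; p__Firmicutes",
            "OTU2": "k__Bacteria; p__Bacteroidetes",
            "OTU3": "k__Bacteria",
        },
    )


@pytest.fixture
def tiny_meta() -> SampleMetadata:
    return SampleMetadata(
        sample_ids=["S1", "S2", "S3"],
        columns={"Helminth": ["Pos", "Neg", "NA"], "Village": ["A", "B", "A"]},
    )


@pytest.fixture
def worked_X() -> ClrMatrix:
    """The 4-sample, 3-feature hand-computable instance."""
    return ClrMatrix(
        sample_ids=["a", "b", "c", "d"],
        otu_ids=["f1", "f2", "f3"],
        values=np.array(
            [[2.0, 0.0, 1.0], [1.0, 1.0, -1.0], [-1.0, -1.0, 1.0],
             [-2.0, 0.0, -1.0]]
        ),
    )


@pytest.fixture
def worked_Y():
    return encode_response(["Pos", "Pos", "Neg", "Neg"])


def random_clr_instance(rng: np.random.Generator, n: int = 20, p: int = 8):
    """A random centered instance with binary labels for property tests."""
    X = ClrMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        otu_ids=[f"f{j}" for j in range(p)],
        values=rng.normal(size=(n, p)),
    )
    labels = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    return X, labels
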