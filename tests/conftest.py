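import numpy as np
import pytest

from splicescan.encoding_io import GeneRecord, WindowSpec
from splicescan.synthetic_genome import SyntheticGenomeConfig, generate, make_fixture


@pytest.fixture(scope="session")
def unit_genes():
    """Five small synthetic genes with planted splice signals."""
    return make_fixture("unit")


@pytest.fixture(scope="session")
def five_gene_fixture():
    return generate(
        SyntheticGenomeConfig(
            n_genes=5, gene_length_range=(400, 900), exons_per_gene_range=(2, 4), seed=7
        )
    )


@pytest.fixture
def toy_gene():
    return GeneRecord(
        id="toy",
        sequence="ACGTACGTTG",
        donor_sites=[3],
        acceptor_sites=[7],
    )


@pytest.fixture
def small_spec():
    return WindowSpec(2)


class StubModel:
    """Deterministic probability function of the window contents.

    Produces a softmax over (#A bases, #C bases, a constant) so that the
    output depends on the window and rows sum to one.
    """

    def __init__(self, window_length: int):
        self.input_length = window_length

    def predict(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float64)
        a = batch[:, :, 0].sum(axis=1)
        c = batch[:, :, 1].sum(axis=1)
        logits = np.stack([a, c, np.full(len(batch), 2.0)], axis=1) / 4.0
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


@pytest.fixture
def stub_model_factory():
    return StubModel
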