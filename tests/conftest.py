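import pytest

from patatinpred import SyntheticConfig, encode_dataset, generate


@pytest.fixture(scope="session")
def separable_small():
    """Balanced planted-signal dataset, small enough for fast unit tests."""
    return generate(SyntheticConfig(n_per_class=60, seed=11))


@pytest.fixture(scope="session")
def separable_small_dpc(separable_small):
    return encode_dataset(separable_small, "DPC")


@pytest.fixture(scope="session")
def null_small():
    """Exchangeable (enrichment 0) dataset for chance-level checks."""
    return generate(SyntheticConfig(n_per_class=60, enrichment=0.0, seed=11))


@pytest.fixture()
def toy_fasta(tmp_path):
    path = tmp_path / "toy.fasta"
    path.write_text(">a\nACDE\n>b\nGGGG\n")
    return path
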