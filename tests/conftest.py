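import pytest

from contigdedup.synthetic import SyntheticDataset, generate_dataset


@pytest.fixture(scope="session")
def dataset() -> SyntheticDataset:
    """One default-preset synthetic study, shared across tests."""
    return generate_dataset(seed=0)


@pytest.fixture
def fasta_file(tmp_path):
    def _write(entries, name="test.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for header, seq in entries:
                fh.write(f">{header}\n{seq}\n")
        return path

    return _write
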