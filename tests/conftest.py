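import pytest

from immunopep import bundled_mask_table, load_published_model


@pytest.fixture(scope="session")
def published_model():
    return load_published_model()


@pytest.fixture(scope="session")
def masks():
    return bundled_mask_table()


@pytest.fixture()
def peptide_table(tmp_path):
    """Factory writing a TSV peptide table and returning its path."""

    def write(rows, header="sequence\tallele\thost\tlabel\taffinity_nM\tentry_count",
              name="peptides.tsv"):
        path = tmp_path / name
        path.write_text("\n".join([header, *rows]) + "\n")
        return path

    return write
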