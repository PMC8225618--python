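import pytest

from arvquant import build_toy_ar_model


@pytest.fixture(scope="session")
def toy_model():
    return build_toy_ar_model()


@pytest.fixture()
def sam_file(tmp_path):
    """Write SAM text to a temp file and return its path."""

    def _write(text, name="reads.sam"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write
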