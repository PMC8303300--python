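import numpy as np
import pandas as pd
import pytest

from hgsoctype import CohortConfig, ExpressionMatrix, Unit, generate


@pytest.fixture
def tiny_tpm():
    """3-gene x 2-sample TPM matrix (proportion columns scaled to 1e6)."""
    df = pd.DataFrame(
        {"s1": [200000.0, 300000.0, 500000.0], "s2": [100000.0, 400000.0, 500000.0]},
        index=["A", "B", "C"],
    )
    return ExpressionMatrix(df, Unit.TPM)


@pytest.fixture
def write_tsv(tmp_path):
    def _write(name, text):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort reused across read-only tests."""
    return generate(CohortConfig(seed=11))


def constant_panel_matrix(genes, samples, value):
    """TPM-tagged matrix with every entry equal to ``value`` (sums unchecked)."""
    df = pd.DataFrame(value, index=list(genes), columns=list(samples), dtype=float)
    return ExpressionMatrix(df, Unit.TPM, _check_tpm_sums=False)
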