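import numpy as np
import pytest

from isopick.averagine import build_tid_table, fit_most_likely_model, get_residue
from isopick.pipeline import prepare_models


@pytest.fixture(scope="session")
def ave_models():
    """Averagine TID table + most-likely model up to 20 kDa."""
    return prepare_models(("ave",), 20000.0)


@pytest.fixture(scope="session")
def ave_models_170k():
    """Averagine table extended to 170 kDa (low-resolution/high-mass cases)."""
    return prepare_models(("ave",), 170000.0)


@pytest.fixture(scope="session")
def leu_table():
    return build_tid_table(get_residue("leu"), 20000.0)


@pytest.fixture(scope="session")
def leu_model(leu_table):
    return fit_most_likely_model(leu_table)
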