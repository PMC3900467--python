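import warnings

import numpy as np
import pytest

from sarmap.chem_features import FeatureTable
from sarmap.core_data import BioactivityMatrix, CompoundInstance, binarize
from sarmap.synthetic import SyntheticConfig, generate_panel


def make_matrix(values, targets=None, compounds=None, concentrations=(1.0, 10.0)):
    """Small panel from a 2D array; columns cycle compound x concentration."""
    values = np.asarray(values, dtype=float)
    n_t, n_i = values.shape
    assert n_i % len(concentrations) == 0
    n_c = n_i // len(concentrations)
    targets = targets or [f"T{i}" for i in range(n_t)]
    compounds = compounds or [f"c{i}" for i in range(n_c)]
    instances = [CompoundInstance(c, conc) for c in compounds
                 for conc in concentrations]
    return BioactivityMatrix(list(targets), instances, values)


def make_calls(bools, **kw):
    """ActivityCalls from a 2D boolean array (via a 0/100 value matrix)."""
    vals = np.where(np.asarray(bools, dtype=bool), 100.0, 0.0)
    return binarize(make_matrix(vals, **kw))


@pytest.fixture(scope="session")
def default_panel():
    """The default synthetic panel: 6 x 8 clustered targets, 3 sparse,
    1 zero-active, 150 compounds at 1 and 10 uM."""
    return generate_panel(SyntheticConfig())


@pytest.fixture(scope="session")
def default_calls(default_panel):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return binarize(default_panel.matrix)


@pytest.fixture()
def toy_feature_table():
    return FeatureTable({
        "c1": frozenset({"f1", "f2"}),
        "c2": frozenset({"f1"}),
        "c3": frozenset({"f2"}),
    })
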