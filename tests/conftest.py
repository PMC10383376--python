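import numpy as np
import pytest

from mixcarc.chem import synth_library
from mixcarc.descriptors import compute_single_descriptors, filter_complete


@pytest.fixture(scope="session")
def small_library():
    """15 synthetic chemicals: 5 per class, class 2 TD50-annotated."""
    return synth_library(5, 5, 5, seed=42)


@pytest.fixture(scope="session")
def small_descriptors(small_library):
    return filter_complete(compute_single_descriptors(small_library))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def write_chemicals_csv(path, rows, header=("chem_id", "smiles", "source", "source_group", "td50", "concentration")):
    """Write a minimal chemicals CSV from tuples following ``header`` order."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)
    return path
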