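import numpy as np
import pytest

import nbscreen as nbs
from nbscreen import datasets


@pytest.fixture(scope="session")
def panel():
    """(definitions, cutoff ranges) of the shipped 74-indicator panel."""
    return nbs.load_cutoff_table()


@pytest.fixture(scope="session")
def defs(panel):
    return panel[0]


@pytest.fixture(scope="session")
def ranges(panel):
    return panel[1]


@pytest.fixture(scope="session")
def rules(defs):
    return nbs.load_rules(defs=defs)


@pytest.fixture(scope="session")
def dists(ranges, defs):
    return nbs.calibrate_normal_distributions(ranges, defs)


@pytest.fixture(scope="session")
def confirmed_cases():
    return datasets.load_confirmed_cases()


def random_panels(defs, ranges, n, seed, p_missing=0.0):
    """Random raw panels spanning normal and abnormal values (uniform on [0, 3*high]).

    Yields PanelRecords with raw/combined values only; with probability
    ``p_missing`` a marker is dropped, exercising absent-operand paths.
    """
    rng = np.random.default_rng(seed)
    by_marker = {r.marker: r for r in ranges}
    measured = [d.name for d in defs if d.kind != "ratio"]
    out = []
    for i in range(n):
        values = {}
        for name in measured:
            if p_missing and rng.random() < p_missing:
                continue
            values[name] = rng.uniform(0.0, 3.0 * by_marker[name].high)
        out.append(nbs.PanelRecord(f"R{i}", values))
    return out
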