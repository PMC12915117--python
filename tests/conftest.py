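"""Shared fixtures: materials and small forward-simulated datasets.

The forward solves are session-scoped because they are the expensive part;
every test that needs a synthetic measurement reuses them.
"""

import numpy as np
import pytest

from tfm3d import materials as M
from tfm3d import synthetic as syn


@pytest.fixture(scope="session")
def table2():
    """Ogden constants of the substrate model (G0 = 0.4705 MPa, nu = 0.45)."""
    return M.TABLE_PDMS


@pytest.fixture(scope="session")
def avg_pdms():
    """Batch-average substrate model (G0 = 0.475 MPa, E = 1.38 MPa)."""
    return M.AVERAGE_PDMS


@pytest.fixture(scope="session")
def sphere_small():
    """Small frictionless sphere-indentation dataset (0.05 N, 17 mm ball).

    Window 1.8 mm half-width at 0.15 mm spacing inside a 4.2 mm half-width
    graded domain — big enough that the contact patch (~0.45 mm radius) and
    its decay fit, small enough to solve in well under a minute.
    """
    sc = syn.SyntheticScenario(kind="sphere_indent", net_force=0.05,
                               window_halfwidth=1.8, extent_halfwidth=4.2)
    grid, truth = syn.gen_sphere_indent(sc)
    return sc, grid, truth


@pytest.fixture(scope="session")
def plaque_small():
    """Plaque-pull dataset at the reference load (0.19 N at 15 degrees)."""
    sc = syn.SyntheticScenario(kind="plaque_pull", domain_halfwidth=2.1)
    grid, truth = syn.gen_plaque_pull(sc)
    return sc, grid, truth
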