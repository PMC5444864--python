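import numpy as np
import pandas as pd
import pytest

from spermlimit.model import EggLayingParams
from spermlimit.panel import GeneticMap, RILPanel

# the reference parameter set used across the model tests: an N2-like
# hermaphrodite laying ~260 eggs over ~4 days
BASE = EggLayingParams(k_o=5.0, k_f=2.6e-4, s_0=263.0)

#: coarse physiological grid shared by the equivalence/recovery tests
GRID_KO = np.linspace(1.0, 10.0, 5)
GRID_KF = np.geomspace(1e-4, 1e-3, 5)
GRID_S0 = np.linspace(100.0, 500.0, 4)


def param_grid():
    return [
        EggLayingParams(k_o=ko, k_f=kf, s_0=s0)
        for ko in GRID_KO
        for kf in GRID_KF
        for s0 in GRID_S0
    ]


@pytest.fixture(scope="session")
def base_params():
    return BASE


@pytest.fixture(scope="session")
def grid_params():
    return param_grid()


@pytest.fixture(scope="session")
def tiny_map():
    """Two chromosomes, three markers each, 10 cM spacing."""
    rows = []
    for chrom in ("I", "II"):
        for i in range(3):
            rows.append({"marker": f"c{chrom}_m{i:02d}", "chrom": chrom, "cM": 10.0 * i})
    return GeneticMap(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def hand_panel(tiny_map):
    """12 strains with hand-listed genotypes: every oracle test can redo the
    regressions with explicit normal-equation arithmetic."""
    geno = np.array(
        [
            [0, 0, 0, 0, 0, 0],
            [1, 1, 1, 1, 1, 1],
            [0, 0, 1, 1, 1, 0],
            [1, 1, 0, 0, 0, 1],
            [0, 1, 1, 0, 1, 1],
            [1, 0, 0, 1, 0, 0],
            [0, 0, 0, 1, 1, 1],
            [1, 1, 1, 0, 0, 0],
            [0, 1, 0, 0, 1, 0],
            [1, 0, 1, 1, 0, 1],
            [0, 0, 1, 0, 0, 1],
            [1, 1, 0, 1, 1, 0],
        ],
        dtype=np.int8,
    )
    frame = pd.DataFrame(
        geno,
        index=[f"RIL{i + 1:03d}" for i in range(12)],
        columns=tiny_map.markers,
    )
    return RILPanel(genotypes=frame, gmap=tiny_map)
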