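import numpy as np
import pandas as pd
import pytest

from stiffchrom import (
    ContactMap,
    SyntheticTruth,
    build_chain_layout,
    init_system,
    make_bins,
    plant_loops,
    run_simulation,
    synth_contact_map,
)
from stiffchrom.energy import EnergyModel
from stiffchrom.mapcore import dense_to_pixels


@pytest.fixture(scope="session")
def paper_layout():
    return build_chain_layout()


@pytest.fixture(scope="session")
def desk_layout(paper_layout):
    # desk-scale geometry: 400-bead chains preserving block proportions
    return paper_layout.scaled(0.1)


@pytest.fixture(scope="session")
def tiny_layout(paper_layout):
    # 40-bead chains for bookkeeping-only tests
    return paper_layout.scaled(0.01)


@pytest.fixture(scope="session")
def equilibrated_ensemble(desk_layout):
    """One moderately equilibrated 2-chain system with default energies."""
    ens = init_system(desk_layout, 2, 0.10, seed=42)
    return run_simulation(ens, EnergyModel(), 8000, sample_every=800, seed=43)


@pytest.fixture(scope="session")
def truth_plain():
    return SyntheticTruth()


@pytest.fixture(scope="session")
def truth_with_loops():
    return plant_loops(SyntheticTruth(), n_loops=40, seed=11)


@pytest.fixture(scope="session")
def synthetic_map(truth_with_loops):
    return synth_contact_map(truth_with_loops, depth=3e6, replicate_seed=1)


def map_from_dense(matrix, chromsizes=None, resolution=20_000):
    """Helper: wrap a dense symmetric matrix into a single-chrom ContactMap."""
    n = matrix.shape[0]
    if chromsizes is None:
        chromsizes = {"chr1": n * resolution}
    bins = make_bins(chromsizes, resolution)
    assert len(bins) == n
    return ContactMap(
        bins=bins, pixels=dense_to_pixels(np.triu(matrix)), resolution=resolution
    )


@pytest.fixture
def map_from_dense_factory():
    return map_from_dense


def loops_frame(rows):
    """Helper: loop table from (chromA,startA,endA,chromB,startB,endB,res,cond)."""
    return pd.DataFrame(
        rows,
        columns=[
            "chromA", "startA", "endA", "chromB", "startB", "endB",
            "resolution_bp", "source_condition",
        ],
    )


@pytest.fixture
def loops_frame_factory():
    return loops_frame
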