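import numpy as np
import pytest

from twinconn import CohortSpec, RegionTimeSeries, simulate_cohort
from twinconn.pipeline import ec_feature_table
from twinconn.prep import discard_initial_volumes


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def planted_cohort_spec(seed: int, n_regions: int = 20, n_per_group: int = 20,
                        weight: float = 0.4, n_edges: int = 9) -> CohortSpec:
    """Two-group cohort with `n_edges` disjoint directed couplings planted
    (+weight) in the SZ group; 0-based edge (2k, 2k+1)."""
    edges = {(2 * k, 2 * k + 1): weight for k in range(n_edges)}
    return CohortSpec(
        n_regions=n_regions,
        n_volumes=180,
        groups=(("HC", n_per_group), ("SZ", n_per_group)),
        group_coupling_deltas={"SZ": edges},
        seed=seed,
    )


def planted_edge_ids(n_edges: int = 9):
    """1-based region-id pairs of the edges planted by planted_cohort_spec."""
    return {(2 * k + 1, 2 * k + 2) for k in range(n_edges)}


def cohort_ec_table(spec: CohortSpec, n_discard: int = 10):
    """Simulate, discard initial volumes, and build the EC feature table."""
    subjects = [discard_initial_volumes(s, n_discard) for s in simulate_cohort(spec)]
    return ec_feature_table(subjects)


@pytest.fixture
def small_series(rng):
    return RegionTimeSeries(
        subject_id="s1", group="HC", data=rng.standard_normal((5, 170)), tr_seconds=2.0
    )
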