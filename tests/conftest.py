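import numpy as np
import pytest

import nanoagg as na


@pytest.fixture(scope="session")
def aggregate() -> na.Trajectory:
    """Full-size packed aggregate: 14 chains x 40 units, 12 dispersed guests,
    hydration shell; shared across tests (packing is the expensive step)."""
    return na.pack_aggregate(na.AggregateSpec(seed=7, hydration_shell=True, n_waters=300))


@pytest.fixture(scope="session")
def small_aggregate() -> na.Trajectory:
    """Cheap 4-chain aggregate for structural/plumbing tests."""
    # probe radii are comparable to the blob size at this scale, so the
    # density tolerance is relaxed: these tests exercise structure, not density
    return na.pack_aggregate(
        na.AggregateSpec(n_chains=4, n_units=10, n_guests=3, seed=11,
                         density_tolerance=0.5)
    )


@pytest.fixture(scope="session")
def host_group(aggregate) -> np.ndarray:
    return na.select(aggregate, tag="host")
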