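"""Shared fixtures.

The two-phase training runs and the propagation analyses are expensive, so
they are session-scoped: the end-to-end suite trains the scaled-down model
once per seed and the temporal suite reuses the first seed's model.
"""

import pytest

from segnet import protocols

SMOKE_SEEDS = (0, 1, 2)


@pytest.fixture(scope="session")
def smoke_runs():
    """Two-phase training of the scaled-down square/rectangle protocol."""
    return {seed: protocols.run_smoke_training(seed) for seed in SMOKE_SEEDS}


@pytest.fixture(scope="session")
def temporal_results(smoke_runs):
    """Propagation analyses on the first trained smoke model."""
    net, _ = smoke_runs[SMOKE_SEEDS[0]]
    return protocols.run_temporal_suite(net, seed=SMOKE_SEEDS[0])
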