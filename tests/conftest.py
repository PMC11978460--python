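import numpy as np
import pytest

from traplinesim.engine import BoutRecord
from traplinesim.environment import Environment, FeedingSite


def make_env(positions, arena_side=500.0, max_nectar=20.0,
             renewal_duration=500.0, layout="uniform"):
    sites = [
        FeedingSite(
            id=i,
            position=(float(x), float(y)),
            nectar=max_nectar,
            max_nectar=max_nectar,
            renewal_duration=renewal_duration,
        )
        for i, (x, y) in enumerate(positions)
    ]
    return Environment(arena_side=arena_side, sites=sites, layout_kind=layout)


def make_bout(sequence, bee_id=0, bout_index=1, nectar=100.0,
              t_start=0.0, t_end=200.0):
    visits = [(t_start + 10.0 * (k + 1), s) for k, s in enumerate(sequence)]
    return BoutRecord(
        bee_id=bee_id,
        bout_index=bout_index,
        visits=visits,
        nectar_collected=nectar,
        t_start=t_start,
        t_end=t_end,
    )


@pytest.fixture
def pentagon_env():
    """Five sites on a regular pentagon 60 m from the nest."""
    angles = 2 * np.pi * np.arange(5) / 5
    pos = 60.0 * np.column_stack([np.cos(angles), np.sin(angles)])
    return make_env(pos, arena_side=200.0)


@pytest.fixture
def uniform_env():
    from traplinesim.environment import generate_uniform

    return generate_uniform(25, 500.0, rng_seed=42)
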