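"""Multi-bee discrete-time foraging simulation.

Each bee repeatedly performs foraging bouts: it leaves the nest, feeds at
a succession of sites chosen by softmax over its learned transition
values (recently visited sites excluded by working memory), and returns
to the nest when its crop is full, its distance budget is spent, or no
destination remains; it then waits a fixed time before the next bout.
Bees compete only through nectar depletion of the shared sites.

Time is discretized with step ``dt`` (1 s by default): travel over
distance d takes ``ceil(d / (speed * dt)) * dt`` and sites refill
linearly each step. The implementation is event-driven — between feeding
events a site's linear refill is integrated in closed form, which is
exactly equivalent to stepping the renewal every ``dt`` with depletion
applied before renewal within a step — so runtime scales with the number
of visits, not with the horizon.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .cognition import (
    BeeParams,
    NoAllowedDestination,
    WorkingMemory,
    build_discovery_matrix,
    choice_probabilities,
    choose_next,
    q_init,
)
from .environment import ConfigurationError, Environment
from .seeds import derive_seed

__all__ = [
    "SimulationConfig",
    "BoutRecord",
    "SimulationResult",
    "run_simulation",
    "arrive_and_feed",
    "should_end_bout",
    "bouts_to_frame",
    "frame_to_sequences",
]

logger = logging.getLogger(__name__)

NEST = -1  # sentinel for the nest in visit/transition logs (site ids are >= 0)

# event kinds, processed via a time-ordered heap with random tie-breaking
_DEPART, _ARRIVE_SITE, _ARRIVE_NEST = 0, 1, 2


@dataclass
class SimulationConfig:
    """Bundle of everything one simulation needs."""

    env: Environment
    params: BeeParams = field(default_factory=BeeParams)
    n_bees: int = 1
    horizon: float = 25200.0  # 7 h of foraging
    dt: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bees < 1:
            raise ConfigurationError(f"n_bees must be >= 1, got {self.n_bees}")
        if self.horizon <= 0:
            raise ConfigurationError(f"horizon must be > 0, got {self.horizon}")
        if self.dt <= 0:
            raise ConfigurationError(f"dt must be > 0, got {self.dt}")


@dataclass
class BoutRecord:
    """One completed foraging bout of one bee.

    ``bout_index`` is 1-based (the first completed bout is 1), matching
    how reporting bouts are counted in sweeps.
    """

    bee_id: int
    bout_index: int
    visits: list[tuple[float, int]]  # (arrival time, site id)
    nectar_collected: float
    t_start: float
    t_end: float

    @property
    def visit_sequence(self) -> list[int]:
        """Ordered site ids of the bout (nest entries not stored)."""
        return [site for _, site in self.visits]

    @property
    def bout_duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class SimulationResult:
    config: SimulationConfig
    bouts: list[BoutRecord]
    q_tables: dict[int, np.ndarray]  # per bee, axis: 0 = nest, j+1 = site j
    transitions: dict[int, list[tuple[float, int, int, float]]]  # (t, from, to, v)
    final_nectar: np.ndarray
    ledger: pd.DataFrame  # per-site initial / renewed / collected / final

    def bouts_for(self, bee_id: int) -> list[BoutRecord]:
        return sorted(
            (b for b in self.bouts if b.bee_id == bee_id),
            key=lambda b: b.bout_index,
        )


class _Bee:
    __slots__ = (
        "id", "rng", "q", "wm", "prev_idx", "crop", "bout_distance",
        "bout_index", "bout_start", "visits", "nectar_this_bout",
        "transitions",
    )

    def __init__(self, bee_id: int, q0: np.ndarray, span: float, rng) -> None:
        self.id = bee_id
        self.rng = rng
        self.q = q0.copy()
        self.wm = WorkingMemory(span)
        self.prev_idx = 0  # matrix index of current/previous location
        self.crop = 0.0
        self.bout_distance = 0.0
        self.bout_index = 0  # completed bouts
        self.bout_start = 0.0
        self.visits: list[tuple[float, int]] = []
        self.nectar_this_bout = 0.0
        self.transitions: list[tuple[float, int, int, float]] = []


def arrive_and_feed(
    bee_crop: float,
    crop_capacity: float,
    site_nectar: float,
) -> tuple[float, float, float]:
    """Feeding rule at a site: collect ``min(standing crop, crop space)``.

    Returns ``(collected, new_bee_crop, new_site_nectar)``. Kept as a
    pure function so the depletion arithmetic is testable in isolation;
    the engine applies it together with the learning update.
    """
    collected = min(site_nectar, crop_capacity - bee_crop)
    collected = max(collected, 0.0)
    return collected, bee_crop + collected, site_nectar - collected


def should_end_bout(
    crop: float,
    crop_capacity: float,
    bout_distance: float,
    max_bout_distance: float,
    any_allowed: bool,
) -> bool:
    """A bout ends when the crop is full, the distance budget is spent,
    or no destination remains outside the working-memory window."""
    return (
        crop >= crop_capacity
        or bout_distance >= max_bout_distance
        or not any_allowed
    )


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Run one simulation and return its complete event record.

    Deterministic under ``config.rng_seed``; each bee draws from its own
    seed-derived stream, so runs with different ``n_bees`` share the
    per-bee randomness of the bees they have in common.
    """
    env, p = config.env, config.params
    n = env.n_sites
    dt = config.dt

    pd_mat = build_discovery_matrix(env)
    q0 = q_init(pd_mat, env.sites[0].max_nectar)
    pos = np.vstack([np.asarray(env.nest_position, float), env.positions])
    dist = cdist(pos, pos)

    nectar = np.array([s.nectar for s in env.sites], dtype=float)
    initial = nectar.copy()
    nmax = np.array([s.max_nectar for s in env.sites], dtype=float)
    renew_dur = np.array([s.renewal_duration for s in env.sites], dtype=float)
    last_update = np.zeros(n)
    renewed = np.zeros(n)
    collected_tot = np.zeros(n)

    def bring_current(j: int, t: float) -> None:
        # closed-form linear refill since the site's last depletion;
        # identical to per-dt stepping with depletion-before-renewal
        if t > last_update[j]:
            inc = min(
                nmax[j] - nectar[j],
                nmax[j] * (t - last_update[j]) / renew_dur[j],
            )
            nectar[j] += inc
            renewed[j] += inc
            last_update[j] = t

    scheduler = np.random.default_rng(
        derive_seed(config.rng_seed, "scheduler")
    )
    bees = [
        _Bee(
            i,
            q0,
            p.wm_span,
            np.random.default_rng(derive_seed(config.rng_seed, f"bee:{i}")),
        )
        for i in range(config.n_bees)
    ]

    def travel_time(d: float) -> float:
        return max(dt, math.ceil(d / (p.speed * dt)) * dt)

    heap: list[tuple[float, float, int, int, int, int]] = []
    seq = 0

    def push(t: float, kind: int, bee_id: int, target: int) -> None:
        nonlocal seq
        heapq.heappush(heap, (t, scheduler.random(), seq, kind, bee_id, target))
        seq += 1

    def allowed_sites(bee: _Bee, t: float, origin_site: int | None) -> np.ndarray:
        mask = ~bee.wm.excluded_mask(t, n)
        if origin_site is not None:
            mask[origin_site] = False  # no self-transition
        return mask

    def choose_destination(bee: _Bee, t: float, origin_idx: int) -> int | None:
        origin_site = origin_idx - 1 if origin_idx >= 1 else None
        mask = allowed_sites(bee, t, origin_site)
        if not mask.any():
            return None
        probs = choice_probabilities(bee.q[origin_idx, 1:], p.beta, mask)
        return choose_next(probs, bee.rng)

    def start_transit(bee: _Bee, t: float, dest_site: int) -> None:
        d = dist[bee.prev_idx, dest_site + 1]
        bee.bout_distance += d
        push(t + travel_time(d), _ARRIVE_SITE, bee.id, dest_site)

    bouts: list[BoutRecord] = []

    # staggered departures, one timestep apart, in randomized order
    order = scheduler.permutation(config.n_bees)
    for rank, bee_id in enumerate(order):
        push(rank * dt, _DEPART, int(bee_id), -1)

    while heap:
        t, _, _, kind, bee_id, target = heapq.heappop(heap)
        if t > config.horizon:
            break
        bee = bees[bee_id]

        if kind == _DEPART:
            bee.crop = 0.0
            bee.bout_distance = 0.0
            bee.bout_start = t
            bee.visits = []
            bee.nectar_this_bout = 0.0
            bee.prev_idx = 0
            dest = choose_destination(bee, t, 0)
            if dest is None:
                # everything in working memory: wait one step and retry
                push(t + dt, _DEPART, bee_id, -1)
                continue
            start_transit(bee, t, dest)

        elif kind == _ARRIVE_SITE:
            j = target
            bring_current(j, t)
            standing = nectar[j]
            got, bee.crop, nectar[j] = arrive_and_feed(
                bee.crop, p.crop_capacity, standing
            )
            collected_tot[j] += got
            bee.nectar_this_bout += got
            reward = got if p.value_from_collected else standing
            v = reward * pd_mat[bee.prev_idx, j + 1]
            bee.q[bee.prev_idx, j + 1] += p.alpha * (v - bee.q[bee.prev_idx, j + 1])
            origin_site = bee.prev_idx - 1 if bee.prev_idx >= 1 else NEST
            bee.transitions.append((t, origin_site, j, v))
            bee.wm.record(j, t)
            bee.visits.append((t, j))
            bee.prev_idx = j + 1

            mask = allowed_sites(bee, t, j)
            if should_end_bout(
                bee.crop, p.crop_capacity, bee.bout_distance,
                p.max_bout_distance, bool(mask.any()),
            ):
                d = dist[bee.prev_idx, 0]
                bee.bout_distance += d
                push(t + travel_time(d), _ARRIVE_NEST, bee_id, -1)
            else:
                dest = choose_destination(bee, t, bee.prev_idx)
                if dest is None:  # unreachable given mask.any(), kept defensive
                    raise NoAllowedDestination
                start_transit(bee, t, dest)

        else:  # _ARRIVE_NEST
            # convexity of the update keeps Q within [0, n_max]
            assert bee.q.min() >= 0.0 and bee.q.max() <= nmax.max() + 1e-9
            bee.bout_index += 1
            bouts.append(
                BoutRecord(
                    bee_id=bee_id,
                    bout_index=bee.bout_index,
                    visits=list(bee.visits),
                    nectar_collected=bee.nectar_this_bout,
                    t_start=bee.bout_start,
                    t_end=t,
                )
            )
            bee.prev_idx = 0
            push(t + p.nest_wait, _DEPART, bee_id, -1)

    for j in range(n):
        bring_current(j, config.horizon)

    ledger = pd.DataFrame(
        {
            "site": np.arange(n),
            "initial": initial,
            "renewed": renewed,
            "collected": collected_tot,
            "final": nectar,
        }
    )
    logger.info(
        "simulation done: %d bees, %d bouts, %.1f ul collected",
        config.n_bees, len(bouts), collected_tot.sum(),
    )
    return SimulationResult(
        config=config,
        bouts=bouts,
        q_tables={b.id: b.q for b in bees},
        transitions={b.id: b.transitions for b in bees},
        final_nectar=nectar,
        ledger=ledger,
    )


def bouts_to_frame(bouts: list[BoutRecord]) -> pd.DataFrame:
    """Tabulate bout records (visit sequences as dash-delimited id strings)."""
    return pd.DataFrame(
        {
            "bee_id": [b.bee_id for b in bouts],
            "bout_index": [b.bout_index for b in bouts],
            "t_start": [b.t_start for b in bouts],
            "t_end": [b.t_end for b in bouts],
            "nectar_collected": [b.nectar_collected for b in bouts],
            "visit_sequence": [
                "-".join(str(s) for s in b.visit_sequence) for b in bouts
            ],
        }
    )


def frame_to_sequences(df: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`bouts_to_frame` for the visit sequences column."""
    out = df.copy()
    out["visit_sequence"] = [
        [int(x) for x in s.split("-")] if isinstance(s, str) and s else []
        for s in df["visit_sequence"]
    ]
    return out
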