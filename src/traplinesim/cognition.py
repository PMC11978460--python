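"""Bee cognition: valuation, reinforcement learning and decision-making.

Locations are indexed on a common axis: index 0 is the nest, index
``j + 1`` is feeding site ``j``. The discovery matrix, Q-table and
softmax all operate on this axis.

The model: on a realized transition A -> B the bee perceives a value

    v_t(A, B) = n_t(B) * p_d(A, B)

where ``n_t(B)`` is the standing crop at arrival and ``p_d(A, B)`` is a
row-normalized inverse-square-distance weight approximating the chance of
discovering B from A by random walk. Expected transition values start at
``Q0 = 1/2 * n_max * p_d`` and are updated by the one-step average

    Q_t = alpha * v_t + (1 - alpha) * Q_{t-1}.

Destinations are chosen by a softmax over the allowed (not recently
visited) sites, with sharpness beta: beta = 0 is uniform random choice,
large beta is greedy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .environment import ConfigurationError, Environment

__all__ = [
    "BeeParams",
    "WorkingMemory",
    "NoAllowedDestination",
    "build_discovery_matrix",
    "perceived_value",
    "q_init",
    "q_update",
    "choice_probabilities",
    "choose_next",
    "q_table_to_frame",
]


class NoAllowedDestination(Exception):
    """Every candidate destination is excluded (working memory covers all).

    Signalled to the engine, which responds by ending the bout (return to
    the nest) or postponing departure.
    """


@dataclass
class BeeParams:
    """Cognitive and physical parameters of a forager.

    Parameters
    ----------
    alpha
        Learning rate in [0, 1]; 0 disables learning (Q stays at Q0),
        1 replaces Q by the latest perceived value.
    beta
        Exploration-exploitation (softmax sharpness) parameter, >= 0.
    wm_span
        Working-memory span in seconds: a visited site is excluded from
        destination choices for this long after the visit.
    crop_capacity
        Maximal nectar load per bout, microlitres (five full site loads
        by default).
    speed
        Flight speed, metres per second (straight-line movement).
    max_bout_distance
        Maximal distance flown in one bout, metres; reaching it ends the
        bout.
    nest_wait
        Fixed time spent in the nest between bouts, seconds.
    value_from_collected
        If True, v_t uses the nectar actually collected rather than the
        standing crop at arrival (these differ when the crop is nearly
        full). Default False: standing crop.
    """

    alpha: float = 0.5
    beta: float = 20.0
    wm_span: float = 30.0
    crop_capacity: float = 100.0
    speed: float = 3.0
    max_bout_distance: float = 3000.0
    nest_wait: float = 300.0
    value_from_collected: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.beta < 0:
            raise ConfigurationError(f"beta must be >= 0, got {self.beta}")
        if self.wm_span < 0:
            raise ConfigurationError(f"wm_span must be >= 0, got {self.wm_span}")
        for name in ("crop_capacity", "speed", "max_bout_distance", "nest_wait"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(
                    f"{name} must be > 0, got {getattr(self, name)}"
                )


class WorkingMemory:
    """Short-term inhibition of return.

    Records the entry time of each visited site; a site visited at time
    ``t`` is excluded from choices at all times ``t'`` with
    ``t' - t < span`` (half-open window). The nest is never excluded.
    """

    def __init__(self, span: float) -> None:
        if span < 0:
            raise ConfigurationError(f"span must be >= 0, got {span}")
        self.span = float(span)
        self._last_visit: dict[int, float] = {}

    def record(self, site_id: int, time: float) -> None:
        self._last_visit[site_id] = time

    def is_excluded(self, site_id: int, time: float) -> bool:
        t = self._last_visit.get(site_id)
        return t is not None and (time - t) < self.span

    def excluded_mask(self, time: float, n_sites: int) -> np.ndarray:
        """Boolean mask over site ids (True = excluded at *time*)."""
        mask = np.zeros(n_sites, dtype=bool)
        if self.span > 0:
            for site_id, t in self._last_visit.items():
                if time - t < self.span:
                    mask[site_id] = True
        return mask


def build_discovery_matrix(env: Environment) -> np.ndarray:
    """Row-normalized inverse-square-distance matrix over nest + sites.

    Entry ``[a, b]`` is the discovery probability p_d from location a to
    location b (index 0 = nest, index j+1 = site j): proportional to
    ``1 / d(a, b)^2`` and normalized so every row sums to 1, with a zero
    diagonal (no self-transition).
    """
    pos = np.vstack([np.asarray(env.nest_position, dtype=float), env.positions])
    d = cdist(pos, pos)
    off = ~np.eye(len(pos), dtype=bool)
    if np.any(d[off] == 0.0):
        a, b = np.argwhere((d == 0.0) & off)[0]
        raise ConfigurationError(
            f"coincident locations {a} and {b} (distance 0); "
            "discovery probabilities are undefined"
        )
    with np.errstate(divide="ignore"):
        w = 1.0 / d**2
    np.fill_diagonal(w, 0.0)
    return w / w.sum(axis=1, keepdims=True)


def perceived_value(nectar_collected: float, p_d_entry: float) -> float:
    """Perceived transition value v = n_t(B) * p_d(A, B)."""
    if nectar_collected < 0:
        raise ValueError(f"nectar must be >= 0, got {nectar_collected}")
    if not 0.0 <= p_d_entry <= 1.0:
        raise ValueError(f"p_d entry must be in [0, 1], got {p_d_entry}")
    return nectar_collected * p_d_entry


def q_init(pd_matrix: np.ndarray, n_max: float) -> np.ndarray:
    """Initial expectations Q0 = 1/2 * n_max * p_d, elementwise."""
    if n_max <= 0:
        raise ValueError(f"n_max must be > 0, got {n_max}")
    return 0.5 * n_max * np.asarray(pd_matrix, dtype=float)


def q_update(q_prev: float, v_new: float, alpha: float):
    """One-step value update: Q <- alpha * v + (1 - alpha) * Q."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return alpha * v_new + (1.0 - alpha) * q_prev


def choice_probabilities(
    q_row: np.ndarray, beta: float, allowed: np.ndarray
) -> np.ndarray:
    """Softmax choice distribution over the allowed destinations.

    Parameters
    ----------
    q_row
        Expected values of the candidate destinations (one entry per
        destination on the caller's axis).
    beta
        Softmax sharpness, >= 0.
    allowed
        Boolean mask on the same axis; excluded entries receive
        probability exactly 0.

    Returns
    -------
    numpy.ndarray
        Probabilities on the same axis, summing to 1 over the allowed
        entries. Computed with max-subtraction for numerical stability.

    Raises
    ------
    NoAllowedDestination
        If no entry is allowed.
    """
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    q_row = np.asarray(q_row, dtype=float)
    allowed = np.asarray(allowed, dtype=bool)
    if q_row.shape != allowed.shape:
        raise ValueError("q_row and allowed must have the same shape")
    if not allowed.any():
        raise NoAllowedDestination
    z = beta * q_row[allowed]
    z = np.exp(z - z.max())
    probs = np.zeros_like(q_row)
    probs[allowed] = z / z.sum()
    return probs


def choose_next(probabilities: np.ndarray, rng: np.random.Generator) -> int:
    """Sample one destination index from a categorical distribution."""
    probabilities = np.asarray(probabilities, dtype=float)
    if probabilities.ndim != 1 or np.any(probabilities < 0):
        raise ValueError("probabilities must be a non-negative vector")
    total = probabilities.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"probabilities must sum to 1, got {total}")
    return int(rng.choice(len(probabilities), p=probabilities / total))


def q_table_to_frame(q: np.ndarray) -> pd.DataFrame:
    """Flatten a Q-table to long form (origin, destination, q_value).

    Location labels: ``nest`` for index 0, site ids otherwise.
    """
    n = q.shape[0]
    labels = ["nest"] + [str(j) for j in range(n - 1)]
    rows = [
        (labels[a], labels[b], q[a, b]) for a in range(n) for b in range(n)
    ]
    return pd.DataFrame(rows, columns=["origin", "destination", "q_value"])
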