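"""Parameter sweeps reproducing the model's main experiments.

Three sweep families are provided, each aggregating the per-bout
similarity index (consecutive and every-other-bout) and foraging success
over independently drawn environments and replicate simulations:

* *spatial*: a single bee in a patch, varying patch density (hence mean
  inter-site distance) and the number of sites;
* *renewal x working memory*: a single bee on uniformly scattered sites,
  varying nectar renewal duration with a short (30 s) or matched
  (= renewal duration) working-memory span;
* *competition*: several bees on shared sites, varying colony size under
  fast or slow renewal.

A *control comparison* contrasts learners (alpha = 0.5, beta = 20) with
non-learning, noisy deciders (alpha = 0, beta = 2) on identical
environment draws across an inter-site-distance grid.

Aggregation follows the replicate-over-environments protocol: each cell
mean is taken over ``n_environments * sims_per_environment`` runs at a
reporting bout where the metrics have plateaued (detected automatically
by :func:`plateau_bout` unless overridden).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cognition import BeeParams
from .engine import SimulationConfig, run_simulation
from .environment import (
    ConfigurationError,
    Environment,
    PatchSpec,
    generate_patch,
    generate_uniform,
    mean_intersite_distance,
)
from .metrics import bout_metrics_frame
from .seeds import derive_seed

__all__ = [
    "SweepCell",
    "SweepSpec",
    "SweepResult",
    "run_sweep",
    "plateau_bout",
    "control_comparison",
    "spatial_cells",
    "renewal_memory_cells",
    "competition_cells",
]

logger = logging.getLogger(__name__)

MATCHED = "matched"  # wm_span placeholder: span = renewal_duration


@dataclass(frozen=True)
class SweepCell:
    """One grid cell: an environment recipe plus bee/colony parameters."""

    label: str
    layout: str = "uniform"  # "uniform" or "patch"
    n_sites: int = 25
    arena_side: float = 500.0
    density: float | None = None  # patch layout only, sites per m^2
    max_nectar: float = 20.0
    renewal_duration: float = 500.0
    n_bees: int = 1
    alpha: float = 0.5
    beta: float = 20.0
    wm_span: float | str = 30.0  # seconds, or "matched"
    speed: float = 3.0
    max_bout_distance: float = 3000.0
    nest_wait: float = 300.0

    def resolved_wm_span(self) -> float:
        if self.wm_span == MATCHED:
            return self.renewal_duration
        return float(self.wm_span)

    def bee_params(self) -> BeeParams:
        return BeeParams(
            alpha=self.alpha,
            beta=self.beta,
            wm_span=self.resolved_wm_span(),
            crop_capacity=5.0 * self.max_nectar,
            speed=self.speed,
            max_bout_distance=self.max_bout_distance,
            nest_wait=self.nest_wait,
        )

    def environment_seed_label(self, env_idx: int) -> str:
        # deliberately excludes bee/colony parameters so cells sharing a
        # geometry (e.g. learner vs control) get identical environments
        return (
            f"env|{self.layout}|{self.n_sites}|{self.arena_side}"
            f"|{self.density}|{self.max_nectar}|{self.renewal_duration}|{env_idx}"
        )

    def make_environment(self, master_seed: int, env_idx: int) -> Environment:
        seed = derive_seed(master_seed, self.environment_seed_label(env_idx))
        if self.layout == "uniform":
            return generate_uniform(
                self.n_sites, self.arena_side, seed,
                max_nectar=self.max_nectar,
                renewal_duration=self.renewal_duration,
            )
        if self.layout == "patch":
            if self.density is None:
                raise ConfigurationError(
                    f"cell {self.label!r}: patch layout needs a density"
                )
            return generate_patch(
                PatchSpec(n_sites=self.n_sites, density=self.density),
                self.arena_side, seed,
                max_nectar=self.max_nectar,
                renewal_duration=self.renewal_duration,
            )
        raise ConfigurationError(f"unknown layout {self.layout!r}")


@dataclass(frozen=True)
class SweepSpec:
    """A full sweep: cells plus the replication protocol."""

    cells: tuple[SweepCell, ...]
    n_environments: int = 5
    sims_per_environment: int = 2
    horizon: float = 7200.0
    dt: float = 1.0
    reporting_bout: int | None = None  # None: automatic plateau detection
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.cells:
            raise ConfigurationError("sweep needs at least one cell")
        if self.n_environments < 1 or self.sims_per_environment < 1:
            raise ConfigurationError("replication counts must be >= 1")
        if self.reporting_bout is not None and self.reporting_bout < 1:
            raise ConfigurationError("reporting_bout must be >= 1")


@dataclass
class SweepResult:
    """Long-format per-bout records plus cell-level summaries."""

    spec: SweepSpec
    records: pd.DataFrame  # cell, env_idx, sim_idx, bee_id, bout_index, ...
    failed_cells: list[tuple[str, str]] = field(default_factory=list)

    def reporting_bout(self, tolerance: float = 0.05) -> int:
        """Reporting bout: the spec's, or the latest per-cell plateau."""
        if self.spec.reporting_bout is not None:
            return self.spec.reporting_bout
        plateaus = []
        for _, grp in self.records.groupby("cell"):
            series = (
                grp.groupby("bout_index")["si_lag1"].mean().sort_index()
            )
            series = series.dropna()
            if len(series) >= 3:
                plateaus.append(
                    int(series.index[plateau_bout(series.to_numpy(), tolerance) - 1])
                )
        if not plateaus:
            return 1
        # cap at a bout that every cell's typical replicate reaches,
        # leaving room for the lag-2 comparison
        per_rep_last = self.records.groupby(
            ["cell", "env_idx", "sim_idx", "bee_id"]
        )["bout_index"].max()
        last_common = int(per_rep_last.groupby("cell").median().min())
        return min(max(plateaus), max(last_common - 2, 1))

    def summary(self, bout: int | None = None) -> pd.DataFrame:
        """Cell means/sd/count of SI (both lags) and success at one bout."""
        if bout is None:
            bout = self.reporting_bout()
        at = self.records[self.records["bout_index"] == bout]
        out = (
            at.groupby("cell")[["si_lag1", "si_lag2", "success"]]
            .agg(["mean", "std", "count"])
        )
        out.columns = ["_".join(c) for c in out.columns]
        out = out.reset_index()
        out["bout_index"] = bout
        return out


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Execute every cell of a sweep; reproducible under the master seed.

    Infeasible cells (e.g. a patch that cannot fit the arena) are
    recorded in ``failed_cells`` and skipped; the sweep continues.
    """
    frames: list[pd.DataFrame] = []
    failed: list[tuple[str, str]] = []
    for cell in spec.cells:
        try:
            frames.extend(_run_cell(cell, spec))
        except ConfigurationError as err:
            logger.warning("cell %s failed: %s", cell.label, err)
            failed.append((cell.label, str(err)))
    records = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=[
                "cell", "env_idx", "sim_idx", "bee_id", "bout_index",
                "n_visits", "nectar_collected", "bout_duration", "success",
                "si_lag1", "si_lag2",
            ]
        )
    )
    return SweepResult(spec=spec, records=records, failed_cells=failed)


def _run_cell(cell: SweepCell, spec: SweepSpec) -> list[pd.DataFrame]:
    frames = []
    params = cell.bee_params()
    for env_idx in range(spec.n_environments):
        env = cell.make_environment(spec.rng_seed, env_idx)
        for sim_idx in range(spec.sims_per_environment):
            env.reset_nectar()
            sim_seed = derive_seed(
                spec.rng_seed, f"sim|{cell.label}|{env_idx}|{sim_idx}"
            )
            result = run_simulation(
                SimulationConfig(
                    env=env,
                    params=params,
                    n_bees=cell.n_bees,
                    horizon=spec.horizon,
                    dt=spec.dt,
                    rng_seed=sim_seed,
                )
            )
            for bee_id in range(cell.n_bees):
                df = bout_metrics_frame(result.bouts_for(bee_id))
                if df.empty:
                    continue
                df.insert(0, "bee_id", bee_id)
                df.insert(0, "sim_idx", sim_idx)
                df.insert(0, "env_idx", env_idx)
                df.insert(0, "cell", cell.label)
                frames.append(df)
    return frames


def plateau_bout(
    series: Sequence[float], tolerance: float = 0.05
) -> int:
    """Earliest 1-based index after which a metric series has plateaued.

    The series is smoothed with a short rolling mean; the plateau point
    is the earliest position from which every later step-to-step change
    of the smoothed series stays below ``tolerance`` relative to the
    series' final level. If the series never settles, the last index is
    returned with a warning.
    """
    arr = np.asarray(series, dtype=float)
    if len(arr) < 3:
        raise ValueError("series must have length >= 3")
    m = pd.Series(arr).rolling(3, min_periods=1).mean().to_numpy()
    scale = max(abs(m[-1]), 1e-12)
    steps = np.abs(np.diff(m))
    for i in range(len(m) - 1):
        if np.all(steps[i:] <= tolerance * scale):
            return i + 1
    warnings.warn("no plateau found within the series; using the last bout")
    return len(m)


# ---------------------------------------------------------------------------
# Ready-made cell grids for the three experiments.

def spatial_cells(
    n_sites_list: Iterable[int] = (5, 25),
    densities: Iterable[float] = (0.1, 0.01, 0.001),
    renewal_duration: float = 500.0,
    wm_span: float | str = 30.0,
    **overrides,
) -> tuple[SweepCell, ...]:
    """Single-bee patch cells over a sites x density grid.

    Lower density means a larger patch radius and hence a larger mean
    inter-site distance; the distance proxy for each density can be
    computed with :func:`annotate_intersite_distance`.
    """
    return tuple(
        SweepCell(
            label=f"n{n}_d{d:g}",
            layout="patch",
            n_sites=n,
            density=d,
            renewal_duration=renewal_duration,
            wm_span=wm_span,
            **overrides,
        )
        for n in n_sites_list
        for d in densities
    )


def renewal_memory_cells(
    renewal_durations: Iterable[float] = (100.0, 500.0, 1000.0, 1500.0),
    wm_modes: Iterable[float | str] = (30.0, MATCHED),
    n_sites: int = 25,
    **overrides,
) -> tuple[SweepCell, ...]:
    """Single-bee uniform-layout cells over renewal x working-memory."""
    def wm_label(wm) -> str:
        return wm if isinstance(wm, str) else f"{wm:g}s"

    return tuple(
        SweepCell(
            label=f"renew{r:g}_wm{wm_label(wm)}",
            layout="uniform",
            n_sites=n_sites,
            renewal_duration=r,
            wm_span=wm,
            **overrides,
        )
        for r in renewal_durations
        for wm in wm_modes
    )


def competition_cells(
    n_bees_list: Iterable[int] = (1, 5, 10),
    renewal_durations: Iterable[float] = (250.0, 1500.0),
    n_sites: int = 25,
    **overrides,
) -> tuple[SweepCell, ...]:
    """Multi-bee uniform-layout cells over colony size x renewal speed."""
    return tuple(
        SweepCell(
            label=f"bees{k}_renew{r:g}",
            layout="uniform",
            n_sites=n_sites,
            renewal_duration=r,
            n_bees=k,
            **overrides,
        )
        for r in renewal_durations
        for k in n_bees_list
    )


def annotate_intersite_distance(
    cells: Sequence[SweepCell],
    rng_seed: int,
    n_environments: int = 200,
) -> dict[str, float]:
    """Mean pairwise inter-site distance proxy for each patch cell."""
    out = {}
    for cell in cells:
        if cell.layout != "patch" or cell.density is None:
            continue
        out[cell.label] = mean_intersite_distance(
            PatchSpec(n_sites=cell.n_sites, density=cell.density),
            n_environments=n_environments,
            rng_seed=derive_seed(rng_seed, f"isd|{cell.label}"),
            arena_side=cell.arena_side,
        )
    return out


def control_comparison(
    densities: Iterable[float] = (0.1, 0.01, 0.001),
    n_sites: int = 25,
    learner: tuple[float, float] = (0.5, 20.0),
    control: tuple[float, float] = (0.0, 2.0),
    n_environments: int = 5,
    sims_per_environment: int = 2,
    horizon: float = 7200.0,
    rng_seed: int = 0,
    reporting_bout: int | None = None,
    **cell_overrides,
) -> tuple[SweepResult, pd.DataFrame]:
    """Learners vs non-learning noisy deciders over a distance grid.

    The control foragers have alpha = 0 (expectations frozen at their
    initial values) and beta = 2 (noisy decisions). Environment draws are
    paired: for each density and environment index, the learner and
    control cells run on the same environment.

    Returns the raw sweep result and a per-density summary with the
    learner-minus-control foraging-success difference.
    """
    cells = []
    for d in densities:
        for name, (a, b) in (("learner", learner), ("control", control)):
            cells.append(
                SweepCell(
                    label=f"{name}_d{d:g}",
                    layout="patch",
                    n_sites=n_sites,
                    density=d,
                    alpha=a,
                    beta=b,
                    **cell_overrides,
                )
            )
    spec = SweepSpec(
        cells=tuple(cells),
        n_environments=n_environments,
        sims_per_environment=sims_per_environment,
        horizon=horizon,
        rng_seed=rng_seed,
        reporting_bout=reporting_bout,
    )
    result = run_sweep(spec)
    summary = result.summary()
    rows = []
    for d in densities:
        learner_row = summary[summary["cell"] == f"learner_d{d:g}"]
        control_row = summary[summary["cell"] == f"control_d{d:g}"]
        if learner_row.empty or control_row.empty:
            continue
        rows.append(
            {
                "density": d,
                "learner_success": float(learner_row["success_mean"].iloc[0]),
                "control_success": float(control_row["success_mean"].iloc[0]),
                "success_difference": float(
                    learner_row["success_mean"].iloc[0]
                    - control_row["success_mean"].iloc[0]
                ),
            }
        )
    return result, pd.DataFrame(rows)
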