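# Methods

## Model overview

The simulator models one colony of central-place nectar foragers
("bees") exploiting `N` point-like feeding sites in a square arena with
continuous coordinates and the nest fixed at the origin (arena centre;
uniform site draws cover `[−side/2, side/2]²`). Each site holds at most
`n_max` µl of nectar and, once depleted, refills linearly to `n_max`
over `renewal_duration` seconds. Bees fly in straight lines at constant
speed, know all site positions (long-term spatial memory), and decide
where to go next at every feeding site.

A foraging bout starts at the nest and ends — with a direct return
flight — when the crop (five full site loads) is full, the distance
budget for the bout is exhausted, or no site remains eligible. After a
fixed nest wait the next bout begins. Learning state (Q-table, working
memory) persists across bouts; the working memory decays only with
time and is deliberately not cleared at the nest, which is what couples
successive bouts and produces route alternation (below).

## Decision rule and learning

Transition values are initialised as `Q₀(A,B) = ½ n_max p_d(A,B)` with
`p_d` the row-normalised inverse-square-distance matrix over
{nest} ∪ sites (zero diagonal). On every realised transition the bee
perceives `v = n_t(B) · p_d(A,B)` — by default the standing crop on
arrival, before collection; a switch (`value_from_collected`) uses the
amount actually collected instead, which differs only when the crop is
nearly full — and applies the one-step update
`Q ← α v + (1−α) Q`. Updates are on-policy and per-transition only; the
nest has its own outgoing Q-row (used for the first leg of each bout)
and also learns. The nest is never a softmax destination: returns happen
only through the bout-termination rules.

Softmax choice uses max-subtraction for numerical stability and
excludes the current site (no self-transitions) and all sites inside
the working-memory window `[t_visit, t_visit + wm_span)`. If every site
is excluded at a feeding site the bout ends; if every site is excluded
at departure time the bee waits one timestep and retries.

Since `v ≤ n_max` and the update is a convex combination, every Q stays
in `[0, n_max]`; this is asserted at the end of every bout. With
`α = 0` the Q-table is bit-for-bit equal to `Q₀` after any simulation.

## Time discretisation and the event-driven engine

The model's native clock is a 1-second timestep (`dt`, configurable):
travel over distance `d` takes `ceil(d/(speed·dt))·dt`, and renewal
adds `n_max·dt/renewal_duration` per step, with depletion applied
before renewal within a step. Because the refill is piecewise linear
between depletion events, the engine advances event-to-event
(departures, site arrivals, nest returns in a time-ordered queue with
randomised tie-breaking) and integrates each site's refill in closed
form since its last depletion. This is exactly equivalent to stepping
every second — the accrued refill between events equals the sum of the
per-step increments — and makes runtime scale with the number of visits
rather than the horizon. A per-site ledger (initial + renewed −
collected = final) is returned with every simulation and checked to
1e−9 in the tests.

Several bees interact only through nectar depletion; bees arriving at
one site in the same timestep feed in randomised order, and departures
at t = 0 are staggered by one timestep in randomised order to break
symmetry. Every bee draws from its own stream derived from the master
seed (`derive_seed(master, "bee:i")`), so adding a forager does not
perturb the others' draws.

## Metrics

*Similarity index.* Two bout sequences (site visits only, nest entries
stripped) are decomposed into all contiguous subsequences of window
length 3. Every position covered by a subsequence occurring in both
sequences — including repeated occurrences — is marked; the index is
the marked count divided by twice the longer sequence length
(positional-cover reading; the normalisation gives exactly 1 for
identical sequences). Sequences shorter than the window contribute no
subsequences and score 0; the index is reported as missing only when
both sequences are empty, and missing values propagate to aggregates.
An independent brute-force enumeration oracle in the test suite agrees
on 1000 random pairs. The lag-1 series (bouts k vs k+1) measures route
fidelity; the lag-2 series (k vs k+2) detects alternation between two
routes.

*Foraging success.* Nectar collected per second of bout (µl/s),
undefined for zero-duration bouts (rejected).

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `n_max` | 20 µl | maximal site load |
| `crop_capacity` | 100 µl | five full site loads |
| `speed` | 3 m/s | straight-line flight |
| `max_bout_distance` | 3000 m | per-bout flight budget |
| `nest_wait` | 300 s | pause between bouts |
| `renewal_duration` | 500 s | empty-to-full refill time |
| `wm_span` | 30 s (or matched = renewal) | inhibition of return |
| `α` | 0.5 | learning rate |
| `β` | 20 | softmax sharpness (2 in the no-learning control) |
| horizon | 25 200 s (7 h) | one foraging day |

These sit on the timescale coherence the model assumes: working memory,
nest wait and renewal are all tens of seconds to ~1500 s, resolved by
the 1-s step. α = 0.5 weighs new experience and prior expectation
equally; β = 20 makes a converged bee nearly greedy while leaving some
exploration.

## Sweep study conditions

Sweeps aggregate the two metrics over independent environment draws ×
replicate simulations (the replication protocol reads "50 simulations
on 25 environments" as 2 × 25; both counts are knobs). The scaled `ci`
profile uses 5 environments × 2 simulations over a 2-h horizon; the
`paper` profile restores 25 environments and the 7-h day. Metrics are
reported at a plateau bout detected automatically: the earliest bout
from which the step-to-step change of a 3-bout rolling mean of the
cell's similarity series stays below 5% of its final level, capped at a
bout every cell's typical replicate reaches.

Grids not fully pinned down elsewhere were fixed once as realistic bee
foraging conditions: patch densities 0.1 and 0.01 sites/m² (mean
inter-site distances ≈ 8 m and ≈ 25 m for 25 sites) for the spatial
sweep with renewal 500 s and wm 30 s; renewal grid
{100, 500, 1000, 1500} s for the renewal × memory sweep on 25 uniform
sites; fast/slow renewal {250, 1500} s with 1/5/10 bees for the
competition sweep (25 sites × 20 µl = five crops, so five bees saturate
the environment).

With the default nest wait (300 s) and ≈ 200-s bouts, one bout cycle is
≈ 500 s. The matched-memory alternation regime — consecutive-bout
similarity near 0 with every-other-bout similarity near 1 — therefore
appears where the working-memory span exceeds one bout cycle but not
two, i.e. renewal ≈ 500–1000 s here; at still longer spans the memory
covers two previous bouts and the bee cycles among three or more
routes, so both similarity series drop. The regime sequence (single
route → two-route alternation → multi-route) is the robust prediction;
where it falls on the renewal axis scales with the bout cycle, hence
with nest wait, speed and site spacing.

In the competition sweep, slow renewal lowers similarity and success at
*every* colony size and the proportional loss of foraging success from
1 to 10 bees is steeper under slow renewal. The proportional loss of
*similarity* is not steeper, because slow renewal already floors the
single-bee similarity (the same renewal effect seen in the
renewal × memory sweep), leaving little room to fall.

## What the synthetic environments do and do not capture

Generated environments share one `n_max` and one `renewal_duration`
across sites, have no landscape structure (obstacles, wind, flower-level
heterogeneity), and renew deterministically. Passing sweeps therefore
show that the cognitive mechanism produces the qualitative patterns
under idealised resource geometry; they say nothing about heterogeneous
rewards, weather, energetics or multi-day effects, none of which are
modelled. Competition is purely resource-mediated: no explicit
encounters or displacement.

## Numerical and degenerate-input choices

* Coincident locations make `p_d` undefined and are rejected with the
  offending pair named.
* The distance budget is checked after arrival (the bee commits to a
  chosen transition even if it overshoots).
* Travel time is rounded up to whole timesteps, never below one step.
* Environment CSV files are written with 17 significant digits and read
  with round-trip float parsing, so serialisation is exact.
* Derived seeds are SHA-256 hashes of `"master:label"` reduced mod 2³¹;
  the mapping is frozen by a golden test.

## Known limitations

Site handling (feeding) takes zero time, so bout durations are pure
travel; success rates are correspondingly optimistic. The plateau
detector assumes the metric series settles monotonically-ish; strongly
oscillating series fall back to the last common bout with a warning.
The no-learning control shares the learners' environment draws but not
their decision draws.
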