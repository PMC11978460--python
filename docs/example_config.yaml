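# Example configuration for traplinesim (all values shown are defaults).
# Any key may be omitted; unknown keys are rejected.

schema_version: "1"

environment:
  layout: uniform            # uniform | patch
  n_sites: 25
  arena_side: 500.0          # metres; nest at the centre (0, 0)
  density: null              # patch layout only: sites per square metre
  buffer: null               # patch layout only: edge margin (default: patch radius)
  patch_radius_formula: sqrt_density   # sqrt_density | literal
  max_nectar: 20.0           # microlitres per site
  renewal_duration: 500.0    # seconds from empty to full (linear)

bee:
  alpha: 0.5                 # learning rate, in [0, 1]
  beta: 20.0                 # softmax sharpness, >= 0 (0 = uniform random)
  wm_span: 30.0              # working-memory span, seconds
  crop_capacity: null        # microlitres; default 5 * max_nectar
  speed: 3.0                 # metres per second
  max_bout_distance: 3000.0  # metres per bout
  nest_wait: 300.0           # seconds between bouts
  value_from_collected: false  # value transitions by collected rather than standing nectar

simulation:
  n_bees: 1
  horizon: 25200.0           # seconds of foraging (7 h)
  dt: 1.0                    # timestep, seconds

sweep:
  profile: ci                # ci (5 env x 2 sims, 2 h) | paper (25 env x 2 sims, 7 h)
  kind: renewal_memory       # spatial | renewal_memory | competition | control
  n_environments: null       # override the profile
  sims_per_environment: null
  horizon: null
  reporting_bout: null       # default: automatic plateau detection
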