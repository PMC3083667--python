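# Methods

## Model overview

`tiedsim` couples three layers: an environment (a dense monthly grid of
temperature, precipitation and runoff), a community of agents who each hold
a partial memory of that environment, and an emergent community-level
perception of change. One simulation steps month by month over the
simulation window (2010–2090 by default) while agents observe the current
month, compare it with their remembered past, optionally borrow the
perception of a more experienced community member, and aggregate into a
weighted consensus. Vulnerability is the signed gap `v = q − P_c` between
the recorded change `q` (current value minus the month-of-year mean over
*all* years since the history start, 1960) and the community perception
`P_c`. The model's purpose is not to ask whether agents can perceive change
but how far a community's aggregate view drifts from the record as direct
environmental experience is lost and knowledge is (or is not) passed on.

## Agents and demographics

* Ages are integers ≥ 18 (the minimum decision-making age); age classes are
  Y 18–39, M 40–59, O ≥ 60. Age exactly 60 is assigned to O so the classes
  partition all adult ages.
* Annual mortality is `m = (age / max_age)^e`, with `e` Euler's number used
  as an exponent and `max_age` the current eldest age, evaluated once per
  annual update after aging and before any deaths. The eldest agent
  therefore dies with probability 1 every year — community life expectancy
  self-limits, and long memories are structurally rare. The exponent is
  configurable for sensitivity runs.
* The population is constant. A deceased agent is replaced by an
  18-year-old of the same type (behaviour is inherited within families)
  whose `t_TRU` is the mean over young-class agents surviving the same
  update; if none survive, the scenario's scheduled young-class value for
  that year is used. Replacements start with an empty memory.
* Order within an annual update is fixed for reproducibility: age
  increment → `t_TRU` decline → mortality draws → replacement. Annual
  events fire at the January step; the first simulated year performs
  history initialization only (the freshly sampled community is not aged
  before its first observation).
* Initial demographics are configurable because the source communities'
  exact frequency tables are not available in numeric form. Defaults,
  chosen once as plausible for a small rural-Alaska community: age classes
  Y/M/O = 0.45/0.35/0.20 with uniform integer ages within class (O capped
  at 80); types α/β/γ = 0.40/0.40/0.20 (γ a minority); population 152.

## Memory, perception and knowledge transfer

* **Known history.** A candidate year is any year of the agent's adult
  lifetime (`current_year − y ≤ age − 18`) inside the record. The first
  time a year becomes a candidate it faces a single admission draw: it is
  memorised iff the agent's *current* `t_TRU` exceeds a Uniform[0, 1)
  draw. Memory is sticky — admitted years persist for life, rejected years
  are never reconsidered. One draw per (agent, year) avoids memories that
  flicker from month to month. The history is shared across variables and
  months: exposure is physical presence in the landscape, not per-variable.
* **Individual perception** is the current month's value minus the
  month-of-year mean over the agent's known history; the current
  observation is available to everyone regardless of `t_TRU` (an optional
  stricter reading, gating the current observation as well, is not
  enabled). An empty history yields an *undefined* perception, which is
  excluded from the consensus rather than treated as zero.
* **LK provider selection.** Eligible providers hold a strictly longer
  known history than the recipient, measured by year count (a span
  (max − min) measure is available behind `lk_eligibility="span"`). Among
  eligible agents the provider maximises `(age / eldest age) · t_TRU`,
  ties broken by smallest agent id. Transfer is a convex blend
  `p′ = w_k p_provider + (1 − w_k) p_own`; an undefined recipient adopts
  `w_k p_provider`. Blending (rather than permanently copying the
  provider's year set) was chosen because only scalar perceptions are
  exchanged in the model's weight tables; it reproduces the qualitative
  discontinuities expected when a heavily-consulted elder dies.
* **Consensus.** `P_c = Σ w_i p_i / Σ w_i` over defined perceptions, with
  `w_i` from the age-class × type influence table. If all participating
  weights are zero the unweighted mean is used; if no perception is defined
  at all, `P_c = 0` and the step is flagged `degenerate` — vulnerability
  then equals the recorded change itself, the "no better than random"
  regime.
* The two weight tables (influence `w_p`, transfer `w_k`) default to the
  published values and can be overridden per entry in the run
  configuration.

## Scenarios

Per-age-class initial `t_TRU` and annual declines (percentage points,
clamped at 0):

| scenario | Y | M | O | reading |
|---|---|---|---|---|
| A | 1.00, −0.0 | 1.00, −0.0 | 1.00, −0.0 | perfect knowledge |
| B | 0.95, −0.0 | 0.95, −0.0 | 0.95, −0.0 | traditional use by all |
| C | 0.95, −5.0 | 0.95, −1.0 | 0.95, −0.0 | young distancing |
| D | 0.95, −0.0 | 0.95, −1.0 | 0.95, −5.0 | old distancing |
| E | 0.95, −4.0 | 0.95, −2.5 | 0.95, −1.0 | gradual, all classes |
| F | 0.95, −15.0 | 0.95, −10.0 | 0.95, −5.0 | rapid, all classes |

All printed annual changes are treated as declines (the scenario
descriptions uniformly describe diminishing use) applied to each agent at
the rate of its current class. The decline is per-agent: an agent whose
`t_TRU` has decayed does not regain engagement on entering an older class.

## Synthetic climate forcing

The generator emulates the structure of the original downscaled
GCM-plus-water-balance forcing, which has no public accession: monthly
resolution, a seasonal cycle, an upward trend in all three variables, and
month-to-month noise. Per variable, the value at year offset `k`, month `m`
is

```
value = start_mean + slope · (t − 2.5) + A · cos(2π (m − peak)/12) + ε,
t = k + (m − 0.5)/12,   slope = (end_mean − start_mean)/(n_years − 5),
ε ~ N(0, noise_sd²),
```

clipped at zero for precipitation and runoff. The cosine sums to zero over
any calendar year and the trend is linear in time, so the noise-free annual
means of the first and last five years equal `start_mean` and `end_mean`
exactly — the calibration anchors are the published five-year endpoint
averages. Defaults (units as printed in the source tables, nominally °C
and mm/month):

| variable | start → end mean | amplitude | noise sd | peak month |
|---|---|---|---|---|
| temperature | −4.4 → 3.9 | 13.0 | 2.5 | July |
| precipitation | 23.9 → 45.0 | 15.0 | 8.0 | August |
| runoff | 5.6 → 13.0 | 5.0 | 2.5 | June |

Amplitudes and noise levels were fixed once from western-Alaska (Seward
Peninsula) monthly climatology: a ~26 °C seasonal swing, late-summer
precipitation maximum, June snowmelt runoff peak. For clipped flux
variables the amplitude must not exceed `start_mean`, otherwise the
noise-free series itself would clip and the endpoint calibration could not
be exact; runoff's amplitude (5.0 < 5.6) respects this while noisy winter
months still clip to zero, as frozen-season runoff should. What the
generator does **not** emulate: interannual autocorrelation (e.g. ENSO/PDO
persistence), trend acceleration, covariance between the three variables,
and any spatial structure. Passing tests therefore demonstrate the social
mechanism against a *plausible* forcing, not a reconstruction of the
original climate realization; the CSV loader accepts real forcing with
columns `year,month,temperature,precipitation,runoff` when available.

## Simulation, replication, determinism

Default window 2010–2090 (972 monthly steps, 2 916 records) with the
record back to 1960. Replicates run with seeds `base_seed + 0 … + r − 1`
(default r = 30) and are averaged pointwise (mean of `v` and `|v|`, with
replicate standard deviations; both signed and absolute means are emitted
since either could be the quantity of interest). By default the climate
realization is generated once from the climate config's own seed and
shared across replicates, so replicate variance isolates the social
process; `freeze_climate: false` regenerates it per replicate seed. All
randomness flows through a single `numpy` generator per run; identical
(config, seed) reproduces every output bit (CSV floats are pinned to
`%.17g` / `%.10g` formats).

Internally the monthly loop caches per-year quantities: population state
only changes at annual events, so known-history matrices, provider choices
and perception arrays are computed once per simulated year, vectorized
over agents and months. The test suite verifies that these caches
reproduce the scalar operation-by-operation pipeline exactly.

## Numerical and degenerate-input conventions

* Empty year set → a distinct "no history" error at the statistics layer,
  mapped to undefined perceptions (never silently zero) in the engine.
* All-zero consensus weights → unweighted mean; no defined perceptions →
  `P_c = 0` with a `degenerate` flag on the emitted record.
* Provider eligibility is strict (`>`), so an agent never selects a peer
  with an equal-length history, and a provider always has a defined
  perception (its history count exceeds a non-negative count).
* Tie-breaks (provider score, duplicate ids) resolve to the smallest agent
  id; the annual update draws one uniform per agent in population order.
* Climate tables must be dense; the first missing (year, month) is named
  in the error.

## Known limitations

* The mortality rule makes annual death rates high at all ages relative to
  actuarial reality (a 40-year-old in an 80-max community dies with
  p ≈ 0.15/yr); it is implemented as specified, and its consequence —
  rapid demographic memory loss — is central to the model's behaviour, not
  an artefact to be corrected here.
* With sticky per-agent memory and per-agent `t_TRU` decline, a scenario
  that drives the young class's engagement to zero (C, F) eventually stops
  all new memory formation: once the last carriers die, every perception
  is undefined and vulnerability equals the recorded change, with or
  without LK transfer. Knowledge transfer in this regime has no providers
  to draw on, so it cannot restore the community's accuracy — an
  interpretable, but strong, consequence of the chosen memory mechanism.
* No migration, births, population growth, social networks, partial or
  errorful knowledge content, or forgetting; two-site comparisons are done
  by running the model once per site configuration.
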