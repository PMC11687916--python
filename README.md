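# matchmomentum

Point-by-point momentum quantification for tennis matches.

Given a point-by-point match table, the package derives six momentum
events per player per point — winning serves, winning shots, three
consecutive points won, double faults, unforced errors, three consecutive
points lost — and integrates them into a per-player momentum series via a
difference equation with exponential forgetting:

```
M_i = f(Δt_i) · M_{i-1} + ΔM_i,        M_0 = 0
f(Δt) = 0.6 + 0.4 · exp(−λ·Δt)
ΔM    = α · Σ_k w_pk · flag_pk  −  β · Σ_j w_nj · flag_nj
```

with server modifiers α = 1.2 (serving) / 1.0 and β = 1.0 (serving) / 1.2,
positive weights w_p = (0.30, 0.32, 0.38) and negative weights
w_n = (0.32, 0.26, 0.42). The match winner is predicted from the momentum
differential (match mean by default; final-point and cumulative scores are
one flag away), with a per-set break-point adjustment. A statistics layer
reproduces the associated event-level analyses (server × game-winner
chi-square, winner/loser event tallies, court-type indicator variance,
event correlation matrices, score time series), and a full scoring
state-machine simulator generates schema-valid synthetic matches with
ground-truth annotations so every stage is testable without external data.

Two model constants are not pinned by the published constants and are
package choices, exposed in the config: the forgetting decay rate
(default λ = ln 2 / 40 s⁻¹, a 40 s memory half-life) and the break-point
set-adjustment weights (defaults 0.05 per break point created, 0.10 per
break point converted).

## Command line

All subcommands read an optional YAML config (`momentum:` and
`simulation:` blocks overriding the shipped defaults in
`src/matchmomentum/data/defaults.yaml`), write artifacts into `--out`,
and drop a `manifest.json` (config hash, seed, version) beside them.

```bash
# synthetic corpus + ground truth sidecar
matchmomentum simulate --out out/sim --seed 7 --n-matches 20

# per-point event flags
matchmomentum extract-events --input out/sim/points.csv --out out/events

# momentum series (and optional per-match curve PNGs)
matchmomentum momentum --input out/sim/points.csv --out out/momentum --plot

# event tallies, chi-square report, correlation matrix
matchmomentum stats --input out/sim/points.csv --out out/stats --plots

# winner predictions + accuracy per prediction mode
matchmomentum predict --input out/sim/points.csv --out out/pred
```

Real Grand Slam point-by-point CSVs are read with `--dialect slam_pbp`
(column names of the public point-by-point repository, `ElapsedTime`
clocks parsed from `H:MM:SS`); the package's own snake_case schema is the
`canonical` dialect and round-trips losslessly.

## Layout

| module | contents |
| --- | --- |
| `matchmomentum.match_io` | CSV dialects, `PointRecord`/`MatchRecord`, validation |
| `matchmomentum.events` | event flags, streak detection, break-point reconstruction, tallies |
| `matchmomentum.momentum` | `MomentumParams`, forgetting coefficient, recursion, set scores |
| `matchmomentum.stats` | chi-square, server outcome table, court summary, correlations |
| `matchmomentum.predict` | match-level scores, winner prediction, corpus evaluation |
| `matchmomentum.simulate` | scoring state machine, game-probability calibration, generator |
| `matchmomentum.cli` | `matchmomentum` entry point |
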