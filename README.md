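# ambientropy

Entropy-based analysis of human mobility inside sensor-instrumented homes.

Ambient PIR motion sensors report an ON event whenever movement enters
their viewing area. For a single resident, the chronological sequence of
sensor identities fired in one day is a symbolic *daily trajectory* of the
resident's movement between rooms. `ambientropy` turns raw event logs into
these trajectories and asks two questions a smart-home or remote-monitoring
system needs answered:

1. **How regular is the resident's movement, and how predictable is it at
   best?** Quantified by three entropy rates per day and by inverting a
   Fano-type bound into an upper limit on next-location prediction
   accuracy.
2. **Which stretches of the record do not reflect single-occupant routine**
   (long-term visitors, malfunctioning or battery-drained sensors, system
   changes)? Found by segmenting the series of daily entropy rates with an
   exact penalized-contrast change-point detector, then corroborating each
   segment's start date against dated maintenance/visitor records.

## The quantities

For a daily trajectory of length `n` over `N` distinct sensors:

- random entropy `S_rand = log2 N` — uncertainty under fully random
  movement;
- temporal-uncorrelated entropy `S_unc = -Σ_i p̂(i) log2 p̂(i)` with plug-in
  visit frequencies `p̂(i) = N_i / n` — ignores visit order;
- real entropy `S_real` — the entropy rate of the ordered sequence,
  estimated with a Burrows–Wheeler-transform block-sorting estimator: the
  reversed, sentinel-terminated sequence is suffix-sorted, the transform
  output is split into `⌈√n⌉` contiguous blocks, and the estimate is the
  length-weighted mean of per-block plug-in entropies. For stationary
  ergodic sources `S_real ≤ S_unc ≤ S_rand`.

The predictability limit `Π_max` solves
`S = -Π log2 Π - (1-Π) log2(1-Π) + (1-Π) log2(N-1)` by bisection
(the right side decreases strictly from `log2 N` to 0 on `Π ∈ [1/N, 1]`).

The daily series `s_j = μ_k + ε_j` is modelled as piecewise constant;
for each candidate segment count `K` the contrast
`J(τ, s) = (1/n) Σ_k Σ_{j∈k} (s_j - mean_k)²` is minimized exactly by
dynamic programming, and `K̂` is chosen automatically from the bend of the
lower convex hull of the normalized `(K, J_K)` curve (threshold ρ = 0.75).

## Worked example

The bundled simulator generates event logs with the statistical structure
the analysis assumes — a Markov-chain resident plus planted visitor /
malfunction / behavior-shift regimes — together with ground truth. The
`house55-like` preset is a 208-day installation with five regimes of sizes
31, 33, 102, 29, 13 days and daily-entropy means stepping through
1.48 → 1.18 → 1.46 → 1.82 → 1.45 bits:

```
ambientropy run --preset house55-like --seed 11 -o out/
```

prints `pipeline complete; K_hat=5 -> out/` and writes, among other
artifacts, `out/segments.csv`:

```
segment,start_date,end_date,n_days,mean_entropy,sd_entropy
1,2018-06-05,2018-07-05,31,1.530,0.124
2,2018-07-06,2018-08-07,32,1.097,0.118
3,2018-08-08,2018-11-13,98,1.496,0.134
4,2018-11-14,2018-12-16,33,1.781,0.143
5,2018-12-17,2018-12-29,13,1.456,0.098
```

The selector recovered all five planted regimes; the detected change
dates (2018-07-06, 2018-08-08, 2018-11-14, 2018-12-17) sit within a few
days of the planted boundaries (the middle ones shift slightly because a
handful of outlier days are dropped before segmentation). Segment 4 is the
visitor regime: its mean daily entropy (1.78 bits) is visibly above the
routine level (≈1.5), while regime 2's low 1.10 bits reflects a quieter
movement pattern. Per-day output in `out/entropy.csv` holds all six
quantities, e.g. a day with `N = 10` sensors and `S_real = 1.71` bits has
`Π_real = 0.73`: at best, 73% of next-location predictions can be correct.

Stage-wise subcommands (`simulate`, `trajectories`, `entropy`, `segment`,
`compare`) expose the same pipeline piecewise; `--help` documents each.

## Layout

- `src/ambientropy/ingest.py` — event-log parsing, daily trajectories, day
  filters, isolated-outlier removal
- `src/ambientropy/entropy.py` — the three entropy rates and the BWT
  estimator
- `src/ambientropy/predictability.py` — Fano-bound inversion
- `src/ambientropy/changepoint.py` — exact DP segmentation and automatic
  model selection
- `src/ambientropy/compare.py` — segment categorization and Welch's t-test
  comparisons
- `src/ambientropy/simulate.py` — synthetic scenario generator with ground
  truth
- `src/ambientropy/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — modelling assumptions, estimator details, parameter
  defaults, limitations
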