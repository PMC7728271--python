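# Methods

## Mobility model and trajectory construction

A resident's movement is modelled as a stationary stochastic process over
the finite set of motion sensors installed in the home. Only PIR ON events
carry location information; the daily trajectory is the chronological
sequence of sensor identities that fired between local midnights. Ties in
timestamps keep input-file order (stable sort). By default consecutive
firings of the same sensor are collapsed into one symbol
(`collapse_repeats=True`), so the trajectory records transitions between
viewing areas rather than re-triggers while the resident stays in one
room; the flag is exposed because raw ON sequences are also a defensible
reading, and both are supported. The day boundary is local midnight of the
home's configured timezone, since daily routines anchor to local clock
time.

Day-level exclusions, in order of precedence: explicitly recorded vacation
days; days with fewer than 12 raw ON events (a threshold separating
occupied days from vacations, visitors checking on the house, and sensor
errors — counted before repeat collapsing). After the daily entropy series
is computed, isolated outliers are removed: a day is an outlier when its
real entropy lies outside the Tukey fences `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`
(quartiles by linear interpolation, numpy's default, computed once on the
unfiltered per-house series), and it is removed only when no other outlier
lies within ±3 *calendar* days. The calendar reading (rather than index
distance) is deliberate: the isolation rule exists to protect multi-day
episodes, which are calendar phenomena, and the kept-day series may have
gaps.

## Entropy rates

Per day with trajectory length `n` and alphabet size `N`:

- `S_rand = log2 N`.
- `S_unc = −Σ p̂ log2 p̂` with plug-in frequencies; by Gibbs' inequality
  `S_unc ≤ S_rand` holds exactly, and the tests assert it without
  tolerance.
- `S_real` is estimated with the Burrows–Wheeler block-sorting estimator.
  Implementation choices (the estimator family leaves them open; these are
  this package's declared conventions, not attributed elsewhere):
  - the *reversed* sequence is transformed, so that sorted suffixes are
    preceding histories and the transform groups each emitted symbol by
    its context;
  - a unique sentinel (lexicographically smallest) terminates the
    sequence for suffix sorting and its output position is dropped, making
    the transform an exact permutation of the input;
  - suffix sorting is prefix doubling over an integer alphabet mapped by
    first appearance (deterministic; O(n log n) lexsorts, adequate to the
    n ≤ 10⁵ used anywhere in this package);
  - the transform output is split into `T = ⌈√n⌉` contiguous
    near-equal-length blocks and the estimate is the length-weighted mean
    of per-block plug-in (maximum-likelihood) zero-order entropies.
    Consistency requires `T → ∞` with `T/n → 0`; `⌈√n⌉` satisfies both and
    is parameter-free. The block count is overridable.
  - no smoothing of block probabilities: plug-in matches the style of
    `S_unc` and the consistency checks pass without it (i.i.d. alphabets
    2–12 and a 3-state Markov chain with closed-form rate
    `−Σ_i π_i Σ_j P_ij log2 P_ij`, both within ±0.05 bits at n = 10⁵).

At daily lengths (tens to a few hundred events) the estimator carries a
finite-sample negative bias of order `(N−1)/(2·(n/T)·ln 2)` per block;
daily values are therefore *estimates*, comparable across days of similar
length, and the synthetic calibration (below) targets the finite-length
estimate rather than the asymptotic rate for exactly this reason.

## Predictability bound

`Π_max` inverts `S_F(Π) = −Π log2 Π − (1−Π) log2(1−Π) + (1−Π) log2(N−1)`.
On `[1/N, 1]`, `S_F` decreases strictly from `log2 N` to 0, so bisection
is safe; Newton iteration was rejected because `dS_F/dΠ` is unbounded as
`Π → 1`. Bisection runs to an interval width of 1e−13 (cap 200
iterations) so the round-trip residual in `S` stays below 1e−8 bits even
where the curve is steep; the `tol` parameter documents the guaranteed
1e−9 accuracy on `Π`. Entropies outside `[0, log2 N]` by more than 1e−9
(estimator noise) are clamped with a warning. `N` is each day's observed
distinct-symbol count, not the house-wide maximum; this is configurable by
passing a different `n_symbols`.

## Change-point detection

The daily real-entropy series is modelled as piecewise constant with
homoscedastic noise. For fixed `K` the least-squares contrast is minimized
exactly by dynamic programming over segment ends with prefix-sum O(1)
segment costs (O(K n²) total; n ≤ ~700 and K ≤ ~100 complete in about a
second). Ties are broken toward the lexicographically smallest
change-point vector, which the backward-DP argmin-first reconstruction
yields directly; equality with exhaustive enumeration is asserted for all
n ≤ 14, K ≤ 4, L_min ∈ {1, 2}.

`K̂` is selected automatically. The contrasts `J_1 ≥ … ≥ J_Kmax` are
rescaled affinely so the normalized curve spans `[1, K_max]` — making the
*average* decrement per added segment exactly 1 — and candidates are
restricted to the lower convex hull of `(K, J_K)`. Each hull point is the
minimizer of `J + β·K` for an interval of penalties β whose length equals
the change of slope of the convex minorant at that point; thresholding
that bend (ρ, default 0.75) therefore selects the `K` that would be chosen
over the widest range of penalties, replacing an explicit β sweep. Two
details matter in practice and are part of this package's design:

- curvature is measured on the **convex minorant** (slope change between
  adjacent hull points), not by the raw second difference
  `J̃_{K−1} − 2J̃_K + J̃_{K+1}`: the raw curve is not convex, and raw
  second differences at hull points are contaminated by non-hull
  neighbours (measured null false-alarm rate ~50%);
- a hull point qualifies only if its outgoing minorant slope is shallower
  than the average decrement (−1 in normalized units): under pure noise
  the first optimal split removes a disproportionate share of the sum of
  squares, which otherwise produces a spurious bend at K = 2–3. With both
  conditions the selector returns `K̂ = 1` on constant-mean Gaussian noise
  in ≥ 95% of seeded replicates while recovering planted `K` essentially
  always at ≥ 3σ jumps.

The raw-second-difference variant remains available via
`hull_only=False`. Defaults `L_min = 1` and `K_max` = number of weeks
spanned by the series (distinct ISO weeks when dates are present,
`⌈n/7⌉` otherwise), both overridable. The series is indexed by kept-day
position, not calendar time, so excluded days do not create placeholder
points. Per-segment sample SDs are reported descriptively;
homoscedasticity is not enforced.

## Segment categorization and comparisons

A segment's start date is corroborated against dated external records
within ±2 days (default). Mapping: battery-drained / network problems →
system malfunction; visitor arrival → multiple occupant; sensor addition →
single-occupant mode (2), an upgrade that persists; visitor departure or
sensor/battery replacement → return to the prevailing single-occupant
mode; nothing in the window → unknown. When several kinds fall in one
window, precedence is malfunction > visitor > system change > revert —
worst case first, since a malfunction invalidates the data regardless of
what else happened; the precedence is a package choice and is logged with
the evidence. The first segment has no detected change point and takes a
declared initial state. Records of kind `other` are kept in the input but
never corroborate.

Group comparisons use Welch's t-test (two-sided, Welch–Satterthwaite df,
scipy's implementation) with no multiple-testing correction by default —
significance flagging at 0.01 is left downstream, and symmetry /
closed-form identities are verified in the tests. The two single-occupant
categories together form the "normal" day set used for weekday/weekend
and similar contrasts.

## Synthetic data

The generator exists so that every pipeline property can be tested against
known truth. The resident is a first-order Markov chain over the home's
sensors with a softmax-tempered cycle matrix: preferred next sensor
`i+1 (mod N)`, self-transitions excluded, and a scalar temperature
interpolating between a deterministic tour (rate 0) and a uniform walk
(rate `log2(N−1)`). Daily event counts are negative binomial (default
mean 150, dispersion 8, truncated to 15–550 — the realistic range for
instrumented homes) and timestamps are uniform jitter within 07:00–23:00,
sorted. Disturbances: visitor regimes superpose an independent second
walker, interleaved by event time with each walker's internal order
preserved; malfunction regimes suppress designated sensors' events;
behavior shifts swap the temperature. One `default_rng(seed)` drives
everything, so fixed spec + seed gives byte-identical logs.

Fixture calibration: the temperature-to-entropy map is monotone, so
regime temperatures are bisected (in log space, common random numbers)
against the *mean finite-length daily estimate* produced by the same BWT
estimator the pipeline uses. Visitor regimes cannot be calibrated by
temperature — interleaving saturates the estimate near 2.7–2.9 bits
regardless — so they keep the prevailing routine temperature and bisect
the visitor's event share instead. The `house55-like` preset encodes a
208-day installation with five regimes (31/33/102/29/13 days; target
daily means 1.48/1.18/1.46/1.82/1.45 bits); the `null` and
`occupancy-contrast` presets use temperature 0.32, which yields the
1.5-bit routine level typical of single residents in such installations.

What the generator does **not** emulate: sensor-physics artifacts
(double-triggers, dead zones), floor-plan geometry, circadian structure
within the day, correlated resident–visitor movement, and gradual (rather
than step) behavioral drift. Passing tests therefore demonstrate that the
estimators and the detector recover the structure they assume, at
realistic sizes and noise levels — not that real homes satisfy those
assumptions.

## Sizes and tolerances used in the test suite

Estimator consistency at n = 10⁵ (±0.05 bits); DP-vs-enumeration at
n ≤ 14; Fano round trip over 1000 random `(s, N)` pairs at ≤ 1e−8 bits;
regime recovery and null calibration over 20 seeded replicates of the
into-the-pipeline scenarios (208 and 178 days); directional occupancy
ordering on three 50-day regimes with pairwise Welch p < 0.01. These sizes
keep the full suite under a minute while leaving each check comfortably
away from its threshold.

## Known limitations

- The BWT estimator's daily values are biased low at short lengths;
  cross-day comparisons implicitly assume comparable lengths. The day
  filter (≥ 12 events) bounds but does not remove this effect.
- `L_min = 1` permits single-day segments; the selector's elbow conditions
  keep the usual false-alarm modes in check, but a single extreme day that
  survives the isolated-outlier rule can still become its own segment.
- Segment categorization implements the stated ±window rule only; it does
  not attempt the judgment calls a human analyst might make from free-text
  evidence.
- Multi-resident disambiguation, OFF-event/duration analysis, and
  non-PIR sensors are out of scope.
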