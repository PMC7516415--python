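# Methods

## Model

A trial is one participant driving one scenario × alignment condition; its
scanpath is the time-ordered sequence of fixations. Each fixation is
assigned to one of six areas by point-in-polygon containment against a
screen layout (origin top-left, x rightward, y downward, pixels): five
named AOIs — pavement area (PA), central area (CA), top wall (TW), left
wall (LW), right wall (RW) — and white space (WS) as the complement. Points
on a shared polygon boundary go to the first covering region in a fixed,
configurable priority order (default PA, CA, TW, LW, RW). Assignment is a
total function: every point gets exactly one label.

Two analyses follow, and they deliberately treat WS differently:

**Dwell.** Per trial and area, `T_s` sums integer fixation durations (ms)
and `β_s = T_s / T_total` over **all six** areas. Durations stay integer
milliseconds internally; proportions are reported to 3 decimals. An empty
trial is flagged `undefined` rather than yielding silent NaNs.

**Entropy.** WS fixations are removed and the sequence spliced closed
(PA–WS–CA yields a PA→CA transition), leaving a sequence over
`S = (PA, RW, LW, TW, CA)` — this state order is used for all matrices.
Splice-on-deletion is one reading of "exclude white space"; the alternative
(breaking the sequence at WS so no transition is formed) changes counts
only at WS boundaries and is not currently exposed. Consecutive same-AOI
fixations are **not** merged, so the diagonal of the count matrix is
typically large. From consecutive-pair counts `n_ij`:

    p_ij = n_ij / Σ_j n_ij             (rows with no out-transitions stay
                                        zero and are flagged; no pseudocounts)
    Ht   = −Σ_i π_i Σ_j p_ij log2 p_ij
    Hs   = −Σ_i π_i log2 π_i

with `0·log2 0 = 0`, logs base 2 (bits). Both entropies lie in
`[0, log2 5]`. The weight vector π has two first-class modes:

* `empirical` (default): visit frequencies, `π_i = count_i / length`;
* `eigenvector`: the solution of `πP = π`, found by power iteration
  (tolerance 1e-12) on the single closed communicating class of the visited
  subchain; a chain with several closed classes raises an ambiguity error
  listing them. In this mode `Ht ≤ Hs` holds exactly (conditioning reduces
  entropy at stationarity); in empirical mode it holds approximately for
  long stationary sequences.

Trials with fewer than two non-WS fixations have undefined entropies; they
are kept in the output flagged `excluded` and dropped (logged) from group
statistics.

Validation tolerances: computed rows and vectors must be stochastic within
1e-6; the direct-entry path for externally printed matrices uses 5e-3,
because a matrix rounded to 3 decimals can have row sums like 1.001.

### The embedded reference trial

The worked example ships as an integer count matrix (row sums 45, 6, 20,
45, 13; 129 transitions) rather than the 3-decimal transition matrix
usually quoted, because accumulated rounding in the printed matrix shifts
Ht from 1.593 to 1.592. Rounding the rebuilt full-precision matrix to 3
decimals reproduces the printed matrix entry for entry, and the printed
visit vector is within 0.0065 per component of the matrix's stationary
solution, so both π modes give consistent results.

## Group statistics

The entropy grid (participant × scenario × alignment) feeds a two-way
fixed-effects ANOVA with interaction, fit per dependent variable (Ht, Hs).
All observations enter one between-style model; **participant is not a
factor**, so for the full 21×3×3 design the dfs are (2,180), (2,180),
(4,180). This is intentional — it mirrors how such grids are commonly
analysed with repeated measurements pooled — and is noted in the report; a
repeated-measures or mixed model would be the stricter alternative and is
out of scope. The design must be balanced (equal cell counts), which makes
Type I/II/III sums of squares coincide; unbalanced grids are rejected
rather than silently reweighted. Effect size is partial eta squared,
`ηp² = SS_effect / (SS_effect + SS_residual)`. The fit itself is delegated
to statsmodels OLS + `anova_lm`; the test suite checks it against an
independent hand sums-of-squares decomposition.

Dominance: for a scenario pair within one alignment, the percentage of
participants whose entropy is **strictly** smaller under the first
scenario, rounded to the nearest integer; ties count as not smaller, and
participants missing either arm are excluded and logged.

## Synthetic cohort

The generator emulates the study design the analysis assumes: 21
participants × scenarios A (wall + pavement delineators), B (pavement
only), C (none) × alignments straight, left curve, right curve.

Each condition's template chain is a sticky mixture
`P = (1−d)·I + d·1wᵀ`: stay put with probability `1−d`, otherwise redraw
the AOI from visit profile `w`. Its stationary law is exactly `w`, so the
template's true `Hs = H(w)` and `Ht = Σ_i w_i H((1−d)e_i + d·w)` are in
closed form and the encoded orderings are verifiable: entropies A < B < C
within every alignment, straight > curves within every scenario, PA mass
above 0.5 in scenario A, CA+TW dominant in scenario C, and the inner wall
(LW on left curves, RW on right curves) elevated. The profile/rate values
are design constants chosen once to realise those orderings with
comfortable margins.

Per-participant heterogeneity perturbs each template row by
`Dirichlet(κ · row)` (default κ = 200, a moderate spread that leaves the
main effects clearly detectable at n = 21; `κ = ∞` disables variation).
Dirichlet is the minimal perturbation family on the simplex. Other
defaults: trial length Poisson(120) fixations (floor 10) — around 120
on-AOI fixations per drive, comparable to the ~129 transitions of the
reference trial; fixation durations lognormal with median 300 ms and
σ = 0.45 (typical of fixation-duration literature); saccade gaps uniform
20–80 ms; WS fixations interleaved with probability 0.05 to exercise the
exclusion path; positions sampled uniformly strictly inside the intended
AOI polygon of the default layout, so labels round-trip through the
geometric assignment. Everything is driven by one seeded generator:
identical config + seed gives byte-identical output. Per-trial ground
truth (perturbed matrix and its exact entropies) is written as a sidecar.

What the generator does **not** emulate: head movement, calibration error
and other position noise (a fixation never lands in the wrong AOI by
accident), within-trial non-stationarity (curve entry/exit dynamics),
correlation between a participant's behaviour across conditions beyond the
shared template, and realistic WS structure (dashboard glances are
independent coin flips). Passing tests therefore show the estimator and
statistics machinery are correct under the stated model, not that the model
captures real tunnel driving.

The default AOI layout is a schematic tunnel view on a 1920×1080 frame
(rectangles: top-wall band, left/right wall bands, central area, wide
pavement band, white-space margins). It is an engineering default — real
studies should supply their measured layout file.

## Numerical choices

* Power iteration from the uniform vector, tolerance 1e-12 (max-abs change),
  cap 1e5 iterations; closed classes found via strongly connected
  components of the positive-transition graph.
* Zero-count rows contribute zero row entropy and are flagged, never
  smoothed.
* Matrix values are only rounded at report time (3 decimals); all internal
  computation is double precision.
* A constant-response ANOVA (zero variance) reports SS = 0, F undefined,
  ηp² = 0 exactly rather than floating-point dust.
* Dominance rounding uses nearest-integer; with 21 participants no exact
  .5 cases arise.

## Problem sizes in tests

Consistency checks use chains of length 1e5 (plug-in estimates recover
template matrices to < 0.02 max-abs and entropies to < 0.01 bits);
exhaustive oracle comparison enumerates all sequences of length ≤ 6 over a
3-symbol sub-alphabet; cohort-level significance is checked over 20 seeded
full-size cohorts (scenario and alignment effects significant at α = 0.05
in ≥ 90% of seeds).

## Known limitations

* The ANOVA ignores the repeated-measures structure (see above); p values
  for within-participant factors are anti-conservative under positive
  within-participant correlation.
* The plug-in entropy estimator is biased downward at short sequence
  lengths; no bias correction (e.g. Miller–Madow) is applied, matching the
  plain estimator the analysis defines. Trial-length differences between
  conditions therefore translate into small entropy differences.
* Only first-order chains: higher-order dependence in scanpaths is
  invisible to Ht.
* Fixation detection is upstream: the package consumes fixation events,
  never raw gaze samples.
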