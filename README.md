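# scanpath-entropy

Entropy-based analysis of driver gaze behaviour from eye-tracking fixation
tables, built around the question of how visual guidance facilities
(delineator posts in road tunnels) change where and how restlessly drivers
look.

The package is written for human-factors / visual-attention researchers who
have per-fixation exports from an eye tracker (start, duration, end in ms,
plus 2-D position) and want, per trial:

* **dwell-time proportions** over six screen areas — pavement (PA), central
  area (CA), top wall (TW), left wall (LW), right wall (RW), and the white
  space (WS) outside them: `β_s = T_s / T_total` with `T_s = Σ_i t_i`;
* a **first-order Markov chain** over the five named AOIs
  `S = (PA, RW, LW, TW, CA)` fit from consecutive-pair counts,
  `p_ij = n_ij / Σ_j n_ij`, with visit probabilities `π_i = p_i / Σ_i p_i`;
* the two **gaze entropies** in bits:
  * transition entropy `Ht = −Σ_i π_i Σ_j p_ij log2 p_ij` — how
    unpredictable the next AOI is given the current one;
  * stationary entropy `Hs = −Σ_i π_i log2 π_i` — how widely attention is
    spread over AOIs;
* **group statistics** over a participants × scenarios × alignments grid: a
  two-way fixed-effects ANOVA with partial eta squared, and pairwise
  scenario "dominance" percentages (share of participants with the strictly
  smaller entropy under one scenario).

A synthetic cohort generator reproduces the structure of a
21-participant × 3-scenario × 3-alignment driving-simulator study, so the
whole pipeline is testable end to end without any proprietary data.

## Worked example

The package embeds one reference trial (a participant driving the straight
section of a tunnel equipped with both wall and pavement delineators) as an
integer transition-count matrix plus its visit-probability vector:

```bash
$ scanpath-entropy worked-example
Ht = 1.593 bits
Hs = 2.098 bits
```

`Ht = 1.593` says that, on average, knowing the currently fixated AOI
leaves about 1.6 bits of uncertainty about the next one (out of a maximum
of `log2 5 ≈ 2.32`); `Hs = 2.098` says this driver's attention is spread
fairly evenly across the five AOIs.

## The analysis, step by step

The numbered scripts under `analysis/` run the full study-shaped analysis
on a simulated cohort and write their tables under `results/`:

```bash
python analysis/01_worked_example.py    # reference trial entropies
python analysis/02_simulate_cohort.py   # 21 x 3 x 3 synthetic fixation data
python analysis/03_dwell_proportions.py # per-area dwell shares
python analysis/04_entropy_table.py     # 189-trial Ht/Hs grid vs ground truth
python analysis/05_group_stats.py       # ANOVA + dominance report
```

On the default seed the simulated cohort reproduces the qualitative
pattern the generator encodes: mean pavement dwell share 0.60 in scenario A
(both delineator types) falling to 0.14 with no delineators (scenario C,
where CA+TW rise to 0.63); both entropies ordered A < B < C within every
alignment and straight > curves within every scenario; strongly significant
scenario and alignment main effects on both entropies (e.g. scenario on Ht:
F(2,180) ≈ 209, p < 1e-40, ηp² ≈ 0.70); and the lower-entropy scenario
winning 62–100% of participants across the pairwise comparisons (scenario A
vs C: 95–100%).

The same pipeline runs on real exports via the CLI:

```bash
scanpath-entropy analyze --fixations my_fixations.csv \
    --layout my_aoi_layout.yaml --out results/my_run
```

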