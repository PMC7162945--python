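# Methods

## Setting and model

`dielrhythm` analyses diel (day/night) expression time courses from one
or more organs. A course is a transcripts × time points table of
normalized log-scale values with a parallel 0/1 detection mask; time is
expressed in Zeitgeber Time (ZT, hours after dawn). The default design
is 14 samples every 2 h from ZT−2 to ZT24, dawn at 5:45 and dusk at
19:00 local clock time, i.e. a 13.25-h photoperiod within a 24-h cycle.
The rhythm model underlying both the detector and the generator is a
cosine of fixed period with an organ- and transcript-specific phase
(peak time); detection is purely rank-based, so only the ordering of
the cosine at the sample times matters, not its amplitude or any
monotone distortion of the measurement scale.

## Pipeline stages and their parameters

Stage order: expression call → Z-score → network → modules → sign split
→ representatives → merge → adjacency filter → rhythmicity test →
module rhythm call → member noise filter → dendrogram phase correction
→ per-transcript calls.

* **Expression call** (`min_detected_timepoints`, default 8 of 14): a
  transcript is expressed when detected at more than half of the
  samples. The mask is an input; computing it from raw intensities is
  upstream of this package.
* **Z-score**: each series is standardized to mean 0, sample (n−1)
  SD 1. Constant series cannot be standardized; they are excluded from
  the network and logged rather than silently zeroed.
* **Network** (`beta`, default 18): unsigned soft-threshold adjacency
  `a_ij = |r_ij|^β` on Pearson correlations, diagonal set to 0. The
  unsigned choice is deliberate: anti-phase transcripts are *meant* to
  land in the same module and are recovered afterwards by sign
  splitting.
* **Topological overlap**: `TOM_ij = (Σ_u a_iu a_uj + a_ij) /
  (min(k_i, k_j) + 1 − a_ij)` with connectivity `k` = row sum; the
  clustering dissimilarity is `1 − TOM`. Raw `1 − a` is available via
  `use_tom: false`.
* **Tree cut** (`cut_height`, default 0.9; `min_module_size`, default
  10): average-linkage clustering with a single static cut. This
  replaces the hybrid dynamic tree cut of full WGCNA — a deliberate
  simplification; the cut height was calibrated once on the synthetic
  planted-structure suite (well-separated phase groups are recovered
  over the whole 0.8–0.95 range, so the choice is not delicate) and is
  exposed in the config. Clusters below the minimum size go to an
  unassigned pool and are non-rhythmic by definition.
* **Sign split**: within a module, the member most correlated (in
  absolute value) with the module mean seeds the split; members with
  `r ≥ 0` against the seed form the "plus" module, the rest the
  "minus" module.
* **Representative**: the pointwise median of the member Z-scores — a
  robust "typical series" that tolerates a minority of outlying
  members.
* **Merge** (`merge_dissim_max`, default 0.25): greedy closest-pair
  merging on `1 − Pearson` between representatives, recomputing the
  representative after every merge; ties break lexicographically on
  module id. Anti-correlated representatives (dissimilarity near 2)
  never merge.
* **Adjacency membership filter** (`adjacency_min`, default 0.175): a
  member is kept iff its mean adjacency to the other members of its
  module is at least the threshold (boundary kept). This is the one
  genuinely ambiguous published parameter — "a 0.175 adjacency
  threshold" — and the membership-filter reading is adopted here
  because it is the only one that uses adjacency units directly; a
  static tree-cut height is the alternative reading and remains
  available through `cut_height`. Singleton modules have no
  intramodular adjacency and are dropped.
* **Rhythmicity test**: see below. Modules with Bonferroni-adjusted
  `P < 0.75` (strict) are rhythmic. The threshold is deliberately
  permissive — it operates at module level, on median representatives
  that are already strongly denoised, not per transcript.
* **Member noise filter** (`member_min_spearman`, default 0.3): members
  with Spearman ρ below 0.3 against their representative (strictly) are
  discarded as noisy; constant members, whose rank correlation is
  undefined, are dropped and logged. Under independence at n = 14 the
  retention probability of an unrelated series is ≈ 0.14.
* **Phase correction** (`dendrogram_cut`, default 0.25): the
  representatives of *all* modules of *all* organs are clustered
  (average linkage on `1 − Pearson`) and the tree is cut; modules in
  one cluster are considered to share a phase and receive the circular
  median of their test phases (ties resolved toward the earliest
  phase). The cut height is unspecified in the published procedure; the
  default reuses the merge scale, which is the same dissimilarity, and
  is configurable.
* **Calls**: a transcript is rhythmic iff it is a retained member of a
  rhythmic module; its phase is the module's corrected phase, binned
  into 2-h ZT bins; a peak is a day peak iff phase < photoperiod
  (13.25 h), strictly.

## The exact rank test

For each candidate period (default only 24 h — 14 points over 26 h
cannot usefully resolve other periods) and each lag on a grid covering
`[0, period)` in sampling-interval steps, the reference cosine
`cos(2π(t − lag)/period)` is converted to midranks at the sample times.
The statistic `S = Σ_{i<j} sign(x_j − x_i)·sign(ref_j − ref_i)` counts
concordant minus discordant pairs; pairs tied in either vector
contribute 0.

Under the null that the series values are exchangeable (and continuous,
so untied), `S = 2·JT − P`, where `P` is the number of reference-untied
pairs and `JT` is a Jonckheere–Terpstra statistic over the reference
tie groups. `JT` decomposes into independent Mann–Whitney components —
one per tie group against the union of its predecessors — whose count
generating function is the Gaussian binomial coefficient, so the exact
null pmf is obtained by exact integer convolution (the q-multinomial,
symmetric in group sizes, which the cache exploits). The one-sided
upper-tail P of the observed S is minimized over the grid; the winning
lag, mapped into `[0, period)`, is the phase; the reported
`p_adjusted = min(1, p_min × n_combinations)` is a Bonferroni bound.
Because the lag grid spans the full period, anti-phase signals are
captured (the test is effectively two-sided). An exhaustive-permutation
oracle (n ≤ 8) exists solely for testing and matches the convolution
exactly. Ties *within the data* make the test conservative (tied pairs
can only shrink |S|); they are noted in results, not corrected.

Numerical choices: cosine values are rounded to 9 decimals before
ranking so symmetric samples tie exactly; equal-P grid ties resolve to
the earlier period and smaller lag; constant series return τ = 0,
P = 1, flagged. The amplitude estimate (half peak-to-trough of the
least-squares scaling of the winning reference) is diagnostic only.

## Synthetic data: what it emulates, and what not

The generator emulates the *statistical structure* of a two-color
oligoarray diel course: LOWESS-normalized log-ratio scale (so noise is
additive i.i.d. Gaussian), two replicate hybridizations per time point
(averaged by the pipeline; a cell is detected if detected in any
replicate), per-cell detection dropout, a rhythmic fraction with exact
planting (`round(n × fraction)`), phases drawn from a wrapped-normal
mixture concentrated at dawn and dusk (weights 0.6/0.4, means ZT0.5 and
ZT12, SD 0.6 h — chosen once so the modal 2-h bin holds ~35–45% of
rhythmic transcripts, as observed in real diel phase histograms), and a
multi-organ sharing structure (default: 75% of transcripts expressed in
all organs, half of the rhythmic quota shared with a common base phase
plus optional planted per-organ shifts; organ-absent transcripts appear
as background rows with 15% spurious detection). Defaults:
amplitude 1.0, per-replicate noise SD 0.25 (amplitude/noise 4),
dropout 0.1.

It does **not** emulate probe sequences, dye bias beyond additive
noise, spatial array artifacts, heteroscedastic intensity-dependent
noise, non-sinusoidal waveform zoo (a sawtooth is available for
robustness checks), or correlated noise between transcripts. Passing
tests therefore demonstrate correctness of the inference under the
stated generative model, not performance on any particular real
dataset.

Randomness: one explicit integer seed per dataset; per-organ
sub-streams are derived deterministically as `default_rng([seed, organ
index])`, so adding an organ does not perturb the others.

## Set and enrichment statistics

Euler regions are exact set counts (no area-proportional geometry).
The hypergeometric test reports both tails; the published decision rule
("P < 0.05 over, P > 0.95 under") is applied to the *upper* tail
`P(X ≥ k)`, the only reading consistent with its stated direction. No
multiple-testing correction is applied across categories, matching the
published procedure; this is flagged in output metadata. Chi-square
comparisons use the Pearson statistic with df = categories − 1 and
refuse zero expected cells (pool categories instead). Percentages are
rounded half away from zero to one decimal using integer arithmetic, so
printed values like 68.3% reproduce exactly.

## Numerical and degenerate-input conventions

Strict inequality at the 0.75 adjusted-P threshold; `≥` at the 0.3
Spearman and 0.175 adjacency thresholds; day/night boundary is night
(phase must be strictly below the photoperiod to be a day peak). The
signed circular phase difference wraps into `(−period/2, period/2]`, so
an exact half-period difference is reported as "delayed". Undetected
cells keep their recorded value through correlation and testing (an
option to mask-and-interpolate is a possible extension); the detection
mask only drives the expression call.

## Problem sizes

The bundled test suite and the acceptance script run the full pipeline
at 3 organs × 1,000 transcripts (≈ 1,500-transcript universe), where a
complete simulate→infer→score cycle takes a few seconds; the design
scales comfortably to the ~10⁴-transcript regime of real oligoarray
datasets, for which the dense correlation/TOM matrices (~10⁸ entries)
remain tractable in memory. Block-wise decomposition for >5×10⁴
transcripts is out of scope.

## Known limitations

* The static tree cut is simpler than WGCNA's dynamic hybrid cut and
  can shear very unequal-density clusters; the cut height and minimum
  module size are config knobs.
* Phase resolution is bounded by the lag grid (the sampling interval,
  2 h); member-level phase refinement below module resolution is not
  attempted.
* The exact null assumes untied data; heavily quantized inputs make the
  test conservative.
* The 0.75 module-level threshold is permissive by design and relies on
  the adjacency and Spearman filters to control per-transcript false
  positives; on pure-noise input the realized false-positive fraction
  is low but not zero.
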