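# dielrhythm

Detection and phasing of **diel transcriptional rhythms** in multi-organ
expression time courses.

Plants sampled across a day/night cycle show pervasive 24-h rhythms in
transcription, and different organs (e.g. a source leaf versus sink
internodes) can keep strikingly different rhythmic programs even when
they express nearly the same genes. `dielrhythm` implements a
module-level inference for this setting, aimed at short, densely sampled
courses (the default design is 14 samples at 2-h intervals spanning
26 h, starting 2 h before dawn with a 13.25-h photoperiod):

1. **Expression call** — a transcript is expressed if its signal is
   distinguishable from background at more than half of the time points
   (≥ 8 of 14 by default).
2. **Coexpression modules** — expressed series are Z-scored, correlated,
   and raised to a soft-threshold power (β = 18) to give an unsigned
   weighted adjacency `a_ij = |r_ij|^β`; the topological-overlap
   dissimilarity is clustered (average linkage, static cut). Because an
   unsigned network groups anti-correlated series, each module is split
   by correlation sign, summarized by the pointwise **median
   representative series**, merged with close modules
   (1 − Pearson ≤ 0.25 between representatives), and pruned by a mean
   intramodular adjacency filter (≥ 0.175).
3. **Rhythmicity test** — each representative is scored by an exact
   nonparametric cosine rank test (JTK_CYCLE family): the Kendall-type
   statistic `S = Σ_{i<j} sign(x_j − x_i)·sign(ref_j − ref_i)` against
   reference cosine rank patterns over a (period, lag) grid, with the
   exact null of `S` computed by convolving Mann–Whitney components
   conditioned on the reference tie pattern, and Bonferroni adjustment
   over the grid. Modules with adjusted `P < 0.75` are rhythmic; members
   with Spearman ρ < 0.3 against their representative are filtered out
   as noisy.
4. **Phase correction** — the representatives of all modules of all
   organs are clustered in one dendrogram; modules that cluster together
   receive a consensus phase (circular median of their test phases).
   Phase is reported in Zeitgeber Time: hours between dawn and the peak.
5. **Reporting** — cross-organ Euler region counts, hypergeometric
   over/under-representation of functional categories (upper tail
   `P < 0.05` → over, `P > 0.95` → under), chi-square comparisons,
   2-h phase histograms and day/night peak fractions.

A synthetic-data generator with planted ground truth (rhythmic fraction,
dawn/dusk-concentrated phases, amplitudes, noise, detection dropout,
replicate hybridizations, cross-organ sharing and phase shifts) makes
the whole pipeline testable end to end without external data.

## Worked example

```sh
cat > cfg.yaml <<EOF
rng_seed: 4
synthetic:
  organs: [L1, I1, I5]
  organ_spec:
    n_transcripts: 500
EOF
dielrhythm simulate --config cfg.yaml --out sim
dielrhythm run      --config cfg.yaml --in sim --out run
dielrhythm report   --in run --out report.json
dielrhythm enrich   --calls run/calls_L1.tsv --annotation sim/annotation.tsv \
                    --out enrichment_L1.tsv
```

`run/summary.json` then contains, per organ (here L1):

```json
{
  "day_peak_fraction": 1.0,
  "n_expressed": 507,
  "n_modules": 2,
  "n_rhythmic": 144,
  "n_rhythmic_modules": 2,
  "n_transcripts": 750,
  "pct_rhythmic_of_expressed": 28.4
}
```

Of the 750 transcripts in the simulated universe, 507 pass the
expression call in L1 (the rest are expressed only in other organs);
144 are retained members of rhythmic modules (28.4% of expressed,
against a planted 30% rhythmic fraction), and all recovered peaks fall
in the 13.25-h light interval, as planted. `run/modules.tsv` shows the
sign-split module pair per organ — a dawn-phased "plus" module
(corrected phase ZT0) and its anti-phase "minus" twin at ZT12:

```text
module_id  organ  sign   n_members  p_adjusted   phase_corrected  rhythmic
I1.M01+    I1     plus   89         2.64e-08     0.0              True
I1.M01-    I1     minus  56         2.64e-08     12.0             True
```

`report.json` adds 2-h phase histograms (86 L1 transcripts at ZT00, 58
at ZT12 in this run) and the 7-region Euler counts of
expressed/rhythmic sets across the three organs.

All thresholds (β, merge and adjacency cut-offs, the 0.75 adjusted-P
rule, the 0.3 Spearman filter, the expression call, dawn/dusk clock
times) live in the YAML config and default to the values above; an
empty config reproduces them exactly.

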