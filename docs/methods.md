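# Methods

## Data model

The observational unit is a probe-level log2 expression value for one
array, keyed by (cell line, agent, arm, time).  Arms are `vehicle`, `low`
and `high`; every treated array must have a time-matched vehicle array for
the same cell line and agent, which the sample-sheet reader enforces.
Array normalization is assumed done upstream; the pipeline starts from
normalized log2 intensities.  Identifiers are opaque case-sensitive
strings — no gene-symbol aliasing is attempted, since symbol curation is a
separate task with its own failure modes.

## Fold changes and baseline

Probes of a gene are averaged **on the log2 scale** within each array
(arithmetic mean of present values; a gene is missing only when all its
probes are).  Replicate arrays for one (cell line, agent, arm, time) are
averaged the same way before differencing.  Then

    log2FC(gene, line, agent, conc, time) = treated − vehicle

with an entry only when both sides exist.  This makes `compute_log2fc`
antisymmetric under swapping treated/vehicle roles, which the tests
exercise directly.

Baseline expression per (gene, cell line) is the median of vehicle-arm
values across **all** agents at the baseline time (default 6 hr, the time
point at which vehicle profiles are most representative of untreated
state).  Even-count medians are midpoints.  All vehicle arrays at the
baseline time contribute, regardless of which concentration arm they
nominally control for — they are identically prepared solvent-only
samples.

## Concerted-change calls

For one experiment (gene × agent × concentration × time) with per-line
fold changes, let n_pos, n_neg, n_zero count lines with positive, negative
and exactly zero log2FC.  The call is

- `up` iff n_neg ≤ t and n_pos > n_neg,
- `down` symmetrically,
- `none` otherwise,

with discordance threshold t = 15.  Zeros count as neither direction: the
rule counts lines "moving in the opposite direction" and a zero moves in
none (with continuous data this is a measure-zero event anyway).  The
threshold is absolute, not proportional; experiments with fewer than
`min_cell_lines` (default 40) lines of data are flagged insufficient and
excluded from consensus rather than being called on a small denominator.
Ties (n_pos = n_neg) are `none` — no majority exists.

The null probability attached to each call is the exact one-direction
binomial tail P(X ≤ t) for X ~ Binomial(n_pos + n_neg, ½), computed with
integer binomial coefficients and one exact rational division
(`math.comb` + `Fraction`), never a normal approximation.  At n = 60,
t = 15 this is 6.7257 × 10⁻⁵.  The two-direction null call rate is twice
that, which the Monte-Carlo acceptance study confirms.  No multiplicity
correction is applied across experiments in the consensus table; the
calls are descriptive, and the exact per-experiment null is reported
alongside each.

Amplitude tiers annotate a call with the largest per-line log2FC in the
consensus direction, with inclusive boundaries at 1, 2.5 and 4.  A compact
renderer emits the conventional `H24↑*`-style strings (H/L concentration,
time, arrow, one star per tier step).

## Association screen

Per (gene, agent, condition), the per-line quantity — log2FC at one
(concentration, time), or baseline expression — is correlated with
log10(GI50) over the shared cell lines.  Spearman is the Pearson
correlation of average-ranked values; p-values are two-sided via the
t statistic with n − 2 degrees of freedom (exact permutation adds nothing
at n ≈ 60 and would dominate runtime).  Pairs with a missing value on
either side are dropped; below `min_pairs` (default 10) the gene/condition
is skipped.  Zero-variance vectors yield a *flagged* degenerate row with
undefined ρ rather than a silent 0, so screens cannot be biased by
constant genes.

FDR uses Benjamini–Hochberg step-up (via statsmodels) over a pooled
family: by default one family per correlation method containing every
gene, agent, treatment condition **and** the baseline rows.  A
`per_agent` family option exists because pooling across agents is a
design choice reasonable people make differently; the default is the more
conservative single pooled set.  Degenerate rows stay outside the family
(p_FDR = NA).  Gene-vs-gene analyses (correlating one gene's log2FC with
another's) reuse the same `correlate` routine with the y-vector swapped.

## LS/KS permutation enrichment

The universe is the map gene → two-sided Spearman p₀ at one condition.
For a set S (intersected with the universe, admissible size 5–500 by
default):

    LS = mean over S of −ln p        (p floored at 1e-300)
    KS = max_i ( i/n − p_(i) )       (one-sided toward small p)

The null resamples **gene labels**: `n_perm` (default 10 000) subsets of
size |S| drawn uniformly without replacement from the universe, and

    p = (1 + #{null stat ≥ observed}) / (1 + n_perm),

which is never zero and is an exact Monte-Carlo p-value.  Both statistics
are one-sided toward enrichment for small p-values.  Per-set RNG streams
are spawned deterministically from the configured seed in collection
order.  No FDR is applied across sets; enrichment p-values are reported
raw.  Subset sampling ranks a (chunk × universe) matrix of random keys, so
memory stays bounded for large universes.

## Cross-dataset concordance

External validation tables carry probe/replicate-level log2FC.  They are
averaged in two stages — probes within a replicate, then replicates —
which equals pooled averaging for balanced designs and weights replicates
equally otherwise.  Genes pass to the direction comparison only under the
strict filter |log2FC| > 0.1 (a value exactly at 0.1 fails).  Agreement is
defined only for genes that pass the filter *and* have a sufficient
concerted consensus at the matched panel condition; filtered genes are
reported as filtered, not counted as disagreement.  Matching an external
condition (e.g. a 72-hr profile) to a panel condition is an explicit user
choice, never inferred.

## Synthetic panel generator

`txpanel.simulate` emulates the screen's structure: 60 cell lines ×
15 agents × {low, high} × {2, 6, 24} hr with vehicle-matched controls,
1–3 probes per gene with per-probe offsets (SD 0.3), per-gene baselines
N(6, 1.5²) with per-(gene, line) variation (SD 0.5), and iid array noise
(SD 0.25) — magnitudes typical of normalized two-sample log2 microarray
data.  Planted effects switch on at designated conditions (default
high/24 hr):

- **Concerted genes** (default 16, the size of a small gene family of
  interest) receive an additive shift |N(1.5, 0.5²)| whose sign matches
  the planted direction per line with probability 1 − `discordance_prob`
  (default 0.9).
- **Associated genes** (default 30) are driven by a latent
  per-(line, agent) sensitivity score s ~ N(0, 1) that also generates
  log10(GI50) = −6 + s + N(0, 0.3²).  The gene effect is
  `scale · (r·s + √(1−r²)·z)` with scale 2.  The copula correlation r is
  2 sin(π ρ_target/6) — the exact Spearman↔Pearson relation for
  Gaussians — **divided by the analytic attenuation factors** of the two
  noisy observables (√(scale²+2σ²/k)/scale per gene with k probes, and
  the GI50 counterpart), so the *observed* (log2FC, log GI50) pair has
  population Spearman equal to the target (default −0.8, the magnitude of
  the strongest reported drug–gene correlations).  Without compensation
  the observable correlation falls short of the target by ≈ 0.05.  The
  construction is validated once at n = 10 000 lines.
- **Null genes** (default 400) differ from vehicle by noise only, so
  their log2FC is exactly sign-symmetric.

Gene sets: enriched sets draw `enriched_fraction` (default 1.0) of their
members from associated genes, control sets from null genes.  The
external table gives concerted genes a shift of |N(0.5, 0.2²)| whose sign
matches the planted direction with a configurable concordance rate, with
probe/replicate structure and small noise (SD 0.05).

One master seed governs everything; panel, gene sets and external table
use independent deterministically-spawned sub-streams, so each product is
reproducible on its own.

What the simulation does *not* emulate: Affymetrix intensity
distributions, tissue-of-origin structure, correlated gene modules,
batch/plate effects, or heavy-tailed GI50 censoring at the assay range.
Passing tests therefore demonstrate correctness of the statistical
machinery under a clean generative model, not robustness to every
real-data pathology.

## Validation studies and problem sizes

`txpanel.studies` (used by `tests/test_acceptance.py` and
`scripts/acceptance.py`) runs:

- exact Binomial(60, ½) tail at threshold 15 (analytic);
- Monte-Carlo null call rate of the classifier, 10⁶ genes × 60 lines;
- BH vs a literal double-loop step-up reference, 1000 families ≤ 12;
- planted-ρ recovery, 200 single-agent panels at 60 lines (5 associated
  genes each); type-I error on 2000 null genes with permuted response;
- LS null calibration, 500 replicates of a 400-gene null universe with
  20-gene random sets at 10 000 permutations (the permutation p-value's
  uniformity is a property of set resampling, so uniform universes give
  the same calibration as simulated ones at a fraction of the cost);
  power on 100 end-to-end simulated panels with fully planted sets;
- the three-cell-line worked example (rank-reversed fold changes vs
  GI50 → Spearman ρ = −1; maximum fold change 2.437 → tier 1);
- full-pipeline byte-determinism on a scaled-down two-agent panel
  (60 lines, 44 genes), run twice.

These sizes keep the whole validation under about a minute while leaving
the binomial/BH checks exact and the stochastic checks inside 3-SE bands.

## Numerical conventions

- All tables are tab-delimited UTF-8; missing values serialize as empty
  strings; writers and readers round-trip floats at full precision.
- Medians of even counts are midpoints; probe means skip missing values.
- Permutation p-values use the +1/(n+1) estimator; enrichment p-values
  floor at 1e-300 before logs.
- `null_probability` is exact rational arithmetic rounded once to float.
- Pipeline outputs are a pure function of (inputs, config, seed); the
  determinism study asserts byte identity.

## Known limitations

- Spearman p-values use the t approximation; for n < ~10 pairs an exact
  method would be preferable, hence the `min_pairs` floor.
- The concerted-call threshold is fixed (not scaled to n); experiments
  with 40–59 lines are therefore slightly more conservative than n = 60.
- Gene sets are scored independently; overlapping sets share evidence and
  their permutation p-values are correlated.
- The enrichment per-set RNG stream follows collection order, so adding
  or removing a set changes the streams of later sets (results remain
  reproducible for a fixed collection and seed).
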