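# Methods

## The screening model

The pipeline analyzes a paired-genotype agonist screen: every library
compound is tested (in triplicate, at a single concentration) on cells
expressing the wild-type MRGPRX2 receptor and on cells expressing the N62S
loss-of-function variant. The per-well readout is a signal-to-background
fluorescence ratio, defined here as peak over pre-injection baseline of the
calcium-flux kinetic trace (`compute_ratio`). That definition is an
assumption of this package — it is standard practice for FDSS-style kinetic
readers, but other summaries (area under the trace, baseline-subtracted
peak) exist; anything already reduced to a single ratio per well can be fed
in directly through the `value` column.

### B-score normalization

Screening plates carry additive row and column artifacts (dispense
gradients, edge evaporation, reader bias). Each plate is decomposed by
Tukey's two-way median polish,

    y_ij = mu + R_i + C_j + r_ij,

sweeping row medians and then column medians of the residuals into the
effect vectors until the largest effect change is below `tol` (default
1e-6, max 100 iterations; rows first, the convention pinned down by the
tests). After each sweep the median of the effect vector is folded into mu,
so row and column effects have zero median at convergence. The B-score of a
well is its residual divided by the scaled median absolute deviation of all
analyzable residuals, `1.4826 * median|r|`, making scores comparable across
plates. B-scores are exactly invariant to adding constants to any row,
column, or the whole plate, and invariant to positive rescaling of the
input.

Numerical conventions: even-count medians use the midpoint of the two
central values; a row or column with no analyzable cells keeps a zero
effect and is flagged; a plate whose residuals are identically zero (MAD =
0) gets all-zero B-scores with a `degenerate` flag instead of an error, so
pipelines keep running on pathological inputs.

Control and empty wells are **excluded** from the polish and the MAD by
default. "Non-controls-based" normalization means the scores do not depend
on control performance; excluding controls additionally prevents a strong
positive-control column from leaking into library statistics. Whether the
original screen included controls in its polish is not knowable from the
outside, so `include_controls=True` is available for sensitivity analysis.

Replicates are aggregated by the arithmetic mean of finite per-replicate
B-scores, recording the replicate count; the aggregation rule is this
package's choice since triplicate screens rarely publish theirs.

### Hit calling and differential selection

A compound is called active in WT cells when its aggregated B-score
strictly exceeds `multiplier x SD` (default 3) of the aggregated B-scores
of **all** library compounds — hits are not trimmed before computing the
SD, which reproduces the published summary statistics and means the
threshold adapts to how active the library is. A MAD-based robust spread is
available behind `robust=True`.

Receptor selectivity is assessed on the paired delta
`delta = B(WT) - B(MUT)` (positive for WT-selective agonists). The
selection window is `mean(delta) +/- SD(delta)` over all compounds with
both genotype aggregates; calls are POSITIVE above the upper bound and
NEGATIVE below the lower bound, strict at both edges. The percent change
`100 * (B_MUT - B_WT) / B_WT` is reported wherever `B_WT != 0` (undefined
at zero, returned missing with a warning). Sample (n-1) standard deviations
are used throughout; that convention is what reproduces the published
class summaries to the printed precision.

### Structure-activity clustering

Hits are fingerprinted with extended-connectivity circular substructures of
diameter 4 (Morgan radius 2) folded to 2048 bits, and compared by Tanimoto
similarity. Clustering is greedy sphere exclusion (Butina): the unassigned
compound with the most unassigned neighbors at similarity >= cutoff
(default 0.6) becomes a centroid and absorbs those neighbors; ties break to
the lexicographically smallest compound id, making the partition
independent of input order. The published analysis used a proprietary
alignment tool configured with the same fingerprint and cutoff; this
package deliberately substitutes the open, reproducible sphere-exclusion
algorithm, so cluster counts are not expected to reproduce the published
14-cluster/70-compound figure (whose input compound list is unpublished
anyway). Clusters below `min_report_size` (default 3, inclusive — the
published cluster list itself contains size-3 clusters) remain in the full
partition but are listed as unclustered in the summary view. Two all-zero
fingerprints compare as similarity 1 with a warning.

### Dose-response pharmacology

Potency is modeled by the four-parameter logistic in log10 molar
concentration,

    y(x) = bottom + (top - bottom) / (1 + 10^((log_ec50 - x) * hill)),

the default curve model of standard assay software for this readout.
Fitting is nonlinear least squares with a deterministic multi-start: five
initial midpoints spanning the tested range crossed with both response
directions; the lowest-RSS solution wins, is canonicalized to
`bottom <= top` (negating the Hill slope, which leaves the curve
unchanged), and carries a standard error for `log_ec50` from the fit
curvature. Fits with `log_ec50` outside the tested range are flagged
`extrapolated` — their midpoint standard errors can be large, because one
asymptote is unconstrained by the data. Flat data yields a `degenerate`
flag (or `converged=False`) rather than an error. The assay grid default is
the 8-point half-log series from 1e-6.5 to 1e-3 M.

Genotype comparisons are z-tests on the difference of fitted `log_ec50`
values with combined standard errors, reported with the EC50 fold change
MUT/WT. This is an EC50-level test; a per-concentration Sidak-adjusted
contrast is available through the degranulation ANOVA machinery when
replicate-level responses are the unit of analysis.

Degranulation is quantified as percent release,
`100 * supernatant / (supernatant + lysate)` (the exact published formula
is not printed; this is the standard total-content normalization), and the
receptor dependence of release is tested by two-way fixed-effects ANOVA
(condition x genotype, exactly two genotypes, all cells n >= 2) with
per-condition genotype contrasts using the pooled residual error,
Sidak-adjusted for the number of conditions. A table with zero variance
everywhere returns F = 0 and p = 1 by convention. The ANOVA itself is
delegated to statsmodels.

## The synthetic screen generator

`simulate_screen` emulates the study design: ~3,456 compounds laid out
sequentially on 16x24 plates whose last two columns are vehicle and
substance-P control columns (352 library wells per plate), triplicate, both
genotypes, identical layout across genotypes and replicates. A well value
is assembled additively:

    baseline + effect(compound, genotype) + row_offset + col_offset + noise

Defaults (the generator's study conditions): baseline ratio 1.0, noise SD
0.05, row/column offset SDs 0.03, agonist fraction 3%, agonist effects
N(0.4, 0.15) truncated at zero on the ratio scale, mutant attenuation
N(0.05, 0.05) clipped to [0, 1] (i.e. ~95% of the WT effect lost,
mirroring the ~90% reported loss for mutant-attenuated hits), positive
control effect 1.5. The effect scale is sized so that, as in the real
screen, hit B-scores land one to a few multiples above the 3-SD cutoff;
the library size, plate format, replicate count and agonist fraction follow
the published design, while the effect and noise scales are this package's
choices (the raw screen data are unpublished). All randomness flows from
one seed through a split sequence — truth first, then plates in
WT-before-MUT, replicate-major order — so output is bit-identical per seed.
An optional multiplicative `edge_gain` on rim wells provides a deliberate
violation of the additive model for robustness checks.

What the generator does *not* emulate: kinetic traces (only the ratio
summary), compound-specific weak activity in the "inactive" class,
cross-reactivity with other receptors, plate-to-plate drift beyond the
per-plate offsets, and liquid-handling failures. Passing recovery tests on
this generator therefore demonstrates the pipeline's correctness under the
additive-artifact model, not performance on any particular real screen.

A property worth knowing when interpreting null screens: B-scores from an
iterated median polish are slightly heavy-tailed relative to a Gaussian.
The polish drives the central residuals of every row and column toward
zero, so the residual MAD underestimates the residual SD and the
standardized scores carry mild positive excess kurtosis (~0.2 after
triplicate aggregation at this plate size). The 3-SD rule on a pure-noise
screen therefore calls on the order of 0.2% of compounds rather than the
Gaussian 0.135% — about 1.5x the normal-theory tail. The Gaussian tail
figure is exact when the rule is applied to normally distributed scores
(verified by Monte Carlo in the tests); the pipeline-level excess is
intrinsic to median-polish B-scores, not a defect of the implementation.

## Problem sizes used in tests and the acceptance script

Agonist recovery is measured on full-size screens (3,456 compounds,
triplicate, both genotypes) pooled over 20 seeds in the test suite and 5
seeds in the acceptance script; the Gaussian null-rate Monte Carlo uses
10 x 10,000 scores; noisy EC50 recovery uses 50 replicate curves at 5%-of-
span noise; oracle-equivalence checks for the median polish and the
clustering greedy rule run on matrices up to 6x6, where exhaustive scalar
re-implementations are practical.

## Known limitations

- The hit threshold's SD includes the hits themselves; in libraries with
  many strong actives the threshold inflates (use `robust=True` to check
  sensitivity).
- Sphere-exclusion clustering is greedy: raising the cutoff does not
  guarantee a refinement of the partition, and centroids are not global
  optima of any objective.
- The EC50 z-test treats fitted log-EC50s as independent Gaussians; with
  few concentrations or extrapolated midpoints the curvature-based SEs can
  be optimistic.
- Percent-change scores are unstable when `B_WT` is near zero; interpret
  them jointly with the delta-based differential call.
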