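# Methods

This note documents the statistical procedures implemented in
`ecindex`, the choices made where the underlying workflow is
underdetermined, and what the synthetic experiments do and do not
demonstrate.

## Preprocessing model

Raw input is a samples × miRNAs matrix of nonnegative linear
fluorescence signals with one background scalar per array.

**Positive calls.** A probe enters the analysis on an array only when
its signal strictly exceeds that array's background; the background is
then subtracted, so retained linear values are strictly positive.
Censored cells ("negative calls") are carried as explicit missing
values end to end — a negative call is information ("below detection"),
not a zero.

**Internal-control normalization.** Array $i$ is rescaled by
$f_i = R/c_i$, with $c_i$ the arithmetic mean of the array's detected
internal-control signals (defaults miR-149-3p, miR-2861, miR-4463) and
$R$ the reference level. The reference is a genuinely open choice — the
ratio's target level is a platform convention — so both options are
exposed: `grand_mean` (the mean of the $c_i$ over the study; the
default for within-study work, where only relative scaling matters) and
`fixed_value` (a frozen reference produced by `freeze_reference`,
required to score a single prospective array onto a training scale;
this frozen-reference mechanism is a design of this package, not a
documented step of the original workflow). Under a fixed reference the
transform is exactly invariant to any per-array multiplicative
artifact; under the grand mean, rescaling one array moves every
normalized value by one common factor ($R$ is the only coupling).

**Log scale.** Discriminants operate on log2 normalized signals —
log2 is the standard working scale for fluorescence arrays, and the
original coefficient scale is not recoverable, so this is fixed as the
repository convention. Values are floored at `pseudo_floor` (default
0.1 linear units) before the log, and negative calls among a model's
features are imputed at the floor at scoring time: deterministic,
conservative low-expression handling.

**Robust filter.** A miRNA is retained when its normalized linear
signal strictly exceeds `signal_threshold` (default 64) in strictly
more than `sample_fraction` (default 0.5) of the samples of *every*
group. Both inequalities are strict (literal reading of
"exceeding"/"more than"); "each group" is read as all groups, with
`any_group` available since the phrase admits the weaker reading.
Missing cells never count as exceeding. The rule is monotone: raising
either threshold can only shrink the selection.

## Fisher discriminant and LOOCV

For features $S$, labels case/control, the fitted direction is
$w = (S_w + \lambda I)^{-1}(\bar{x}_1 - \bar{x}_0)$ with $S_w$ the
pooled within-class scatter (sum of squared deviations around each
class mean) and ridge $\lambda = 10^{-8}$ by default — a numerical
stabilizer only, not a tuned hyperparameter. The intercept centers the
boundary at the class-mean midpoint (equal priors, the default for
1:1-designed cohorts); empirical priors add $\ln(n_1/n_0)$. The Fisher
direction is defined only up to positive scale, so coefficient
*magnitudes* are a convention; predictions are scale-invariant, and no
attempt is made to reproduce the published coefficient magnitudes
(feature identity and sign pattern are the comparable surface). A score
strictly above the threshold predicts case; an exact tie predicts
control (deterministic, favors specificity).

Leave-one-out cross-validation refits on every fold. Removing sample
$i$ from its class downdates the pooled scatter by rank one,
$S_w^{(-i)} = S_w - \tfrac{n_c}{n_c-1}u_iu_i^\top$ with
$u_i = x_i - \bar{x}_{c(i)}$, so each fold's solve reduces to a
Sherman–Morrison update of one per-subset inverse. The batched
implementation evaluates hundreds of candidate subsets across all folds
in single vectorized passes; a naive per-fold refit oracle pins its
correctness in the tests (agreement to 1e-7 relative on scores, exact
on predictions).

## Beam search and final-model selection

Size-1 round: every candidate miRNA is scored by LOOCV accuracy and the
best `beam_width` (default 20) kept. Round $s{+}1$: every kept size-$s$
combination is extended by every remaining candidate (per-member
extension — the broader of the two readings of "each remaining miRNA
was added to the selected 20"), identical feature *sets* are collapsed,
and the pool is re-ranked and pruned to `beam_width`, through
`max_features` (default 8). Ranking ties are broken by higher
training-set AUC, then by lexicographically smallest sorted feature
tuple — the procedure is total and deterministic, byte-identical across
runs. Whenever the beam is at least as wide as the number of size-$s$
subsets, the search is provably exhaustive, which the tests exploit as
an oracle.

The final model is the smallest size whose best LOOCV accuracy is
within `epsilon` (default 0.005) of the best across sizes — a
formalization of "high accuracy with few miRNAs". Epsilon is exposed;
0.005 means "within half an accuracy point of the plateau".

LOOCV-subset results are memoized by feature-set key within a search;
no incremental shortcuts are taken across subsets.

## The published EC index

The 6-miRNA discriminant is stored as frozen constants and scored
through the same code path as any fitted model. Its inputs are
normalized log2 signals under this package's conventions; since the
original publication does not state its signal scale, absolute scores
for externally normalized data carry that caveat. Screening arithmetic
is exact Bayes: $\mathrm{PPV} = \frac{se\,p}{se\,p + (1-sp)(1-p)}$ and
$1-\mathrm{NPV} = \frac{(1-se)p}{(1-se)p + sp(1-p)}$, reported at two
significant figures, full precision retained internally.

## Evaluation

AUC is the Mann–Whitney statistic (ties one half), identical to
trapezoidal integration of the ROC curve; the ROC sweeps thresholds
over unique scores descending, with tied scores moving diagonally in
one step. The AUC confidence interval is DeLong's (validated against
R's pROC); proportion CIs default to Wilson with Clopper–Pearson as an
option — the original report does not name its CI procedures, so exact
interval matching is not a goal. Subgroup read-outs compute sensitivity
within tumor-stage strata (cases) and specificity within control-cohort
strata (controls) at the model's fixed threshold; no cutoff
re-optimization is ever performed.

## Synthetic cohorts

The generator emulates exactly the structure the pipeline assumes:
log-normal signals (Gaussian log2 noise, sd 1.0) around per-miRNA
baselines drawn uniformly on log2 [6, 14] — straddling the detection
threshold 64 = 2^6; a log-normal per-array scale factor (sd 0.25) that
normalization must remove; three near-constant internal controls (log2
levels 10/10.5/11, sd 0.05); planted differential miRNAs with log2
shift `effect_size` in cases, alternating up/down, optionally scaled
per stage; per-array Gaussian background (mean 30, sd 5 linear units —
well below typical signals so most probes are positive calls); and a
2% sub-detection dropout that injects negative calls. Default cohort:
100 + 100 samples, 500 probes, 6 planted markers at effect 4. Panel
properties (baselines, which miRNAs are differential) depend only on
the config seed; an optional `sample_seed` draws an independent cohort
on the same panel, which is how validation sets are simulated. Stage
and control-source frequencies default to a realistic ESCC case series
(half early-stage) and a three-source control mix.

What the generator does *not* emulate: correlated miRNA co-expression,
batch or site confounding beyond the array factor, heavy-tailed or
saturating fluorescence, and real 3D-Gene signal distributions in any
quantitative sense. Passing recovery tests therefore show the machinery
is correct and self-consistent, not that comparable performance would
be obtained on real serum cohorts — the published validation metrics
depend on the deposited data and are out of desk-scale scope.

A noteworthy property of the default (strong-effect) regime: one
planted marker alone classifies almost perfectly, so the parsimonious
selection stops at 1–3 markers rather than absorbing all six — the
best single marker is invariably planted, but full planted-set recovery
requires the weak-per-feature regime that real cohorts (single-miRNA
accuracy ~0.8) actually occupy. The no-signal control experiment runs
at 150 probes rather than 500 (the same 100 + 100 samples), a problem
size chosen to keep the full experiment battery fast; under the null
the searched model's accuracy is pure selection bias, and its
independent-cohort AUC falls in [0.4, 0.6] — the demonstration of why
external validation is indispensable.

## Numerical and edge-case choices

- Ridge 1e-8 on the scatter diagonal; exact singularity without ridge
  raises with advice rather than returning a pseudo-solution.
- Constant features give a zero direction, score exactly at threshold,
  hence all-control predictions (the tie rule), a defined degenerate
  result.
- Score ties at the decision threshold always predict control.
- LOOCV requires N ≥ 4 with ≥ 2 per class so no fold loses a class.
- Wilson/DeLong intervals are clipped to [0, 1]; degenerate DeLong
  variance (perfect separation) collapses the CI to the point estimate.
- Model JSON serializes coefficients at full double precision;
  round-trips are bit-exact.
- The GEO series-matrix reader is best-effort (annotations from
  `!Sample_characteristics_ch1` `key: value` pairs); the TSV dialect is
  the first-class interchange format, and no network access happens
  inside the library.

## Known limitations

- Coefficient magnitudes of refitted models are not comparable to the
  published index (scale non-identifiability; see above).
- The robust filter's group rule and the normalization reference level
  are configurable because the source workflow underdetermines them;
  defaults are the conservative readings.
- Wrapper selection with LOOCV is optimistically biased by
  construction; the package deliberately offers no nested-CV
  correction — independent-cohort validation is the intended check,
  and the null experiment quantifies the bias.
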