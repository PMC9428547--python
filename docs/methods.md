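# Methods

`coralrht` quantifies how much heat tolerance varies *within* a single
coral population, using the kind of data a long-duration experimental
heatwave assay produces: ordinal health scores and RGB colour readings
for replicate fragments of ~100 colonies held in heated tanks, plus tank
temperature logs, a symbiont type-profile table, and quarterly DHW
projections from a climate-model ensemble.  This note documents the
models, the synthetic data that stands in for the original experiment,
and the numerical choices that matter.

## Heat stress metric

Accumulated heat stress is expressed as degree heating weeks (DHW,
°C-weeks): the trailing 84-day sum of daily SST anomalies at least 1 °C
above the maximum of the monthly-mean climatology (MMM), divided by 7.
Two conventions are configurable and documented because the definitions
in circulation differ at the margins:

* anomalies **equal** to 1 °C accumulate by default (`include_equal`,
  the operational convention); a strict `>` variant is available;
* the first 83 days accumulate over the available partial history
  rather than being missing — an experiment starts from zero stress.

Inside tanks the satellite MMM is meaningless, so tank DHW accumulates
above an **adjusted stress threshold** supplied by configuration
(default 30.0 °C for the synthetic study: ambient 29 °C + 1).  The
algorithm is otherwise identical.

## The synthetic experiment

The generator emulates the study design rather than any particular data
set: 102 colonies, one fragment per colony in each of five heated tanks
and one procedural control tank.  Colony `i` has a latent death
threshold `theta_i ~ Normal(6.8, 1.38)` °C-weeks; fragment `(i,j)` has
`theta_ij = theta_i + Normal(0, 0.4)`.  Tanks follow the ramp +1 °C on
days 1, 4 and 8 and +0.5 °C on day 21 from a 29 °C ambient; assessments
are every 3 days until day 10 and daily afterwards.

Fragment trajectories are **threshold-driven and deterministic given
`theta_ij`**: a fragment dies (status 4) at the assessment where its
tank's DHW first reaches `theta_ij`; visible bleaching starts
`bleach_offset = 1.5` °C-weeks before death, and the intermediate
ordinal states (partially bleached, bleached, partial mortality)
advance every `logistic_scale = 0.6` °C-weeks within that window.  A
13% random subset of fragments ("direct deaths") skip the visible phase
entirely, as observed in long heatwave assays.  Because every fragment
follows the same response shape shifted by its own threshold, the
group-level dose-response is an exact horizontal shift — the property
the GLMM stage is built to recover, which makes recovery a sharp test.
A hazard-free design was chosen deliberately over stochastic fates: a
per-fragment logistic fate noise at the configured scale was evaluated
by simulation before the build and collapses the classified tails to
~16%, far from the high-20s regime the assay design produces.

Each stress tank stops being recorded at the first assessment at which
at least half of its fragments are dead (a population-level mass
mortality endpoint).  Control fragments experience no heat but die of
handling with probability 0.02 per colony; such colonies are excluded
from every downstream stage.  RGB colour is emitted for live fragments
as a status-dependent whiteness (0.45 / 0.70 / 0.95 of 255, partial
mortality treated like bleached) with Gaussian channel noise (sd 10),
clipped to [0, 255] — arbitrary but fixed values so colour-pipeline
tests are stable.

What the generator does **not** emulate: tank microenvironment effects
(all stress tanks share one temperature history, so they terminate at
nearly the same DHW, whereas real tanks spread out), symbiont
shuffling, physiological covariates, and observer error in the ordinal
scores.  Two consequences matter for interpreting passing tests.
First, the observed DHW range ends just past the population median
threshold (~7 °C-weeks), so the most tolerant decile often shows no
response at all within range — real assays with tank spread observe
more of the tolerant tail.  Second, because endpoint fates are recorded
at the first assessment at or past the 50% crossing, realized endpoint
mortality overshoots 50% slightly (~0.56), which makes the all-dead
fate more common than all-alive: the low-tolerance tail classifies at
~40% while the high-tolerance tail sits at ~29-31%.

## Tolerance classification

A colony is **RHHT** (relatively high heat tolerance) if all five
stressed fragments are alive at their tanks' final assessments, and
**RLHT** if all five are dead.  The chance probability of an all-same
fate under endpoint mortality `p` is `p^n` (all dead) or `(1-p)^n` (all
alive), one-tailed in the observed direction; a category is assigned
only when it is below `alpha = 0.05`.  With five fragments and `p =
0.5` the bound is `0.5^5 = 0.03125`.

The test rate defaults to the **design rate 0.5** — the rate the
termination rule enforces — rather than the realized pooled rate.  The
realized rate necessarily lands just above 0.5 (fates are recorded at
the assessment that crosses the 50% line), and `0.55^5 ≈ 0.05` sits
exactly at the alpha knife edge, which would make the RLHT class
flicker in and out of existence for no biological reason.  The realized
rate remains available (`p_hat="realized"`).

Mean BMI between the groups is compared with a two-sample rank test;
the reported `W` is the Mann-Whitney U of the RHHT group (rank sum
minus its minimum), a convention stated here because `W` definitions
vary across software.

## Indices and profiles

BMI at one assessment is the category-proportion weighted sum
`(0c1+1c2+2c3+3c4+4c5)/4`, equal to the mean ordinal status divided by
4; colony mean BMI is the plain average of daily values (not
DHW-weighted).  CMI replaces live-state scores with the RGB Euclidean
norm normalized by the experiment-wide maximum (range [0, 1]); partial
mortality scores intensity + 1 and death pins the score at 2.  Colony
CMI aggregates fragments by the **median** (midpoint convention for
even counts); a mean switch exists for sensitivity.  Intensity
fractions are clipped at 1 rather than renormalized when a
partial-mortality fragment is unusually bright.

Index observations are mapped from assessment day to the observing
tank's DHW, linearly interpolated onto a shared grid (step 0.1
°C-weeks, from 0 to the largest DHW any tank survived to), and
aggregated across tanks (mean for BMI — which reproduces the
five-fragment proportion definition exactly — median for CMI).  No
extrapolation past a tank's termination: later grid cells are missing
for that tank, and cells missing for every tank stay missing.

Profile matrices are z-scored column-wise (population sd; zero-variance
columns map to zeros) and clustered hierarchically with Euclidean
distances and the classic Ward update applied to unsquared distances
(R's `ward.D`).  SciPy's Ward routine squares its inputs internally, so
the implementation feeds it the square roots of the distances and
squares the returned heights — verified against an independent R
`hclust` run.  Missing cells use pairwise-complete distances rescaled
by `sqrt(p/p_shared)` (the `dist` convention).  Merge ties follow
SciPy's deterministic nearest-neighbor-chain order.

## Dose-response GLMM and ΔDHW

Colony BMI profiles of classified colonies are encoded as binomial
counts `k = round(20 * BMI)` out of `m = 20` (five fragments × four
ordinal steps — the finest grid the index attains) and thinned to one
observation per 0.5 °C-weeks to limit the serial correlation of
interpolated grid points.  The model is

    logit E[BMI] = b0 + b1·DHW + b2·[RLHT] + b3·DHW·[RLHT] + u_colony,
    u_colony ~ Normal(0, sigma_u²),

fitted by maximizing the Gauss-Hermite-quadrature marginal likelihood
(25 nodes, analytic gradient, L-BFGS-B with a trust-region polish and
three starts — the surface has a degenerate basin in which `sigma_u`
absorbs the group contrast, and the best optimum is kept).

Internally the fit is parametrized with per-group intercepts and
**log-slopes**, so dose-response slopes are positive by construction
(heat stress never improves the response), under weakly informative
priors: Normal(0, 10²) on intercepts, Normal(0, 1.5²) on log-slopes,
and Normal(0, 0.5²) on the log-slope *difference*.  The last prior
shrinks the interaction toward parallel curves — exactly the
horizontal-shift structure the analysis interprets — and matters only
when one group barely responds inside the observed DHW range: there the
unpenalized MLE diverges (complete separation), and without the
shrinkage the inverse-dose ratio for that group is arbitrary.  For
identified data all three priors are overwhelmed by the likelihood (the
recovery tests bound the bias).  The fixed-effect covariance is the
inverse observed information, transformed to reference coding.

The DHW dose at a BMI level `b` for group `g` is
`(logit(b) - intercept_g)/slope_g`; confidence intervals come from a
parametric bootstrap (1000 multivariate-normal draws of the fixed
effects, percentile 2.5/97.5).  Draws with non-positive slope have no
crossing and are dropped; the tolerated fraction is 5% for direct
calls and 50% inside the stepwise driver, where the realized fraction
is recorded per step.  ΔDHW is the per-draw difference of group doses
(RHHT minus RLHT); a delta-method CI is deliberately not offered — the
dose is a ratio and its normal approximation is poor near weak slopes.

The comparison level BMI* is the highest multiple of 1/20 at or below
0.5 for which both groups' dose CIs lie inside the observed DHW range
(the highest horizontal cut that all confidence bands reach).  When no
level qualifies — typical for decile subsets under this generator's
truncation — the stepwise driver uses the lowest attainable level
(0.05) and flags the step `level_admissible = False`; direct calls
raise instead.

The stepwise tail reduction starts from the full groups and, at each
iteration, removes from each group still above the target the colony
whose mean BMI is closest to the population-average mean BMI (computed
over all non-excluded colonies, classified or not; ties broken by
colony id), refits, reselects BMI* and re-estimates ΔDHW until both
groups reach `target_n = 10` — the population deciles for a ~100-colony
study.  Because unequal groups reach the target at different
iterations, the larger group keeps shrinking while the smaller holds.

## Climate projection stage

Quarterly projected DHW per GCM is annualized by the **within-year
maximum** (DHW is already an accumulation; the peak is the year's
stress; an annual-sum switch exists for sensitivity).  The onset of
annual bleaching-mortality (ABM) conditions at tolerance threshold `T ∈
{4, 8, 12}` °C-weeks is the first year from which ten consecutive years
all meet or exceed `T` (inclusive exceedance); models whose horizon
ends before any qualifying decade are censored.  Onset years are
modelled as `onset ~ threshold × scenario` with a random intercept per
GCM (statsmodels MixedLM, REML); the 15 pairwise contrasts of the six
cell means are adjusted with the studentized range (Tukey) using a
containment degrees-of-freedom approximation (observations minus cells
minus GCM intercepts).  Censored runs are excluded with a logged count
rather than imputed at the horizon end.

The synthetic GCM ensemble draws quarterly DHW as
`max(0, baseline + model offset + trend·(year-2015) + noise)` with
per-scenario trends 0.235 (moderate mitigation) and 0.40 (high
emissions) °C-weeks/yr, baseline 1.0, offset and noise sd 1.0.  The
trends were set from the projected relationships the analysis is meant
to exhibit — roughly a decade of delay per 4 °C-weeks of extra
tolerance under fast warming, substantially more under mitigation, with
annual severe stress (8 °C-weeks) emerging near the early 2030s — and
are not fitted to any data.

## Problem sizes and reproducibility

Every generator stream derives from one master seed through fixed
stream offsets; identical seeds give byte-identical tables, and the
pipeline report is reproducible end to end from the master seed.  The
acceptance script replicates the full analysis over 20 seeds (the
replicate count used for all across-seed summaries in the tests as
well) at the default study size of 102 colonies; a single replicate
fits roughly 30 GLMMs during the tail reduction and runs in a few
seconds.

## Known limitations

* With all stress tanks sharing one temperature history, the observed
  DHW range ends near the population median threshold; decile-level
  ΔDHW then rests partly on the parallel-curve prior rather than direct
  observation of the tolerant tail, and carries wide, honestly reported
  intervals.
* The binomial encoding treats the 20 index steps of a colony-DHW cell
  as independent trials; they are not (five fragments × four ordinal
  steps), so the model's nominal binomial dispersion is optimistic.
  The bootstrap CIs inherit this.
* The LMM degrees of freedom use a containment approximation;
  Satterthwaite/Kenward-Roger corrections are out of scope.
* The ITS2 stage consumes a relative-abundance table; no sequence
  processing of any kind is attempted.
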