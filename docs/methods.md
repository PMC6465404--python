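# Methods

This note records the models, parameter choices and numerical conventions
behind `playseq`, and what the synthetic validation does and does not
establish about real data.

## Sequence model

Behaviour is interval-sampled: a 30-minute observation at 5-s resolution
gives T = 360 positions per animal.  Raw scoring has two channels —
an instantaneous state (`ObjP_ground`, `ObjP_off_ground`, `NoP`) and
one-zero flags for locomotor and social play within the interval.  The
analysis alphabet merges these to three states with priority
`ObjP > LocSocP > NoP`: any instantaneous object play dominates, then a
set flag, then no play.  Unscored intervals carry a reserved missing
marker; adjacent pairs that span a gap contribute no transition counts,
entropy uses observed proportions, and a state that resumes unchanged
after a gap continues its spell (so the spell sequence never repeats a
state in adjacent positions).

### Complexity measures

For an observed sequence with state proportions πᵢ over an alphabet of
size a:

* longitudinal entropy h(x) = −Σ πᵢ ln πᵢ / ln a ∈ [0, 1] (natural log;
  the normalisation makes a uniform time budget score 1);
* turbulence T(x) = log₂( φ(x) · (s²ₘₐₓ + 1)/(s² + 1) ), with φ(x) the
  number of distinct subsequences of the spell-state sequence (exact
  integer recurrence φₜ = 2φₜ₋₁ − φₖ₋₁, k the previous position of the
  same symbol), s² the population (divide-by-n) variance of spell
  durations and s²ₘₐₓ = (n−1)(1−t̄)².  The population variance is chosen
  so s²ₘₐₓ is exactly attainable; base-2 log follows the established
  sequence-analysis convention.  A single-spell sequence scores exactly 1;
* complexity index C(x) = sqrt( q/qₘₐₓ · h ) ∈ [0, 1], q the number of
  state changes between adjacent observed positions and qₘₐₓ the number
  of adjacent observed pairs.

## Optimal matching

OM distance is the minimal edit cost under insertions/deletions at
constant cost 1 and substitutions priced by
SC(i, j) = 2 − p(j|i) − p(i|j), computed from lag-1 transition rates
pooled over the whole dataset (per-stratum pooling is available but the
pooled matrix is the default: substitution costs should reflect the
global interchangeability of states, not stratum idiosyncrasies).  No
length normalisation is applied because all sequences share one grid.
The dynamic programme is exact; within a row the constant-indel
insertion scan is a min-plus prefix scan, folded into a running minimum,
and all pairs are advanced through the recursion simultaneously (the
grid has no right-to-left dependencies, so sequences of unequal observed
length are padded and each pair's distance read at its own corner).

## Clustering and validation

Ward agglomeration is applied to the OM dissimilarities through the
Lance–Williams recurrence.  The default `D2` convention squares the
dissimilarities inside the recurrence and reports merge heights on the
original scale; the historical `D` convention is available by flag.  The
number of clusters is chosen by maximising the average silhouette width
over k = 2..8; Hubert's C index (share of the way the within-cluster
distance sum sits between its best and worst possible values over the
same number of pairs; lower is better) is reported alongside, and when
the two criteria disagree both candidate k values are exposed with the
silhouette winner taken.  Silhouette values of singleton-cluster members
are defined as 0, as is the 0/0 case.

## Player typing

Every object-play onset is either an *initiation* (the animal starts on
a toy no penmate is currently playing with) or a *join* (it starts on an
occupied toy); every object-play interval is spent *alone* or *together*
according to whether a penmate concurrently interacts with the **same
toy** — a definition that matters, because with two toys animals
frequently play simultaneously without sharing one.  Classification on
each axis is an exact one-sample proportion test against 0.5: two-sided
90% Clopper–Pearson interval entirely above 0.5 → initiator (resp.
solitary), entirely below → joiner (social), else mixed.  Wilson and
normal-approximation intervals are available by flag; the exact interval
is the default because per-animal onset counts are small (tens).  The
initiator/joiner axis uses onset events; the solitary/social axis uses
interval counts, reading "proportion of time" at the 5-s resolution.

Association between the axes uses Kendall's tau-b for ordered r×c
tables, with the asymptotic standard error under the alternative (the
Goodman–Kruskal variance form, suitable for confidence intervals).  With
rows initiator < mixed < joiner and columns solitary < mixed < social
the association on the published reference table is +0.614; the sign is
a pure coding convention.  The Fisher test for r×c tables enumerates all
margin-preserving tables when at most 10⁶ exist, otherwise it switches
to a seeded Monte-Carlo permutation of column labels with the standard
(1 + hits)/(1 + replicates) estimator.

## Stratified tests and models

The CMH test uses the classic Σ(aₖ − Eₖ)² / ΣVar form with
hypergeometric variances, no continuity correction, df = 1 for 2×2×K;
strata with a zero margin carry no information and are skipped with a
warning.  An I×J×K general-association extension inverts the summed
multiple-hypergeometric covariance (df = (I−1)(J−1)).  Transition-usage
comparisons between initiators and joiners are run per ordered state
pair (transitioned vs other departures from the from-state), stratified
by group, Bonferroni-corrected over the six off-diagonal comparisons.

Bout durations (maximal `ObjP` runs, in intervals) are modelled by a
fixed-effects log-link Poisson regression on group, treatment, sex,
player type, the two weights and bout start time in seconds (interval
index × 5).  Complexity traits are modelled by ordinary least squares
with sum-to-zero contrasts and marginal (Type-III-style) F tests, so the
per-term tests do not depend on factor level order.  Random-effect
variants are deliberately out of scope: with one sequence per animal and
four animals per group, the fixed-effects fits are the honest option.

## Synchrony

The unit is the per-interval count of animals simultaneously in a target
state.  Two null models are first-class because "expected by chance" is
genuinely ambiguous:

* the **independence null** computes P(≥ k of 4 simultaneously playing)
  from the Poisson-binomial over the animals' marginal play
  probabilities — analytic, but blind to autocorrelation, so it
  overstates synchrony evidence for bouty behaviour;
* the **cyclic-shift null** rotates each animal's sequence by an
  independent uniform offset per permutation, preserving marginals and
  autocorrelation exactly while destroying cross-animal alignment.  The
  one-sided p is (1 + #{null ≥ observed})/(1 + n_perm); ties count
  against rejection, making the test slightly conservative.  The 95% CI
  on the observed share is a Wilson interval.

Rotation nulls assume the relative phase of animals is exchangeable;
behaviour time-locked to an external event (such as the toy
introduction) violates this, so calibration uses time-homogeneous
dynamics.

## Synthetic generator

The generator reproduces the study design it emulates: 15 groups × 4
littermates × 360 intervals, two toys, ~1.4% missing records (the gap
between the 21,600 expected and ~21,300 scored intervals), and a state
budget of roughly 49% `ObjP` / 5% `LocSocP` / 46% `NoP`.

Object play follows a two-state entry/exit hazard chain per animal,
phase-modulated by the group's archetype: play-rich windows (entry 0.22,
exit 0.06 per interval) against play-poor background (entry 0.004, exit
0.30).  Archetype A is rich in intervals 1–120 only (early players),
B throughout (sustained), C in alternating windows 1–60, 121–180,
241–300 (intermittent).  The windows are anchored to the toy
introduction, giving each archetype a shared temporal template; the
archetype mixture (A 25%, B 30%, C 45%) is apportioned over groups by
largest remainder so every seed carries a balanced planted design.

Social coupling adds γ (default 0.4) to the log-odds of entering object
play per penmate playing in the previous interval.  Player types modulate
entry through a mode-preference factor — 2π when no penmate plays, 1
when a free toy exists alongside players, 2(1−π) when every toy is taken
— plus an exit-hazard multiplier (initiators 0.5, joiners 1.2).  The
factor is exactly 1 for π = 0.5, so neutral-type groups with γ = 0 are
fully independent; this anchors the synchrony null calibration.  Onset
labels follow the toy: an entry onto an unoccupied toy is an initiation,
onto an occupied toy a join.  Locomotor/social flags are overlaid
independently of the toys at a rate giving ~5% merged `LocSocP`
(69% locomotor), and a 5% per-interval toy-switch hazard keeps toy
allegiances from freezing.  Covariates (sex, handling treatment, birth
weight ~ N(1.5, 0.25²) kg, nine-week weight = 18 + 4.5·birth + N(0, 2²)
kg) are drawn per animal; latency to approach is derived from the first
simulated play interval rather than drawn.

The homogeneous preset used for calibration compensates the base entry
hazard for γ through a mean-field fixed point (penmate count ≈
Binomial(3, share)), keeping marginals comparable across coupling
strengths.  The mean-field ignores the positive cross-animal correlation
that coupling itself induces, so realized shares drift low at large γ
(≈ 0.07 instead of 0.35 at γ = 2); the drift reduces power and therefore
cannot manufacture the observed power monotonicity.

### What passing tests show — and do not

The planted-truth suite shows the chain *recovers what the generator
plants*: three archetypes are found at k = 3 with adjusted Rand ≥ 0.8,
strongly-typed players (π = 0.9/0.1, ~30 onsets each) are reclassified
correctly ≥ 90% of the time, and the rotation null holds its 5% level
under independence while gaining power with coupling.  Real pens differ
in ways the generator deliberately simplifies: play phases are not
cleanly windowed, so real silhouettes will be weaker than synthetic
ones; and because grouped play here is window-synchronised, same-toy
sharing is denser than in real pens — the generator consequently
produces far fewer solitary-typed animals than a real population, and
the solitary/social axis is exercised primarily on the published
reference table rather than on generated margins.  The association
statistics, tests and measures themselves are validated exactly against
enumeration, closed forms and independent library oracles, independent
of the generator.

## Numerical conventions

* Transition rows with no observed from-state are all-zero and flagged,
  never renormalised; substitution costs fall back to the available
  direction with a warning.
* Tau-b is undefined (error) when a margin is entirely tied; the
  pipeline reports nulls with a note instead of aborting.
* Hubert's C with all pairwise distances equal is defined as 0 with a
  warning; an all-identical distance matrix yields a `degenerate`
  cluster solution rather than an error.
* Monte-Carlo p-values always use (1 + hits)/(1 + n); every stochastic
  routine takes an explicit seed and the pipeline derives all child
  seeds from one master seed.
* Problem sizes in the validation suite: 200 random pairs for the OM
  oracle, all ~3,000 valid spell sequences of length ≤ 10 for the
  subsequence-count oracle, 50 random instances per statistic oracle,
  400 simulated groups for null calibration and power.
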