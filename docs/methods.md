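# Methods

## Calendar convention and curve handling

Calendar time is a signed year on a continuous axis, `calAD = 1950 − calBP`;
negative years display as `N cal BC` with `N = −year`, and no year-zero
correction is applied.  Curves are piecewise linear between their knots in
both the mean `μ(θ)` and the curve uncertainty `σ_c(θ)` — exact for 5-year
knot spacing at the 1-year reporting resolution used throughout.  The
IntCal `.14c` reader consumes `calBP, age, error` triplets ('#' comments,
comma- or whitespace-separated, extra columns ignored) and re-sorts records
into increasing signed year.  Reverse lookup of a simulated age evaluates
`μ` at the year of death and rounds to 0.1 BP; no measurement noise is
added, so a simulated date's true year always attains the likelihood
maximum.

## Single-date calibration

The likelihood combines measurement and curve error in quadrature,

    p(θ | x) ∝ exp(−(x − μ(θ))² / 2(σ² + σ_c(θ)²)),

evaluated on a uniform grid (default 1 calendar year) and normalised to unit
mass; the grid is trimmed to where the density exceeds 10⁻¹² of its peak.  A
posterior peaking at the edge of the curve support carries a warning flag
rather than raising.  The variance-dependent normalising factor
`(σ² + σ_c(θ)²)^(−1/2)` is deliberately omitted: over the narrow windows a
single date occupies, `σ_c` varies little and the flat-likelihood form keeps
the calibration identical to the convention used by the standard
chronological-modelling software this package is designed to cross-check
against.

Highest-posterior-density regions admit grid cells in decreasing density
order until the target mass (68.2% / 95.4%) is reached; ties break toward
older cells so output is deterministic.  Contiguous runs become sub-ranges
`(older, younger, mass)`.  The *outer span* is `youngest − oldest` across
all sub-ranges with internal gaps ignored — the span-accounting convention
used for every number this package reports.  On a discrete grid the admitted
mass can overshoot the target by at most one cell's mass (≤ ~1% at 5-year
resolution, negligible at 1-year).

## The ordered-phase model

Phases (generation levels) are contiguous: adjacent phases share one
boundary, giving boundaries `b_0 ≤ … ≤ b_K` for `K` phases.  The prior is
the standard uniform-phase convention: event years uniform within their
phase, contributing `(b_j − b_{j−1})^(−n_j)` per phase with `n_j` members,
and boundaries uniform over the model support.  The support is the union of
the single-date calibration windows padded by 150 years on each side (and
clipped to the curve support): wide enough that the mild entropy-like edge
effect of the boundary prior is far from the likelihood mass.

An `Interval(mean, sd)` prior multiplies a normal density on the gap between
the two boundaries it sits between.  With contiguous phases that gap is the
span of the preceding phase — the natural reading of an interval placed
between a phase and the following boundary — and for generation models the
interval mean is the difference of consecutive generations' mean years of
death (the simulation framework computes this from the prescribed deaths; sd
is fixed at 10 years to express that real generation gaps are never known
exactly).  "Died before or simultaneously" pairs are encoded as ordered
phases whose gap may be zero.

## Sampler

Metropolis-within-Gibbs with Gaussian random-walk proposals (scale 15 yr):
each event year is updated conditional on its phase boundaries (proposals
outside the phase are rejected, otherwise accepted by the likelihood ratio),
then each boundary conditional on its neighbours and the events it must
enclose (accepted by the span/interval prior ratio).  Defaults: 5,000
burn-in + 50,000 iterations, thinning 5 (10,000 retained draws), a mandatory
integer seed driving a single `random.Random` stream — results are
bit-for-bit reproducible.  Per-date likelihoods are pre-tabulated on a
1-year lattice and linearly interpolated, which makes a ten-date,
five-phase, 55,000-iteration run take about a second on one CPU.

Marginals are histograms of the retained draws on bins centred on multiples
of the reporting resolution (default 5 years, matching common practice for
5-year-knot curves and aligned with the calibration grid), lightly smoothed
with a (¼, ½, ¼) kernel to stabilise HPD endpoints.  Initialisation takes
each date's unmodelled median, projects the set onto a strictly increasing
phase order, and places boundaries midway between adjacent phases.

Correctness is established against brute-force oracles in the test suite:
for two- and three-phase single-date-per-phase models the boundary nuisance
parameters integrate out in closed form (log factors) or by midpoint
quadrature, and the sampler's marginals agree with the gridded posterior to
total variation < 0.02 at 10⁵ retained draws — the residual being sampling
noise, as seed-to-seed comparisons show the same magnitude.  A one-phase,
one-date model reproduces plain calibration to the same tolerance.

## Agreement indices and diagnostics

Individual agreement is the overlap ratio `A_i = 100·Σ p′p / Σ p²` between
the modelled marginal `p′` and the unmodelled calibration distribution `p`
as per-cell masses on a common grid; identical distributions give exactly
100, disjoint ones 0, and concentration onto the likelihood mode can push
`A_i` above 100.  The model agreement is `100·Π(A_i/100)^(1/√n)`.  Values
below the conventional 60 threshold flag the summary — conflict is reported,
never raised, because a low agreement is itself the diagnostic of interest
(e.g. when testing competing death orders).  Convergence is monitored with a
split-chain potential-scale-reduction statistic on each event-year series;
values beyond 1.1 attach a warning.

## HBCO, C:N and separation caps

The human bone collagen offset (0–25 years, from the anthropological
age-at-death via a user-supplied mapping or an input column) is subtracted
from the conventional age *before* modelling; the corrected determination is
flagged so the subtraction cannot be applied twice.  Subtracting years from
the BP age moves the calibrated distribution younger.  The C:N gate passes
ratios in [2.9, 3.6] inclusive.

Year-of-death separation caps truncate modelled ranges after sampling: with
separation `sep`, a date in generation `k` (1-based) is capped at
`end(gen 1) + Σ_{g<k} min(sep, gap_g)` where `end(gen 1)` is the youngest
2-sigma bound of the first generation and `gap_g` is the known (or modelled)
mean gap between consecutive generations when available, else `sep`.  The
per-gap clipping `min(sep, gap)` is this package's reading of how a known
small generation gap should tighten the cumulative cap; truncated densities
are renormalised inside the cap, so capping never widens a range and never
reorders phases.  Symmetric older-end caps (counted backwards from the last
generation, unclipped) are off by default — they only bind when gaps exceed
the separation.

## Synthetic study curve and simulations

No measured calibration dataset is redistributed with the package.  The
bundled study curve is *synthetic*: deterministic piecewise-linear segments
on 5-year knots (σ_c ≈ 10 BP) encoding the structural regimes that drive
calibrated-range behaviour — a long plateau between 770 and 400 cal BC with
two sub-plateaus split at 540 cal BC and two internal troughs (producing
multi-modal, inverted single-date ranges), a steep stretch at 7600–7500 cal
BC followed by a wiggle shelf, a mixed section at 2040–1770 cal BC with two
sine-wiggle packets around a short steep drop, a steep anchor approach at
810–770 cal BC, and a background slope of ~1 BP/yr.  Feature positions are
fixed generator parameters, not fitted to any dataset.

The simulated pedigree is single-strand: five generations, two adults each,
years of birth stepping 20 years per generation (a mean pre-industrial
reproductive age), `YoD = YoB + AaD` with a fixed AaD table inside [35, 60],
and every generation dying before the next (validated).  The four scenarios
shift the same pedigree along the curve: plateau (first individual dies 655
cal BC, in a trough), steep, mixed, and anchor — the plateau pedigree 135
years older, so its earliest death (800 cal BC) falls on the steep approach.
The AaD table is chosen once to honour those prescribed deaths
(A1 = 790, A2 = 800, E1 = 695, E2 = 707 cal BC in the anchor frame) within
the [35, 60] bound; all AaDs are explicit configuration, not hidden
constants.  Measurement errors of 20/25/30 BP are supported, 25 being the
default reporting level.

`run_experiment` reruns a scenario with 2–5 sequenced generations, with and
without interval priors (eight model runs), against the unmodelled baseline,
and tabulates spans, improvements and truth coverage.  What passing these
simulations shows: the sampler respects order constraints, brackets middle
generations, resolves curve-induced inversions, and always covers the true
death years.  What it does not show: agreement with any measured
calibration dataset — the synthetic curve reproduces regime *shapes*, not
IntCal values, so published numbers tied to IntCal13 (specific calendar
endpoints and case-study spans) are only reproduced when a user supplies the
public curve files, which the corresponding tests then pick up
automatically.

## Problem sizes and defaults

Default sampler settings (50,000 iterations, 10,000 retained draws) were
chosen so a full scenario grid — eight model runs of up to ten dates — takes
a few seconds and the complete simulation battery with all four scenarios
runs in under a minute on a single CPU, while seed-to-seed variation of HPD
endpoints stays within the 5-year reporting grid.  The oracle comparisons
use 200,000 iterations (10⁵ retained draws) to push sampling noise safely
under the 0.02 total-variation bound.

## Known limitations

* Multi-strand pedigrees are modelled per strand; joint multi-strand models
  (shared individuals across strands) are out of scope.
* The OxCal-dialect emitter/parser covers only the restricted
  Sequence/Boundary/Phase/R_Date/Interval subset used for pedigree models.
* Boundary priors follow the documented uniform-phase convention; other
  software versions may use slightly different boundary treatments, so
  agreement indices can differ by a few points.
* The separation-cap clipping rule and the interval-placement semantics are
  documented interpretations of under-specified conventions (see above).
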