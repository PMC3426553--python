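# Methods

## The mutation-accumulation model

A library generation is produced by copying every genome in the population
once per reverse-transcription cycle. Copying is modelled as an independent
Bernoulli trial per site: site i, currently carrying base b, mutates with
probability `rate × h(b)`, where `rate` is the mean per-nt per-cycle
substitution probability and `h(b)` a base-specific hazard multiplier derived
from the substitution spectrum (below). When a site mutates, the new base is
drawn from the spectrum's conditional row for the current base. A Bernoulli
process (rather than a Poisson count per genome) was chosen because at rates
≤ 10⁻³ the two are indistinguishable and the Bernoulli form handles
back-mutation naturally: a site that reverts to the reference simply stops
counting as mutated. "Mutated positions" of a clone are the positions that
differ from the reference at observation time — the quantity sequencing
reports.

Generation labels follow F_k ↔ k+1 cycles: producing the parental vector
stock already passes the gene through reverse transcription once. This
convention is what makes the rate estimator reproduce the canonical
sequencing-table arithmetic (9 cycles at F8, 17 at F16) and is overridable
via the explicit `cycles` argument.

### The substitution spectrum and base-dependent hazards

The spectrum is a joint mass over the 12 ordered substitutions; the default
puts 62.3% of all events on G>A (the signature of HIV-1 RT) and spreads the
remaining 37.7% uniformly over the 11 other types — the marginal is the only
constraint available, so the flat remainder is the least-informative
completion. Because the *marginal* fraction of G>A events is the configured
quantity, a uniform per-site hazard cannot realize it on a sequence with
~25% G content (the G>A fraction could never exceed the G content). Sites
therefore carry base-dependent hazards `h(b) = mass_from(b)/composition(b)`,
normalized so the sequence-averaged hazard is 1: the mean mutation load per
clone stays `rate × length × cycles`, and the realized event-type
distribution equals the configured mass. The consequence — G sites mutate
~2.8× faster than average under the default spectrum — means mutated
positions are uniform *within a base class* but not globally; the positional
goodness-of-fit test therefore takes the process's expected positional law
as its null (and reduces to the plain uniform test for a uniform spectrum).

### Recombination and selection

Copy-choice recombination builds an offspring as a mosaic of two co-packaged
genomes: copying starts on a uniformly chosen parent and switches template at
each position with probability `recombination_switch_rate`. The fraction of
genomes co-packaged with a distinct partner (`heterozygous_virion_fraction`)
is a direct parameter because no measurement of it exists for these vectors;
both default to 0 (off).

Selection is restricted to a lethal/neutral cis mask: any substitution at a
masked position removes the genome, which is replaced by a copy of a uniform
surviving genome in the same cycle. This emulates purifying selection on the
vector's cis-acting regions. Positive selection (e.g. promoter variants
sweeping to fixation) is deliberately not modelled — no fitness function is
available — so the simulator makes no claims about adaptive dynamics.

Every stochastic entry point requires an explicit seed; all randomness flows
through one `numpy` generator per call, so equal seeds give byte-identical
outputs.

## Rate estimation

M mutated positions summed over C clones (shared positions counted per
clone, matching how sequencing tables average per clone) over an exposure of
C·L·G site-cycles give `rate = M/(C·L·G)`. The 95% interval is the exact
Garwood interval on the Poisson count M, rescaled by the exposure — chosen
over a normal approximation because M is typically a few tens (for M = 0 the
upper bound is 3.689/exposure). Table-style renderings truncate rates to the
shown significant figures (1.1457×10⁻⁴ prints as 1.14×10⁻⁴ at three
figures) and round per-clone averages (0.875 prints as 0.88) — the two
conventions the reference tables in this field use; full precision is always
retained on the results object. The dispersion diagnostic uses the
(C−1)·(variance/mean) ~ χ²(C−1) approximation, with an undefined index (zero
mean) flagged rather than raised.

## Planning

The cycles-to-complexity rule is linear: p/(m·n) cycles for p expected
mutations per n-nt copy at rate m. The exact per-site complement
n·(1−(1−m)^c) is exposed alongside because linearity overestimates once
m·c grows, but the linear rule is the default planning convention.
Proviral copies per cell are Poisson(MOI) — the standard single-hit model
for VSV-G pseudotyped vectors — giving P(transduced) = 1−e^(−λ) and
P(≥2 | ≥1) in closed form; `recommend_moi` inverts the latter by bracketed
root-finding (relative tolerance 10⁻⁶). At the conventional screening MOI of
0.03, ~1.5% of transduced cells carry more than one variant.

## Screening analysis

Death rate is 1 − readout(c)/readout(0), clamped to [0, 1] with clamping
logged ("death rate" and "surviving fraction" are complementary; outputs are
labelled explicitly). Hit calling is replicate-wise: a clone scores in an
experiment when its death rate at the screening concentration (default
10 nM, alternates 35 and 70 nM — concentrations that kill >80% of all
populations are unusable for screening) exceeds the death rates of *both*
control populations; a hit needs ≥ `min_experiments` scoring experiments
(default 1).

Dose-response curves use the four-parameter log-logistic
`v(c) = bottom + (top − bottom)/(1 + (c/ic50)^hill)` with the top free,
because normalized transduced populations need not sit exactly at viability
1. Fitting is bounded least squares (trust-region reflective) with a
multi-start grid over log-IC50 and hill slope; a fit is flagged
non-converged when the optimizer fails, the span collapses below 0.02
(flat data — IC50 unidentifiable), or log-IC50 sticks to its bounds.
The reported IC50 is the curve's inflection (relative IC50); the absolute
50%-viability crossing is computed separately for transparency. Fold change
is IC50(reference)/IC50(test) with a seeded residual-resampling bootstrap
(percentile interval, refits initialized at the point estimates). Population
comparisons use Welch's t-test — the safer default where only "two-sample
t-test" is conventional, reducing to Student's under equal variances — with
per-concentration p-values reported unadjusted and an optional Holm
adjustment. The fully degenerate case (both groups constant and equal)
returns p = 1 by convention and is logged.

## What the synthetic generators emulate — and what they do not

The plate generator draws each well as a log-logistic expected signal plus
additive Gaussian noise truncated at zero. Genotypes map to IC50s: ordinary
library clones sit at the baseline (their transgenes are mostly neutral or
inactivating), designated sensitizers at baseline/fold, and the
wild-type-transgene control *below* baseline (40 nM vs 150 nM by default) —
an overexpressed functional kinase activates more prodrug than a mostly
inactive library variant. That gap is load-bearing: if clones and both
controls shared one expected death rate, the rule "above both controls in
≥1 of 3 experiments" would flag ~70% of null clones under any symmetric
noise (P(X > max(Y₁,Y₂)) = 1/3 per experiment); with the default gap and
noise (OD sd 0.02) the expected false-positive count over 74 null clones is
≪ 1 while implanted sensitizers (IC50 2.5 nM, ~89% death at 10 nM) are
detected with probability ~1. The sensitization panel places the test
population at IC50 75 nM with the wild-type control 60-fold and untransduced
cells 300-fold above it, on a 1 nM–100 µM grid.

The generators emulate the *statistical* structure the analysis assumes —
Poisson-like mutation counts, a dominant-transition spectrum, log-logistic
viability with homoscedastic plate noise, independent experiments. They do
not emulate Sanger mixed peaks, indels or insertional position effects
(polyclonal averaging is represented only as independent noise), plate
spatial artefacts, or any genotype–phenotype map: sensitizers are implanted
labels, not consequences of particular substitutions. Passing tests
therefore validate the machinery and its calibration, not biological claims
about any specific mutant.

## Problem sizes and numerical choices

Monte-Carlo checks use 10⁴ lineages (mean/dispersion/spectrum/positional
tests; binomial SE on the mean ≈ 0.012 at a mean of 1.43), 100 seeded
replicates of 40-clone libraries for CI coverage, 10⁶ Poisson draws per MOI
for the closed-form cross-checks, and 100 noisy replicates for IC50
recovery — sizes at which every acceptance tolerance is several standard
errors wide. Statistical tolerances follow the 3-standard-error convention;
root-finding uses scipy's brentq; dose-response bounds are
bottom, span ∈ [0, 1.5], hill ∈ [0.05, 10], log₁₀-IC50 within ±2 decades of
the observed concentration range. Viability inputs outside [0, 1.5] are
rejected as plate errors rather than clipped.

## Known limitations

Positions mutate independently (no local context effects or hotspots beyond
base identity); hazards use the reference composition (drift of composition
over ≤ ~20 cycles at ≤ 10⁻³ per site is negligible); the cis mask is binary
lethal/neutral; MOI statistics assume well-mixed single-hit Poisson
transduction; the bootstrap treats residuals as exchangeable across the
concentration grid.
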