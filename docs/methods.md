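# Methods

## Scope

`forkslip` implements the inference chain used to quantify mutagenesis at
conditional replication-fork barriers in fission yeast: fluctuation-assay
mutation-rate estimation, colony-level event calling from PCR patterns,
classification of sequenced alleles into a replication-slippage-aware
mutation taxonomy, partitioning of total marker-loss rates into per-class
and barrier-induced rates, and estimation of the slippage rate per
generation from reversion kinetics. A synthetic-data generator supplies
every input with the statistical structure the analysis assumes, so the
whole chain runs and is testable without external data.

## Mutation rates from fluctuation assays

Parallel cultures grown without selection follow the Luria–Delbrück
process: mutations arising in early generations found large "jackpot"
clones, so the distribution of mutant counts is heavy-tailed and the
median is the robust summary. The method of the median (Lea & Coulson)
converts the median selected-colony count r̃ into m, the expected number
of mutation events per culture, by solving

    r̃/m − ln(m) = 1.24,

whose left side is strictly decreasing in m; the root is found by
bracketed bisection (`scipy.optimize.brentq`) on m ∈ [10⁻⁶, 10⁶] at
relative tolerance 10⁻⁹. The rate in events/cell/division is m divided by
the mean final viable count N̄t. Requirements and conventions:

- at least 11 independent cultures per experiment;
- counts are divided by the plating fraction before estimation (the
  tables carry counts as plated);
- even culture numbers use the midpoint of the two central order
  statistics as the median;
- r̃ = 0 is uninformative for the median method: the estimate is reported
  as a censored upper bound obtained by solving with r̃ = 1, mirroring
  the "<" entries of published rate tables;
- the 95% CI is a seeded nonparametric bootstrap over cultures (1000
  resamples, percentile interval). The CI method is this package's
  choice; the assay literature reports a 95% CI without naming one.

**Validity range.** The median method is accurate when m is roughly
between 1 and 15; below m ≈ ln 2 the median count is zero and the method
returns only the censored bound, and well above ~15–30 it drifts. On the
synchronous-division generator used here the estimator shows a residual
−15 to −20% median bias at m ≈ 15, consistent with the method's known
behaviour; fold inductions (ratios of ON/OFF rates) cancel most of it
(recovered within ~5% in calibration runs).

Replicate experiments are summarised as mean ± SE (sd/√n, n ≥ 3).
Group comparisons use a two-sided Mann–Whitney U test: exact enumeration
of all assignments of pooled mid-ranks whenever C(n₁+n₂, n₁) ≤ 5·10⁵
(this handles ties exactly and yields p = 1 for identical groups), and a
normal approximation with tie and continuity corrections beyond that.

## Mutation classification and micro-homology

A mutant allele is compared with the reference ORF by longest common
prefix/suffix. Equal lengths with one mismatch give a substitution; a
pure length difference gives an indel, anchored at the left-most (5′-most)
equivalent placement on the reference forward strand (1-based inclusive
coordinates); everything else is complex. The taxonomy:

- substitutions are reported strand-agnostically in six base-pair
  classes (GC→AT, AT→GC transitions; GC→TA, GC→CG, AT→CG, AT→TA
  transversions);
- ±1 nt indels are frameshifts, split by context: `homo_run` when the
  left-aligned indel sits in a reference run of ≥ 2 identical bases
  (equivalently, micro-homology ≥ 1), `mono` otherwise;
- indels of ≥ 2 nt are deletions or, for insertions that are tandem
  copies of the adjacent reference segment, duplications — the
  replication-slippage signature; non-tandem multi-base insertions are
  complex, as observed duplications are tandem.

Micro-homology is the flanking direct repeat measured on the reference
frame: the longest m with ref[a..a+m−1] = ref[a+D..a+D+m−1] for an event
of span D anchored at a. For deletions this equals the placement
ambiguity (placement range [a, a+mh], width mh+1); for duplications it
equals the mediating repeat length, and the same interval convention is
applied (the raw insertion-placement ambiguity of a tandem duplication is
D + mh + 1 and is deliberately not used). Non-tandem insertions carry
mh = 0. Only mutations found on both sequencing strands are retained:
reverse-strand records are mapped to forward coordinates by
reconstructing the mutant, reverse-complementing and re-classifying, then
intersecting on (kind, position, segments).

## Colony event calling

Each selected colony is scored by three exact-match PCR assays. The
control locus must amplify, otherwise the colony is invalid; a
translocation-junction product calls a translocation (precedence over
target-locus loss, since the junction implies loss of the target in this
construct); absence of the target calls a genomic deletion; an intact
target routes the colony to sequencing. Amplicon prediction is
exact-match and convergent-orientation only, with product size measured
5′-end to 5′-end; this is adequate for synthetic genotyping and is a
stated limitation, not a thermodynamic model.

## Rate partitioning

Per-class rates are the total loss rate multiplied by observed class
fractions (conservation is exact by construction). The barrier-induced
rate of a class is rate(ON) − rate(OFF), floored at zero: induction is
defined as the excess over spontaneous events, and the subtraction
removes both spontaneous instability and barrier leakiness. Fold
inductions are ratios ON/OFF, or barrier-strain versus barrier-free
control with both sides measured under barrier-protein expression.
Ratios are returned unrounded (so reciprocal folds multiply to one) and
rounded to one decimal only in reports; spectrum shares are rounded to
whole percents.

## Slippage kinetics

Reversion frequency versus generations is fit per experiment by ordinary
least squares with a free intercept (cultures do not start at zero
frequency); the slippage rate per generation is the mean of
per-experiment slopes with its SE across experiments, matching the
means-of-independent-experiments design rather than a pooled regression.
Under the generative model (line observed with multiplicative Gaussian
noise) the slope estimator is exactly linear-Gaussian, so its sampling SE
has a closed form; calibration checks use that SE as the yardstick.

## Synthetic-data generator

- **Fluctuation cultures.** Synchronous binary fission from n₀ = 100
  cells; at each generation every wild-type division produces one mutant
  daughter with probability μ, so m = μ·(Nt − n₀). Mutants breed true,
  grow at the same rate, never revert and never die — exactly the
  estimator's assumptions. Default 20 generations (Nt ≈ 1.05·10⁸),
  chosen so m = μNt falls in 4–15, the median method's accuracy range,
  with μ_OFF = 4·10⁻⁸ and μ_ON = 1.4·10⁻⁷ (the scale of the
  single-barrier construct). A guard refuses n₀·2^G > 10⁹.
- **Reference.** 795 nt (the scale of the *ura4* ORF), random sequence
  with planted direct-repeat pairs (motifs 1–10 nt, spacings 8–50 nt,
  median slippage size ≈ 23 nt), each pair made left-maximal with
  micro-homology exactly the motif length; candidates containing any
  unintended exact repeat ≥ 12 nt are rejected and redrawn.
- **Events.** Slippage deletions remove the inter-repeat segment (one
  repeat copy retained); duplications insert a tandem copy of it.
  Substitutions and frameshifts are placed at positions honouring the
  requested class and run context. The default mutation mixture is
  proportional to the observed single-barrier fork-arrest spectrum
  (52 substitutions : 8 frameshifts : 27 deletions : 12 duplications of
  99 events), and the default colony-class mixture is 55% deletion, 5%
  translocation, 40% mutation.
- **Kinetics.** f(g) = f₀ + ρ·g with relative Gaussian noise (sd 10%),
  default ρ = 5·10⁻⁷ per generation, f₀ = 2·10⁻⁷, three experiments on a
  0–20 generation grid.
- **Determinism.** One integer master seed; every stage draws from a
  named child stream (SHA-256 of the stream label mixed into a
  `SeedSequence`), so identical configurations give byte-identical
  outputs and each stage is independently reproducible.

What the generator does **not** emulate: mutant fitness costs, phenotypic
lag, cell death, reversion during growth, PCR thermodynamics, sequencing
error, or real *ura4* sequence composition. Passing calibration tests
therefore demonstrates internal consistency of estimator and generator
under the stated model, not robustness to these real-data features.

## Numerical and degenerate-input choices

- Root bracketing [10⁻⁶, 10⁶] covers any realistic median count; the
  solver refuses non-positive medians (the censoring path handles r̃ = 0).
- Identical reference and mutant sequences are refused by the classifier
  (no event to classify); the CLI filters them before classification.
- Rank-sum enumeration treats |U − n₁n₂/2| ties at the observed deviation
  as hits (two-sided mid-p is not used).
- Fractions must sum to 1 within 10⁻⁹; negative induced differences are
  floored at zero.
- Zero variance in generations, fewer than 3 points, or non-increasing
  grids are refused by the kinetics fitter.

## Problem sizes used in tests and calibration

Simulation-backed checks use deliberately desk-scale sizes chosen as the
package's own defaults: 11–50 cultures per experiment, 100–200 replicate
experiments for estimator recovery, 400–3000 synthetic colonies for
call-rate checks, 1000 planted events for classification round-trips and
500 series for kinetics calibration.

## Known limitations

- The median method's small negative bias on the synchronous generator
  is documented above and not corrected; maximum-likelihood estimators
  are out of scope.
- At very small culture scale (m ≲ 0.7) the median method is
  structurally uninformative and only censored upper bounds are
  produced; analyses at that scale need a different estimator.
- Primer matching is exact; degenerate or mismatched annealing is not
  modelled.
- Multi-event alleles are classified as complex rather than decomposed
  into haplotypes.
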