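# Methods

`pollenflow` models the chain from a cultivar genotype table to an
orchard-level statement about pollinator effectiveness: which cultivars'
pollen is on a bee, whether that bee could cross-pollinate the tree it
was netted on, and whether distance from a cross-pollen source changes
the odds.  This note records the models, the defaults and why, and what
the synthetic studies do and do not establish.

## Private-allele panel

Clonally propagated cultivars are fixed genotypes, so a SNP locus at
which exactly one cultivar is homozygous for a base that no other
cultivar is homozygous for (the ALT base) is diagnostic for that
cultivar's pollen.  Discovery scans every locus for a base with exactly
one homozygous carrier; the predominant base among the remaining
cultivars is the REF.  A locus with no such base, or with two
reciprocal sole-homozygous bases, is excluded with a reason rather than
guessed at.  Heterozygous ALT carriers are retained — their pollen
fires the ALT assay at half dosage — and recorded so that downstream
inference can treat them as candidate explanations.  Untyped (NA)
genotypes neither qualify nor disqualify a locus: the cultivar's
carrier status is unknown, so it is carried as an "unknown-dosage"
candidate.  Alleles outside {REF, ALT} (the packaged table contains two
such calls at one locus) are flagged by the validator without guessing
intent; they contribute no ALT dosage.

The packaged 12-cultivar macadamia table yields 18 diagnostic loci;
every cultivar has at least one, four have two or more.  Loci are
partitioned by ALT base (and, for the confirmation assay, by REF base)
because single-base-extension chemistry dispenses one acyclonucleotide
per reaction: loci sharing an extension base can be multiplexed.

## Deconvolution as exact set cover

The ALT-only extension assay reduces a pollen load to a set of fired
loci.  Candidate carriers of a fired locus are its homozygous target,
its het carriers, and its NA cultivars.  With at most 12 cultivars the
inference is solved exhaustively, no heuristics:

* **Confirmed** cultivars are those the calls require: either the sole
  candidate at some fired locus, or a cultivar whose *entire* diagnostic
  signature fired while every explanation of those loci without it is
  strictly worse under the ranking below.
* Remaining detections are covered by all minimum-cardinality candidate
  sets; these **ambiguous alternatives** are ranked by (fewer cultivars,
  better summed dosage quality with hom = 0 / het = 1 / NA = 2, fuller
  support among the fired loci, cultivar name) and reported, best first.
* A fired locus with no candidate (impossible for a valid panel, kept
  for robustness) is reported as unexplained.

A cultivar with several diagnostic loci is admitted into covers even
when only part of its signature fired — per-locus dropout is real — but
ranks below fully supported explanations.  The strict-improvement
condition in the confirmation rule is what separates "the homozygous
target fired its own locus" (confirm) from "one of several equally
plausible carriers" (report as alternatives).

Scoring against the host tree: self-pollen is detected when the host
cultivar itself is confirmed; cross-pollen when a non-host cultivar is
confirmed, or — policy `any_cover_cross`, default on — when every
minimal explanation of the calls involves a non-host cultivar.  The
strict `confirmed_only` policy is a configuration switch.  Categories
are CROSS_ONLY / MIXED / SELF_ONLY (score 1/1/0); a bee with no signal
at all is UNDETERMINED, excluded from statistics with its count logged.

A known identifiability limit: one cultivar's single diagnostic locus
(1724) has three het carriers, one of which (849) has its own two-locus
signature.  A load containing 849 therefore fires 1724 and the rule
confirms the locus's target as well; the bee's *category* is unaffected
unless the host tree is one of that pair, but source-composition tables
can over-report the target cultivar when 849 pollen is present.  This
is a property of the panel, not of the solver: the same call set truly
is produced by both mixtures.

## Assay model

Pollen DNA contribution is taken proportional to grain fraction.  The
ALT dosage fraction at a locus is Σ_c f_c·d_c/2 with d_c ∈ {2, 1, 0}
copies; the locus fires when the fraction reaches `theta_detect`, then
the call is flipped with probability `fn_rate` (missed) or `fp_rate`
(spurious).  Defaults `theta_detect = 0.02`, `fn_rate = 0.01`,
`fp_rate = 0.001` encode an assay chosen precisely for low-fraction
sensitivity: a 2% pollen fraction from a homozygous source is
detectable.  No PCR-efficiency bias is modelled.

## Foraging simulator

An orchard is a grid of trees: contiguous single-cultivar row blocks,
with each tree independently replaced by an off-type cultivar with
probability `offtype_rate` (covert cross-pollen sources such as
storm-damage replacements).  Two presets mirror the common commercial
designs this package targets: a wide-block orchard (42 + 48 rows of two
cultivars, 8 m × 4 m spacing, transect rows 1/2/3/11) and a
narrow-block orchard (five 5-row blocks, 10 m × 2 m, transect rows
1–4); trees per row defaults to 100.

A bee is a discrete tree-level random walk: at each move it switches to
an adjacent row with probability `p_row_switch`, otherwise steps to an
adjacent tree in its row (reflecting at edges).  Each visit multiplies
the existing load by the carryover retention ρ and adds
`pickup_grains` of the current tree's cultivar, so a tree visited j
visits ago contributes ρ^j of a pickup — geometric carryover with an
effective detection window of log(θ·(1−ρ)⁻¹)/log ρ visits (≈ 8 visits
at ρ = 0.7, θ = 0.02; ≈ 10 at ρ = 0.8).  The bee is netted at a
uniformly drawn visit.  For study generation the walk is run backwards
from the netting tree (the step kernel is symmetric, so the reversed
path has the forward law), and each netted bee's position is jittered
along the row with SD `capture_jitter_sd` trees: a netting session
spans neighbouring trees, and without jitter all bees at a sampling
point share the same few upstream trees, producing point-level
clustering that a transect-level random intercept cannot absorb.

Tree-level resolution (not flower-level) is deliberate: the inference
target is cultivar composition, and flower-level detail adds parameters
without observable consequences.  The initial load is empty; an
`initial_load` hook is reserved for in-hive pollen transfer, which is
not modelled.  No quantitative field estimates of ρ or `p_row_switch`
exist; the defaults (ρ = 0.7, `p_row_switch` = 0.1) are exposed
placeholders, not claims.

## The GLMM

Bee scores are modelled as Bernoulli with logit
p(score = 1) = σ(β₀ + β_d·row + β_o·narrow + β_{do}·row·narrow + b_t),
b_t ~ N(0, σ_t²) per transect.  The distance covariate is the row
index as a number (1, 2, 3, 11 / 1…4), matching row-count distance;
metres are carried but unused by default (`distance_unit` switch, and a
nearest-source coding for the narrow design's interior rows is
available because a fourth row is simultaneously two rows from the
opposite block).  Orchard terms drop automatically for single-orchard
data.

The marginal likelihood integrates b_t by adaptive Gauss–Hermite
quadrature: per-transect conditional modes by vectorized Newton,
curvature-scaled nodes, 15 nodes by default (results are insensitive
beyond ~10).  Optimization is L-BFGS-B over (β, log σ_t); Wald SEs come
from the finite-difference Hessian of the negative marginal
log-likelihood, and p-values from the normal reference — the
conventional estimate/s.e./p reporting for such models.  Likelihood-
ratio tests are not provided.  σ_t hitting its lower bound is reported
as a boundary (σ_t = 0) with plain-logistic SEs, not as a failure; an
all-0 or all-1 response is flagged as degenerate/separated and the
effect report refuses unconverged fits.  Against an independent
implementation (lme4::glmer, 15-node AGQ) coefficients, SEs and σ_t
agree to < 1e-3 on test data.

Calibration, verified by simulation from the model itself
(`simulate_scores`, which bypasses the foraging layer on purpose): with
no transect variance the constrained fit reproduces Newton–Raphson
logistic regression to machine-level agreement; the mean of 200
replicate estimates at 200 transects × 20 bees recovers β_d = −0.5
within ±0.1; the distance Wald test rejects a true null at 4–6% across
300 replicates (design: 100 transects × 12 bees, σ_t = 0.5 — sizes
chosen so the whole calibration runs in a few minutes).

## Scenario: covert within-row cross-pollen sources

The shipped `scenario_offtype.yaml` demonstrates the mechanism by which
cross-pollen carriage can be substantial yet distance-independent:
off-type replacement trees *within* the rows (rate 0.10), rare row
switching (0.05), ρ = 0.8, netting jitter SD 10 trees.  The off-type
encounter probability inside the carryover window is then roughly
1 − (1 − 0.10)^10 ≈ 0.4 regardless of the row's distance from the
neighbouring block, so carriage lands in the 30–53% range at every row
and the fitted distance slope is ≈ 0 (over 16 probe seeds: carriage
34–52%, mean slope −0.008, distance p < 0.05 in ~12% of runs — the
residual clustering leaves the Wald test slightly anticonservative in
this design, so occasional nominal significance is expected noise).

## What the synthetic studies do and do not show

Passing tests establish that the inference machinery is exact (panel
discovery equals an exhaustive scan; mixture deconvolution recovers all
298 1–3-cultivar mixtures under perfect detection; categories round-trip
through the full pipeline when detection is noiseless), and that the
estimator is calibrated under its own sampling model.  They do not
validate the foraging model against real bees: carryover is geometric
by assumption, walks are memoryless, in-hive transfer and nectar-vs-
pollen foraging are absent, and off-type placement is independent
per tree.  Field data would be needed to estimate ρ, `p_row_switch` or
off-type rates; the scenario configuration shows plausibility, not
measurement.

## Numerical and interface conventions

Genotypes are unordered pairs ("GT" ≡ "TG"); CSV/TSV dialect is sniffed
from the header; row 1 is the row adjacent to the cross-pollen source;
percentages are of included (non-UNDETERMINED) bees and sum to 100 per
orchard × row cell before rounding.  All randomness flows from one
master seed through `numpy.random.SeedSequence` spawning (layout, walk
and assay streams are independent), so identical configuration + seed
reproduces outputs byte for byte.  CLI outputs carry version, seed and
config-hash header comments.
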