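# Methods

This note records the modelling conventions, default parameters and design
choices behind `molarage`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Segmentation

Voxels inside a supplied tooth mask are classified by T2 signal intensity:
hard tooth tissue (dentine + enamel + cementum, indistinguishable on a T2
acquisition) at intensities ≤ 63, predentine at 64–100, pulp at ≥ 101.
Both cut points are inclusive upper bounds and configurable; the defaults
presuppose the intensity normalization of the scanner they were calibrated
on, and no cross-scanner validity is claimed. Continuous intensities are
floored before thresholding because the bands are defined on integers.
Tissue volume is voxel count × voxel volume (product of spacings in mm³ /
1000, i.e. ml); at 0.37 mm iso-voxels 1 ml ≈ 19,742 ≈ 20,000 voxels. The
mask is taken as ground truth for tooth delineation (including where a root
apex ends); no morphology, bias-field correction or registration is
applied.

## Transformation outcomes

Ten responses are built from (pulp, predentine, hard): the total volume;
odds forms x/(total−x); proportion forms x/total; and two-tissue
proportions (x+y)/total. They satisfy exact identities (the three
proportions sum to 1; each two-tissue proportion is the complement of a
one-tissue proportion; the hard-tissue odds are a deterministic transform
of the soft-tissue fraction), so several pairs are nearly collinear after
the ln transform. The redundancy filter computes pairwise Pearson
correlations of the ln-series and removes, for every pair with
|R| ≥ 0.999, the lower-priority member. Correlation is taken in absolute
value because the hard-tissue odds form is a near-perfect *negative*
log-linear image of the soft-tissue proportion — overlap in either
direction carries no extra information.

Two conventions here were genuinely open:

* **Retention priority.** When an odds form duplicates a proportion form,
  the bounded proportion families (total; x/total; (x+y)/total) are kept
  and the odds family dropped, in label order within a family. Proportions
  are bounded in (0, 1), directly interpretable as tissue fractions, and
  their complements stay inside the outcome set.
* **Series construction for the filter.** Redundancy between
  transformations is an algebraic property, so the filter evaluates each
  outcome on the *pooled* volumes of the tooth set (one virtual tooth per
  participant). Averaging per-tooth ratios instead would inject small
  Jensen-gap discrepancies between outcome pairs that are exact functions
  of each other on a single tooth, making the 0.999 cut seed-dependent.

For regression analysis, by contrast, per-tooth outcome ratios are averaged
across the tooth set and then ln-transformed (`ratio_mean`, the default:
each tooth's developmental state counts equally regardless of tooth size);
summing volumes first (`volume_sum`) is available as a sensitivity switch.
Participants missing any member tooth are dropped from that series with a
logged count.

## Regression model search

Age enters in decimal years (days / 365.25). Sex enters in one of five
structures: (i) ignored; (ii) sex-specific intercepts; (iii) sex-specific
slopes with a common intercept; (iv) both; (v) fully separate per-sex fits,
which is structure (iv) plus a separate residual variance per sex. Variance
weightings are w = 1, w = age and w = 1/age, with w the regression weight,
so Var(εᵢ) = σ²/wᵢ: the 1/age weighting encodes variance growing
proportionally to age, the biologically expected pattern as tooth
maturation asymptotes.

Fits are weighted least squares (via statsmodels). Two variance estimates
are kept: the maximum-likelihood estimate σ̂²ML = Σwe²/n drives the AIC,
while the unbiased estimate (denominator n − p) drives coefficient
covariance, t-based two-sided p-values (n − p df) and prediction variance.
AIC = −2ℓ̂ + 2k with ℓ̂ = −(n/2)ln(2πσ̂²ML) + ½Σln wᵢ − n/2 and k counting
every coefficient plus each variance parameter; structure (v)'s AIC is the
sum of its per-sex AICs. The ½Σln w term makes AIC invariant to rescaling
all weights by a constant, so the three weighting families are comparable
on one scale.

**Selection convention.** Among the 15 candidates, those within 2 AIC units
of the minimum are treated as statistically indistinguishable (the
conventional ΔAIC ≤ 2 equivalence band); within that band the most
parsimonious candidate (fewest parameters) is selected, equally complex
candidates are resolved by strict AIC, and exact ties fall back to the
weighting order (constant, age, 1/age) then the sex-structure order. A
strict arg-min over the grid would select a spuriously enlarged nested
model at the usual ~16% χ² rate; the parsimony band restores the simpler
true structure in those cases. Perfect fits (zero residual variance) have
unbounded likelihood; they are flagged degenerate, their AIC is guarded at
−∞, and selection skips them.

Candidate (outcome, tooth set) pairs — 7 retained outcomes × 11 tooth sets
(4 singles, 6 pairs, 1 quadruple) — are ranked by the age p-value: the
common-slope p for structures (i)–(ii), and the *larger* of the per-sex
p-values for (iii)–(v), so a candidate is only ranked highly if the age
signal holds in both sexes. AIC selection runs independently per candidate
(whether to select once globally was open; per-candidate selection lets
tooth sets differ in their best variance law, and the report records which
structure each candidate used). No multiple-testing correction is applied
across the 77 candidates.

## Bayesian age prediction

The selected regression is inverted by Bayes' theorem on a uniform age
prior, 14.0–23.0 years by default. The prior is an explicit statement of
the reference population and prevents the training sample's age
distribution from contaminating the estimate (age mimicry). The likelihood
of a measured ln-ratio y at age a is Normal with mean μ(a, sex) from the
fitted coefficients and variance σ̂²·v(a), v = 1/w per the selected
weighting. Coefficients are plugged in as known — consistent with
reporting ±2 SD prediction intervals — and an optional flag adds the
mean-prediction variance xᵀΣx as a sensitivity check.

The posterior is evaluated on a grid (default step 0.01 y; halving the
step moves P(>18) by < 1e-4 on toy models) in log space to survive peaked
likelihoods, trapezoid-normalized, and zero outside the prior. P(age > t)
is the trapezoidal tail integral with an interpolated node at t;
thresholds outside the prior support return exact 0 or 1 with a warning.
Hypothetical observations may be supplied as raw ratios or as ln-ratios
via an explicit flag; the CLI default treats inputs as raw ratios and
applies ln internally.

One boundary caveat: the generator (and typical reference cohorts) includes
ages up to 24, while the default prior caps at 23.0. An individual truly
older than 23 is assigned posterior mass only up to the cap, so P(>18)
remains well-defined but the posterior mode saturates at the boundary.

## Synthetic cohort generator

The generator is the package's definition of the data regime the analysis
assumes. Defaults:

| parameter | default | meaning |
|---|---|---|
| n_participants | 67 | analyzed cohort size |
| sex_ratio | 45/67 | fraction female |
| age_range_years | (14, 24) | uniform age range |
| slope | −0.07 /yr | change in ln soft-tissue ratio per year |
| intercept_f / intercept_m | −1.18 / −1.07 | ln-ratio at age 0 per sex |
| sigma2 | 8e-4 | base residual variance (Var = σ²·age) |
| variance_law | proportional_to_age | matches the 1/age weighting |
| tissue_scale | per-sex medians | hard 0.712/0.788, pulp 0.052/0.065, predentine 0.016/0.020 ml |
| agenesis_prob | 0.05 | per-tooth congenital absence |

The anchors: the female ln-ratio at age 18 equals ln(0.068/0.780) (the
value implied by the female median volumes); the male–female intercept gap
0.11 is ln of the ratio of the two sexes' median soft-tissue fractions;
σ² puts the residual SD at age 18 near 0.12 ln-units, matching the spread
of plausible adolescent measurements (ratios roughly 0.067–0.13).

Per present tooth, hard-tissue volume is drawn log-normally (log-SD 0.15)
around the per-sex median; the soft-tissue ratio r is drawn from the
generating law (so the headline outcome obeys it *exactly*); total =
hard/(1−r); and the soft compartment splits pulp:predentine around 76:24
with a logit-normal jitter (SD 0.15). The jitter matters: a deterministic
split would make all soft-tissue outcomes exact scalar multiples of each
other (pairwise ln-correlation 1), which no real cohort shows and which
would collapse the outcome set far beyond the three genuine odds/proportion
overlaps. Per-tooth residuals are independent within a participant — a
simplification; real teeth in one mouth share developmental timing, so
multi-tooth averages on real data will gain less precision than they do
here. Ages are recorded in whole days and re-derived as days/365.25.

The enrollment fixture reproduces the reference accounting: 99 enrolled,
exclusions 4 (missing third molars) + 15 (unsuitable tooth) + 7 (movement
artifact) + 6 (cotton-roll error) = 32, leaving 67 analyzed. Reasons are
mutually exclusive, assigned in that priority order.

Voxel phantoms are concentric digital teeth: voxels ranked by distance from
the grid centre become pulp core, predentine shell, then hard-tissue
mantle; base intensities are drawn uniformly inside each class's threshold
band, so noiseless phantoms segment back to their generating counts
exactly. Additive Gaussian intensity noise (then flooring and clipping at
0) is the only corruption modelled — no MRI physics, partial-volume or
motion effects — so phantom tests validate the *bookkeeping* of
segmentation, not its robustness on clinical images.

## What the tests show, and don't

Passing tests demonstrate that every stage implements its stated
mathematics (verified against independent oracles: brute-force voxel
tallies, normal-equations solutions, textbook Pearson and Normal-pdf
evaluations, fine-grid integration) and that the pipeline recovers the
structure of data generated under its own assumptions. They do not
validate the intensity thresholds, the linear-in-age model, or the
variance law on real cohorts, and the generator's independence
assumptions (across teeth, and between tissue split and age) are idealized.

Known statistical limitation, measured by simulation: joint recovery of the
generating (sex-intercept, 1/age-weighting) structure by AIC at n = 500
plateaus around 65–75%. Discriminating Var ∝ age from constant variance
over ages 14–24 has a mean log-likelihood-ratio separation of only
n·(ln ā − mean ln a) ≈ 6.2 at n = 500 against a sampling SD of ~6, an
irreducible ~15% misselection; the parsimony band leaves a few percent of
overfits to the larger sex structures; and the sex-slope structure (iii)
can mimic a small intercept offset. The slope itself is recovered within
2 SE in ~95% of replicates; it is the *labels* of near-equivalent model
structures that are uncertain, not the age trend.

## Numerical conventions

* Ages in years are days/365.25 throughout.
* Weighted design matrices are solved by statsmodels WLS; rank deficiency
  raises rather than pseudo-inverting.
* Posterior densities are computed as exp(logL − max logL) before
  normalization.
* All randomness flows from one integer seed per run through
  `numpy.random.default_rng`; identical config + seed reproduces every
  numeric artifact byte-for-byte.
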