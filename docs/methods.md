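# Methods

This note documents the models, priors, numerical choices and limitations of
`riskframe`, in the package's own terms.

## Choice core

A framed game pits a risky prospect (payoff x with probability p, else 0)
against a sure payoff.  Subjective value follows cumulative prospect theory
with a power value function, v(x) = x^α for gains and −λ(−x)^α for losses,
and the one-parameter inverse-S probability weighting
ω(p) = p^c / [p^c + (1−p)^c]^{1/c}.  Choice is a softmax on the value
difference.  Two structural choices:

* **λ fixed to 1.**  Every game in the design is pure-gain or pure-loss, so
  λ only rescales the loss-frame value gap and is absorbed by the
  loss-frame slope of the choice rule.  It stays in `CPTParams` for
  mixed-gamble extensions but is not estimated.
* **c bounded below at 0.3.**  The one-parameter weighting form loses
  monotonicity for very small c; 0.3 keeps ω a valid (nondecreasing)
  weighting function with a safety margin, checked by a dense-grid property
  test.

Payoff tables print loss magnitudes as positive numbers; the loader signs
them (negative framing → negative payoffs), because the value function needs
signed arguments.  The gap convention is risky − sure with choice coded
1 = risky, so a negative intercept means preference for the sure option.

Because gaps span hundreds of euros, the choice rule uses
logGap = sign(gap)·log(1+|gap|): approximately the identity near zero,
logarithmic for large gaps.  This keeps the logistic regression
well-conditioned where a raw-gap sensitivity would be driven to ~10⁻².

## Framing-choice model

For observation n with framing F, subject s, testosterone change t:

    logit p(risky) = (a_F + δa_F·t + u_int[s,F]) + (b_F + δb_F·t + u_slope[s,F]) · logGap_n

The hormone covariate Tchange defaults to the relative within-session change
(T1−T0)/T0 — the counterfactual levels "0/60/200%" are natural on this
scale — and can be switched to the absolute change in `RunConfig`.  Missing
hormone values are imputed with the treatment-group (× timepoint) mean and
logged.  The sensitivity φ of the raw softmax is not separately estimated:
the intercept/slope reparameterisation absorbs it.

Subject effects: the 4-vector (int_pos, slope_pos, int_neg, slope_neg) is
drawn from a zero-mean multivariate normal whose covariance is estimated.
Rather than an LKJ prior (whose Cholesky gradients we would have to derive
by hand for the package-native sampler), the covariance is parameterised by
an unconstrained Cholesky factor W: log-diagonals with priors matching
Half-Normal(1) scales, off-diagonal entries Normal(0, 0.5).  This also
concentrates the implied correlation toward the identity, the same
qualitative shape an LKJ(2) prior encodes.  The implied correlation matrix
is reported as a posterior quantity.  Sampling is non-centred (u = W z,
z ~ N(0, I)).

Priors: population coefficients Normal(0, 2) — weakly informative on the
logit scale.  Variants: `pooled` (a_F, b_F), `pooled+T` (adds δ terms),
`hierarchical` (adds independent subject effects), and the full
`hierarchical+T+covariance`.

Model comparison uses PSIS-LOO on pointwise log-likelihoods (via arviz)
plus ROC-AUC of posterior-mean choice probabilities, and requires an
identical observation set across fits.

## CPT re-estimation

The curvatures (α_F, c_F) are estimated from pure-gain/pure-loss choice
data with the rule logit p = φ_s · T(gap), T either logGap or the identity.
Subject-level deviations are partially pooled on transformed scales.  Two
numerical decisions matter:

* **Bounded transforms for α and c.**  α = 2·logistic(θ),
  c = 0.3 + 1.5·logistic(θ).  With payoffs in the hundreds, an unbounded
  log transform lets warmup visit α ≈ 20, where x^α spans tens of orders of
  magnitude and likelihood cliffs defeat any step size.  The bounds contain
  every estimate reported for this model family with a wide margin.
* **Prior centres at the literature's typical values.**  Transformed-scale
  means are Normal(m, 1) with m chosen so the implied prior medians are
  α ≈ 0.85 and c ≈ 0.7 (the typical ranges quoted for this model family).
  A zero-centred prior on the bounded scale would implicitly centre c near
  1.05 and biases weakly-identified fits upward.  The sensitivity mean is
  Normal(0, 2.5) since its scale depends on the gap units; subject scales
  are Half-Normal(0.5).

Whether the original analyses estimated φ per subject or pooled is not
documented; the model uses subject-level φ with partial pooling (assumption,
flagged here).  Called without data, the fit returns the published
framing-specific point estimates α = (0.67, 0.96), c = (0.82, 0.87), which
are also the defaults the framing model fixes its CPT stage to.  The
external gamble dataset used for the original re-estimation is not bundled;
recovery is demonstrated on synthetic cohorts.

## Endowment models

Log WTA/WTP ratios are modelled as Gaussian with crossed subject and item
intercepts.  Ratio construction averages repeated presentations of a role
within a subject × item × treatment cell before dividing, so it supports
both one-bid-per-role and randomised single-role schedules.  Subjects with
zero bids on more than 30% of their items are excluded; remaining
subject-item cells with zero WTP (undefined ratio) are dropped; both are
counted in an exclusion report, never silently.

Parameterisation: the likelihood identifies only the cohort-level intercept
μ_tot = μ0 + mean(μ_ind) + mean(g_item).  The sampler therefore draws μ_tot
together with sum-to-zero effect deviations (Helmert basis) and the two
group means as separate prior-coupled scalars, and reconstructs
μ0 = μ_tot − ū − v̄ per draw.  This is an exact reparameterisation of the
free-mean model; it removes the intercept/group-mean see-saw that otherwise
stalls mixing in crossed-intercept models while preserving the
population-mean uncertainty of exp(μ0).  Group scales have Half-Normal(0.5)
priors, the residual scale Half-Normal(1), μ0 Normal(0, 1).

The testosterone variant uses partially pooled per-item shifts
b_item = b0 + σ_b·z_item (non-centred, because σ_b can sit near zero when
there is no hormone effect), reported with 95% HDIs per item; the overall
coefficient b0 is the population-level testosterone effect.  The goods-type
variant models log(ratio) = μ_type with one mean per category and no other
structure, matching the contrast it is meant to estimate; its μ_type
posteriors estimate the cohort's per-type mean log ratio.

Frequentist companions: a one-tailed one-sample t-test of mean ratio = 1
with a JZS default-prior Bayes factor (via pingouin), and a 2×2
repeated-measures ANOVA (treatment × time) with partial eta squared
η²p = SS_effect/(SS_effect+SS_error) on the hormone panel, with paired
post-hoc tests.  A constant panel returns all-zero effects rather than a
0/0 failure.  The published Bayes-factor magnitude for the pooled ratio test
depends on an unstated prior choice and is not asserted anywhere.

## Sampler

All models share a package-native No-U-Turn sampler: multinomial trajectory
sampling with biased progressive subtree selection, generalized U-turn check
under a diagonal mass matrix, divergence threshold ΔH > 1000, dual-averaging
step-size adaptation, and Stan-style warmup windows (fast / doubling
covariance windows / fast).  Gradients are hand-coded per model and verified
against central finite differences in the test suite; the sampler itself is
validated on correlated Gaussians (mean/covariance/R-hat/ESS) and
cross-checked against an independent affine-invariant ensemble sampler on a
non-Gaussian target.

Defaults: 4 chains × (1000 warmup + 1000 draws), target acceptance 0.9,
R-hat convergence gate 1.01 plus a <1% divergence share; non-convergence
raises a warning, never a silent return.  Every fit takes an explicit
integer seed and is bit-reproducible given it.  CPT re-estimation fits cap
the tree depth at 8 and target 0.85 acceptance: its φ–curvature ridge
otherwise requests maximal trajectories for marginal ESS gains.

## Synthetic data

The generator emulates the study design: 40 men, crossover
placebo/testosterone sessions (order counterbalanced), ten framed games per
session, serum testosterone and cortisol at two timepoints per session, and
WTA/WTP bids for 10 hedonic + 10 utilitarian items, each item in both roles
in each session.

Defaults are the published study conditions: framing coefficients at the
published posterior means (a = (−0.98, −2.10), b = (0.63, 0.63),
δa = (0.24, −0.44), δb = (0.27, −0.02) for (positive, negative)); hormone
moments at the printed values (testosterone arm 18.53 ± 6.04 →
33.76 ± 11.9 nmol/L, placebo 18.69 ± 5.44 → 19.0 ± 6.38; cortisol declining
in both arms).  Where the sources state no value, one realistic choice was
made and fixed: subject-effect SDs 0.5 (intercepts) and 0.15 (slopes) with
0.3 cross-framing correlations — heterogeneity large enough that pooled and
hierarchical fits separate; hormone baseline/post test-retest correlation
0.8 (typical within-session serum stability), which also keeps the placebo
arm's mean relative change near zero; endowment ratios 2.0 (hedonic) and
1.4 (utilitarian) with item SD 0.2, subject SD 0.3, residual SD 0.25, log
item prices ~ N(log 20, 0.6), and a zero testosterone coefficient (the
null the study reports).  Draws are floored at the assay detection scale so
concentrations stay positive; at the study's moments (3+ SDs above zero)
this flooring is essentially never active.

What the generator does not emulate: sequence/order effects, reaction
times, item-specific semantics beyond the type label, non-normal bid noise,
or any coupling between risk attitudes and endowment behaviour.  Passing
recovery tests therefore show the estimators work under the assumed data
model at study scale — not that the assumed model is true of real data.

## Problem sizes in the tests

Unit tests run reduced designs chosen as the package's own test scale:
framing fits with 10–15 subjects and short chains; the CPT
recovery-calibration invariant uses 20 replicate datasets of 12 subjects ×
2 presentations of the 10 games with 2 × (250+250) draws (93.75% of 94%
HDIs covered the generating curvatures in the reference run); the
acceptance-level recovery runs use the full 40-subject (framing) and
37-subject (endowment) designs.  The hormone-ANOVA regime check runs 100
replicate panels at n = 39.

## Known limitations

* The hierarchical framing model estimates the subject-effect covariance
  through a Cholesky-normal prior, not LKJ; with 40 subjects the
  correlation posteriors are wide and shrink toward zero.
* c_F is weakly identified from 5 probability levels per framing; loss-frame
  curvature in particular carries wide HDIs at study scale.
* The endowment goods-type model deliberately omits subject/item effects
  (as specified), so its μ_type estimates cohort means, not
  heterogeneity-adjusted population means.
* The sampler uses a diagonal mass matrix; strongly correlated posteriors
  cost tree depth rather than failing, which shows up as runtime.
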