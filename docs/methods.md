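# Methods

## The type 2 signal-detection model

A two-choice discrimination is modelled as equal-variance Gaussian SDT:
evidence x ~ N(−d'/2, 1) after S1 stimuli and N(+d'/2, 1) after S2 stimuli;
the observer responds "S2" when x exceeds the criterion c. Placing the two
means symmetrically about zero makes c = 0 the unbiased point; only
differences of criteria and means are identified, so this anchoring is a
convention without empirical content.

Confidence is modelled by partitioning the evidence axis further with
response-conditional type 2 criteria: k − 1 criteria cS1 below the
meta-level criterion (used after "S1" responses, confidence increasing as
evidence becomes more negative) and k − 1 criteria cS2 above it. With the
meta-level sensitivity meta-d' replacing d', the model yields

    P(conf = y | stim = i, resp = j) = [Φ(t_{y+1} − μ_i) − Φ(t_y − μ_i)] / P(resp = j | stim = i),

where the t's are the bin edges on the response-j side and μ_i = ∓meta-d'/2.
The concatenation (cS1, meta-c, cS2) must be nondecreasing. Confidence
counts (the vectors nR_S1, nR_S2 of length 2k, running from
high-confidence-"S1" to high-confidence-"S2") are multinomial within each
(stimulus, response) class; the log-likelihood is the sum of n·log P over
cells, with empty cells contributing zero.

Metacognitive efficiency is the ratio M = meta-d'/d'. The meta-level
criterion is anchored to the observed response bias through meta-c' = c'
(criterion in units of sensitivity). We implement this identity in the form
meta-c = c·M, which is algebraically equivalent for d' ≠ 0 and — unlike the
c/d' form — remains defined when a subject's *estimated* d' is zero or
negative, as happens routinely at low trial counts. Subjects with negative
estimated d' are therefore retained in group fits with meta-d' = M·d̂' < 0;
excluding them would select for upward-noise in d̂' and bias group
efficiency downward.

## Single-subject fits

`fit_mle` maximizes the multinomial log-likelihood over meta-d' and the
2(k − 1) criteria, holding (d', c) at their observed values. Criteria are
parameterized as meta-c plus cumulative positive increments (log-increment
coordinates), so the ordering constraint holds by construction and the
search is unconstrained; L-BFGS-B runs from 5 jittered starts (the count is
pragmatic, not principled) with objective tolerance 1e−10, and the best of
the five is returned with a convergence flag. `fit_sse` minimizes the
unweighted sum of squared differences between observed and model
conditional type 2 probabilities over the same parameter space; whether the
historical SSE objective weighted cells by response-class frequency is not
documented anywhere we could verify, so **unweighted** squared error was
chosen.

Point fits default to padding 0.25 on all 4k cells (the multi-cell
generalization of the log-linear correction) before both the type 1 rates
and the type 2 objective are formed; padding is a caller-visible parameter.
At 20–50 trials this correction itself distorts estimates when
high-confidence cells are sparse — reproduced as a property in the test
suite — which is the core argument for the hierarchical route.

## The hierarchical model

For a group of S subjects, (d'_s, c_s) are fixed point estimates computed
from 1/(2k)-adjusted rates (the adjustment keeps every subject finite and
is applied uniformly; the confidence counts themselves are never padded).
The group parameter of interest is μ_M, the mean of log M_s. Priors follow
the standard specification for this model:

    μ_M ~ N(0, 1)        ξ_M ~ Beta(1, 1)       σ_δ ~ HalfNormal(1)
    log M_s = μ_M + ξ_M δ_s,   δ_s ~ N(0, σ_δ)
    μ_c2[j] ~ N(0, 10)   σ_c2[j] ~ HalfNormal(10)
    cS1_s[j] ~ N(−μ_c2[mirror j], σ_c2[mirror j]),  cS2_s[j] ~ N(+μ_c2[j], σ_c2[j])

restricted jointly to the ordering cS1 ≤ meta-c_s ≤ cS2 (each ascending).
The ξ_M/δ_s decomposition is parameter expansion: the hierarchical scale is
only identified as σ_M = |ξ_M|·σ_δ, which is recovered per sample; the
redundant multiplier prevents the scale from sticking near zero. ξ_M, σ_δ
and δ_s individually are *not* identified, so their R-hat values are
reported but excluded from convergence warnings.

Two modelling choices deserve note. First, the compact notation "one
(μ_c2, σ_c2) pair" cannot describe k − 1 *ordered* criteria, so one group
mean/SD per criterion index is used, mirrored across response sides
(cS1 index j pairs with μ_c2 index k−1−j). Second, the joint prior on a
subject's criteria is a product of Normals times the ordering indicator;
when updating μ_c2 and σ_c2 the ordering region's normalizing constant is
treated as independent of the hyperparameters (making μ_c2 conditionally
conjugate). This differs at second order from samplers that truncate each
criterion node at its neighbours; the difference is negligible whenever
violations have small prior mass, and group-level efficiency is insensitive
to it.

### Sampler

The MCMC engine is an adaptive Metropolis-within-Gibbs sampler written in
numpy and vectorized across chains and subjects, with these blocks per
iteration: subject offsets δ_s; each criterion coordinate (bounded by its
neighbours); a common-offset translation of each subject's whole cS1 and
cS2 block (the criteria are strongly correlated a posteriori); the group
scalars μ_M and ξ_M (full-likelihood Metropolis); a likelihood-invariant
translation that shifts μ_M against δ at fixed log M (decorrelates the
group mean from the offsets); σ_δ; a Gibbs draw of μ_c2; and a Metropolis
step for σ_c2. Proposal scales adapt toward 44% acceptance in windows of 50
iterations during burn-in only, so the retained chain is a valid fixed
kernel. Chains initialize from per-subject MLE fits with per-chain jitter,
projected into the ordered region. Defaults: 3 chains, 10,000 retained
draws per chain, 1,000 burn-in; all overridable. Fits are deterministic
given (data, spec): all randomness flows from integer seeds kept below
2^31.

Ordering violations under a proposal are handled by rejection (the prior
has zero mass there); the likelihood of an invalid configuration evaluates
to −inf, so the two guards agree.

### Diagnostics and summaries

- **R-hat**: classic Gelman–Rubin PSRF from within/between-chain variances,
  computed per scalar component; zero-variance chains return 1 by
  convention and sampling noise below 1 is floored at 1. Values ≥ 1.1 log a
  warning (identified parameters only); they never raise.
- **CI**: 2.5th–97.5th percentiles with linear interpolation (the numpy
  default convention). **HDI**: shortest sorted window containing 95% of
  draws. Both require ≥ 40 samples.
- **DIC**: mean deviance plus p_D, with p_D = mean deviance − deviance at
  the posterior mean of the continuous parameters (log M_s and criteria,
  re-projected to the ordered region). The half-variance p_D convention
  would give different values; DICs are comparable only within one
  convention.
- **Group differences**: elementwise difference of pooled μ_M draws
  (random subsampling with a fixed seed if lengths differ), summarized by
  its CI and whether it excludes zero.

### Two-task correlation extension

Subject log-efficiencies for two tasks are bivariate Gaussian,
(log M1_s, log M2_s) ~ N((μ_M1, μ_M2), Σ) with ρ the correlation, priors
μ_Mt ~ N(0, 1), σ_Mt = τ_t^{−1/2} with τ_t ~ Gamma(0.001, 0.001), and
ρ ~ Uniform(−1, 1); no parameter expansion. Criteria are modelled per task
exactly as in the single-group model. The group means and SDs enter only
through the bivariate prior, so their updates are cheap; ρ mixes by scalar
Metropolis.

## Synthetic data

`metad_sim` draws the four type 1 response classes (hits, false alarms,
misses, correct rejections) from binomials implied by (d', c) — not fixed
quotas — and then draws confidence counts within each class from the
multinomial type 2 model at meta-d' = M·d', so first-order performance and
metacognitive efficiency are controlled independently. Trials split
n//2 / n − n//2 between S1 and S2 (odd trial to S2). Type 2 criterion
offsets are specified as positive ascending distances from the meta-level
criterion and mirrored below it. Group draws take d'_s ~ N(mean, sd),
floored at 0.1 so the contract is total (the default N(2, 0.2) essentially
never hits the floor); each subject consumes a generator seeded by
(seed, subject index), so a subject's data are independent of group size.

Default group conditions — 20 subjects, 400 trials, 4 confidence levels,
c = 0, offsets (0.5, 1.0, 1.5), d' ~ N(2, 0.2) — are the canonical
simulation conditions of the validation literature for this model, and the
recovery grid spans efficiencies 0.5–2.0. For the two-task generator the
published description of the simulation is ambiguous about whether "mean
0.8, SD 0.5" lives on the ratio or the log scale; we place the bivariate
Gaussian on log-efficiency with means log(0.8) and SDs 0.5, keeping
efficiencies centred at the empirically typical 0.8. The target correlation
applies to the latent log-efficiencies; with 100 subjects the realized
sample correlation has SD ≈ 0.06 about it.

`simulate_noisy_confidence` is the mechanistic observer: the decision uses
evidence x against c, the rating uses x + N(0, σ_noise) binned by the
criteria on the chosen-response side, clamping to lowest confidence if the
noisy value crosses the decision criterion (the decision is not revisited).
At σ_noise = 0 it is the ideal observer (meta-d' = d'); efficiency declines
monotonically in σ_noise.

What the generators do **not** emulate: criterion drift or sequential
effects across trials, unequal-variance evidence distributions, response
times, lapses, or idiosyncratic confidence-scale use beyond the binomial /
multinomial sampling noise. Passing tests therefore demonstrate correctness
of the estimator under its own generative assumptions, not robustness to
their violation.

## Problem sizes in the shipped tests and experiments

Routine tests run reduced-size fits (typically 1,500–2,500 retained draws
per chain, groups of 8–20 subjects); the acceptance tests run the canonical
20 × 400 fits at the default 3 × 10,000 draws, the correlation fit at
3 × 4,000–5,000, and the false-positive comparison at 8 replicates per
cell. These sizes are package choices that keep the full suite in the
tens-of-minutes range on a single core while leaving Monte-Carlo error well
inside the asserted tolerances; `experiments` exposes full-size settings
through its arguments (e.g. `n_reps=100`, seven-level recovery grid).

## Known limitations

- **Low first-order sensitivity with few trials.** When d' ≈ 0.5 and
  subjects contribute only tens of trials, per-subject d̂' is noisy on the
  scale of d' itself and a non-trivial fraction of subjects have d̂' ≤ 0.
  Such subjects' likelihoods are monotone decreasing in log M (the model
  can only shrink their meta-level sensitivity toward zero), so they pull
  the group posterior down without a compensating pull from the others;
  group efficiency is then systematically underestimated and its credible
  interval can exclude the truth. This is a property of the fixed-d̂'
  hierarchical model itself, not of the sampler. The false-positive-rate
  experiment reproduces the classical result — point-estimate methods
  misestimate badly below ~100–200 trials when high-confidence cells are
  sparse, while the hierarchical fit stays calibrated from ~50 trials
  upward at moderate-to-high d' — but at the low-d'/20-trial corner *all*
  methods, including the hierarchical one, are unreliable. Jointly
  estimating d' hierarchically would address this and is out of scope here.
- The equal-variance type 1 model is assumed throughout; no
  unequal-variance option is provided.
- DIC values are convention-bound (see above) and not comparable across
  packages.
- The correlation model reports ρ of *latent log-efficiencies*; attenuation
  from first-order estimation noise is handled by the model, but realized
  sample correlations in any one simulated cohort scatter around the
  generative value.
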