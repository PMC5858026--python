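# hmetad

Hierarchical Bayesian and maximum-likelihood estimation of **metacognitive
efficiency** (meta-d'/d') from confidence-rating data.

## The problem

In a two-choice task (stimulus S1 vs S2), signal detection theory separates
how well someone discriminates the stimuli (sensitivity d') from their
response bias (criterion c). Metacognition research asks a second-order
question: how well do a person's *confidence ratings* track whether their own
decisions were correct? Raw confidence–accuracy correlations confound this
"type 2" sensitivity with first-order performance and bias. The meta-d'
framework removes the confound: **meta-d'** is the sensitivity an ideal SDT
observer would need in order to produce the observed confidence data, and the
ratio **meta-d'/d'** (the M-ratio) is metacognitive *efficiency* — 1 for an
observer whose confidence uses all the decision evidence, below 1 when
confidence is noisier than the decision.

Formally, with evidence x ~ N(∓meta-d'/2, 1) for the two stimulus classes,
the axis is partitioned by response-conditional type 2 criteria
(cS1 ≤ meta-c ≤ cS2) and the model assigns a multinomial distribution
P(conf = y | stim, resp). The likelihood of the observed count vectors
nR_S1, nR_S2 under this distribution is maximized (single-subject MLE/SSE
fits), or embedded in a hierarchical model whose group-level parameter is
μ_M = E[log(meta-d'/d')], sampled by MCMC with parameter expansion:

    μ_M ~ N(0, 1)    ξ_M ~ Beta(1, 1)    σ_δ ~ HN(1)
    log M_s = μ_M + ξ_M δ_s,   δ_s ~ N(0, σ_δ),   σ_M = |ξ_M| σ_δ
    cS1_s ~ N(−μ_c2, σ_c2),  cS2_s ~ N(+μ_c2, σ_c2)   (ordered)

Each subject's (d'_s, c_s) is a fixed point estimate; the multinomial
likelihood handles empty cells, so confidence counts need no edge correction.
The hierarchical route matters most when trials are scarce (patient studies,
neuroimaging): partial pooling stabilizes subject fits, and inference on the
group posterior replaces t-tests over noisy point estimates. A bivariate
extension estimates the correlation ρ of efficiencies across two tasks.

The package is for researchers quantifying metacognition: it provides the
type 2 SDT core (`sdt_core`), generators with independently controlled d'
and meta-d' (`simulate`), single-subject MLE/SSE fits (`fit_point`), the
hierarchical model with its own vectorized adaptive
Metropolis-within-Gibbs sampler plus R-hat/CI/HDI/DIC diagnostics
(`fit_hierarchical`), trial-table ingestion (`dataprep`), the validation
experiments (`experiments`), and an `hmetad` command-line interface.

## Worked example

```python
from hmetad import (SimSpec, GroupSimSpec, metad_sim, simulate_group,
                    fit_mle, fit_group, HierModelSpec)

# one subject: 400 trials, 4 confidence levels, d' = 2, efficiency 0.8
counts = metad_sim(SimSpec(d_prime=2.0, c=0.0, n_trials=400, mratio=0.8, seed=7))
print("nR_S1 =", counts.nR_S1.tolist())
print("nR_S2 =", counts.nR_S2.tolist())
fit = fit_mle(counts)
print(f"d' = {fit.type1.d_prime:.3f}, meta-d' = {fit.params.meta_d:.3f}, "
      f"meta-d'/d' = {fit.mratio:.3f}")

# a group of 20 such subjects, hierarchical fit (3 chains x 10,000 draws)
data = simulate_group(GroupSimSpec(n_subjects=20, n_trials=400, mratio=0.8, seed=7))
post = fit_group(data, HierModelSpec(seed=0))
ci = post.ci_mratio()
print(f"group meta-d'/d': posterior mean = {post.mean_mratio:.3f}, "
      f"95% CI = [{ci.lo:.3f}, {ci.hi:.3f}], "
      f"R-hat = {float(post.rhat['mu_logMratio'][0]):.3f}")
```

Output:

```
nR_S1 = [44, 40, 49, 29, 23, 10, 4, 1]
nR_S2 = [4, 7, 4, 16, 39, 40, 35, 55]
d' = 1.868, meta-d' = 1.415, meta-d'/d' = 0.758
group meta-d'/d': posterior mean = 0.780, 95% CI = [0.727, 0.836], R-hat = 1.028
```

The single subject's MLE recovers an efficiency near the generative 0.8
(noisy at 400 trials); the hierarchical fit pools 20 subjects and pins the
group efficiency at 0.780 with a credible interval containing the truth, with
R-hat ≈ 1 indicating convergent chains. The count vectors follow the standard
convention: entry 1 is a maximum-confidence "S1" response, entry 2k a
maximum-confidence "S2" response.

The same workflows are available from the shell:

```bash
hmetad simulate --n-subjects 20 --n-trials 400 --mratio 0.8 --seed 7 --out counts.csv
hmetad fit-group --counts counts.csv --seed 0 --out-prefix results/fit
hmetad fit-subject --counts counts.csv --subject 0
```

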