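# trustmotives

Computational analysis of *why* people reciprocate trust. In a multiplier
Trust Game an Investor sends `I` of 10 tokens to a Trustee; the investment
is multiplied by `M2` and the Trustee freely returns `S2 ∈ {0, …, I·M2}`
tokens. In the standard ×4 game, returning half the pot is equally
consistent with **inequity aversion** (split all tokens evenly) and
**guilt aversion** (meet the Investor's expectation), so the two motives are
confounded. The hidden-multiplier game (HMTG) breaks the confound by
secretly varying the true multiplier (×2/×4/×6 or ×4/×6/×8) while the
Investor believes it fixed; the false-belief variant (FBMTG) inverts this,
varying the Investor's *believed* multiplier while the true one stays ×4.

`trustmotives` implements the full analysis pipeline for such data:

* **Utility models.** Four Trustee decision models over payoff
  `π₂ = (I·M2 − S2)/(I·M2)`, guilt
  `Guilt₂ = ((E₂(E₁(S₂)) − S2)/(E₁(M₁)·I))²` with the second-order
  expectation fixed at `E₂(E₁(S₂)) = ½·E₁(M₁)·I`, and inequity
  `Inequity₂ = ((I·M2 − S2)/(10 − I + I·M2) − ½)²`:
  greed `U = π₂`; inequity aversion `U = π₂ − Θ·Inequity₂`; guilt aversion
  `U = π₂ − Θ·Guilt₂`; and the integrative **moral-strategy (MS) model**
  `U = Θ·π₂ − (1−Θ)·min(Guilt₂ + Φ, Inequity₂ − Φ)`, whose `min` operator
  lets a Trustee satisfy whichever moral obligation is cheaper per trial
  (moral opportunism at Φ ≈ 0). Predicted behavior is the exact argmax over
  the integer strategy space.
* **Fitting and model comparison.** Per-participant least-squares fits by
  dense multi-start search (1000 restarts by default) with
  `AIC = n·ln(SSE/n) + 2k`, the SSE < 10 near-perfect exclusion rule, and
  paired t-tests on AIC.
* **Strategy classification.** The MS model is simulated at 101 × 101
  = 10,201 points of its (Θ, Φ) space (Θ ∈ [0, 0.5], Φ ∈ [−0.1, 0.1]) over
  all investment × condition stimuli; Ward clustering of the simulated
  behavior partitions the space into greed / guilt-averse /
  inequity-averse / opportunist zones, and each participant is labelled by
  the zone containing their fitted (Θ, Φ).
* **Stability statistics.** Test–retest Pearson correlations of parameters
  and inter-participant distances, Stuart–Maxwell marginal-homogeneity
  tests on paired strategy labels, prevalence chi-squares with Bonferroni
  pairwise follow-ups, and Φ-on-Θ residualization for trait correlations.
* **Synthetic populations.** Agents with known strategies (default mixture
  40% IA / 10% GA / 40% MO / 10% GR) drawn from strategy-zone interiors,
  playing seeded 80-trial blocks with additive token noise — so the whole
  pipeline is testable end to end without any external data.

The core objects follow scikit-learn conventions (`TrusteeModel` and
`StrategyMap` expose `fit`/`predict`/`get_params`); module-level functions
are thin wrappers around them.

## Worked example

```python
import trustmotives as tm

# 1. Task: hidden-multiplier game, 80 trials, true multiplier x2/x4/x6,
#    Investor always believes x4
config = tm.make_hmtg_config([2, 4, 6], believed=4, n_trials=80)
print("trials per condition:", config.trial_counts())

# 2. A guilt-averse synthetic Trustee plays one block
schedule = tm.generate_investment_schedule(config, seed=7)
agent = tm.Agent("p01", "GA", theta=0.05, phi=-0.09, noise_sd=1.0)
record = tm.simulate_agent(agent, schedule, config, seed=7)

# 3. Fit all four decision models and compare
fits = {m: tm.fit_model(m, record, n_restarts=1000, seed=7) for m in tm.MODEL_NAMES}
for name, fit in fits.items():
    print(f"{name}: SSE = {fit.sse:6.1f}  AIC = {fit.aic:7.2f}  params = "
          + ", ".join(f"{k}={v:.3f}" for k, v in fit.params.items()))

# 4. Classify the participant in the theta-phi strategy map
strategy_map = tm.StrategyMap(config=config).fit()
ms = fits["MS"].params
print("strategy:", tm.classify_participant(ms["theta"], ms["phi"], strategy_map))
```

prints

```
trials per condition: [20, 40, 20]
MS: SSE =   72.0  AIC =   -4.43  params = theta=0.050, phi=-0.084
GA: SSE =   72.0  AIC =   -6.43  params = theta=19.840
IA: SSE = 1670.0  AIC =  245.08  params = theta=11.336
GR: SSE = 9984.0  AIC =  386.14  params =
strategy: GA
```

The guilt-averse agent's 80 noisy returns are explained equally well by
the MS and GA models (SSE 72, roughly the 1-token decision noise), but the
GA model wins the AIC comparison by the two-point complexity penalty,
while the inequity-aversion and greed models miss the behavior by an order
of magnitude. The fitted (Θ, Φ) = (0.050, −0.084) lands in the guilt-averse
zone of the strategy map — the generating motive is recovered end to end.

A `trustmotives` command-line interface wraps the same pipeline
(`simulate`, `fit`, `classify`, `stability`, `prevalence`); every
subcommand reads and writes plain CSV/JSON.

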