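# infoval

Computational modelling of **how much physical effort people will trade for
non-instrumental information** — information that cannot change an outcome,
only the knower's certainty about it.

The package is aimed at decision-neuroscience and computational-psychiatry
researchers who run effort-based information-seeking experiments. It covers
the full analysis chain for a two-task paradigm:

- an **effort-discounting task** (fixed 1¢/low-effort baseline vs a 2–10¢
  offer at grip-force levels of 13–78% of maximum voluntary contraction),
  which pins down each subject's effort aversion; and
- an **information-seeking task** built on a nine-card lottery (win 10¢ iff
  ≥5 of 9 cards are the winning colour; hidden cards are fair coin flips, so
  Pr(win) is a binomial tail). Subjects may exert effort to reveal all the
  cards early — the information is worthless for the outcome, so any effort
  spent measures its intrinsic value.

## The model

An option's subjective value combines effort-discounted reward with the
value of the information it delivers:

```
V(O) = R − k_e·E²  +  k_i·I(O)  +  k_w·W(O)          (winning variant)
```

- effort cost: linear `k_e·E`, parabolic `k_e·E²`, or hyperbolic
  `R/(1 + k_e·E)` in the MVC fraction `E`;
- `I(O)`: the uncertainty the option resolves — the prior entropy of the
  lottery for the informative option, 0 for the non-informative one. Entropy
  is Shannon's, or the Rényi family `H_α(p) = log(p^α + (1−p)^α)/(1−α)`
  whose order α captures individual differences in sensitivity to
  uncertainty (α→1 recovers Shannon), or a card-count heuristic
  (proportion of cards still hidden);
- `W = Pr(win) − 0.5`: the expected valence of the news, weighted by `k_w`;
- choices follow a softmax with inverse temperature β,
  `Pr(A) = 1/(1 + e^{−β(V_A − V_B)})`.

Crossing the 3 discounting forms with {control, 3 content forms, 3 content
forms + valence} yields a 21-model space, plus a constrained control with
`k_i = k_w`. Models are fit **jointly to both tasks** (k_e and β shared
within subject) by hierarchical Bayesian estimation — subject parameters
partially pooled under group Gaussians on an unconstrained scale, with
`k_e = 100·Φ(raw)`, `α = 50·Φ(raw)`, `β = 20·Φ(raw)` — using an adaptive
Metropolis-within-Gibbs sampler (numba-compiled) with non-centred
interweaving. Model comparison uses WAIC on the deviance scale; model- and
parameter-recovery studies and posterior predictive checks are built in, as
is a synthetic-cohort generator standing in for the original 26-participant
study. See `docs/methods.md` for the full model account.

## Worked example

Simulate a study-sized cohort from the winning model (parabolic discounting
+ Rényi entropy + valence) and fit it back:

```python
import infoval as iv

group = iv.GroupParameters.defaults()          # k_e≈7.75, α≈1.22, k_i≈3.01, k_w≈0.60
subjects = iv.sample_subjects(group, 26, seed=1)
data = iv.simulate_dataset(iv.winning_model(), subjects, seed=2)

print(iv.summarise_choices(data)["pr_info_by_effort"].round(3).to_string(index=False))

fit = iv.fit_hierarchical(iv.winning_model(), data,
                          iv.SamplerConfig(chains=2, warmup=500, draws=600, seed=3))
print(fit.group_summary().round(2).to_string(index=False))
w = iv.compute_waic(fit)
print(f"WAIC {w.waic:.1f}  (elpd {w.elpd:.1f}, p_eff {w.p_eff:.1f}, se {w.se:.1f})")
```

Output:

```
 info_level  mean   sem  n_subjects
          1 0.818 0.025          26
          2 0.746 0.036          26
          3 0.560 0.046          26
          4 0.341 0.050          26
          5 0.147 0.039          26
          6 0.068 0.033          26
parameter  raw_loc_mean  raw_scale_mean  constrained_group_mean  constrained_group_hdi_low  constrained_group_hdi_high
      k_e         -1.43            0.19                    7.97                       7.71                        8.26
     beta         -1.33            0.33                    2.01                       1.84                        2.19
    alpha         -2.10            0.42                    1.28                       0.80                        2.30
      k_i          2.71            1.26                    2.88                       2.65                        3.14
      k_w          0.48            0.56                    0.49                       0.26                        0.70
WAIC 2793.7  (elpd -1304.2, p_eff 92.7, se 74.5)
```

The first table is the behavioural signature: preference for the
informative option falls monotonically as its effort cost rises from 13% to
78% MVC. The second shows the fitted group-level posterior recovering the
generative group means (effort aversion ≈ 8 vs the true 7.75; uncertainty
sensitivity α ≈ 1.3 vs 1.22; information preference k_i ≈ 2.9 vs 3.01;
valence preference k_w ≈ 0.5 vs 0.60; choice consistency β ≈ 2.0 vs 2.0),
with 95% intervals on the implied group distribution. WAIC is on the
deviance scale, so lower values mean better expected out-of-sample fit;
`p_eff` is the effective number of parameters after partial pooling.

A command-line interface mirrors the library:

```bash
infoval design effort --reps 4 --seed 1      # 120-trial discounting design
infoval design info --runs 3 --seed 1        # 96-trial lottery design
infoval simulate --n 26 --seed 1 --out ds/   # synthetic cohort (TSV + JSON)
infoval fit ds/ --chains 4 --seed 2          # hierarchical fit + WAIC summary
infoval compare ds/ --full-space             # rank all 21 models
infoval recover-models --n-sims 10           # confusion matrix
infoval run config.json                      # full pipeline with manifest
```

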