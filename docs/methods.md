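# Methods

## The behavioural model

`infoval` models how people trade physical effort for non-instrumental
information about a lottery outcome. Two tasks are modelled jointly.

**Effort-discounting task.** On each of 120 trials (6 effort levels x 5
rewards x 4 repetitions) a subject chooses between a fixed baseline (1 cent,
effort level 1) and an offer of R in {2, 4, 6, 8, 10} cents at effort level
1-6. Effort level L costs a grip force of E = 0.13 L as a fraction of the
subject's maximum voluntary contraction (MVC), so E ranges from 0.13 to 0.78.
Three canonical discounting forms are implemented:

- linear: V = R - k_e E
- parabolic: V = R - k_e E^2
- hyperbolic: V = R / (1 + k_e E)

with k_e >= 0 the subject's effort aversion.

**Information-seeking task.** Each of 96 trials (16 card configurations x 6
effort levels, in 3 runs of 32) presents a nine-card lottery: the lottery is
won (10 cents) iff at least five of the nine cards are of the winning colour.
A subset of cards is revealed; hidden cards are i.i.d. fair coin flips, so the
win probability is the binomial tail

    Pr(win | n, n_req) = 1 - sum_{k=0}^{n_req-1} C(n, k) 0.5^n,

with n the number of hidden cards and n_req = max(0, 5 - wins shown). The
subject can exert effort (level 1-6) to reveal all cards immediately
(informative option) or exert minimal effort (level 1) and wait (non-
informative option). The information is non-instrumental: it never changes
the outcome. Both options carry the same expected reward R = 5 cents, which
therefore cancels in choice probabilities and is retained only for value
reporting.

An option's value adds an information term and a valence term to the
discounted reward:

    V(O) = discounted reward + k_i I(O) + k_w W(O)

- I(O) is the uncertainty the option resolves: the prior entropy of the
  lottery for the informative option (the full card set is revealed, so the
  posterior entropy is 0) and 0 for the non-informative option. Entropy is
  Shannon's H(p) = -[p log p + (1-p) log(1-p)], the Renyi family
  H_a(p) = log(p^a + (1-p)^a) / (1-a) whose order a ("alpha") captures
  individual differences in sensitivity to uncertainty (a -> 1 recovers
  Shannon), or a visual card-count heuristic I = hidden / 9.
- W = Pr(win) - 0.5 is the expected valence of the information; k_w > 0
  means a preference for news about likely wins.

Choices follow a softmax with inverse temperature beta:
Pr(choose A) = 1 / (1 + exp(-beta (V_A - V_B))).

Crossing {linear, parabolic, hyperbolic} x {no-information control; Shannon,
Renyi, card-count content; each content form with/without valence} gives the
21-model space; a 22nd constrained control ties k_i = k_w in the winning
model (parabolic + Renyi + valence).

### Conventions that matter

- **Entropy base.** All entropies are natural-log (nats). The base is a pure
  rescaling of k_i (and of nothing else once alpha is fixed), so fitted k_i
  magnitudes are only comparable between analyses using the same base.
- **Valence attaches to the informative option only.** Both options share the
  same Pr(win); if W entered both option values it would cancel in the
  softmax and k_w would be unidentifiable. The package therefore sets
  W(non-informative) = 0, reading k_w W as part of the value of *obtaining*
  the information.
- **Joint fitting.** k_e and beta are shared by both tasks within a subject;
  the information-task parameters (alpha, k_i, k_w) enter only there.
- **Catch trials** (engagement probes, round-half-up 5% of information
  trials) carry no choice model and are excluded from every likelihood.

## The default lottery set

The sixteen starting configurations are found by deterministic search over
all 45 valid (wins shown, losses shown) pairs with at least one hidden card:
7 positively valenced configurations whose sorted Pr(win) values rise in
steps of 0.05-0.07 above the minimum attainable increment of ~0.14 over 0.5,
their 7 mirror images, and 2 neutral configurations. The search is forced:
the binomial grid admits exactly one such positive chain,

    Pr(win) = 0.6367, 0.6875, 0.75, 0.8125, 0.875, 0.9375, 1.0
    configs  = (1W,0L) (3W,2L) (4W,3L) (3W,1L) (4W,2L) (4W,1L) (5W,0L)

Ties at the same Pr(win) are broken toward the fewest revealed cards, which
also selects the neutral pair (0W,0L) and (1W,1L); the neutral members share
Pr(win) = 0.5 by definition but differ in hidden-card count, which the
card-count model distinguishes.

## Hierarchical estimation

Subject-level parameters live on an unconstrained raw scale and are partially
pooled: raw_ps ~ Normal(mu_p, sigma_p) for each free parameter p, with
weakly informative hyperpriors mu_p ~ Normal(0, 1) and
sigma_p ~ HalfNormal(1) (both exposed in `SamplerConfig`). Box-bounded
parameters map through the normal CDF — k_e = 100 Phi(raw),
alpha = 50 Phi(raw), beta = 20 Phi(raw) — while k_i and k_w stay Gaussian on
their natural scale.

Sampling is by an adaptive Metropolis-within-Gibbs scheme (numba-compiled,
with a pure-numpy reference path). Given the group parameters the subjects
are conditionally independent, so each iteration:

1. runs three random-walk Metropolis sweeps over per-subject parameter
   blocks, with per-subject proposal covariances adapted to the warmup
   history (target acceptance 0.3);
2. redraws one rotating coordinate per subject from its group prior as an
   independence proposal — this gives global jumps along weakly identified
   directions (for many subjects the data barely constrain alpha);
3. draws the group locations from their conjugate normal conditionals;
4. updates the group scales by adaptive log-scale Metropolis;
5. applies an interweaved non-centred update: jointly perturb
   (mu_j, sigma_j) while holding the standardised subject effects fixed,
   rescaling the whole subject column. This steps across the funnel that
   traps purely centred kernels when a group scale is small.

Chains start from a greedy accept-if-better search that lands each subject
near its conditional mode, so warmup is spent calibrating proposals rather
than travelling. Convergence is monitored with split-R-hat and bulk ESS
(via arviz) on all group and subject-level quantities; a fit with max
R-hat > 1.05 is flagged `converged = False` and raises a warning, never
silently dropped. Defaults are 4 chains x (1000 warmup + 1000 draws);
reduced presets are used for the simulation studies (sizes below).

The pointwise log-likelihood of every non-catch choice record is stored for
each posterior draw (float32). WAIC is computed from it as

    elpd = sum_i log mean_s p(y_i | theta_s),
    p_eff = sum_i Var_s log p(y_i | theta_s)   (sample variance, ddof = 1),
    WAIC  = -2 (elpd - p_eff),

reported on the deviance scale (lower is better), with a standard error from
the across-record variance of the pointwise contributions. Model families
are compared by the mean WAIC of their members.

## Synthetic cohorts

The generator emulates the study conditions: 26 subjects, the full two-task
design, choices sampled from the model's own softmax. Group-level defaults
put the constrained group means at k_e = 7.75, alpha = 1.22, k_i = 3.01,
k_w = 0.60, with raw-scale group SDs (0.2, 0.5, 1.0, 0.5) chosen once to
produce heterogeneous but plausible cohorts (e.g. the implied alpha range
spans roughly 0.1-10, and a small minority of subjects get negative k_w);
k_i and k_w are drawn with correlation rho = 0.6, matching the observed
between-subject association. No group-mean inverse temperature is reported
for the original cohort, so the default targets beta = 2 on the cents value
scale, which yields consistent but non-degenerate choices (e.g. ~80% for a
1-cent value difference); it is a calibration choice, not an empirical value.

The generator does not emulate: reaction times, learning or fatigue across
trials, failed effort executions, catch-trial misses, or any neural signal.
Passing recovery tests therefore show that the estimation machinery is
self-consistent under the model's own assumptions at the study's design
size — not that real participants satisfy those assumptions.

## Simulation studies and problem sizes

- **Model recovery**: cohorts are simulated from each of the 7
  parabolic-discounting models (the discounting winner) and all 7 candidates
  are re-fit to each cohort; the lowest-WAIC model is selected. The package
  default is 26-subject cohorts — model discrimination is an asymptotic
  property, and under-sized cohorts make nested pairs (control vs content,
  content vs content+valence) near-ties whose WAIC margins are ~1-2 points.
  The bundled studies run a reduced number of cohorts per generative model
  with 2 chains x (400 + 500) draws per fit; the full 21-model space is
  available behind a flag.
- **Parameter recovery**: cohorts simulated from the winning model at the
  study size, re-fit with the same model; reports pooled truth-vs-estimate
  Pearson correlations per parameter. Per-subject alpha is the weakest
  (individual lotteries carry little information about it; its recovery
  correlation is typically ~0.4-0.6, vs ~0.9 for k_e, k_i, k_w).
- **Posterior predictive checks**: replicate datasets simulated from
  subsampled posterior draws; condition-level choice proportions (Pr of the
  high-reward offer by effort and reward; Pr of the informative option by
  effort and by Pr(win)) are compared with the observed summaries through
  central 95% predictive bands.

## Numerical choices and edge cases

- Renyi entropy switches to the Shannon form within |alpha - 1| < 1e-6, and
  returns 0 for degenerate lotteries (Pr(win) in {0, 1}) at every order.
- The softmax is evaluated as a logistic of beta (V_A - V_B) via
  log1p/expit, so it cannot overflow at any bound.
- WAIC uses the sample variance (ddof = 1) in the penalty, the convention of
  the R `loo` package; arviz uses ddof = 0 (the test suite reconciles the
  two explicitly).
- Catch-trial counts round half-up; trial order is a uniform permutation
  under the run seed.
- A cohort of one subject is rejected: partial pooling is undefined.
- Parameter-recovery correlations for a generative parameter with (numerically)
  zero variance across subjects are reported as NaN with a note, not as 0.
- The per-trial effort modulator defaults to the winning model's parabolic
  cost k_e E^2, with a `linear` switch (k_e E) for sensitivity analyses.
- The Outcome-event information modulator is k_i I + k_w W on trials where
  the non-informative option was chosen (uncertainty resolves only when the
  outcome is shown) and 0 otherwise; the Reveal-event modulator is its
  complement.

## Known limitations

- The sampler is a random-walk scheme: it needs more draws than a gradient
  sampler for the same effective sample size, and small presets can leave
  split-R-hat above 1.05 (always reported on the fit).
- Nested model pairs are genuinely hard to separate by WAIC when the extra
  parameter's generative value is zero; selection accuracy for the
  no-information control model is limited by this at any cohort size.
- Group hyperpriors are fixed defaults (Normal(0,1) / HalfNormal(1) on the
  raw scale); with very small cohorts they shrink group locations of
  large-magnitude parameters (e.g. k_i ~ 3) noticeably toward zero.
- Only binary, trial-independent choices are modelled; no learning,
  satiation, or response-time structure.
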