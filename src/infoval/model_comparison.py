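"""Model comparison, recovery studies, and derived per-trial quantities.

Covers the full 21-model WAIC comparison with family-level aggregation,
model-recovery (confusion matrix of generative vs selected model), parameter
recovery (truth vs posterior-mean correlations on synthetic cohorts),
between-parameter correlations with Holm-corrected p-values, and export of
per-trial subjective-value modulators for event-related GLM analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from statsmodels.stats.multitest import multipletests

from .inference import PosteriorFit, SamplerConfig, compute_waic, fit_hierarchical
from .synthetic_data import (
    ChoiceDataset,
    GroupParameters,
    default_designs,
    sample_subjects,
    simulate_dataset,
)
from .value_models import ModelSpec, renyi_entropy, shannon_entropy

__all__ = [
    "ComparisonTable",
    "RecoveryResult",
    "compare_models",
    "parabolic_family",
    "model_recovery",
    "parameter_recovery",
    "parameter_correlations",
    "export_modulators",
]


@dataclass
class ComparisonTable:
    """Per-model WAIC results plus family-level means."""

    table: pd.DataFrame  # one row per spec: label, waic, se, elpd, p_eff, delta, rank
    fits: list[PosteriorFit] | None = None

    @property
    def best(self) -> str:
        return self.table.loc[self.table["rank"] == 0, "label"].iloc[0]

    def family_means(self, by: str = "discount") -> pd.Series:
        """Mean WAIC over the models within each family.

        ``by`` is one of ``"discount"`` (linear/parabolic/hyperbolic),
        ``"info"`` (none/shannon/renyi/card_count) or ``"valence"``.
        """
        if by not in ("discount", "info", "valence"):
            raise ValueError(f"unknown family grouping {by!r}")
        return self.table.groupby(by)["waic"].mean()


@dataclass
class RecoveryResult:
    """Outcome of a model- or parameter-recovery simulation study."""

    n_sims: int
    seed: int
    confusion: pd.DataFrame | None = None  # generative (rows) x selected (cols)
    accuracy: pd.Series | None = None  # per generative model
    param_correlations: pd.Series | None = None  # truth vs estimate, per parameter
    pooled: pd.DataFrame | None = None  # per-subject truth/estimate pairs
    converged_fraction: float = 1.0
    notes: list = field(default_factory=list)


def compare_models(
    data: ChoiceDataset,
    specs: list[ModelSpec],
    config: SamplerConfig | None = None,
    keep_fits: bool = False,
) -> ComparisonTable:
    """Fit every candidate model to the dataset and rank them by WAIC.

    Any non-converged member fit is flagged in the table (``converged``
    column) rather than dropped.  Each model is fit with a distinct
    seed derived from the configured one.
    """

    if config is None:
        config = SamplerConfig()
    rows, fits = [], []
    for i, spec in enumerate(specs):
        fit = fit_hierarchical(spec, data, config.with_seed(config.seed + 7919 * i))
        w = compute_waic(fit)
        rows.append(
            {
                "label": spec.label,
                "discount": spec.discount,
                "info": spec.info,
                "valence": spec.valence,
                "family": spec.family,
                "waic": w.waic,
                "se": w.se,
                "elpd": w.elpd,
                "p_eff": w.p_eff,
                "converged": fit.converged,
            }
        )
        if keep_fits:
            fits.append(fit)
    table = pd.DataFrame(rows)
    table["delta_waic"] = table["waic"] - table["waic"].min()
    table["rank"] = table["waic"].rank(method="first").astype(int) - 1
    return ComparisonTable(table=table, fits=fits if keep_fits else None)


def parabolic_family() -> list[ModelSpec]:
    """The seven parabolic-discounting models (the discount-form winner)."""
    return [
        ModelSpec("parabolic", "none", valence=False),
        ModelSpec("parabolic", "shannon", valence=False),
        ModelSpec("parabolic", "renyi", valence=False),
        ModelSpec("parabolic", "card_count", valence=False),
        ModelSpec("parabolic", "shannon", valence=True),
        ModelSpec("parabolic", "renyi", valence=True),
        ModelSpec("parabolic", "card_count", valence=True),
    ]


def model_recovery(
    specs: list[ModelSpec] | None = None,
    n_sims: int = 10,
    n_subjects: int = 8,
    seed: int = 0,
    group: GroupParameters | None = None,
    config: SamplerConfig | None = None,
) -> RecoveryResult:
    """Simulate cohorts from each candidate model and re-select by WAIC.

    For every generative spec, ``n_sims`` cohorts are drawn from the default
    group distribution, all candidates are fit to each cohort, and the model
    with the lowest WAIC is selected; the confusion matrix tallies the
    selections.  Per-fit convergence flags propagate into
    ``converged_fraction``.
    """

    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if specs is None:
        specs = parabolic_family()
    if group is None:
        group = GroupParameters.defaults()
    if config is None:
        config = SamplerConfig.test_preset()

    labels = [s.label for s in specs]
    confusion = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    n_fits, n_conv = 0, 0
    ss = np.random.SeedSequence(seed)
    sim_seeds = ss.generate_state(len(specs) * n_sims * 2) % (2**31 - 1)
    k = 0
    for gen in specs:
        for _ in range(n_sims):
            subj_seed, choice_seed = int(sim_seeds[k]), int(sim_seeds[k + 1])
            k += 2
            subjects = sample_subjects(group, n_subjects, seed=subj_seed)
            eff_d, inf_d = default_designs(seed=subj_seed)
            data = simulate_dataset(gen, subjects, eff_d, inf_d, seed=choice_seed)
            comp = compare_models(data, specs, config.with_seed(choice_seed))
            confusion.loc[gen.label, comp.best] += 1
            n_fits += len(specs)
            n_conv += int(comp.table["converged"].sum())
    accuracy = pd.Series(np.diag(confusion) / n_sims, index=labels, name="accuracy")
    return RecoveryResult(
        n_sims=n_sims,
        seed=seed,
        confusion=confusion,
        accuracy=accuracy,
        converged_fraction=n_conv / n_fits,
    )


def parameter_recovery(
    spec: ModelSpec | None = None,
    n_sims: int = 5,
    n_subjects: int = 26,
    seed: int = 0,
    group: GroupParameters | None = None,
    config: SamplerConfig | None = None,
) -> RecoveryResult:
    """Simulate cohorts from known parameters and fit the same model back.

    Reports the Pearson correlation between generative and posterior-mean
    parameters per subject, pooled over simulations.  A parameter whose
    generative values are constant has no defined correlation and is
    reported as NaN with an explanatory note.
    """

    if spec is None:
        spec = ModelSpec()  # parabolic + Renyi + valence
    if not spec.free_parameters:
        raise ValueError("spec has no free parameters to recover")
    if group is None:
        group = GroupParameters.defaults()
    if config is None:
        config = SamplerConfig.test_preset()

    frames = []
    n_conv = 0
    ss = np.random.SeedSequence(seed)
    sim_seeds = ss.generate_state(n_sims * 2) % (2**31 - 1)
    for i in range(n_sims):
        subj_seed, choice_seed = int(sim_seeds[2 * i]), int(sim_seeds[2 * i + 1])
        subjects = sample_subjects(group, n_subjects, seed=subj_seed)
        eff_d, inf_d = default_designs(seed=subj_seed)
        data = simulate_dataset(spec, subjects, eff_d, inf_d, seed=choice_seed)
        fit = fit_hierarchical(spec, data, config.with_seed(choice_seed))
        n_conv += int(fit.converged)
        est = fit.subject_means().rename(
            columns={p: f"est_{p}" for p in fit.param_names}
        )
        truth = subjects[["subject"] + [p for p in fit.param_names if p != "k_iw"]]
        if spec.tie:
            truth = truth.assign(k_iw=subjects["k_i"])
        merged = truth.rename(
            columns={p: f"true_{p}" for p in truth.columns if p != "subject"}
        ).merge(est, on="subject")
        merged["sim"] = i
        frames.append(merged)

    pooled = pd.concat(frames, ignore_index=True)
    corrs, notes = {}, []
    for p in spec.free_parameters:
        t, e = pooled[f"true_{p}"], pooled[f"est_{p}"]
        if t.std() < 1e-8:  # constant truth: zero-variance correlation undefined
            corrs[p] = np.nan
            notes.append(f"{p}: generative values constant; correlation undefined")
        else:
            corrs[p] = pearsonr(t, e).statistic
    return RecoveryResult(
        n_sims=n_sims,
        seed=seed,
        param_correlations=pd.Series(corrs, name="r"),
        pooled=pooled,
        converged_fraction=n_conv / n_sims,
        notes=notes,
    )


def parameter_correlations(fit: PosteriorFit) -> pd.DataFrame:
    """Pairwise Pearson correlations of per-subject posterior-mean parameters.

    p-values are adjusted with the Holm step-down procedure across all pairs.
    Constant parameter vectors yield undefined correlations, reported as NaN.
    """

    means = fit.subject_means()
    if len(means) < 3:
        raise ValueError("need at least 3 subjects to correlate parameters")
    rows = []
    for a, b in combinations(fit.param_names, 2):
        x, y = means[a], means[b]
        if x.nunique() <= 1 or y.nunique() <= 1:
            rows.append({"param_a": a, "param_b": b, "r": np.nan, "p": np.nan})
        else:
            res = pearsonr(x, y)
            rows.append(
                {"param_a": a, "param_b": b, "r": res.statistic, "p": res.pvalue}
            )
    out = pd.DataFrame(rows)
    defined = out["p"].notna()
    out["p_holm"] = np.nan
    if defined.any():
        out.loc[defined, "p_holm"] = multipletests(
            out.loc[defined, "p"], method="holm"
        )[1]
    return out


def export_modulators(
    params: pd.DataFrame | PosteriorFit,
    data: ChoiceDataset,
    spec: ModelSpec | None = None,
    effort_form: str = "parabolic",
) -> pd.DataFrame:
    """Per-trial subjective-value modulators for the Scenario/Reveal/Outcome events.

    At Scenario, the chosen option's information value k_i*I + k_w*W and its
    effort cost are emitted.  Uncertainty resolves at Reveal when the
    informative option was chosen, and at Outcome when it was not, so the
    full information value k_i*H_prior + k_w*W attaches to exactly one of
    those events per trial and the other is 0.  ``effort_form`` selects the
    cost term (``"parabolic"`` -> k_e * E**2, ``"linear"`` -> k_e * E).

    ``params`` is a per-subject parameter frame (e.g. generative truth or
    posterior means, with a ``subject`` column) or a fitted
    :class:`PosteriorFit` whose subject means are used.
    """

    if isinstance(params, PosteriorFit):
        if spec is None:
            spec = params.spec
        params = params.subject_means()
    if spec is None:
        raise ValueError("spec must be given when params is a plain frame")
    if effort_form not in ("parabolic", "linear"):
        raise ValueError("effort_form must be 'parabolic' or 'linear'")

    non_catch = data.info_design.loc[~data.info_design["is_catch"].astype(bool)]
    merged = data.info_choices.merge(non_catch, on="trial").merge(
        params, on="subject", suffixes=("", "_param")
    )
    if len(merged) < len(data.info_choices):
        raise ValueError("missing choices or parameters for some trials")

    p = merged["pr_win"].to_numpy(float)
    if spec.info == "shannon":
        content = shannon_entropy(p)
    elif spec.info == "renyi":
        content = renyi_entropy(p, merged["alpha"].to_numpy(float))
    elif spec.info == "card_count":
        content = merged["hidden"].to_numpy(float) / 9.0
    else:
        content = np.zeros(len(merged))
    k_i = merged["k_i"].to_numpy(float) if "k_i" in merged else np.zeros(len(merged))
    if spec.tie:
        k_w = k_i
    else:
        k_w = merged["k_w"].to_numpy(float) if "k_w" in merged else np.zeros(len(merged))
    w = p - 0.5
    info_value = k_i * content + k_w * w
    chose_info = merged["chose_info"].to_numpy(bool)

    e_chosen = np.where(
        chose_info,
        merged["info_mvc"].to_numpy(float),
        merged["noninfo_mvc"].to_numpy(float),
    )
    k_e = merged["k_e"].to_numpy(float)
    effort_cost = k_e * (e_chosen**2 if effort_form == "parabolic" else e_chosen)

    base = merged[["subject", "trial"]]
    blocks = [
        base.assign(
            event="scenario",
            modulator="info_value",
            value=np.where(chose_info, info_value, 0.0),
        ),
        base.assign(event="scenario", modulator="effort_cost", value=effort_cost),
        base.assign(
            event="reveal",
            modulator="info_value",
            value=np.where(chose_info, info_value, 0.0),
        ),
        base.assign(
            event="outcome",
            modulator="info_value",
            value=np.where(chose_info, 0.0, info_value),
        ),
    ]
    return pd.concat(blocks, ignore_index=True)
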