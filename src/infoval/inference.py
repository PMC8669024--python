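"""Hierarchical Bayesian estimation of the choice models.

Per-subject parameters live on an unconstrained (raw) scale and are partially
pooled under group-level Gaussians: raw_ps ~ Normal(mu_p, sigma_p) for every
free parameter p of the model, with weakly informative hyperpriors
mu_p ~ Normal(0, 1) and sigma_p ~ HalfNormal(1).  Bounded parameters map to
the model scale through the normal CDF (k_e = 100 Phi, alpha = 50 Phi,
beta = 20 Phi); k_e and beta are shared across the two tasks within subject.

Sampling uses an adaptive Metropolis-within-Gibbs scheme: given the group
parameters, subjects are conditionally independent, so each iteration updates
all subject blocks in parallel with random-walk proposals (proposal
covariances adapted to the warmup history), draws the group locations from
their conjugate normal conditionals, and updates the group scales with an
adaptive log-scale Metropolis step.  The pointwise log-likelihood of every
choice record is stored for each posterior draw, feeding WAIC and posterior
predictive checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .synthetic_data import ChoiceDataset, constrain, summarise_choices
from . import _fastll
from .value_models import LikelihoodEngine, ModelSpec

__all__ = [
    "SamplerConfig",
    "PosteriorFit",
    "WAICResult",
    "fit_hierarchical",
    "compute_waic",
    "posterior_predictive",
]

@dataclass(frozen=True)
class SamplerConfig:
    """Sampler settings and hyperprior scales.

    ``prior_loc_sd`` / ``prior_scale_sd`` are the Normal(0, .) and
    HalfNormal(.) hyperprior scales on the raw group locations and scales.
    """

    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    prior_loc_mean: float = 0.0
    prior_loc_sd: float = 1.0
    prior_scale_sd: float = 1.0
    rhat_threshold: float = 1.05
    subject_substeps: int = 3  # subject-block Metropolis sweeps per iteration

    @classmethod
    def test_preset(cls, seed: int = 0) -> "SamplerConfig":
        """Small, fast preset for smoke tests and scaled-down studies."""
        return cls(chains=2, warmup=300, draws=300, seed=seed)

    def with_seed(self, seed: int) -> "SamplerConfig":
        return replace(self, seed=seed)


@dataclass
class WAICResult:
    """Watanabe-Akaike information criterion on the deviance scale.

    ``elpd`` is the expected log pointwise predictive density, ``p_eff`` the
    effective parameter count (summed posterior variance of the pointwise
    log-likelihood), and ``waic = -2 (elpd - p_eff)`` so that lower is better.
    """

    elpd: float
    p_eff: float
    waic: float
    se: float


@dataclass
class PosteriorFit:
    """Posterior draws, pointwise log-likelihoods and diagnostics for one model."""

    spec: ModelSpec
    config: SamplerConfig
    subjects: list
    param_names: tuple[str, ...]
    raw: np.ndarray  # (chains, draws, subjects, params)
    group_loc: np.ndarray  # (chains, draws, params)
    group_scale: np.ndarray  # (chains, draws, params)
    log_lik: np.ndarray  # (chains, draws, records), float32
    record_index: pd.DataFrame
    accept_rate: np.ndarray  # (chains, subjects)
    diagnostics: dict = field(default_factory=dict)
    converged: bool = True
    divergences: int = 0  # random-walk kernels have no divergent transitions

    @property
    def n_draws(self) -> int:
        return self.raw.shape[0] * self.raw.shape[1]

    def constrained(self, name: str) -> np.ndarray:
        """Constrained-scale draws of one parameter, (chains, draws, subjects)."""
        j = self.param_names.index(name)
        return constrain(name if name != "k_iw" else "k_iw", self.raw[..., j])

    def subject_means(self) -> pd.DataFrame:
        """Posterior mean of each subject's constrained parameters."""
        out = {"subject": list(self.subjects)}
        for name in self.param_names:
            out[name] = self.constrained(name).mean(axis=(0, 1))
        return pd.DataFrame(out)

    def save(self, path) -> None:
        """Persist draws, pointwise matrix and metadata (.npz + JSON sidecar)."""
        import json
        from pathlib import Path

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            path.with_suffix(".npz"),
            raw=self.raw,
            group_loc=self.group_loc,
            group_scale=self.group_scale,
            log_lik=self.log_lik,
            accept_rate=self.accept_rate,
        )
        meta = {
            "spec": self.spec.to_json(),
            "subjects": [int(s) for s in self.subjects],
            "param_names": list(self.param_names),
            "record_index": self.record_index.to_dict(orient="list"),
            "diagnostics": self.diagnostics,
            "converged": self.converged,
            "config": {
                "chains": self.config.chains,
                "warmup": self.config.warmup,
                "draws": self.config.draws,
                "seed": self.config.seed,
            },
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "PosteriorFit":
        import json
        from pathlib import Path

        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            spec=ModelSpec.from_json(meta["spec"]),
            config=SamplerConfig(**meta["config"]),
            subjects=meta["subjects"],
            param_names=tuple(meta["param_names"]),
            raw=arrays["raw"],
            group_loc=arrays["group_loc"],
            group_scale=arrays["group_scale"],
            log_lik=arrays["log_lik"],
            record_index=pd.DataFrame(meta["record_index"]),
            accept_rate=arrays["accept_rate"],
            diagnostics=meta["diagnostics"],
            converged=meta["converged"],
        )

    def group_summary(self) -> pd.DataFrame:
        rows = []
        for j, name in enumerate(self.param_names):
            loc = self.group_loc[..., j].ravel()
            scale = self.group_scale[..., j].ravel()
            con = self.constrained(name).mean(axis=2).ravel()
            rows.append(
                {
                    "parameter": name,
                    "raw_loc_mean": loc.mean(),
                    "raw_scale_mean": scale.mean(),
                    "constrained_group_mean": con.mean(),
                    "constrained_group_hdi_low": np.quantile(con, 0.025),
                    "constrained_group_hdi_high": np.quantile(con, 0.975),
                }
            )
        return pd.DataFrame(rows)


def fit_hierarchical(
    spec: ModelSpec,
    data: ChoiceDataset,
    config: SamplerConfig | None = None,
) -> PosteriorFit:
    """Fit one model to a two-task dataset by adaptive Metropolis-within-Gibbs.

    Requires at least two subjects (partial pooling is undefined for one).
    Non-convergence (max split-R-hat above the configured threshold) is
    reported as a warning and flagged on the returned fit, never hidden.
    """

    if config is None:
        config = SamplerConfig()
    data.validate()
    if len(data.subjects) < 2:
        raise ValueError("hierarchical fitting requires at least 2 subjects")

    engine = LikelihoodEngine.from_dataset(spec, data)
    names = spec.free_parameters
    S, d = len(engine.subjects), len(names)
    n_rec = engine.n_records

    raw_out = np.empty((config.chains, config.draws, S, d))
    loc_out = np.empty((config.chains, config.draws, d))
    scale_out = np.empty((config.chains, config.draws, d))
    ll_out = np.empty((config.chains, config.draws, n_rec), dtype=np.float32)
    accept_out = np.empty((config.chains, S))

    root = np.random.SeedSequence(config.seed)
    chain_seeds = root.generate_state(config.chains) % (2**31 - 1)
    for c in range(config.chains):
        _run_chain(
            engine,
            names,
            config,
            int(chain_seeds[c]),
            raw_out[c],
            loc_out[c],
            scale_out[c],
            ll_out[c],
            accept_out[c],
        )

    fit = PosteriorFit(
        spec=spec,
        config=config,
        subjects=list(engine.subjects),
        param_names=names,
        raw=raw_out,
        group_loc=loc_out,
        group_scale=scale_out,
        log_lik=ll_out,
        record_index=engine.record_index,
        accept_rate=accept_out,
    )
    fit.diagnostics = _diagnose(fit)
    fit.converged = fit.diagnostics["max_rhat"] <= config.rhat_threshold
    if not fit.converged:
        warnings.warn(
            f"fit of {spec.label} did not converge: "
            f"max split-R-hat = {fit.diagnostics['max_rhat']:.3f}",
            RuntimeWarning,
            stacklevel=2,
        )
    return fit


def _run_chain(engine, names, config, seed, raw_out, loc_out, scale_out, ll_out, acc_out):
    """Prepare kernel inputs for one chain and run it."""
    spec = engine.spec
    pos = {name: j for j, name in enumerate(names)}
    if spec.tie:
        ki = kw = pos["k_iw"]
    else:
        ki = pos.get("k_i", -1)
        kw = pos.get("k_w", -1)
    idx = np.array(
        [pos["k_e"], pos["beta"], pos.get("alpha", -1), ki, kw], dtype=np.int64
    )
    h_sh = (
        engine._h_shannon
        if spec.info in ("shannon", "renyi")
        else np.zeros(engine.n_info)
    )
    _fastll.chain_kernel(
        seed,
        config.warmup,
        config.draws,
        config.subject_substeps,
        config.prior_loc_mean,
        config.prior_loc_sd,
        config.prior_scale_sd,
        idx,
        _fastll.DISC_CODE[spec.discount],
        _fastll.INFO_CODE[spec.info],
        engine.r_offer,
        engine.e_offer,
        engine.r_base,
        engine.e_base,
        engine.pr_win,
        engine.hidden_frac,
        engine.e_info,
        engine.e_noninfo,
        h_sh,
        engine._sign_e,
        engine._sign_i,
        raw_out,
        loc_out,
        scale_out,
        ll_out,
        acc_out,
    )


def _diagnose(fit: PosteriorFit) -> dict:
    """Split-R-hat and bulk ESS for group and subject parameters (via arviz)."""
    import arviz as az

    post = {}
    for j, name in enumerate(fit.param_names):
        post[f"mu_{name}"] = fit.group_loc[..., j]
        post[f"sigma_{name}"] = fit.group_scale[..., j]
        post[f"raw_{name}"] = fit.raw[..., j]
    idata = az.from_dict(posterior=post)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rhat_max = float(max(np.nanmax(rhat[v].values) for v in rhat.data_vars))
    ess_min = float(min(np.nanmin(ess[v].values) for v in ess.data_vars))
    per_param = {
        str(v): float(np.nanmax(rhat[v].values)) for v in rhat.data_vars
    }
    return {"max_rhat": rhat_max, "min_ess": ess_min, "rhat": per_param}


def compute_waic(fit_or_loglik) -> WAICResult:
    """WAIC from a pointwise log-likelihood matrix.

    elpd = sum_i log mean_s exp(lp_is); the complexity penalty is the summed
    posterior variance of the pointwise log-likelihood; the criterion is
    reported on the deviance scale, waic = -2 (elpd - p_eff), lower better.
    Accepts a :class:`PosteriorFit` or a (draws, records) matrix.
    """

    if isinstance(fit_or_loglik, PosteriorFit):
        ll = fit_or_loglik.log_lik.reshape(-1, fit_or_loglik.log_lik.shape[-1])
    else:
        ll = np.asarray(fit_or_loglik, dtype=float)
    if ll.ndim != 2 or ll.size == 0:
        raise ValueError("need a non-empty (draws, records) log-likelihood matrix")
    ll = ll.astype(float)
    n_draws = ll.shape[0]
    # log mean exp over draws, stable
    m = ll.max(axis=0)
    lpd = m + np.log(np.mean(np.exp(ll - m), axis=0))
    p_i = ll.var(axis=0, ddof=1) if n_draws > 1 else np.zeros(ll.shape[1])
    elpd_i = lpd - p_i
    waic_i = -2.0 * elpd_i
    se = float(np.sqrt(len(waic_i) * np.var(waic_i, ddof=1))) if len(waic_i) > 1 else 0.0
    return WAICResult(
        elpd=float(lpd.sum()),
        p_eff=float(p_i.sum()),
        waic=float(-2.0 * (lpd.sum() - p_i.sum())),
        se=se,
    )


def posterior_predictive(
    fit: PosteriorFit,
    data: ChoiceDataset,
    n_rep: int = 200,
    seed: int | None = None,
    level: float = 0.95,
) -> dict:
    """Replicate condition-level choice proportions from posterior draws.

    For each of ``n_rep`` subsampled posterior draws a full replicate dataset
    is simulated and summarised exactly like the observed data.  Returns the
    per-condition observed mean, the predictive median and central
    ``level`` band, and the fraction of conditions whose observed mean falls
    inside its band (``coverage``).
    """

    engine = LikelihoodEngine.from_dataset(fit.spec, data)
    rng = np.random.default_rng(seed)
    C, D = fit.raw.shape[:2]
    idx = rng.integers(0, C * D, size=n_rep)
    cc, dd = np.unravel_index(idx, (C, D))

    observed = summarise_choices(data)
    sims: dict[str, list] = {k: [] for k in observed}
    eff = data.effort_design
    non_catch = data.info_design.loc[~data.info_design["is_catch"].astype(bool)]
    eff_levels = eff["offer_level"].to_numpy()
    eff_rewards = eff["offer_reward"].to_numpy()
    inf_levels = non_catch["info_level"].to_numpy()
    inf_prwin = non_catch["pr_win"].round(4).to_numpy()

    for c, k in zip(cc, dd):
        params = {
            name: constrain(name, fit.raw[c, k, :, j])
            for j, name in enumerate(fit.param_names)
        }
        beta = params["beta"][:, None]
        p_e = expit(beta * engine.dv_effort(params["k_e"]))
        p_i = expit(beta * engine.dv_info(params))
        ch_e = (rng.random(p_e.shape) < p_e).astype(float)
        ch_i = (rng.random(p_i.shape) < p_i).astype(float)
        sims["pr_hr_by_effort"].append(_cond_means(ch_e, eff_levels))
        sims["pr_hr_by_reward"].append(_cond_means(ch_e, eff_rewards))
        sims["pr_info_by_effort"].append(_cond_means(ch_i, inf_levels))
        sims["pr_info_by_prwin"].append(_cond_means(ch_i, inf_prwin))

    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    tables = {}
    n_in, n_tot = 0, 0
    key_col = {
        "pr_hr_by_effort": "offer_level",
        "pr_hr_by_reward": "offer_reward",
        "pr_info_by_effort": "info_level",
        "pr_info_by_prwin": "pr_win_bin",
    }
    for name, obs in observed.items():
        arr = np.vstack(sims[name])  # (n_rep, n_conditions)
        levels_sorted = np.unique(
            {
                "pr_hr_by_effort": eff_levels,
                "pr_hr_by_reward": eff_rewards,
                "pr_info_by_effort": inf_levels,
                "pr_info_by_prwin": inf_prwin,
            }[name]
        )
        table = obs.set_index(key_col[name]).loc[levels_sorted].reset_index()
        table["pred_median"] = np.median(arr, axis=0)
        table["pred_low"] = np.quantile(arr, lo_q, axis=0)
        table["pred_high"] = np.quantile(arr, hi_q, axis=0)
        inside = (table["mean"] >= table["pred_low"]) & (
            table["mean"] <= table["pred_high"]
        )
        table["inside_band"] = inside
        n_in += int(inside.sum())
        n_tot += len(table)
        tables[name] = table
    return {"tables": tables, "coverage": n_in / n_tot, "n_rep": n_rep}


def _cond_means(choices: np.ndarray, cond: np.ndarray) -> np.ndarray:
    """Group mean of per-subject condition means, conditions sorted."""
    out = []
    for v in np.unique(cond):
        out.append(choices[:, cond == v].mean())
    return np.array(out)
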