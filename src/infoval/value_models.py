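"""Subjective-value models for effortful information seeking.

An option's value combines up to four ingredients: monetary reward, a physical
effort cost (linear, parabolic or hyperbolic in the required fraction of MVC),
the content of the information it delivers (scaled by a preference weight k_i),
and the expected valence of that information (scaled by k_w):

    V(O) = effort-discounted reward + k_i * I(O) + k_w * W(O)

Information content I is the uncertainty (entropy) the option resolves: the
informative option fully resolves the lottery (I = prior entropy), the
non-informative option resolves nothing (I = 0).  Entropy is Shannon's, or the
more flexible Renyi form whose order alpha captures individual differences in
sensitivity to uncertainty, or a card-count heuristic (proportion of cards
still hidden).  Valence W = Pr(win) - 0.5.  Choices follow a softmax with
inverse temperature beta.  Crossing 3 discounting forms with the information
variants yields the 21-model space, plus a constrained control with k_i = k_w.

All entropies are in nats; the log base only rescales k_i (and the alpha-free
terms), so fitted k_i magnitudes are base-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from . import _fastll
from .task_design import (
    CardConfiguration,
    EffortDiscountTrial,
    EffortLevel,
    InfoSeekTrial,
)

__all__ = [
    "DISCOUNT_FORMS",
    "INFO_FORMS",
    "PARAM_BOUNDS",
    "ModelSpec",
    "SubjectParameters",
    "OptionValue",
    "model_space",
    "winning_model",
    "constrained_control",
    "shannon_entropy",
    "renyi_entropy",
    "information_content",
    "option_value",
    "option_value_table",
    "choice_probability",
    "dataset_loglik",
    "LikelihoodEngine",
]

DISCOUNT_FORMS = ("linear", "parabolic", "hyperbolic")
INFO_FORMS = ("none", "shannon", "renyi", "card_count")
INFO_TASK_REWARD = 5.0  # expected value of the 10-cent lottery, common to both options

#: upper bounds of the cumulative-normal-constrained parameters
PARAM_BOUNDS = {"k_e": 100.0, "alpha": 50.0, "beta": 20.0}

_ALPHA_SHANNON_EPS = 1e-6  # switch to the Shannon limit this close to alpha = 1


@dataclass(frozen=True)
class ModelSpec:
    """One candidate value model.

    ``discount`` selects the effort-discounting form; ``info`` how (and
    whether) information content is computed; ``valence`` whether the k_w * W
    term is included; ``tie`` constrains k_i = k_w (the single-coefficient
    control model).
    """

    discount: str = "parabolic"
    info: str = "renyi"
    valence: bool = True
    tie: bool = False

    def __post_init__(self) -> None:
        if self.discount not in DISCOUNT_FORMS:
            raise ValueError(f"unknown discount form {self.discount!r}")
        if self.info not in INFO_FORMS:
            raise ValueError(f"unknown info form {self.info!r}")
        if self.info == "none" and (self.valence or self.tie):
            raise ValueError("a no-information model cannot include valence terms")
        if self.tie and not self.valence:
            raise ValueError("tying k_i = k_w requires the valence term")

    @property
    def family(self) -> str:
        """Family label: 1 = control, 2.x = content only, 3.x = content + valence."""
        if self.info == "none":
            return "1"
        sub = {"shannon": 1, "renyi": 2, "card_count": 3}[self.info]
        fam = 3 if self.valence else 2
        return f"{fam}.{sub}"

    @property
    def label(self) -> str:
        prefix = {"linear": "L", "parabolic": "P", "hyperbolic": "H"}[self.discount]
        return f"{prefix}{self.family}" + ("c" if self.tie else "")

    @property
    def free_parameters(self) -> tuple[str, ...]:
        names = ["k_e", "beta"]
        if self.info == "renyi":
            names.append("alpha")
        if self.info != "none":
            if self.tie:
                names.append("k_iw")
            else:
                names.append("k_i")
                if self.valence:
                    names.append("k_w")
        return tuple(names)

    def to_json(self) -> dict:
        return {
            "discount": self.discount,
            "info": self.info,
            "valence": self.valence,
            "tie": self.tie,
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "ModelSpec":
        return cls(
            discount=obj["discount"],
            info=obj["info"],
            valence=bool(obj["valence"]),
            tie=bool(obj.get("tie", False)),
        )


def model_space() -> list[ModelSpec]:
    """The 21 candidate models: 7 per discounting form."""
    specs = []
    for disc in DISCOUNT_FORMS:
        specs.append(ModelSpec(disc, "none", valence=False))
        for form in ("shannon", "renyi", "card_count"):
            specs.append(ModelSpec(disc, form, valence=False))
        for form in ("shannon", "renyi", "card_count"):
            specs.append(ModelSpec(disc, form, valence=True))
    return specs


def winning_model() -> ModelSpec:
    """Parabolic discounting + Renyi entropy + valence (model 3.2)."""
    return ModelSpec("parabolic", "renyi", valence=True)


def constrained_control() -> ModelSpec:
    """The winning model refit under the constraint k_i = k_w."""
    return replace(winning_model(), tie=True)


@dataclass(frozen=True)
class SubjectParameters:
    """Constrained-scale parameters for one subject.

    k_e (effort aversion), alpha (Renyi order / uncertainty sensitivity) and
    beta (inverse temperature) are box-bounded; k_i (uncertainty-reduction
    preference) and k_w (valence preference) are unbounded.
    """

    k_e: float
    beta: float
    alpha: float = 1.0
    k_i: float = 0.0
    k_w: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_e", "alpha", "beta"):
            v = getattr(self, name)
            if not 0.0 <= v <= PARAM_BOUNDS[name]:
                raise ValueError(f"{name}={v} outside [0, {PARAM_BOUNDS[name]}]")


@dataclass(frozen=True)
class OptionValue:
    """Decomposition of one option's subjective value."""

    reward_term: float
    effort_cost: float
    info_term: float
    valence_term: float

    @property
    def total(self) -> float:
        return self.reward_term - self.effort_cost + self.info_term + self.valence_term


def shannon_entropy(p):
    """Binary Shannon entropy in nats, with 0 log 0 = 0."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    q = 1.0 - p
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(np.where(p > 0, p * np.log(p), 0.0) + np.where(q > 0, q * np.log(q), 0.0))
    return h if h.ndim else float(h)


def renyi_entropy(p, alpha):
    """Binary Renyi entropy of order alpha in nats.

    H_a(p) = log(p**a + (1-p)**a) / (1 - a) for a >= 0, a != 1; the a -> 1
    limit is the Shannon entropy and is used within 1e-6 of 1.  Degenerate
    distributions (p in {0, 1}) have zero entropy at every order.
    """

    p = np.asarray(p, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if np.any(alpha < 0):
        raise ValueError("alpha must be non-negative")

    p, alpha = np.broadcast_arrays(p, alpha)
    out = np.empty(p.shape, dtype=float)
    degenerate = (p == 0) | (p == 1)
    near_one = np.abs(alpha - 1.0) < _ALPHA_SHANNON_EPS
    out[near_one] = shannon_entropy(p[near_one])
    rest = ~near_one
    with np.errstate(divide="ignore"):
        a = alpha[rest]
        pr = p[rest]
        out[rest] = np.log(pr**a + (1.0 - pr) ** a) / (1.0 - a)
    out[degenerate] = 0.0
    return out if out.ndim else float(out)


def _entropy_prior(spec: ModelSpec, config: CardConfiguration, params: SubjectParameters):
    if spec.info == "shannon":
        return shannon_entropy(config.pr_win)
    if spec.info == "renyi":
        return renyi_entropy(config.pr_win, params.alpha)
    if spec.info == "card_count":
        return config.hidden_fraction
    raise ValueError(f"no information measure for info form {spec.info!r}")


def information_content(
    trial: InfoSeekTrial,
    option: str,
    spec: ModelSpec,
    params: SubjectParameters,
) -> float:
    """I(O): prior entropy for the informative option, 0 for the non-informative.

    The informative option fully resolves the lottery (posterior entropy 0),
    so its content equals the prior entropy of the starting configuration;
    under the card-count heuristic it is the proportion of hidden cards.
    """

    if spec.info == "none":
        raise ValueError("information content is undefined for a no-information model")
    if option == "noninformative":
        return 0.0
    if option != "informative":
        raise ValueError(f"unknown option {option!r}")
    return float(_entropy_prior(spec, trial.configuration, params))


def _discounted_reward(form: str, reward, k_e, effort):
    """Effort-discounted reward (the full first term of the value function)."""
    if form == "linear":
        return reward - k_e * effort
    if form == "parabolic":
        return reward - k_e * effort**2
    if form == "hyperbolic":
        return reward / (1.0 + k_e * effort)
    raise ValueError(f"unknown discount form {form!r}")


def option_value(
    spec: ModelSpec,
    params: SubjectParameters,
    trial: EffortDiscountTrial | InfoSeekTrial,
    option: str,
) -> OptionValue:
    """Value decomposition of one option of one trial.

    For :class:`EffortDiscountTrial`, ``option`` is ``"offer"`` or
    ``"baseline"`` and the information/valence terms are identically zero.
    For :class:`InfoSeekTrial`, ``option`` is ``"informative"`` or
    ``"noninformative"``; both options carry the same expected reward
    (R = 5 cents), and the information and valence terms attach to the
    informative option only.
    """

    if isinstance(trial, EffortDiscountTrial):
        if option == "offer":
            reward, effort = float(trial.offer_reward), trial.offer_effort.mvc_fraction
        elif option == "baseline":
            reward, effort = float(trial.baseline_reward), trial.baseline_effort.mvc_fraction
        else:
            raise ValueError(f"unknown effort-task option {option!r}")
        info = val = 0.0
    elif isinstance(trial, InfoSeekTrial):
        reward = INFO_TASK_REWARD
        if option == "informative":
            effort = trial.info_effort.mvc_fraction
            if spec.info == "none":
                info = val = 0.0
            else:
                content = information_content(trial, option, spec, params)
                k_i = params.k_i
                k_w = k_i if spec.tie else params.k_w
                info = k_i * content
                val = k_w * trial.configuration.valence if (spec.valence or spec.tie) else 0.0
        elif option == "noninformative":
            effort = trial.noninfo_effort.mvc_fraction
            info = val = 0.0
        else:
            raise ValueError(f"unknown info-task option {option!r}")
    else:
        raise TypeError(f"unsupported trial type {type(trial).__name__}")

    discounted = float(_discounted_reward(spec.discount, reward, params.k_e, effort))
    return OptionValue(
        reward_term=reward,
        effort_cost=reward - discounted,
        info_term=float(info),
        valence_term=float(val),
    )


def choice_probability(beta: float, v_chosen, v_other):
    """Softmax probability of the chosen option over a binary choice.

    Pr = exp(beta * v_c) / (exp(beta * v_c) + exp(beta * v_o)), evaluated as a
    logistic in beta * (v_c - v_o) so it never overflows.
    """

    if beta < 0:
        raise ValueError("beta must be non-negative")
    v_chosen = np.asarray(v_chosen, dtype=float)
    v_other = np.asarray(v_other, dtype=float)
    if not (np.all(np.isfinite(v_chosen)) and np.all(np.isfinite(v_other))):
        raise ValueError("option values must be finite")
    out = expit(beta * (v_chosen - v_other))
    return out if out.ndim else float(out)


def _log_sigmoid(x):
    return -np.logaddexp(0.0, -x)


class LikelihoodEngine:
    """Vectorised joint choice likelihood for a cohort under one model.

    Precomputes per-trial design quantities from a dataset's effort and
    information design tables and evaluates, for a matrix of per-subject
    parameters, the pointwise log-likelihood of every non-catch choice record.
    k_e and beta are shared by both tasks within a subject.  Record order is
    all effort-task records (subject-major, design order) followed by all
    information-task records.
    """

    def __init__(
        self,
        spec: ModelSpec,
        effort_design: pd.DataFrame,
        info_design: pd.DataFrame,
        subjects: Iterable,
        effort_choices: pd.DataFrame | None = None,
        info_choices: pd.DataFrame | None = None,
    ) -> None:
        self.spec = spec
        ed = effort_design
        info = info_design.loc[~info_design["is_catch"].astype(bool)]
        self.effort_trials = ed["trial"].to_numpy(int)
        self.info_trials = info["trial"].to_numpy(int)

        self.r_offer = ed["offer_reward"].to_numpy(float)
        self.e_offer = ed["offer_mvc"].to_numpy(float)
        self.r_base = ed["base_reward"].to_numpy(float)
        self.e_base = ed["base_mvc"].to_numpy(float)

        self.pr_win = info["pr_win"].to_numpy(float)
        self.valence = self.pr_win - 0.5
        self.hidden_frac = info["hidden"].to_numpy(float) / 9.0
        self.e_info = info["info_mvc"].to_numpy(float)
        self.e_noninfo = info["noninfo_mvc"].to_numpy(float)
        if spec.info in ("shannon", "renyi"):
            self._h_shannon = shannon_entropy(self.pr_win)
            self._p_degenerate = (self.pr_win == 0.0) | (self.pr_win == 1.0)

        self.subjects = list(subjects)
        self.n_effort = self.r_offer.size
        self.n_info = self.pr_win.size
        self.n_records = len(self.subjects) * (self.n_effort + self.n_info)
        self.chose_offer = self.chose_info = None
        self._sign_e = self._sign_i = None
        if effort_choices is not None:
            self.chose_offer = self._pivot(
                effort_choices, "chose_offer", ed["trial"], set(ed["trial"])
            )
            self._sign_e = 2.0 * self.chose_offer - 1.0
        if info_choices is not None:
            self.chose_info = self._pivot(
                info_choices, "chose_info", info["trial"], set(info_design["trial"])
            )
            self._sign_i = 2.0 * self.chose_info - 1.0

    @classmethod
    def from_dataset(cls, spec: ModelSpec, data) -> "LikelihoodEngine":
        return cls(
            spec,
            data.effort_design,
            data.info_design,
            data.subjects,
            data.effort_choices,
            data.info_choices,
        )

    def _pivot(
        self,
        choices: pd.DataFrame,
        col: str,
        trials: pd.Series,
        known_trials: set,
    ) -> np.ndarray:
        orphans = sorted(set(choices["trial"].astype(int)) - {int(t) for t in known_trials})
        if orphans:
            raise ValueError(f"choice records reference unknown trials: {orphans[:5]}")
        # records on catch trials (if present) are dropped from the likelihood
        keep = choices[choices["trial"].isin(set(int(t) for t in trials))]
        wide = keep.pivot(index="subject", columns="trial", values=col)
        wide = wide.reindex(index=self.subjects, columns=list(trials))
        if wide.isna().any().any():
            raise ValueError("missing choice records for some subject/trial cells")
        return wide.to_numpy(float)

    @property
    def record_index(self) -> pd.DataFrame:
        """(task, subject, trial) for each row of the pointwise vector."""
        rows = []
        for s in self.subjects:
            rows += [("effort", s, int(t)) for t in range(self.n_effort)]
        for s in self.subjects:
            rows += [("info", s, int(t)) for t in range(self.n_info)]
        return pd.DataFrame(rows, columns=["task", "subject", "trial"])

    def _renyi(self, alpha: np.ndarray) -> np.ndarray:
        """Renyi prior entropy, (S, n_info_trials); fast path for the sampler."""
        a = alpha[:, None]
        p = self.pr_win[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.log(p**a + (1.0 - p) ** a) / (1.0 - a)
        h = np.where(np.abs(a - 1.0) < 1e-6, self._h_shannon[None, :], h)
        return np.where(self._p_degenerate[None, :], 0.0, h)

    # -- vectorised value differences ------------------------------------

    def dv_effort(self, k_e: np.ndarray) -> np.ndarray:
        """Value(offer) - value(baseline), shape (n_subjects, n_effort_trials)."""
        k = k_e[:, None]
        return _discounted_reward(self.spec.discount, self.r_offer, k, self.e_offer) - (
            _discounted_reward(self.spec.discount, self.r_base, k, self.e_base)
        )

    def dv_info(self, params: Mapping[str, np.ndarray]) -> np.ndarray:
        """Value(informative) - value(noninformative), shape (S, n_info_trials)."""
        spec = self.spec
        k = params["k_e"][:, None]
        dv = _discounted_reward(spec.discount, INFO_TASK_REWARD, k, self.e_info) - (
            _discounted_reward(spec.discount, INFO_TASK_REWARD, k, self.e_noninfo)
        )
        if spec.info == "none":
            return dv
        if spec.info == "shannon":
            content = self._h_shannon[None, :]
        elif spec.info == "renyi":
            content = self._renyi(params["alpha"])
        else:  # card_count
            content = self.hidden_frac[None, :]
        if spec.tie:
            dv = dv + params["k_iw"][:, None] * (content + self.valence[None, :])
        else:
            dv = dv + params["k_i"][:, None] * content
            if spec.valence:
                dv = dv + params["k_w"][:, None] * self.valence[None, :]
        return dv

    def pointwise_numpy(self, params: Mapping[str, np.ndarray]) -> np.ndarray:
        """Pointwise log-likelihood over all records (numpy reference path)."""
        if self.chose_offer is None or self.chose_info is None:
            raise ValueError("engine was built without choice data")
        beta = params["beta"][:, None]
        lp_e = _log_sigmoid(self._sign_e * beta * self.dv_effort(params["k_e"]))
        lp_i = _log_sigmoid(self._sign_i * beta * self.dv_info(params))
        return np.concatenate([lp_e.ravel(), lp_i.ravel()])

    def subject_loglik_numpy(self, params: Mapping[str, np.ndarray]) -> np.ndarray:
        """Summed log-likelihood per subject (numpy reference path)."""
        if self.chose_offer is None or self.chose_info is None:
            raise ValueError("engine was built without choice data")
        beta = params["beta"][:, None]
        lp_e = _log_sigmoid(self._sign_e * beta * self.dv_effort(params["k_e"]))
        lp_i = _log_sigmoid(self._sign_i * beta * self.dv_info(params))
        return lp_e.sum(axis=1) + lp_i.sum(axis=1)

    def _kernel_params(self, params: Mapping[str, np.ndarray]):
        S = len(self.subjects)
        zeros = np.zeros(S)
        alpha = params.get("alpha", zeros)
        if self.spec.tie:
            k_i = k_w = params["k_iw"]
        else:
            k_i = params.get("k_i", zeros)
            k_w = params.get("k_w", zeros) if self.spec.valence else zeros
        return params["k_e"], params["beta"], alpha, k_i, k_w

    def _kernel(self, params: Mapping[str, np.ndarray], pointwise: bool) -> np.ndarray:
        if self.chose_offer is None or self.chose_info is None:
            raise ValueError("engine was built without choice data")
        k_e, beta, alpha, k_i, k_w = self._kernel_params(params)
        S = len(self.subjects)
        out_subject = np.empty(S)
        out_point = np.empty(self.n_records if pointwise else 0)
        h_sh = self._h_shannon if self.spec.info in ("shannon", "renyi") else (
            np.zeros(self.n_info)
        )
        _fastll.loglik_kernel(
            k_e,
            beta,
            alpha,
            k_i,
            k_w,
            _fastll.DISC_CODE[self.spec.discount],
            _fastll.INFO_CODE[self.spec.info],
            self.r_offer,
            self.e_offer,
            self.r_base,
            self.e_base,
            self.pr_win,
            self.hidden_frac,
            self.e_info,
            self.e_noninfo,
            h_sh,
            self._sign_e,
            self._sign_i,
            pointwise,
            out_subject,
            out_point,
        )
        return out_point if pointwise else out_subject

    def pointwise(self, params: Mapping[str, np.ndarray]) -> np.ndarray:
        """Pointwise log-likelihood over all records, in canonical record order."""
        if _fastll.HAVE_NUMBA:
            return self._kernel(params, pointwise=True)
        return self.pointwise_numpy(params)

    def subject_loglik(self, params: Mapping[str, np.ndarray]) -> np.ndarray:
        """Summed log-likelihood per subject (both tasks)."""
        if _fastll.HAVE_NUMBA:
            return self._kernel(params, pointwise=False)
        return self.subject_loglik_numpy(params)


def _params_frame(params, subjects: Iterable) -> pd.DataFrame:
    if isinstance(params, pd.DataFrame):
        return params.set_index("subject") if "subject" in params.columns else params
    # mapping subject -> SubjectParameters
    rows = {}
    for s in subjects:
        p = params[s]
        rows[s] = {
            "k_e": p.k_e,
            "alpha": p.alpha,
            "k_i": p.k_i,
            "k_w": p.k_w,
            "beta": p.beta,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def option_value_table(
    spec: ModelSpec, params: SubjectParameters, info_design: pd.DataFrame
) -> pd.DataFrame:
    """Per-trial value decomposition of both options, for audit export (TSV).

    One row per (trial, option) with the reward, effort-cost, information and
    valence components and the total subjective value.
    """

    rows = []
    for _, r in info_design.iterrows():
        trial = InfoSeekTrial(
            configuration=CardConfiguration(int(r["wins_shown"]), int(r["losses_shown"])),
            info_effort=EffortLevel(int(r["info_level"])),
        )
        for option in ("informative", "noninformative"):
            v = option_value(spec, params, trial, option)
            rows.append(
                {
                    "trial": int(r["trial"]),
                    "option": option,
                    "reward_term": v.reward_term,
                    "effort_cost": v.effort_cost,
                    "info_term": v.info_term,
                    "valence_term": v.valence_term,
                    "total": v.total,
                }
            )
    return pd.DataFrame(rows)


def dataset_loglik(spec: ModelSpec, params, data) -> pd.Series:
    """Pointwise log-likelihood of every non-catch choice record of a dataset.

    ``params`` is a DataFrame indexed by subject (columns k_e, alpha, k_i,
    k_w, beta; a ``k_iw`` column is accepted for the tied model, otherwise
    k_i is used as the tied coefficient) or a mapping from subject id to
    :class:`SubjectParameters`.  Returns a Series indexed by
    (task, subject, trial); its sum is the joint log-likelihood.
    """

    engine = LikelihoodEngine.from_dataset(spec, data)
    frame = _params_frame(params, engine.subjects).loc[engine.subjects]
    arrays = {c: frame[c].to_numpy(float) for c in frame.columns}
    if spec.tie and "k_iw" not in arrays:
        arrays["k_iw"] = arrays["k_i"]
    lp = engine.pointwise(arrays)
    idx = engine.record_index
    return pd.Series(lp, index=pd.MultiIndex.from_frame(idx), name="log_lik")
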