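"""Synthetic cohorts: simulated subjects and their choices on both tasks.

Subjects are drawn from group-level Gaussians on an unconstrained (raw) scale.
Three parameters are mapped into a priori plausible boxes through the standard
normal CDF — k_e = 100 * Phi(raw), alpha = 50 * Phi(raw), beta = 20 * Phi(raw)
— while k_i and k_w stay on the raw (unbounded) scale.  Choices are then
sampled from the softmax over the model's option values, trial by trial.

Default group parameters emulate the study cohort: 26 subjects whose
constrained group means sit near k_e = 7.75, alpha = 1.22, k_i = 3.01,
k_w = 0.60, with k_i and k_w positively correlated (rho = 0.6) and a group
mean inverse temperature of about 2 on the cents value scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr
from scipy.stats import norm

from . import task_design
from .value_models import PARAM_BOUNDS, LikelihoodEngine, ModelSpec

__all__ = [
    "PARAM_NAMES",
    "GroupParameters",
    "ChoiceDataset",
    "constrain",
    "unconstrain",
    "sample_subjects",
    "default_designs",
    "simulate_dataset",
    "summarise_choices",
]

PARAM_NAMES = ("k_e", "alpha", "k_i", "k_w", "beta")


def constrain(name: str, raw):
    """Map a raw-scale value to the model scale (identity for k_i / k_w)."""
    bound = PARAM_BOUNDS.get(name)
    if bound is None:
        return np.asarray(raw, float) + 0.0
    return bound * ndtr(raw)


def unconstrain(name: str, value):
    """Inverse of :func:`constrain`."""
    bound = PARAM_BOUNDS.get(name)
    if bound is None:
        return np.asarray(value, float) + 0.0
    return norm.ppf(np.asarray(value, float) / bound)


@dataclass(frozen=True)
class GroupParameters:
    """Group-level Gaussian locations and scales on the raw scale.

    ``rho_ki_kw`` is the generative correlation between the raw k_i and k_w
    of a subject (the study found r = .60 across participants).
    """

    loc: dict = field(default_factory=dict)
    scale: dict = field(default_factory=dict)
    rho_ki_kw: float = 0.6

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            if name not in self.loc or name not in self.scale:
                raise ValueError(f"missing group location/scale for {name}")
            if self.scale[name] <= 0:
                raise ValueError(f"group scale for {name} must be positive")
        if not -1.0 < self.rho_ki_kw < 1.0:
            raise ValueError("rho_ki_kw must lie in (-1, 1)")

    @classmethod
    def defaults(cls) -> "GroupParameters":
        """Group distribution targeting the study's fitted means.

        Raw locations of the bounded parameters are Phi^-1(mean / bound);
        raw scales are fixed calibration choices producing heterogeneous but
        plausible cohorts (see the methods note).
        """
        loc = {
            "k_e": float(unconstrain("k_e", 7.75)),
            "alpha": float(unconstrain("alpha", 1.22)),
            "beta": float(unconstrain("beta", 2.0)),
            "k_i": 3.01,
            "k_w": 0.60,
        }
        scale = {"k_e": 0.2, "alpha": 0.5, "beta": 0.35, "k_i": 1.0, "k_w": 0.5}
        return cls(loc=loc, scale=scale)

    def with_loc(self, **kwargs) -> "GroupParameters":
        return replace(self, loc={**self.loc, **kwargs})


@dataclass
class ChoiceDataset:
    """Joined two-task design and choice records for a cohort.

    ``effort_choices`` has one row per (subject, trial) with a boolean
    ``chose_offer``; ``info_choices`` one row per non-catch (subject, trial)
    with ``chose_info``.  For synthetic cohorts ``true_parameters`` stores the
    generative per-subject parameters on both raw and constrained scales.
    """

    effort_design: pd.DataFrame
    info_design: pd.DataFrame
    effort_choices: pd.DataFrame
    info_choices: pd.DataFrame
    subjects: list
    spec: ModelSpec | None = None
    seed: int | None = None
    true_parameters: pd.DataFrame | None = None

    def validate(self) -> None:
        """Schema and referential-integrity checks; raises on violation."""
        for col in ("trial", "offer_reward", "offer_mvc", "base_reward", "base_mvc"):
            if col not in self.effort_design.columns:
                raise ValueError(f"effort design lacks column {col!r}")
        for col in ("trial", "pr_win", "hidden", "info_mvc", "noninfo_mvc", "is_catch"):
            if col not in self.info_design.columns:
                raise ValueError(f"info design lacks column {col!r}")
        non_catch = self.info_design.loc[~self.info_design["is_catch"].astype(bool)]
        for choices, design, n_expected in (
            (self.effort_choices, self.effort_design, len(self.effort_design)),
            (self.info_choices, non_catch, len(non_catch)),
        ):
            known = set(design["trial"].astype(int))
            seen = set(choices["trial"].astype(int))
            if seen - known:
                raise ValueError("choice records reference unknown trials")
            counts = choices.groupby("subject")["trial"].count()
            if not (counts == n_expected).all():
                raise ValueError("expected exactly one choice per non-catch trial")
        if set(self.effort_choices["subject"]) != set(self.subjects):
            raise ValueError("effort choices do not cover the subject list")

    # -- text round trip -------------------------------------------------

    def to_dir(self, path: str | Path) -> None:
        """Write design/choice TSVs plus a JSON sidecar (seed, spec, truth)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.effort_design.to_csv(path / "effort_design.tsv", sep="\t", index=False)
        self.info_design.to_csv(path / "info_design.tsv", sep="\t", index=False)
        self.effort_choices.to_csv(path / "effort_choices.tsv", sep="\t", index=False)
        self.info_choices.to_csv(path / "info_choices.tsv", sep="\t", index=False)
        meta = {
            "subjects": [int(s) for s in self.subjects],
            "seed": self.seed,
            "spec": self.spec.to_json() if self.spec else None,
            "true_parameters": (
                self.true_parameters.to_dict(orient="records")
                if self.true_parameters is not None
                else None
            ),
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_dir(cls, path: str | Path) -> "ChoiceDataset":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        truth = meta.get("true_parameters")
        data = cls(
            effort_design=pd.read_csv(path / "effort_design.tsv", sep="\t"),
            info_design=pd.read_csv(path / "info_design.tsv", sep="\t"),
            effort_choices=pd.read_csv(path / "effort_choices.tsv", sep="\t"),
            info_choices=pd.read_csv(path / "info_choices.tsv", sep="\t"),
            subjects=meta["subjects"],
            spec=ModelSpec.from_json(meta["spec"]) if meta.get("spec") else None,
            seed=meta.get("seed"),
            true_parameters=pd.DataFrame(truth) if truth else None,
        )
        data.validate()
        return data


def sample_subjects(
    group: GroupParameters, n: int, seed: int | None = None
) -> pd.DataFrame:
    """Draw ``n`` subjects from the group distribution.

    Returns a frame with one row per subject: ``raw_<name>`` columns on the
    sampling scale and constrained-scale columns for the model.  k_i and k_w
    are drawn jointly with correlation ``group.rho_ki_kw``.
    """

    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    raw = {}
    for name in ("k_e", "alpha", "beta"):
        raw[name] = rng.normal(group.loc[name], group.scale[name], size=n)
    rho = group.rho_ki_kw
    cov = np.array(
        [
            [group.scale["k_i"] ** 2, rho * group.scale["k_i"] * group.scale["k_w"]],
            [rho * group.scale["k_i"] * group.scale["k_w"], group.scale["k_w"] ** 2],
        ]
    )
    kikw = rng.multivariate_normal([group.loc["k_i"], group.loc["k_w"]], cov, size=n)
    raw["k_i"], raw["k_w"] = kikw[:, 0], kikw[:, 1]

    out = {"subject": np.arange(n)}
    for name in PARAM_NAMES:
        out[f"raw_{name}"] = raw[name]
        out[name] = constrain(name, raw[name])
    return pd.DataFrame(out)


def default_designs(seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The study's design: 120 effort trials and 3 x 32 information trials."""
    effort = task_design.effort_trials_frame(task_design.generate_effort_task(seed=seed))
    info = task_design.info_trials_frame(
        task_design.generate_info_task(seed=None if seed is None else seed + 1)
    )
    return effort, info


def simulate_dataset(
    spec: ModelSpec,
    subjects: pd.DataFrame,
    effort_design: pd.DataFrame | None = None,
    info_design: pd.DataFrame | None = None,
    seed: int | None = None,
) -> ChoiceDataset:
    """Sample one choice per subject per non-catch trial from the softmax.

    ``subjects`` is the frame produced by :func:`sample_subjects` (it must
    carry every parameter the spec needs).  Generative parameters are stored
    on the dataset for recovery scoring.
    """

    if len(subjects) == 0:
        raise ValueError("subjects must be non-empty")
    missing = [
        p
        for p in spec.free_parameters
        if p != "k_iw" and p not in subjects.columns
    ]
    if missing:
        raise ValueError(f"subjects frame lacks parameters required by spec: {missing}")

    if effort_design is None or info_design is None:
        eff_d, inf_d = default_designs(seed=None if seed is None else seed + 1_000_003)
        effort_design = effort_design if effort_design is not None else eff_d
        info_design = info_design if info_design is not None else inf_d

    ids = list(subjects["subject"])
    engine = LikelihoodEngine(spec, effort_design, info_design, ids)
    params = {
        name: subjects[name].to_numpy(float)
        for name in ("k_e", "alpha", "k_i", "k_w", "beta")
        if name in subjects.columns
    }
    if spec.tie:
        params["k_iw"] = subjects["k_i"].to_numpy(float)

    rng = np.random.default_rng(seed)
    beta = params["beta"][:, None]
    p_offer = expit(beta * engine.dv_effort(params["k_e"]))
    p_info = expit(beta * engine.dv_info(params))
    chose_offer = rng.random(p_offer.shape) < p_offer
    chose_info = rng.random(p_info.shape) < p_info

    effort_choices = pd.DataFrame(
        {
            "subject": np.repeat(ids, engine.n_effort),
            "trial": np.tile(engine.effort_trials, len(ids)),
            "chose_offer": chose_offer.ravel().astype(int),
        }
    )
    info_choices = pd.DataFrame(
        {
            "subject": np.repeat(ids, engine.n_info),
            "trial": np.tile(engine.info_trials, len(ids)),
            "chose_info": chose_info.ravel().astype(int),
        }
    )
    data = ChoiceDataset(
        effort_design=effort_design,
        info_design=info_design,
        effort_choices=effort_choices,
        info_choices=info_choices,
        subjects=ids,
        spec=spec,
        seed=seed,
        true_parameters=subjects.copy(),
    )
    data.validate()
    return data


def _condition_summary(
    merged: pd.DataFrame, by: str, value: str
) -> pd.DataFrame:
    per_subject = merged.groupby(["subject", by])[value].mean().reset_index()
    grp = per_subject.groupby(by)[value]
    n = grp.count()
    out = pd.DataFrame(
        {"mean": grp.mean(), "sem": grp.std(ddof=1) / np.sqrt(n), "n_subjects": n}
    )
    return out.reset_index()


def summarise_choices(data: ChoiceDataset) -> dict[str, pd.DataFrame]:
    """Condition-level choice proportions with subject-mean SEMs.

    Returns Pr(HR) by effort level and by reward for the effort task, and
    Pr(Info) by effort level and by Pr(win) for the information task
    (non-catch trials only), mirroring the standard behavioural summaries.
    """

    if len(data.effort_choices) == 0 or len(data.info_choices) == 0:
        raise ValueError("dataset has no choices to summarise")
    eff = data.effort_choices.merge(data.effort_design, on="trial")
    non_catch = data.info_design.loc[~data.info_design["is_catch"].astype(bool)]
    inf = data.info_choices.merge(non_catch, on="trial")
    inf["pr_win_bin"] = inf["pr_win"].round(4)
    return {
        "pr_hr_by_effort": _condition_summary(eff, "offer_level", "chose_offer"),
        "pr_hr_by_reward": _condition_summary(eff, "offer_reward", "chose_offer"),
        "pr_info_by_effort": _condition_summary(inf, "info_level", "chose_info"),
        "pr_info_by_prwin": _condition_summary(inf, "pr_win_bin", "chose_info"),
    }
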