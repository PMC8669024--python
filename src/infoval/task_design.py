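"""Designs for the two choice tasks: effort discounting and effortful information seeking.

The information-seeking task is a nine-card lottery: a subset of cards is revealed
at the start of a trial, the lottery is won if the majority (>= 5) of the nine
cards are of the winning colour, and the subject may invest physical effort to
reveal the hidden cards early (non-instrumental information).  The effort
discounting task trades a fixed 1-cent / minimal-effort baseline against a
larger reward at equal or higher effort.  Effort is expressed as a fraction of
the subject's maximum voluntary contraction (MVC), in six levels from 13% to
78% in 13% steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CardConfiguration",
    "EffortLevel",
    "EffortDiscountTrial",
    "InfoSeekTrial",
    "N_CARDS",
    "MAJORITY",
    "MVC_STEP",
    "win_probability",
    "all_valid_configurations",
    "build_default_configurations",
    "generate_effort_task",
    "generate_info_task",
    "effort_trials_frame",
    "info_trials_frame",
    "write_design",
]

N_CARDS = 9
MAJORITY = 5  # cards of the winning colour needed to win
MVC_STEP = 0.13
OFFER_REWARDS = (2, 4, 6, 8, 10)
N_EFFORT_LEVELS = 6


@dataclass(frozen=True)
class CardConfiguration:
    """A partially revealed nine-card lottery state.

    ``wins_shown`` / ``losses_shown`` count revealed cards of the winning and
    losing colour.  At least one card must remain hidden, otherwise there is
    no information left to purchase.
    """

    wins_shown: int
    losses_shown: int

    def __post_init__(self) -> None:
        if self.wins_shown < 0 or self.losses_shown < 0:
            raise ValueError("card counts must be non-negative")
        if self.wins_shown + self.losses_shown > N_CARDS - 1:
            raise ValueError("at most 8 of the 9 cards may be revealed")

    @property
    def hidden(self) -> int:
        return N_CARDS - self.wins_shown - self.losses_shown

    @property
    def pr_win(self) -> float:
        return win_probability(self)

    @property
    def valence(self) -> float:
        """W = Pr(win) - 0.5: positive for likely wins, negative for likely losses."""
        return self.pr_win - 0.5

    @property
    def hidden_fraction(self) -> float:
        """Proportion of the nine cards still hidden (card-count heuristic)."""
        return self.hidden / N_CARDS

    def mirror(self) -> "CardConfiguration":
        return CardConfiguration(self.losses_shown, self.wins_shown)


@dataclass(frozen=True)
class EffortLevel:
    """One of six grip-force levels, expressed as a fraction of MVC."""

    level: int

    def __post_init__(self) -> None:
        if not 1 <= self.level <= N_EFFORT_LEVELS:
            raise ValueError(f"effort level must be in 1..{N_EFFORT_LEVELS}")

    @property
    def mvc_fraction(self) -> float:
        return MVC_STEP * self.level


@dataclass(frozen=True)
class EffortDiscountTrial:
    """Fixed low-reward/low-effort baseline vs a more lucrative offer."""

    offer_reward: int
    offer_effort: EffortLevel
    baseline_reward: int = 1
    baseline_effort: EffortLevel = field(default_factory=lambda: EffortLevel(1))

    def __post_init__(self) -> None:
        if self.baseline_reward != 1 or self.baseline_effort.level != 1:
            raise ValueError("baseline is fixed at 1 cent / level 1")
        if self.offer_reward not in OFFER_REWARDS:
            raise ValueError(f"offer reward must be one of {OFFER_REWARDS}")


@dataclass(frozen=True)
class InfoSeekTrial:
    """Informative option at `info_effort` vs non-informative option at level 1."""

    configuration: CardConfiguration
    info_effort: EffortLevel
    run_index: int = 0
    is_catch: bool = False
    win_reward: int = 10
    noninfo_effort: EffortLevel = field(default_factory=lambda: EffortLevel(1))

    def __post_init__(self) -> None:
        if self.noninfo_effort.level != 1:
            raise ValueError("non-informative option is fixed at effort level 1")
        if self.win_reward != 10:
            raise ValueError("lottery stake is fixed at 10 cents")


def win_probability(config: CardConfiguration) -> float:
    """Binomial probability that the winning colour ends up in the majority.

    With ``n`` hidden cards, each independently the winning colour with
    probability 0.5, the lottery is won iff at least
    ``n_req = max(0, 5 - wins_shown)`` of them are winners:

        Pr(win) = 1 - sum_{k=0}^{n_req - 1} C(n, k) * 0.5**n
    """

    n = config.hidden
    n_req = max(0, MAJORITY - config.wins_shown)
    if n_req == 0:
        return 1.0
    if n_req > n:
        return 0.0
    losing = sum(comb(n, k) for k in range(n_req))
    return 1.0 - losing / 2.0**n


def all_valid_configurations() -> list[CardConfiguration]:
    """Every (wins_shown, losses_shown) pair with at least one hidden card."""
    return [
        CardConfiguration(w, l)
        for w in range(N_CARDS)
        for l in range(N_CARDS - w)
        if w + l <= N_CARDS - 1
    ]


def build_default_configurations() -> list[CardConfiguration]:
    """The default 16-configuration lottery set.

    Searches the valid configurations for a set with 7 positively valenced,
    7 negatively valenced (the mirrors of the positive ones), and 2 neutral
    members, such that sorted non-neutral Pr(win) values are spaced by
    ~0.05-0.07 apart from the +-0.14 jump on either side of 0.5, and no two
    non-neutral members share a Pr(win).  Ties between configurations with
    equal Pr(win) are broken in favour of the fewest revealed cards.
    """

    candidates = {}
    for cfg in all_valid_configurations():
        p = round(cfg.pr_win, 10)
        if p <= 0.5:
            continue
        prev = candidates.get(p)
        if prev is None or cfg.wins_shown + cfg.losses_shown < prev.wins_shown + prev.losses_shown:
            candidates[p] = cfg

    # greedy chain upward from the smallest positive Pr(win): each next value
    # must lie 0.05-0.07 above the previous (the first step up from 0.5 is the
    # task's minimum increment of ~0.14)
    levels = sorted(candidates)
    chain = [levels[0]]
    for p in levels[1:]:
        gap = p - chain[-1]
        if 0.05 <= gap <= 0.07:
            chain.append(p)
    if len(chain) != 7:  # pragma: no cover - structural guarantee of the 9-card task
        raise RuntimeError("configuration search failed to find a 7-member positive chain")

    positives = [candidates[p] for p in chain]
    negatives = [cfg.mirror() for cfg in positives]
    neutrals_pool = sorted(
        (c for c in all_valid_configurations() if c.pr_win == 0.5),
        key=lambda c: c.wins_shown + c.losses_shown,
    )
    neutrals = neutrals_pool[:2]
    out = sorted(negatives, key=lambda c: c.pr_win) + neutrals + positives
    return out


def generate_effort_task(
    reps: int = 4, seed: int | None = None
) -> list[EffortDiscountTrial]:
    """Fully crossed 6 effort x 5 reward design, each condition ``reps`` times.

    Trial order is a uniform random shuffle under ``seed``.
    """

    if reps < 1:
        raise ValueError("reps must be >= 1")
    trials = [
        EffortDiscountTrial(offer_reward=r, offer_effort=EffortLevel(e))
        for e in range(1, N_EFFORT_LEVELS + 1)
        for r in OFFER_REWARDS
        for _ in range(reps)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


def generate_info_task(
    configs: Sequence[CardConfiguration] | None = None,
    runs: int = 3,
    catch_rate: float = 0.05,
    seed: int | None = None,
) -> list[InfoSeekTrial]:
    """Each configuration crossed once with each effort level, split into runs.

    ``round(catch_rate * total)`` trials (round-half-up) are flagged as catch
    trials; catch trials are engagement probes and are excluded from choice
    likelihoods downstream.
    """

    if configs is None:
        configs = build_default_configurations()
    if not configs:
        raise ValueError("configs must be non-empty")
    if runs < 1:
        raise ValueError("runs must be >= 1")
    total = len(configs) * N_EFFORT_LEVELS
    if total % runs:
        raise ValueError(f"{total} trials cannot be split into {runs} equal runs")
    per_run = total // runs

    cells = [(c, e) for c in configs for e in range(1, N_EFFORT_LEVELS + 1)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(total)
    n_catch = int(np.floor(catch_rate * total + 0.5))
    catch_idx = set(rng.choice(total, size=n_catch, replace=False).tolist())
    return [
        InfoSeekTrial(
            configuration=cells[j][0],
            info_effort=EffortLevel(cells[j][1]),
            run_index=i // per_run,
            is_catch=i in catch_idx,
        )
        for i, j in enumerate(order)
    ]


def effort_trials_frame(trials: Sequence[EffortDiscountTrial]) -> pd.DataFrame:
    """Tabulate an effort-discounting design (one row per trial)."""
    return pd.DataFrame(
        {
            "trial": np.arange(len(trials)),
            "offer_reward": [t.offer_reward for t in trials],
            "offer_level": [t.offer_effort.level for t in trials],
            "offer_mvc": [t.offer_effort.mvc_fraction for t in trials],
            "base_reward": [t.baseline_reward for t in trials],
            "base_mvc": [t.baseline_effort.mvc_fraction for t in trials],
        }
    )


def info_trials_frame(trials: Sequence[InfoSeekTrial]) -> pd.DataFrame:
    """Tabulate an information-seeking design (one row per trial)."""
    return pd.DataFrame(
        {
            "trial": np.arange(len(trials)),
            "run": [t.run_index for t in trials],
            "wins_shown": [t.configuration.wins_shown for t in trials],
            "losses_shown": [t.configuration.losses_shown for t in trials],
            "hidden": [t.configuration.hidden for t in trials],
            "pr_win": [t.configuration.pr_win for t in trials],
            "info_level": [t.info_effort.level for t in trials],
            "info_mvc": [t.info_effort.mvc_fraction for t in trials],
            "noninfo_mvc": [t.noninfo_effort.mvc_fraction for t in trials],
            "win_reward": [t.win_reward for t in trials],
            "is_catch": [t.is_catch for t in trials],
        }
    )


_SCHEMA_DOC = {
    "effort": {
        "trial": "0-based trial index (presentation order)",
        "offer_reward": "reward of the lucrative offer, cents",
        "offer_level": "effort level of the offer, 1-6",
        "offer_mvc": "offer effort as fraction of MVC (0.13 * level)",
        "base_reward": "baseline reward, fixed at 1 cent",
        "base_mvc": "baseline effort fraction, fixed at 0.13",
    },
    "info": {
        "trial": "0-based trial index (presentation order)",
        "run": "0-based scanner run index",
        "wins_shown": "revealed winning-colour cards",
        "losses_shown": "revealed losing-colour cards",
        "hidden": "cards still hidden (9 - wins - losses)",
        "pr_win": "binomial probability that the winning colour is in the majority",
        "info_level": "effort level of the informative option, 1-6",
        "info_mvc": "informative-option effort as fraction of MVC",
        "noninfo_mvc": "non-informative option effort fraction, fixed at 0.13",
        "win_reward": "lottery stake, fixed at 10 cents",
        "is_catch": "engagement probe; excluded from choice modelling",
    },
}


def write_design(frame: pd.DataFrame, path: str | Path, task: str) -> None:
    """Write a design table as TSV alongside a JSON column-schema file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
    schema = {"task": task, "columns": _SCHEMA_DOC[task]}
    path.with_suffix(".schema.json").write_text(json.dumps(schema, indent=2))
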