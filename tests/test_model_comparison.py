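"""Model comparison tables, recovery studies, correlations, and modulators."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

import infoval as iv
from infoval.inference import PosteriorFit, SamplerConfig
from infoval.value_models import ModelSpec

TINY = SamplerConfig(chains=2, warmup=150, draws=150, seed=0)


@pytest.fixture(scope="module")
def two_model_comparison(small_cohort):
    _, data = small_cohort
    specs = [ModelSpec("parabolic", "none", valence=False), iv.winning_model()]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return iv.compare_models(data, specs, TINY)


class TestComparisonTable:
    def test_delta_and_rank_structure(self, two_model_comparison):
        tab = two_model_comparison.table
        assert (tab["delta_waic"] >= 0).all()
        assert tab.loc[tab["rank"] == 0, "delta_waic"].iloc[0] == 0
        assert sorted(tab["rank"]) == list(range(len(tab)))

    def test_single_member_family_mean_is_member(self, two_model_comparison):
        tab = two_model_comparison.table
        fam = two_model_comparison.family_means("info")
        control_waic = tab.loc[tab["info"] == "none", "waic"].iloc[0]
        assert fam["none"] == pytest.approx(control_waic)

    def test_unknown_family_grouping_rejected(self, two_model_comparison):
        with pytest.raises(ValueError):
            two_model_comparison.family_means("colour")

    def test_identical_specs_agree_within_monte_carlo_error(self, small_cohort):
        _, data = small_cohort
        specs = [iv.winning_model(), iv.winning_model()]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            comp = iv.compare_models(data, specs, TINY)
        w = comp.table["waic"]
        se = comp.table["se"].max()
        assert abs(w.iloc[0] - w.iloc[1]) < se


class TestModelRecovery:
    def test_single_candidate_is_always_recovered(self, group_defaults):
        spec = ModelSpec("parabolic", "none", valence=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rec = iv.model_recovery(
                [spec], n_sims=2, n_subjects=4, seed=1, config=TINY
            )
        assert rec.accuracy.loc[spec.label] == 1.0
        assert rec.confusion.sum(axis=1).eq(rec.n_sims).all()

    def test_invalid_n_sims(self):
        with pytest.raises(ValueError):
            iv.model_recovery(n_sims=0)


class TestParameterRecovery:
    def test_constant_truth_reported_undefined(self, group_defaults):
        group = iv.GroupParameters(
            loc=group_defaults.loc,
            scale={**group_defaults.scale, "beta": 1e-12},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rec = iv.parameter_recovery(
                iv.winning_model(),
                n_sims=1,
                n_subjects=4,
                seed=2,
                group=group,
                config=TINY,
            )
        assert math.isnan(rec.param_correlations["beta"])
        assert any("beta" in n for n in rec.notes)
        # the well-dispersed parameters still get a defined correlation
        assert not math.isnan(rec.param_correlations["k_i"])


def _synthetic_fit(raw, param_names, data, spec):
    from infoval.value_models import LikelihoodEngine

    engine = LikelihoodEngine.from_dataset(spec, data)
    C, D, S, d = raw.shape
    return PosteriorFit(
        spec=spec,
        config=SamplerConfig(chains=C, warmup=0, draws=D),
        subjects=list(data.subjects),
        param_names=param_names,
        raw=raw,
        group_loc=np.zeros((C, D, d)),
        group_scale=np.ones((C, D, d)),
        log_lik=np.zeros((C, D, engine.n_records), dtype=np.float32),
        record_index=engine.record_index,
        accept_rate=np.ones((C, S)),
    )


class TestParameterCorrelations:
    def test_holm_adjustment_matches_stepdown_rule(self, small_fit):
        out = iv.parameter_correlations(small_fit)
        defined = out.dropna(subset=["p"]).reset_index()
        # independent re-implementation of Holm's step-down adjustment
        order = np.argsort(defined["p"].to_numpy())
        m = len(defined)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * defined["p"][i])
            adj[i] = min(1.0, running)
        np.testing.assert_allclose(defined["p_holm"].to_numpy(), adj, atol=1e-12)

    def test_constant_parameter_yields_nan(self, small_cohort):
        _, data = small_cohort
        spec = ModelSpec("parabolic", "shannon", valence=False)
        S = len(data.subjects)
        rng = np.random.default_rng(0)
        raw = rng.normal(0, 0.3, size=(1, 20, S, 3))
        raw[..., 2] = 1.7  # k_i constant across subjects and draws
        fit = _synthetic_fit(raw, ("k_e", "beta", "k_i"), data, spec)
        out = iv.parameter_correlations(fit)
        nan_rows = out[(out["param_a"] == "k_i") | (out["param_b"] == "k_i")]
        assert nan_rows["r"].isna().all()
        other = out[(out["param_a"] != "k_i") & (out["param_b"] != "k_i")]
        assert other["r"].notna().all()

    def test_generative_ki_kw_correlation_recovered(self, group_defaults):
        """Cohorts built with correlated k_i / k_w preferences show that
        correlation in the fitted per-subject means."""
        subj = iv.sample_subjects(group_defaults, 16, seed=51)  # rho = 0.6
        data = iv.simulate_dataset(iv.winning_model(), subj, seed=52)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = iv.fit_hierarchical(
                iv.winning_model(),
                data,
                SamplerConfig(chains=2, warmup=300, draws=300, seed=53),
            )
        out = iv.parameter_correlations(fit).set_index(["param_a", "param_b"])
        assert out.loc[("k_i", "k_w"), "r"] > 0

    def test_requires_three_subjects(self, group_defaults):
        subj = iv.sample_subjects(group_defaults, 2, seed=0)
        data = iv.simulate_dataset(iv.winning_model(), subj, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = iv.fit_hierarchical(iv.winning_model(), data, TINY)
        with pytest.raises(ValueError):
            iv.parameter_correlations(fit)


def _two_trial_dataset():
    effort_design = pd.DataFrame(
        {
            "trial": [0],
            "offer_reward": [10],
            "offer_level": [3],
            "offer_mvc": [0.39],
            "base_reward": [1],
            "base_mvc": [0.13],
        }
    )
    info_design = pd.DataFrame(
        {
            "trial": [0, 1],
            "run": [0, 0],
            "wins_shown": [1, 0],
            "losses_shown": [0, 0],
            "hidden": [8, 9],
            "pr_win": [163 / 256, 0.5],
            "info_level": [3, 1],
            "info_mvc": [0.39, 0.13],
            "noninfo_mvc": [0.13, 0.13],
            "win_reward": [10, 10],
            "is_catch": [False, False],
        }
    )
    effort_choices = pd.DataFrame({"subject": [0], "trial": [0], "chose_offer": [1]})
    info_choices = pd.DataFrame(
        {"subject": [0, 0], "trial": [0, 1], "chose_info": [1, 0]}
    )
    return iv.ChoiceDataset(
        effort_design=effort_design,
        info_design=info_design,
        effort_choices=effort_choices,
        info_choices=info_choices,
        subjects=[0],
    )


class TestExportModulators:
    PARAMS = pd.DataFrame(
        {"subject": [0], "k_e": [7.75], "alpha": [2.0], "k_i": [2.0], "k_w": [1.0], "beta": [2.0]}
    )

    def test_hand_worked_trial(self):
        data = _two_trial_dataset()
        mods = iv.export_modulators(self.PARAMS, data, iv.winning_model())
        tab = mods.set_index(["trial", "event", "modulator"])["value"]
        p = 163 / 256
        h = math.log(p**2 + (1 - p) ** 2) / (1 - 2)  # Renyi order 2
        expected = 2.0 * h + 1.0 * (p - 0.5)
        assert tab.loc[(0, "scenario", "info_value")] == pytest.approx(expected)
        assert tab.loc[(0, "reveal", "info_value")] == pytest.approx(expected)
        assert tab.loc[(0, "outcome", "info_value")] == 0.0
        assert tab.loc[(0, "scenario", "effort_cost")] == pytest.approx(7.75 * 0.39**2)

    def test_uncertainty_resolves_at_outcome_when_ignorant(self):
        data = _two_trial_dataset()
        mods = iv.export_modulators(self.PARAMS, data, iv.winning_model())
        tab = mods.set_index(["trial", "event", "modulator"])["value"]
        # trial 1: non-informative chosen, maximal uncertainty, neutral valence
        assert tab.loc[(1, "reveal", "info_value")] == 0.0
        assert tab.loc[(1, "scenario", "info_value")] == 0.0
        assert tab.loc[(1, "outcome", "info_value")] == pytest.approx(2.0 * math.log(2))
        # minimal effort was exerted
        assert tab.loc[(1, "scenario", "effort_cost")] == pytest.approx(7.75 * 0.13**2)

    def test_zero_weights_zero_information_modulators(self):
        data = _two_trial_dataset()
        params = self.PARAMS.assign(k_i=0.0, k_w=0.0)
        mods = iv.export_modulators(params, data, iv.winning_model())
        info = mods[mods["modulator"] == "info_value"]
        assert (info["value"] == 0).all()

    def test_linear_effort_switch(self):
        data = _two_trial_dataset()
        mods = iv.export_modulators(
            self.PARAMS, data, iv.winning_model(), effort_form="linear"
        )
        tab = mods.set_index(["trial", "event", "modulator"])["value"]
        assert tab.loc[(0, "scenario", "effort_cost")] == pytest.approx(7.75 * 0.39)
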