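"""Entropy functions, the 21-model value space, and the choice likelihood."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import infoval as iv
from infoval.task_design import CardConfiguration, EffortLevel, InfoSeekTrial
from infoval.value_models import (
    LikelihoodEngine,
    ModelSpec,
    SubjectParameters,
    option_value,
)


class TestEntropies:
    def test_shannon_known_values(self):
        assert iv.shannon_entropy(0.5) == pytest.approx(math.log(2))
        assert iv.shannon_entropy(0.0) == 0.0
        assert iv.shannon_entropy(1.0) == 0.0
        # 0.25 ln 4 + 0.75 ln(4/3), evaluated independently
        assert iv.shannon_entropy(0.25) == pytest.approx(
            0.25 * math.log(4) + 0.75 * math.log(4 / 3), abs=1e-12
        )

    def test_renyi_known_values(self):
        for alpha in (0.0, 0.5, 2.0, 10.0):
            assert iv.renyi_entropy(0.5, alpha) == pytest.approx(math.log(2))
        assert iv.renyi_entropy(0.25, 2.0) == pytest.approx(-math.log(0.625), abs=1e-12)
        assert iv.renyi_entropy(0.0, 2.0) == 0.0
        assert iv.renyi_entropy(1.0, 0.3) == 0.0

    def test_renyi_shannon_limit(self):
        for p in (0.1, 0.3, 0.7):
            for alpha in (1 - 1e-6, 1 + 1e-6):
                assert iv.renyi_entropy(p, alpha) == pytest.approx(
                    iv.shannon_entropy(p), abs=1e-4
                )

    @given(
        st.floats(min_value=0.01, max_value=0.99),
        st.floats(min_value=0.0, max_value=30.0),
        st.floats(min_value=0.0, max_value=30.0),
    )
    @settings(deadline=None, max_examples=200)
    def test_renyi_monotone_in_alpha_and_symmetric(self, p, a1, a2):
        lo, hi = sorted([a1, a2])
        assert iv.renyi_entropy(p, lo) >= iv.renyi_entropy(p, hi) - 1e-9
        assert iv.renyi_entropy(p, a1) == pytest.approx(
            iv.renyi_entropy(1 - p, a1), abs=1e-9
        )
        assert iv.renyi_entropy(p, a1) <= math.log(2) + 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            iv.shannon_entropy(1.2)
        with pytest.raises(ValueError):
            iv.renyi_entropy(0.5, -0.1)
        with pytest.raises(ValueError):
            iv.renyi_entropy(-0.01, 1.0)


class TestModelSpace:
    def test_exactly_21_models(self):
        space = iv.model_space()
        assert len(space) == 21
        assert len({s.label for s in space}) == 21
        per_discount = {d: 0 for d in ("linear", "parabolic", "hyperbolic")}
        for s in space:
            per_discount[s.discount] += 1
        assert all(v == 7 for v in per_discount.values())

    def test_invalid_combinations_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("parabolic", "none", valence=True)
        with pytest.raises(ValueError):
            ModelSpec("parabolic", "renyi", valence=False, tie=True)
        with pytest.raises(ValueError):
            ModelSpec("cubic", "renyi", valence=True)

    def test_free_parameters(self):
        assert iv.winning_model().free_parameters == ("k_e", "beta", "alpha", "k_i", "k_w")
        assert ModelSpec("linear", "none", valence=False).free_parameters == ("k_e", "beta")
        assert iv.constrained_control().free_parameters == ("k_e", "beta", "alpha", "k_iw")

    def test_json_round_trip(self):
        for spec in iv.model_space() + [iv.constrained_control()]:
            assert ModelSpec.from_json(spec.to_json()) == spec


def _trial(w, l, level=3):
    return InfoSeekTrial(
        configuration=CardConfiguration(w, l), info_effort=EffortLevel(level)
    )


class TestInformationContent:
    def test_noninformative_is_zero(self):
        p = SubjectParameters(k_e=5, beta=2, alpha=1.5, k_i=2, k_w=1)
        for spec in (iv.winning_model(), ModelSpec("linear", "shannon", valence=False)):
            assert iv.information_content(_trial(1, 0), "noninformative", spec, p) == 0.0

    def test_resolved_lottery_has_no_content(self):
        p = SubjectParameters(k_e=5, beta=2)
        spec = ModelSpec("parabolic", "shannon", valence=False)
        assert iv.information_content(_trial(5, 0), "informative", spec, p) == 0.0

    def test_card_count_full_deck(self):
        p = SubjectParameters(k_e=5, beta=2)
        spec = ModelSpec("parabolic", "card_count", valence=False)
        assert iv.information_content(_trial(0, 0), "informative", spec, p) == 1.0

    def test_no_information_model_rejects(self):
        p = SubjectParameters(k_e=5, beta=2)
        with pytest.raises(ValueError):
            iv.information_content(
                _trial(1, 0), "informative", ModelSpec("linear", "none", valence=False), p
            )


class TestOptionValue:
    def test_control_parabolic_at_level_six(self):
        # R - k_e E^2 with R = 5, k_e = 7.75, E = 0.78
        spec = ModelSpec("parabolic", "none", valence=False)
        p = SubjectParameters(k_e=7.75, beta=2)
        v = option_value(spec, p, _trial(0, 0, level=6), "informative")
        assert v.total == pytest.approx(5 - 7.75 * 0.78**2, abs=1e-12)

    def test_family3_reduces_to_control_at_zero_weights(self):
        spec3 = iv.winning_model()
        control = ModelSpec("parabolic", "none", valence=False)
        p0 = SubjectParameters(k_e=6.0, beta=2, alpha=1.3, k_i=0.0, k_w=0.0)
        for w, l, level in [(0, 0, 1), (1, 0, 4), (3, 2, 6), (0, 5, 2)]:
            t = _trial(w, l, level)
            for option in ("informative", "noninformative"):
                assert option_value(spec3, p0, t, option).total == pytest.approx(
                    option_value(control, p0, t, option).total
                )

    def test_hyperbolic_without_effort_aversion(self):
        spec = ModelSpec("hyperbolic", "renyi", valence=True)
        p = SubjectParameters(k_e=0.0, beta=2, alpha=2.0, k_i=1.5, k_w=0.8)
        t = _trial(1, 0, level=5)
        v = option_value(spec, p, t, "informative")
        assert v.total == pytest.approx(
            5.0 + 1.5 * iv.renyi_entropy(163 / 256, 2.0) + 0.8 * (163 / 256 - 0.5)
        )

    def test_audit_table_totals_are_consistent(self, small_cohort):
        _, data = small_cohort
        p = SubjectParameters(k_e=6.0, beta=2.0, alpha=1.3, k_i=2.0, k_w=0.7)
        tab = iv.option_value_table(iv.winning_model(), p, data.info_design.head(5))
        assert len(tab) == 10
        np.testing.assert_allclose(
            tab["total"],
            tab["reward_term"] - tab["effort_cost"] + tab["info_term"] + tab["valence_term"],
        )
        non_info = tab[tab["option"] == "noninformative"]
        assert (non_info["info_term"] == 0).all()

    def test_valence_applies_to_informative_only(self):
        p = SubjectParameters(k_e=5.0, beta=2, alpha=1.3, k_i=2.0, k_w=1.0)
        t = _trial(3, 1, level=2)
        v_non = option_value(iv.winning_model(), p, t, "noninformative")
        assert v_non.info_term == 0.0 and v_non.valence_term == 0.0


class TestChoiceProbability:
    def test_symmetry_and_normalisation(self):
        assert iv.choice_probability(2.0, 1.0, 1.0) == 0.5
        assert iv.choice_probability(0.0, 10.0, -3.0) == 0.5
        for a, b in [(0.3, 1.2), (-4, 2), (100, -100)]:
            total = iv.choice_probability(1.5, a, b) + iv.choice_probability(1.5, b, a)
            assert total == pytest.approx(1.0)

    def test_logistic_identity(self):
        # beta (v_c - v_o) = log 3  ->  Pr = 3/4
        assert iv.choice_probability(1.0, math.log(3), 0.0) == pytest.approx(0.75)

    def test_overflow_free(self):
        assert iv.choice_probability(20.0, 1e4, -1e4) == 1.0
        assert iv.choice_probability(20.0, -1e4, 1e4) == 0.0

    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(0.01, 5))
    @settings(deadline=None, max_examples=100)
    def test_increasing_in_own_value(self, v, dv, beta):
        assert iv.choice_probability(beta, v + abs(dv) + 1e-3, 0.0) > (
            iv.choice_probability(beta, v, 0.0)
        )

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            iv.choice_probability(1.0, np.nan, 0.0)
        with pytest.raises(ValueError):
            iv.choice_probability(-1.0, 0.0, 0.0)


def _params_frame(subjects, **overrides):
    base = {"k_e": 6.0, "alpha": 1.3, "k_i": 2.5, "k_w": 0.7, "beta": 2.0}
    base.update(overrides)
    return pd.DataFrame({"subject": subjects, **{k: [v] * len(subjects) for k, v in base.items()}})


class TestDatasetLoglik:
    def test_beta_zero_gives_log_half_per_record(self, small_cohort):
        _, data = small_cohort
        params = _params_frame(data.subjects, beta=0.0)
        lp = iv.dataset_loglik(iv.winning_model(), params, data)
        n = len(lp)
        assert lp.sum() == pytest.approx(n * math.log(0.5))

    def test_matches_per_trial_recomputation(self, small_cohort):
        """Spreadsheet-style oracle on a handful of records via option_value."""
        _, data = small_cohort
        params = _params_frame(data.subjects)
        spec = iv.winning_model()
        lp = iv.dataset_loglik(spec, params, data)
        p = SubjectParameters(k_e=6.0, beta=2.0, alpha=1.3, k_i=2.5, k_w=0.7)
        non_catch = data.info_design.loc[~data.info_design["is_catch"].astype(bool)]
        subj = data.subjects[0]
        choices = data.info_choices.query("subject == @subj").set_index("trial")
        for _, row in non_catch.head(4).iterrows():
            t = InfoSeekTrial(
                configuration=CardConfiguration(
                    int(row.wins_shown), int(row.losses_shown)
                ),
                info_effort=EffortLevel(int(row.info_level)),
            )
            v_i = option_value(spec, p, t, "informative").total
            v_n = option_value(spec, p, t, "noninformative").total
            chose_info = bool(choices.loc[int(row.trial), "chose_info"])
            expected = math.log(
                iv.choice_probability(2.0, v_i, v_n)
                if chose_info
                else iv.choice_probability(2.0, v_n, v_i)
            )
            # info-task rows are indexed by position within the non-catch table
            pos = int(np.where(non_catch["trial"].to_numpy() == row.trial)[0][0])
            assert lp.loc[("info", subj, pos)] == pytest.approx(expected, abs=1e-9)

    def test_nested_model_equalities(self, small_cohort):
        _, data = small_cohort
        spec3 = iv.winning_model()
        spec2 = ModelSpec("parabolic", "renyi", valence=False)
        control = ModelSpec("parabolic", "none", valence=False)
        tied = iv.constrained_control()
        base = _params_frame(data.subjects)
        # family 3 at k_w = 0 == family 2
        lp3 = iv.dataset_loglik(spec3, _params_frame(data.subjects, k_w=0.0), data)
        lp2 = iv.dataset_loglik(spec2, base, data)
        np.testing.assert_allclose(lp3.to_numpy(), lp2.to_numpy(), atol=1e-12)
        # family 2 at k_i = 0 == control
        lp2z = iv.dataset_loglik(spec2, _params_frame(data.subjects, k_i=0.0), data)
        lpc = iv.dataset_loglik(control, base, data)
        np.testing.assert_allclose(lp2z.to_numpy(), lpc.to_numpy(), atol=1e-12)
        # tied at coefficient c == untied at k_i = k_w = c
        lpt = iv.dataset_loglik(tied, _params_frame(data.subjects, k_i=0.9), data)
        lpu = iv.dataset_loglik(
            spec3, _params_frame(data.subjects, k_i=0.9, k_w=0.9), data
        )
        np.testing.assert_allclose(lpt.to_numpy(), lpu.to_numpy(), atol=1e-12)

    def test_info_effort_discourages_informative_choice(self):
        """Softmax preference for information falls with its effort cost."""
        p = SubjectParameters(k_e=7.75, beta=2.0, alpha=1.22, k_i=3.0, k_w=0.6)
        spec = iv.winning_model()
        probs = []
        for level in range(1, 7):
            t = _trial(0, 0, level)
            v_i = option_value(spec, p, t, "informative").total
            v_n = option_value(spec, p, t, "noninformative").total
            probs.append(iv.choice_probability(p.beta, v_i, v_n))
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_orphan_choice_records_rejected(self, small_cohort):
        _, data = small_cohort
        bad = data.info_choices.copy()
        bad.loc[bad.index[0], "trial"] = 9999
        broken = iv.ChoiceDataset(
            effort_design=data.effort_design,
            info_design=data.info_design,
            effort_choices=data.effort_choices,
            info_choices=bad,
            subjects=data.subjects,
        )
        with pytest.raises(ValueError):
            iv.dataset_loglik(iv.winning_model(), _params_frame(data.subjects), broken)


class TestEngineFastPath:
    def test_numba_kernel_matches_numpy_reference(self, small_cohort):
        _, data = small_cohort
        rng = np.random.default_rng(0)
        for spec in iv.model_space() + [iv.constrained_control()]:
            eng = LikelihoodEngine.from_dataset(spec, data)
            params = {}
            for name in spec.free_parameters:
                if name in ("k_e", "alpha", "beta"):
                    from infoval.synthetic_data import constrain

                    params[name] = constrain(name, rng.normal(0, 1, len(data.subjects)))
                else:
                    params[name] = rng.normal(0, 1, len(data.subjects))
            np.testing.assert_allclose(
                eng.subject_loglik(params), eng.subject_loglik_numpy(params), rtol=1e-9
            )
            np.testing.assert_allclose(
                eng.pointwise(params), eng.pointwise_numpy(params), rtol=1e-9
            )

    def test_engine_info_term_matches_direct_computation(self, small_cohort):
        """dv_info minus the effort-only part equals k_i I + k_w W per trial."""
        _, data = small_cohort
        spec = iv.winning_model()
        eng = LikelihoodEngine.from_dataset(spec, data)
        n = len(data.subjects)
        params = {
            "k_e": np.full(n, 6.0),
            "beta": np.full(n, 2.0),
            "alpha": np.full(n, 1.3),
            "k_i": np.full(n, 2.0),
            "k_w": np.full(n, 0.8),
        }
        zero = dict(params, k_i=np.zeros(n), k_w=np.zeros(n))
        info_part = eng.dv_info(params) - eng.dv_info(zero)
        expected = 2.0 * iv.renyi_entropy(eng.pr_win, 1.3) + 0.8 * (eng.pr_win - 0.5)
        np.testing.assert_allclose(info_part, np.tile(expected, (n, 1)), atol=1e-10)
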