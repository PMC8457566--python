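import numpy as np
import pytest

from wormspan.datasets import STRAINS, occupancy_summaries
from wormspan.healthspan import (MOBILE, NOT_FRAIL, StateOccupancySummary,
                                 TransitionSpec, daily_state_distribution,
                                 extract_transition_times, fraction_change,
                                 motility_logrank, state_mean_durations)
from wormspan.simulate import SimulationConfig, simulate_cohort

class TestTransitionTimes:
    def test_first_exit_by_motility_transition(self, make_cohort):
        cohort = make_cohort([("w1", "WT", 0, "AABB", "dead")]).validate()
        t = extract_transition_times(cohort, "WT", TransitionSpec(MOBILE))
        assert t["duration"].tolist() == [2] and t["event"].tolist() == [True]

    def test_death_while_mobile_is_an_event(self, make_cohort):
        cohort = make_cohort([("w1", "WT", 0, "AA", "dead")]).validate()
        t = extract_transition_times(cohort, "WT", TransitionSpec(MOBILE))
        assert t["duration"].tolist() == [2] and t["event"].tolist() == [True]

    def test_censored_while_mobile_is_censored(self, make_cohort):
        cohort = make_cohort([("w1", "WT", 0, "AAA", "censored", "wall")]).validate()
        t = extract_transition_times(cohort, "WT", TransitionSpec(MOBILE))
        assert t["duration"].tolist() == [3] and t["event"].tolist() == [False]

    def test_exclude_policy_drops_censored_worms(self, make_cohort):
        cohort = make_cohort([("w1", "WT", 0, "AAA", "censored", "wall"),
                              ("w2", "WT", 0, "AB", "dead")]).validate()
        t = extract_transition_times(cohort, "WT", TransitionSpec(MOBILE, "exclude"))
        assert t["worm_id"].tolist() == ["w2"]

    def test_frailty_onset_spec(self, make_cohort):
        cohort = make_cohort([("w1", "WT", 0, "ABBC", "dead")]).validate()
        t = extract_transition_times(cohort, "WT", TransitionSpec(NOT_FRAIL))
        assert t["duration"].tolist() == [3]


class TestOccupancy:
    def test_reference_wildtype_fractions(self):
        s = StateOccupancySummary.from_durations("WT(EV)", 17.3, 1.5, 1.8, 20.6)
        assert (s.frac_mobile, s.frac_impaired, s.frac_frail) == (84.0, 7.3, 8.7)

    def test_fully_mobile_until_death(self, make_cohort):
        cohort = make_cohort([("w1", "WT", 0, "AAAA", "dead"),
                              ("w2", "WT", 0, "AAAAAA", "dead")]).validate()
        s = state_mean_durations(cohort, "WT")
        assert s.mean_mobile == pytest.approx(s.mean_lifespan)
        assert s.mean_impaired == pytest.approx(0.0)
        assert s.mean_frail == pytest.approx(0.0)

    def test_decomposition_identity_exact_without_censoring(self):
        cfg = SimulationConfig(seed=21, n_worms=150, n_replicates=1,
                               censor_daily_prob=0.0, horizon_days=200)
        cohort = simulate_cohort(cfg, [STRAINS["WT(EV)"], STRAINS["odr-3"]])
        for strain in cohort.strains():
            s = state_mean_durations(cohort, strain)
            total = s.mean_mobile + s.mean_impaired + s.mean_frail
            assert total == pytest.approx(s.mean_lifespan, abs=1e-9)
            # and the KM mean here equals the plain mean of death days
            d = cohort.worm_outcomes(strain)["duration"]
            assert s.mean_lifespan == pytest.approx(d.mean())

    def test_recovers_true_sojourn_means_within_2_sem(self):
        cfg = SimulationConfig(seed=22, n_worms=300, n_replicates=1, horizon_days=200)
        cohort, truth = simulate_cohort(cfg, [STRAINS["WT(EV)"]], return_truth=True)
        s = state_mean_durations(cohort, "WT(EV)")
        d = truth["death_day"].to_numpy()
        true_mobile = np.minimum(np.ceil(truth["t_ab"]), d)
        true_not_frail = np.minimum(np.ceil(truth["t_bc"]), d)
        for est, tru in [(s.mean_mobile, true_mobile),
                         (s.mean_mobile + s.mean_impaired, true_not_frail),
                         (s.mean_lifespan, d)]:
            sem = tru.std(ddof=1) / np.sqrt(len(tru))
            assert abs(est - tru.mean()) <= 2 * sem

    def test_ordering_and_fraction_sum_invariants(self, sim_cohort):
        for strain in sim_cohort.strains():
            s = state_mean_durations(sim_cohort, strain)
            not_frail = s.mean_mobile + s.mean_impaired
            assert s.mean_mobile <= not_frail + 1e-12
            assert not_frail <= s.mean_lifespan + 1e-12
            assert 99.8 <= s.frac_mobile + s.frac_impaired + s.frac_frail <= 100.2


class TestFractionChange:
    def test_reference_mobile_fraction_change(self):
        occ = occupancy_summaries()
        assert round(fraction_change(occ["odr-3"], occ["WT(EV)"], "mobile"), 1) == -4.8

    def test_reference_frail_fraction_change(self):
        occ = occupancy_summaries()
        assert round(fraction_change(occ["ife-2"], occ["WT(EV)"], "frail"), 1) == -19.5
        assert round(fraction_change(occ["ife-2"], occ["WT(EV)"], "impaired"), 1) == -9.6

    def test_identical_summaries_change_zero(self):
        occ = occupancy_summaries()
        for state in ("mobile", "impaired", "frail"):
            assert fraction_change(occ["WT(EV)"], occ["WT(EV)"], state) == 0.0


class TestDailyDistribution:
    def test_all_mobile_on_day_zero(self, make_cohort):
        cohort = make_cohort([("w1", "WT", 0, "AA", "dead"),
                              ("w2", "WT", 0, "AB", "dead")]).validate()
        d = daily_state_distribution(cohort, "WT")
        day0 = d[d["day"] == 0].iloc[0]
        assert (day0["frac_A"], day0["frac_B"], day0["frac_C"]) == (1.0, 0.0, 0.0)
        day1 = d[d["day"] == 1].iloc[0]
        assert (day1["frac_A"], day1["frac_B"]) == (0.5, 0.5)

    def test_matches_brute_force_tally(self, sim_cohort):
        strain = "odr-3"
        d = daily_state_distribution(sim_cohort, strain)
        df = sim_cohort.strain_data(strain)
        alive = df[df["status"] == "alive"]
        for _, row in d.sample(10, random_state=0).iterrows():
            day_rows = alive[alive["day"] == row["day"]]
            assert row["n_alive"] == len(day_rows)
            assert row["frac_B"] == pytest.approx((day_rows["motility"] == "B").mean())
        assert np.allclose(d[["frac_A", "frac_B", "frac_C"]].sum(axis=1), 1.0)

    def test_days_with_no_alive_worms_are_omitted(self, make_cohort):
        cohort = make_cohort([("w1", "WT", 0, "AA", "dead")]).validate()
        d = daily_state_distribution(cohort, "WT")
        assert d["day"].tolist() == [0, 1]


class TestMotilityLogrank:
    def test_strain_against_itself_is_null(self, make_cohort):
        cohort = make_cohort([("w1", "WT", 0, "AAB", "dead"),
                              ("w2", "WT", 0, "AB", "dead")]).validate()
        chi2, p = motility_logrank(cohort, "WT", "WT")
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_detects_simulated_healthspan_extension(self):
        # slower A->B hazard for the intervention strain
        cfg = SimulationConfig(seed=31, n_worms=250, n_replicates=1,
                               motility_effects={"odr-3": -1.4, "ife-2": -1.5,
                                                 "cku-70": 0.2},
                               censor_daily_prob=0.0)
        cohort = simulate_cohort(cfg, [STRAINS["WT(EV)"], STRAINS["ife-2"]])
        _, p = motility_logrank(cohort, "ife-2", "WT(EV)")
        assert p < 1e-6
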