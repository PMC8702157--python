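"""Propensity matching, incremental cost-effectiveness, bootstrap and reporting."""

import math

import numpy as np
import pytest

from rrms_cea import (
    CohortTable,
    PatientRecord,
    bootstrap_cea,
    delta_cost_effect,
    estimate_propensity,
    icer,
    match_nearest,
    quadrant_report,
)
from rrms_cea.cohort import CohortError
from rrms_cea.psm import CEAResult, CEReplicate, MatchingError, PropensityMatch
from rrms_cea.synth import SimulationParams, simulate_cohort


def _rec(pid, cls, age=30, sex="female", band="1-2yr", composite=0, cost=100.0):
    agent = {"ORAL": "fingolimod", "IFN": "rebif", "MAB": "rituximab"}[cls]
    return PatientRecord(
        patient_id=pid,
        sex=sex,
        age_years=age,
        treatment_class=cls,
        agent=agent,
        duration_band=band,
        relapse=composite,
        progression=0,
        mri_lesion=0,
        annual_cost_usd=cost,
    )


def _two_arm_identical_covariates(n_treat=3, n_comp=2, treat="MAB", comp="ORAL"):
    recs = [_rec(f"T{i}", treat) for i in range(n_treat)]
    recs += [_rec(f"C{i}", comp) for i in range(n_comp)]
    return CohortTable(recs)


class TestEstimatePropensity:
    def test_identical_covariates_give_treated_fraction(self):
        cohort = _two_arm_identical_covariates(3, 2)
        scores = estimate_propensity(cohort, "MAB", "ORAL")
        assert all(s == pytest.approx(0.6, abs=1e-6) for s in scores.values())

    def test_confounded_assignment_scores_increase_with_age(self):
        # older patients preferentially on MAB: fitted scores must rise with age
        rng = np.random.default_rng(5)
        recs = []
        for i in range(60):
            age = int(rng.integers(18, 60))
            p_mab = 1 / (1 + math.exp(-(age - 38) / 6))
            cls = "MAB" if rng.random() < p_mab else "ORAL"
            recs.append(_rec(f"P{i}", cls, age=age))
        cohort = CohortTable(recs)
        scores = estimate_propensity(cohort, "MAB", "ORAL")
        ages = {r.patient_id: r.age_years for r in recs}
        pairs = sorted(scores, key=lambda pid: ages[pid])
        assert scores[pairs[-1]] > scores[pairs[0]]

    def test_missing_arm_errors(self):
        cohort = _two_arm_identical_covariates(3, 2, treat="MAB", comp="ORAL")
        with pytest.raises(CohortError):
            estimate_propensity(cohort, "MAB", "IFN")

    def test_same_class_twice_rejected(self):
        cohort = _two_arm_identical_covariates()
        with pytest.raises(CohortError):
            estimate_propensity(cohort, "MAB", "MAB")


def _sigmoid(x):
    return 1 / (1 + math.exp(-x))


class TestMatchNearest:
    def test_identical_scores_pair_by_id(self):
        scores = {k: 0.5 for k in ("T1", "T2", "T3", "C1", "C2", "C3")}
        match = match_nearest(scores, ["T1", "T2", "T3"], ["C1", "C2", "C3"])
        assert match.pairs == [("T1", "C1"), ("T2", "C2"), ("T3", "C3")]
        assert match.n_unmatched == 0

    def test_hand_example_matches_greedy_rule(self):
        # treated logits 0.1, 0.2, 0.9; comparator logits 0.15, 0.85, 2.0
        scores = {
            "T1": _sigmoid(0.1), "T2": _sigmoid(0.2), "T3": _sigmoid(0.9),
            "C1": _sigmoid(0.15), "C2": _sigmoid(0.85), "C3": _sigmoid(2.0),
        }
        match = match_nearest(
            scores, ["T1", "T2", "T3"], ["C1", "C2", "C3"], caliper_sd=None
        )
        # descending treated score: T3->C2 (|.9-.85|), T2->C1 (|.2-.15|), T1->C3
        assert set(match.pairs) == {("T3", "C2"), ("T2", "C1"), ("T1", "C3")}

    def test_zero_caliper_without_ties_errors(self):
        scores = {"T1": 0.3, "T2": 0.4, "C1": 0.31, "C2": 0.45}
        with pytest.raises(MatchingError, match="zero pairs"):
            match_nearest(scores, ["T1", "T2"], ["C1", "C2"], caliper_sd=0.0)

    def test_caliper_excludes_distant_comparator(self):
        scores = {"T1": _sigmoid(0.0), "C1": _sigmoid(0.05), "T2": _sigmoid(3.0), "C2": _sigmoid(-3.0)}
        match = match_nearest(scores, ["T1", "T2"], ["C1", "C2"], caliper_sd=0.2)
        assert match.pairs == [("T1", "C1")]
        assert match.n_unmatched == 2

    def test_no_pair_reuses_a_patient(self):
        scores = {"T1": 0.5, "T2": 0.5, "C1": 0.5}
        match = match_nearest(scores, ["T1", "T2"], ["C1"], caliper_sd=None)
        assert len(match.pairs) == 1
        with pytest.raises(ValueError, match="more than one pair"):
            PropensityMatch("t", "c", scores, [("T1", "C1"), ("T2", "C1")], 1.0, 0)


class TestDeltaAndIcer:
    def test_fixture_mab_vs_oral_fully_matched(self, study_cohort):
        scores = estimate_propensity(study_cohort, "MAB", "ORAL")
        df = study_cohort.to_frame()
        t = list(df[df.treatment_class == "MAB"].patient_id)
        c = list(df[df.treatment_class == "ORAL"].patient_id)
        match = match_nearest(scores, t, c, treat="MAB", comparator="ORAL")
        assert len(match.pairs) == 40  # identical covariate multisets match fully
        rep = delta_cost_effect(study_cohort, match)
        assert rep.delta_cost == pytest.approx(5717.88)
        assert rep.delta_effect == pytest.approx(0.35)
        res = icer(rep)
        assert res.value == pytest.approx(16336.81, abs=0.02)
        assert res.quadrant == "NE"

    def test_fixture_oral_vs_ifn_cost_saving(self, study_cohort):
        scores = estimate_propensity(study_cohort, "ORAL", "IFN")
        df = study_cohort.to_frame()
        t = list(df[df.treatment_class == "ORAL"].patient_id)
        c = list(df[df.treatment_class == "IFN"].patient_id)
        match = match_nearest(scores, t, c, caliper_sd=None, treat="ORAL", comparator="IFN")
        rep = delta_cost_effect(study_cohort, match)
        # arm costs are constant, so the matched increment is exact
        assert rep.delta_cost == pytest.approx(-4336.65)

    def test_arm_against_itself_is_null(self, study_cohort):
        df = study_cohort.to_frame()
        ids = list(df[df.treatment_class == "ORAL"].patient_id)
        match = PropensityMatch(
            "ORAL", "ORAL", {i: 0.5 for i in ids}, [(i, i) for i in ids], math.inf, 0
        )
        rep = delta_cost_effect(study_cohort, match)
        assert rep.delta_cost == 0.0 and rep.delta_effect == 0.0

    @pytest.mark.parametrize(
        "dc, de, value, quadrant",
        [
            (5717.88, 0.35, 16336.8, "NE"),
            (0.0, 0.5, 0.0, "SE"),
            (-4336.65, 0.0811, -53472.87, "SE"),
            (-10.0, -0.2, 50.0, "SW"),
            (10.0, -0.2, -50.0, "NW"),
        ],
    )
    def test_icer_values_and_quadrants(self, dc, de, value, quadrant):
        res = icer(CEReplicate(dc, de))
        assert res.defined
        assert res.value == pytest.approx(value, abs=0.05)
        assert res.quadrant == quadrant

    def test_icer_undefined_at_zero_effect(self):
        res = icer(CEReplicate(100.0, 0.0))
        assert not res.defined and res.value is None
        assert res.quadrant == "NE"  # zero effect counts as "more effective"


def _degenerate_cohort(n=6):
    recs = [_rec(f"T{i}", "ORAL", age=20 + i, cost=100.0) for i in range(n)]
    recs += [_rec(f"C{i}", "IFN", age=20 + i, cost=100.0) for i in range(n)]
    return CohortTable(recs)


class TestBootstrap:
    def test_degenerate_cohort_collapses(self):
        res = bootstrap_cea(_degenerate_cohort(), "ORAL", "IFN", B=50, seed=0)
        assert res.ci_delta_cost == (0.0, 0.0)
        assert res.ci_delta_effect == (0.0, 0.0)
        assert res.quadrant_probs["SE"] == 1.0

    def test_single_replicate_ci(self):
        res = bootstrap_cea(_degenerate_cohort(), "ORAL", "IFN", B=1, seed=4)
        assert res.ci_delta_cost[0] == res.ci_delta_cost[1]
        assert res.B == 1

    def test_same_seed_byte_identical(self, study_cohort):
        a = bootstrap_cea(study_cohort, "MAB", "IFN", B=100, seed=9)
        b = bootstrap_cea(study_cohort, "MAB", "IFN", B=100, seed=9)
        assert a.to_json().encode() == b.to_json().encode()
        assert (a.replicates == b.replicates).all().all()
        c = bootstrap_cea(study_cohort, "MAB", "IFN", B=100, seed=10)
        assert a.to_json() != c.to_json()

    def test_quadrant_probs_sum_to_one(self, study_cohort):
        for seed in (1, 2):
            res = bootstrap_cea(study_cohort, "ORAL", "IFN", B=73, seed=seed)
            assert abs(sum(res.quadrant_probs.values()) - 1.0) <= 1e-12

    def test_full_matching_limit_equals_raw_differences(self):
        # identical covariates across all patients: matched increments must
        # reduce to the raw arm-mean differences
        recs = [_rec(f"T{i}", "MAB", composite=int(i < 2), cost=200.0) for i in range(10)]
        recs += [_rec(f"C{i}", "ORAL", composite=int(i < 5), cost=120.0) for i in range(10)]
        cohort = CohortTable(recs)
        res = bootstrap_cea(cohort, "MAB", "ORAL", B=10, seed=0)
        assert res.delta_cost == pytest.approx(200.0 - 120.0)
        assert res.delta_effect == pytest.approx(0.8 - 0.5)

    def test_pairs_mode_reproducible_and_same_point(self, study_cohort):
        a = bootstrap_cea(study_cohort, "MAB", "ORAL", B=50, seed=3, resample_mode="pairs")
        b = bootstrap_cea(study_cohort, "MAB", "ORAL", B=50, seed=3, resample_mode="pairs")
        full = bootstrap_cea(study_cohort, "MAB", "ORAL", B=50, seed=3)
        assert a.to_json() == b.to_json()
        assert a.delta_cost == full.delta_cost
        assert a.delta_effect == full.delta_effect

    def test_ci_width_shrinks_with_arm_size(self):
        widths = []
        for n in (50, 200, 800):
            params = SimulationParams(
                arm_sizes={"ORAL": n, "IFN": n},
                event_prob={"ORAL": 0.45, "IFN": 0.55},
                cost_sd={"ORAL": 1000.0, "IFN": 1000.0},
                seed=21,
            )
            cohort = simulate_cohort(params)
            res = bootstrap_cea(cohort, "ORAL", "IFN", B=200, seed=21, caliper_sd=None)
            widths.append(res.ci_delta_effect[1] - res.ci_delta_effect[0])
        assert widths[0] > widths[1] > widths[2]
        # 16-fold n increase should shrink the width roughly 4-fold
        assert 2.0 < widths[0] / widths[2] < 8.0

    def test_invalid_inputs(self, study_cohort):
        with pytest.raises(ValueError):
            bootstrap_cea(study_cohort, "MAB", "ORAL", B=0, seed=0)
        with pytest.raises(ValueError):
            bootstrap_cea(study_cohort, "MAB", "ORAL", B=10, seed=0, resample_mode="jack")


class TestQuadrantReport:
    def _result(self, probs, **kw):
        base = dict(
            treat="ORAL",
            comparator="IFN",
            delta_cost=-4336.65,
            delta_effect=0.0811,
            icer=-53472.87,
            icer_defined=True,
            quadrant="SE",
            ci_delta_cost=(-5207.89, -3903.32),
            ci_delta_effect=(-0.1481, 0.1807),
            quadrant_probs=probs,
            B=10_000,
            seed=0,
            n_failures=0,
            caliper_sd=0.2,
            resample_mode="rematch",
            replicates=None,
        )
        base.update(kw)
        return CEAResult(**base)

    def test_dominance_statement(self):
        res = self._result({"SE": 0.9605, "SW": 0.0394, "NE": 0.0001, "NW": 0.0})
        text = quadrant_report(res)
        assert "dominant" in text
        assert "96.05%" in text

    def test_uniform_quadrants_no_dominance(self):
        res = self._result({q: 0.25 for q in ("NE", "SE", "SW", "NW")})
        text = quadrant_report(res)
        assert "no dominant" in text
        assert text.count("25.00%") == 4

    def test_invalid_probabilities_surfaced(self):
        with pytest.raises(ValueError, match="sum"):
            self._result({"SE": 0.5, "SW": 0.1, "NE": 0.1, "NW": 0.1})
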