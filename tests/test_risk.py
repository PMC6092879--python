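"""Risk scores and observed-vs-simulated validation summaries."""

import numpy as np
import pandas as pd
import pytest

from metatraj.io import CohortTable
from metatraj.model import MEASURES, build_index_map
from metatraj.risk import (
    RiskScoreDef,
    compare_moments,
    compute_risk_scores,
    packaged_score,
    risk_score_comparison,
)
from metatraj.simulate import TrajectorySet


def _records(n=50, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "participant": np.arange(n), "phase": 1,
        "age_at_phase": rng.uniform(45, 65, n),
        "sex": rng.integers(0, 2, n), "ethnicity": 0, "smoking": rng.integers(0, 2, n),
        "fh_diabetes": rng.integers(0, 2, n), "fh_cvd": 0,
        "bmi": rng.normal(26, 3, n), "fpg": rng.normal(5.4, 0.6, n),
        "glu2h": rng.normal(5.6, 1.5, n), "hba1c": rng.normal(5.5, 0.5, n),
        "sbp": rng.normal(122, 12, n), "tc": rng.normal(5.8, 1.0, n),
        "hdl": rng.normal(1.4, 0.3, n).clip(0.5),
    })


def _traj_from_cohort(cohort, replicate=0):
    """TrajectorySet that replays a cohort's own values (self-comparison)."""
    Y, _ = cohort.to_matrices()
    return TrajectorySet(
        replicate=replicate,
        participants=cohort.frame["participant"].unique(),
        factors=np.zeros((Y.shape[0], 12)),
        values=Y,
        censored=np.isnan(Y),
        seed=0,
        spec=cohort.spec,
    )


class TestComputeRiskScores:
    def test_zero_coefficients_logistic_gives_half(self):
        sdef = RiskScoreDef(name="null", link="logistic",
                            terms=({"input": "sbp", "coef": 0.0},))
        s = compute_risk_scores(_records(), sdef)
        np.testing.assert_array_equal(s.to_numpy(), 0.5)

    @pytest.mark.parametrize("score,column", [
        ("framingham_cvd_2008", "sbp"),
        ("diabetes_fpg_synthetic", "fpg"),
        ("diabetes_2h_synthetic", "glu2h"),
    ])
    def test_monotone_in_positive_coefficient_input(self, score, column):
        sdef = packaged_score(score)
        rec = _records(30, seed=1)
        lo = compute_risk_scores(rec, sdef)
        rec2 = rec.copy()
        rec2[column] = rec2[column] + 10.0
        hi = compute_risk_scores(rec2, sdef)
        assert (hi >= lo).all()
        assert ((lo >= 0) & (hi <= 1)).all()

    def test_framingham_matches_step_by_step_hand_calculation(self):
        """One fully specified profile, computed independently term by term
        from the packaged coefficient table."""
        rec = pd.DataFrame({
            "participant": [1], "phase": [1], "age_at_phase": [60.0],
            "sex": [1], "ethnicity": [0], "smoking": [0],
            "fh_diabetes": [0], "fh_cvd": [0],
            "bmi": [26.0], "fpg": [5.3], "glu2h": [5.5], "hba1c": [5.4],
            "sbp": [123.0], "tc": [5.8], "hdl": [1.4],
        })
        lp = (3.06117 * np.log(60.0)
              + 1.1237 * np.log(5.8 * 38.67)
              - 0.93263 * np.log(1.4 * 38.67)
              + 1.93303 * np.log(123.0))
        expected = 1.0 - 0.88936 ** np.exp(lp - 23.9802)
        got = compute_risk_scores(rec, packaged_score("framingham_cvd_2008"))
        np.testing.assert_allclose(got.iloc[0], expected, rtol=1e-12)
        assert 0.05 < got.iloc[0] < 0.30   # plausible 10-y risk for this profile

    def test_missing_inputs_yield_nan(self):
        rec = _records(5)
        rec.loc[2, "sbp"] = np.nan
        s = compute_risk_scores(rec, packaged_score("framingham_cvd_2008"))
        assert np.isnan(s.iloc[2]) and s.drop(index=2).notna().all()

    def test_malformed_definition_rejected(self):
        with pytest.raises(ValueError):
            RiskScoreDef(name="bad", link="probit", terms=())
        with pytest.raises(ValueError):
            RiskScoreDef(name="bad", link="logistic",
                         terms=({"input": "sbp"},))
        with pytest.raises(ValueError):
            RiskScoreDef(name="bad", link="cox", terms=())


class TestCompareMoments:
    def test_self_comparison_is_exact(self, complete_cohort):
        traj = _traj_from_cohort(complete_cohort)
        rep = compare_moments(complete_cohort, [traj])
        np.testing.assert_allclose(rep.moments["difference"], 0.0, atol=1e-12)
        np.testing.assert_allclose(
            rep.moments["simulated_sd"], rep.moments["observed_sd"], atol=1e-12)
        for d in rep.correlations.values():
            np.testing.assert_allclose(d["simulated"], d["observed"], atol=1e-12)

    def test_constant_bmi_shift_moves_mean_not_sd(self, complete_cohort):
        traj = _traj_from_cohort(complete_cohort)
        imap = build_index_map(complete_cohort.spec)
        shifted = traj.values.copy()
        for t in range(4):
            shifted[:, imap.index("bmi", t)] += 1.0
        traj_s = TrajectorySet(replicate=0, participants=traj.participants,
                               factors=traj.factors, values=shifted,
                               censored=traj.censored, seed=0, spec=traj.spec)
        rep = compare_moments(complete_cohort, [traj_s])
        bmi = rep.moments[rep.moments["measure"] == "bmi"]
        np.testing.assert_allclose(bmi["difference"], 1.0, atol=1e-9)
        np.testing.assert_allclose(bmi["simulated_sd"], bmi["observed_sd"], atol=1e-9)
        other = rep.moments[rep.moments["measure"] != "bmi"]
        np.testing.assert_allclose(other["difference"], 0.0, atol=1e-12)

    def test_summaries_equal_naive_recomputation(self, spec, params):
        from metatraj.cohort import MissingnessConfig, generate_cohort
        from metatraj.simulate import AlertThresholds
        cohort, _ = generate_cohort(30, params, spec,
                                    missingness=MissingnessConfig.none(),
                                    thresholds=AlertThresholds.none(), seed=55)
        traj = _traj_from_cohort(cohort)
        rng = np.random.default_rng(5)
        traj.values = traj.values + rng.normal(0, 0.1, traj.values.shape)
        rep = compare_moments(cohort, [traj])
        imap = build_index_map(spec)
        for _, row in rep.moments.iterrows():
            t = int(row["phase"]) - 1
            m = row["measure"]
            if not spec.availability[m][t]:
                continue
            obs = cohort.frame.loc[cohort.frame["phase"] == t + 1, m].dropna()
            sim = traj.values[:, imap.index(m, t)]
            np.testing.assert_allclose(row["observed_mean"], obs.mean(), atol=1e-12)
            np.testing.assert_allclose(row["observed_sd"], obs.std(), atol=1e-12)
            np.testing.assert_allclose(row["simulated_mean"], np.nanmean(sim), atol=1e-12)

    def test_disjoint_participants_rejected(self, complete_cohort):
        traj = _traj_from_cohort(complete_cohort)
        traj.participants = traj.participants + 10_000
        with pytest.raises(ValueError, match="overlap"):
            compare_moments(complete_cohort, [traj])


class TestRiskScoreComparison:
    def test_self_comparison_perfect_correlation(self, complete_cohort):
        traj = _traj_from_cohort(complete_cohort)
        defs = [packaged_score("framingham_cvd_2008"),
                packaged_score("diabetes_fpg_synthetic")]
        out = risk_score_comparison(complete_cohort, [traj], defs)
        np.testing.assert_allclose(out["difference"], 0.0, atol=1e-12)
        np.testing.assert_allclose(out["mean_correlation"], 1.0, atol=1e-9)

    def test_table_layout_four_phases_two_scores(self, complete_cohort):
        traj = _traj_from_cohort(complete_cohort)
        defs = [packaged_score("framingham_cvd_2008"),
                packaged_score("diabetes_fpg_synthetic")]
        out = risk_score_comparison(complete_cohort, [traj, traj], defs)
        assert len(out) == 8   # 4 phases x 2 scores
        assert {"observed_mean", "observed_sd", "simulated_mean", "simulated_sd",
                "difference", "mean_correlation"} <= set(out.columns)

    def test_noise_attenuates_correlation_by_reliability_ratio(self, spec, params):
        """Simulated scores = observed + independent noise: the mean
        correlation matches the analytic attenuation 1/sqrt(1 + s2/var)."""
        from metatraj.cohort import MissingnessConfig, generate_cohort
        from metatraj.simulate import AlertThresholds
        cohort, _ = generate_cohort(2000, params, spec,
                                    missingness=MissingnessConfig.none(),
                                    thresholds=AlertThresholds.none(), seed=77)
        # near-linear score of FPG only, so score correlation == FPG correlation
        sdef = RiskScoreDef(name="lin", link="logistic",
                            terms=({"input": "fpg", "coef": 0.05, "center": 5.4},))
        imap = build_index_map(spec)
        rng = np.random.default_rng(6)
        noise_sd = 0.5
        trajs = []
        for r in range(4):
            t = _traj_from_cohort(cohort, replicate=r)
            vals = t.values.copy()
            for ph in range(4):
                vals[:, imap.index("fpg", ph)] += rng.normal(0, noise_sd, vals.shape[0])
            t.values = vals
            trajs.append(t)
        out = risk_score_comparison(cohort, trajs, [sdef])
        fpg1 = cohort.frame.loc[cohort.frame["phase"] == 1, "fpg"]
        expected = 1.0 / np.sqrt(1.0 + noise_sd**2 / fpg1.var())
        got = out.loc[out["phase"] == 1, "mean_correlation"].iloc[0]
        assert abs(got - expected) < 0.03

    def test_row_and_replicate_order_invariance(self, complete_cohort):
        traj0 = _traj_from_cohort(complete_cohort, 0)
        traj1 = _traj_from_cohort(complete_cohort, 1)
        rng = np.random.default_rng(1)
        traj1.values = traj1.values + rng.normal(0, 0.05, traj1.values.shape)
        defs = [packaged_score("framingham_cvd_2008")]
        a = risk_score_comparison(complete_cohort, [traj0, traj1], defs)
        b = risk_score_comparison(complete_cohort, [traj1, traj0], defs)
        np.testing.assert_allclose(a["simulated_mean"], b["simulated_mean"], atol=1e-12)
        np.testing.assert_allclose(a["mean_correlation"], b["mean_correlation"], atol=1e-12)
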