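"""Gait score components, formula properties and clinical correlations."""

import numpy as np
import pytest
from scipy import stats as sps

from imugait import score as sc
from imugait.errors import CorrelationError, ScoreError
from imugait.synthetic import simulate_walk

from conftest import run_analysis


def stats_example():
    return sc.StepPitchStats(
        p_l_max=[20.0, 22.0], p_l_min=[-10.0, -12.0],
        p_r_max=[30.0, 30.0], p_r_min=[-15.0, -15.0],
        t1=[1.4, 1.4], t2=[1.2, 1.2],
    )


class TestScoreComponents:
    def test_hand_computed_example(self):
        comp = sc.score_components(stats_example())
        assert (comp.e, comp.f, comp.c, comp.d) == (21.0, -11.0, 22.0, -12.0)
        assert (comp.g, comp.h_pitch, comp.k, comp.m) == (30.0, -15.0, 30.0, -15.0)
        assert comp.a == pytest.approx(9.0)
        assert comp.b == pytest.approx(4.0)
        assert (comp.arange_l, comp.arange_r) == (32.0, 45.0)
        assert comp.p == pytest.approx(0.2)
        assert comp.q == pytest.approx(1.3)
        score = sc.gait_score(comp)
        assert score == pytest.approx(15.0 / 32.0 * (0.2 / 1.3 + 1.0), abs=1e-9)
        assert score == pytest.approx(0.5409, abs=5e-4)

    def test_symmetric_consistent_gait_scores_zero(self):
        st = sc.StepPitchStats(
            p_l_max=[25.0, 25.0], p_l_min=[-15.0, -15.0],
            p_r_max=[25.0, 25.0], p_r_min=[-15.0, -15.0],
            t1=[1.3, 1.3], t2=[1.3, 1.3],
        )
        comp = sc.score_components(st)
        assert comp.a == comp.b == comp.p == 0.0
        assert (comp.c, comp.k) == (comp.e, comp.g)
        assert sc.gait_score(comp) == 0.0

    def test_one_constant_foot_range_logic(self):
        st = sc.StepPitchStats(
            p_l_max=[20.0, 24.0], p_l_min=[-8.0, -12.0],
            p_r_max=[25.0, 25.0], p_r_min=[-15.0, -15.0],
            t1=[1.3, 1.3], t2=[1.3, 1.3],
        )
        comp = sc.score_components(st)
        assert comp.arange_l == pytest.approx(22.0 - (-10.0))
        assert comp.arange_r == pytest.approx(40.0)

    def test_signed_mode_keeps_signs(self):
        comp = sc.score_components(stats_example(), signed=True)
        assert comp.a == pytest.approx(-9.0)
        assert comp.b == pytest.approx(4.0)
        assert comp.p == pytest.approx(0.2)

    def test_component_ordering_invariants(self):
        comp = sc.score_components(stats_example())
        assert comp.c >= comp.e >= comp.f >= comp.d
        assert comp.k >= comp.g >= comp.h_pitch >= comp.m
        assert comp.arange_l >= 0 and comp.arange_r >= 0

    def test_single_step_rejected(self):
        with pytest.raises(ScoreError, match=">= 2"):
            sc.score_components(
                sc.StepPitchStats(
                    p_l_max=[20.0], p_l_min=[-10.0], p_r_max=[30.0],
                    p_r_min=[-15.0], t1=[1.3], t2=[1.3],
                )
            )


class TestScoreInvariances:
    def test_scale_invariance_of_pitch(self):
        base = sc.gait_score(sc.score_components(stats_example()))
        st = stats_example()
        for name in ("p_l_max", "p_l_min", "p_r_max", "p_r_min"):
            setattr(st, name, getattr(st, name) * 2.0)
        doubled = sc.gait_score(sc.score_components(st))
        assert doubled == pytest.approx(base, rel=1e-12)

    def test_stride_time_scale_invariance(self):
        base = sc.gait_score(sc.score_components(stats_example()))
        st = stats_example()
        st.t1, st.t2 = st.t1 * 3.0, st.t2 * 3.0
        assert sc.gait_score(sc.score_components(st)) == pytest.approx(base, rel=1e-12)

    def test_side_relabeling_invariance(self):
        st = stats_example()
        swapped = sc.StepPitchStats(
            p_l_max=st.p_r_max, p_l_min=st.p_r_min,
            p_r_max=st.p_l_max, p_r_min=st.p_l_min,
            t1=st.t2, t2=st.t1,
        )
        a = sc.gait_score(sc.score_components(st))
        b = sc.gait_score(sc.score_components(swapped))
        assert a == pytest.approx(b, rel=1e-12)

    def test_degenerate_range_rejected(self):
        st = sc.StepPitchStats(
            p_l_max=[0.0, 0.0], p_l_min=[0.0, 0.0],
            p_r_max=[25.0, 25.0], p_r_min=[-15.0, -15.0],
            t1=[1.3, 1.3], t2=[1.3, 1.3],
        )
        with pytest.raises(ScoreError, match="degenerate"):
            sc.gait_score(sc.score_components(st))


class TestStepPitchStats:
    def test_pipeline_recovers_generator_amplitudes(self):
        sess = simulate_walk(
            n_strides=6, accel_bias=0.0, seed=9,
            pitch_max_deg=(20.0, 30.0), pitch_min_deg=(-12.0, -15.0),
        )
        result = run_analysis(sess)
        st = sc.step_pitch_stats(
            result.cycles, result.trajectories["left"], result.trajectories["right"]
        )
        assert np.mean(st.p_l_max) == pytest.approx(20.0, abs=1.0)
        assert np.mean(st.p_r_max) == pytest.approx(30.0, abs=1.0)
        assert np.mean(st.p_l_min) == pytest.approx(-12.0, abs=1.0)
        assert np.mean(st.p_r_min) == pytest.approx(-15.0, abs=1.0)

    def test_identical_cycles_give_identical_steps(self, clean_analysis):
        st = sc.step_pitch_stats(
            clean_analysis.cycles,
            clean_analysis.trajectories["left"],
            clean_analysis.trajectories["right"],
        )
        assert np.ptp(st.p_l_max) < 0.1
        assert np.ptp(st.p_r_max) < 0.1

    def test_single_cycle_rejected(self, clean_analysis):
        with pytest.raises(ScoreError):
            sc.step_pitch_stats(
                clean_analysis.cycles[:1],
                clean_analysis.trajectories["left"],
                clean_analysis.trajectories["right"],
            )


class TestCorrelations:
    def test_perfectly_correlated(self, rng):
        x = rng.normal(size=20)
        assert sc.pearson_correlation(x, x) == pytest.approx(1.0)
        assert sc.pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_monotone_transform_gives_unit_rho(self, rng):
        x = rng.normal(size=30)
        assert sc.spearman_rho(x, np.exp(x)) == pytest.approx(1.0)

    def test_tied_ranks_match_scipy_oracle(self):
        x = [1, 2, 2, 3, 3, 3, 4]
        y = [2, 1, 3, 3, 5, 4, 6]
        ours = sc.spearman_rho(x, y)
        oracle = sps.spearmanr(x, y).statistic
        assert ours == pytest.approx(oracle, abs=1e-12)

    def test_pearson_matches_scipy_oracle(self, rng):
        x, y = rng.normal(size=25), rng.normal(size=25)
        assert sc.pearson_correlation(x, y) == pytest.approx(
            sps.pearsonr(x, y).statistic, abs=1e-12
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(CorrelationError):
            sc.pearson_correlation([1, 1, 1], [1, 2, 3])
        with pytest.raises(CorrelationError):
            sc.spearman_rho([1, 1, 1], [1, 1, 1])

    def test_too_short_rejected(self):
        with pytest.raises(CorrelationError):
            sc.pearson_correlation([1, 2], [3, 4])


class TestClinicalTable:
    def test_fixture_shape(self):
        df = sc.load_clinical_scores()
        assert len(df) == 26
        assert set(df.columns) == {"subject", "doctor_score", "imu_score"}
        assert (df["doctor_score"] >= 0).all()

    def test_validation_report(self):
        rep = sc.validate_scores()
        assert rep["n"] == 26
        assert rep["pearson_significant"] and rep["spearman_significant"]
        assert rep["spearman_rho"] > rep["pearson_r"]

    def test_identical_columns_give_unit_correlations(self):
        df = sc.load_clinical_scores().copy()
        df["imu_score"] = df["doctor_score"]
        rep = sc.validate_scores(df)
        assert rep["pearson_r"] == pytest.approx(1.0)
        assert rep["spearman_rho"] == pytest.approx(1.0)

    def test_truncated_table_rejected(self):
        df = sc.load_clinical_scores().iloc[:2]
        with pytest.raises(CorrelationError):
            sc.validate_scores(df)
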