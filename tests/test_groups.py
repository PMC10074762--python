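"""Group-level statistics and the end-to-end pipeline."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import revpitch as rp


def small_pipeline_config(seed=5, n_observers=6, n_trials=60, melody=False):
    conditions = {"speech": rp.speech_config(n_trials=n_trials,
                                             pool_size=2 * n_trials)}
    if melody:
        conditions["melody"] = rp.melody_config(n_trials=n_trials,
                                                pool_size=2 * n_trials)
    return rp.PipelineConfig(
        cohorts=[
            rp.CohortSpec(group="ASD", n_observers=n_observers,
                          template_dispersion=0.8, seed=0),
            rp.CohortSpec(group="nonASD", n_observers=n_observers,
                          template_dispersion=0.4, seed=0),
        ],
        conditions=conditions, seed=seed, reference_group="nonASD",
    )


class TestWelchT:
    def test_identical_samples(self):
        res = rp.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_stat == 0.0
        assert res.p_value == pytest.approx(1.0)
        assert res.cohens_d == 0.0

    def test_hand_example(self):
        res = rp.welch_t([1, 2, 3], [2, 4, 6])
        assert res.t_stat == pytest.approx(-1.549, abs=1e-3)
        assert res.df == pytest.approx(2.941, abs=1e-3)
        assert res.df <= 3 + 3 - 2

    def test_shift_alternative_power(self):
        gen = np.random.default_rng(2)
        rejections = sum(
            rp.welch_t(gen.normal(0, 1, 200), gen.normal(1, 1, 200)).p_value < 0.05
            for _ in range(100))
        assert rejections >= 99

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            rp.welch_t([1.0], [1.0, 2.0])


class TestTimepointComparison:
    def test_identical_groups_nothing_significant(self):
        gen = np.random.default_rng(4)
        base = gen.normal(0, 5, size=(32, 8))
        table = rp.timepoint_comparison(base, base + 0.0)
        assert (table.p_adj == 1.0).all() or not (table.p_adj < 0.05).any()

    def test_bonferroni_arithmetic(self):
        gen = np.random.default_rng(6)
        table = rp.timepoint_comparison(gen.normal(size=(20, 8)),
                                        gen.normal(size=(20, 8)))
        assert np.allclose(table.p_adj, np.minimum(1.0, table.p * 8))

    def test_localized_group_difference_detected(self):
        """Offset injected at breakpoint 7 only: that breakpoint (and only
        that one) should survive correction in most replicates."""
        gen = np.random.default_rng(8)
        hits, false_extra = 0, 0
        for _ in range(50):
            g1 = gen.normal(0, 1, size=(32, 8))
            g2 = gen.normal(0, 1, size=(32, 8))
            g2[:, 6] += 3.0  # breakpoint 7, offset 3x within-group SD
            table = rp.timepoint_comparison(g1, g2)
            sig = set(table.breakpoint[table.p_adj < 0.05])
            hits += sig == {7}
            false_extra += len(sig - {7})
        assert hits >= 45
        assert false_extra <= 10

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            rp.timepoint_comparison(np.zeros((5, 8)), np.zeros((5, 3)))


class TestIntragroupVariability:
    def test_identical_kernels_give_unit_correlations(self):
        row = np.array([1.0, 3.0, -2.0, 0.5])
        g = np.tile(row, (5, 1))
        res = rp.intragroup_variability(g, g + 0.0)
        assert np.allclose(res.r_group_1, 1.0)
        assert len(res.r_group_1) == 10  # C(5,2)

    def test_pair_count_and_student_df(self):
        gen = np.random.default_rng(10)
        res = rp.intragroup_variability(gen.normal(size=(32, 8)),
                                        gen.normal(size=(32, 8)))
        assert len(res.r_group_1) == 496
        assert res.df == 990  # C(32,2) pairs per group, Student df

    def test_dispersion_difference_detected(self, speech_cfg):
        """Tighter cohorts have higher pairwise kernel correlations."""
        cfg = dataclasses.replace(speech_cfg, n_trials=150, pool_size=300)
        mats = {}
        for delta in (0.2, 0.8):
            spec = rp.CohortSpec(group="g", n_observers=32,
                                 template_dispersion=delta,
                                 internal_noise_mean=1.0,
                                 internal_noise_sd=0.2, seed=14)
            cohort = rp.make_cohort(spec, cfg)
            mats[delta] = np.array([rp.estimate_kernel(s).values
                                    for _, s in cohort])
        res = rp.intragroup_variability(mats[0.2], mats[0.8])
        assert res.mean_1 > res.mean_2
        assert res.t_stat > 0
        assert res.p_value < 0.05

    def test_fisher_z_variant_runs(self):
        gen = np.random.default_rng(16)
        res = rp.intragroup_variability(gen.normal(size=(6, 8)),
                                        gen.normal(size=(6, 8)), fisher_z=True)
        assert res.fisher_z
        assert 0.0 <= res.p_value <= 1.0

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            rp.intragroup_variability(np.zeros((2, 8)), np.zeros((5, 8)))


class TestTypeIError:
    def test_welch_rejects_at_alpha_under_null(self):
        gen = np.random.default_rng(18)
        n_rep = 500
        rejections = sum(
            rp.welch_t(gen.normal(0, 1, 32), gen.normal(0, 1, 32)).p_value < 0.05
            for _ in range(n_rep))
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rejections / n_rep - 0.05) < 3 * se


@pytest.fixture(scope="module")
def report_and_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("report")
    cfg = small_pipeline_config(melody=True)
    report = rp.run_pipeline(cfg, out_dir=out)
    return report, out, cfg


class TestPipeline:
    def test_report_complete_per_participant_condition(self, report_and_dir):
        report, _, cfg = report_and_dir
        m = report.metrics
        assert len(m) == 2 * 6 * 2  # groups x observers x conditions
        assert not m.duplicated(["participant_id", "condition"]).any()
        assert {"rms", "agreement", "n_scored_trials"} <= set(m.columns)

    def test_ladder_only_for_eight_point_conditions(self, report_and_dir):
        report, _, _ = report_and_dir
        assert set(report.shape_selection.condition) == {"speech"}
        assert set(report.timepoint_tables) == {"speech", "melody"}
        assert set(report.prototype.condition) == {"melody"}

    def test_every_p_comes_with_statistic_and_df(self, report_and_dir):
        report, _, _ = report_and_dir
        for table in (report.rms_tests, report.agreement_tests):
            assert {"t_stat", "df", "p_value"} <= set(table.columns)
            assert table.notna().all().all()

    def test_rerun_is_byte_identical(self, tmp_path):
        cfg = small_pipeline_config(seed=9)
        rp.run_pipeline(cfg, out_dir=tmp_path / "a")
        rp.run_pipeline(cfg, out_dir=tmp_path / "b")
        for name in ("report.json", "metrics.csv", "sessions.csv"):
            assert ((tmp_path / "a" / name).read_bytes()
                    == (tmp_path / "b" / name).read_bytes())

    def test_reanalysis_of_saved_logs_reproduces_report(self, report_and_dir):
        report, out, cfg = report_and_dir
        sessions = rp.load_sessions(out / "sessions.csv")
        report2 = rp.analyze_sessions(sessions, config=cfg)
        assert np.allclose(report.metrics.rms, report2.metrics.rms)
        assert np.allclose(report.metrics.agreement, report2.metrics.agreement)
        t1 = report.timepoint_tables["speech"]
        t2 = report2.timepoint_tables["speech"]
        assert np.allclose(t1.p_adj, t2.p_adj)

    def test_group_shape_difference_recovered(self):
        """Cohorts generated from cubic vs quartic templates select the
        matching shapes in the Table-2-style ladder."""
        cfg = rp.PipelineConfig(
            cohorts=[
                rp.CohortSpec(group="A", n_observers=16, base_shape="quartic",
                              template_dispersion=0.2, internal_noise_mean=1.0,
                              internal_noise_sd=0.2, seed=0),
                rp.CohortSpec(group="B", n_observers=16, base_shape="cubic",
                              template_dispersion=0.2, internal_noise_mean=1.0,
                              internal_noise_sd=0.2, seed=0),
            ],
            conditions={"complex_tone": rp.complex_tone_config(
                n_trials=150, pool_size=300)},
            seed=13,
        )
        report = rp.run_pipeline(cfg)
        best = report.shape_selection.groupby("group").best_degree.first()
        assert best["A"] == 4
        assert best["B"] == 3
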