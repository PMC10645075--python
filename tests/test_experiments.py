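"""Paired-branch comparisons, aggregation and the correlation utility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import flownetevo as fe
from flownetevo import ExperimentConfig, normalized_diff
from flownetevo.experiments import ComparisonRecord


def make_record(b_diff, goal_diff, out_links=0, **kw):
    base = dict(
        replicate=0, goal="TST", scenario="ABS_FLOW", size=30, fraction=0.5,
        b_control=-0.5, b_greedy=-0.5, goal_control=1.0, goal_greedy=1.0,
        b_diff=b_diff, goal_diff=goal_diff, greedy_out_links=out_links,
    )
    base.update(kw)
    return ComparisonRecord(**base)


class TestNormalizedDiff:
    def test_identical_endpoints_give_zero(self):
        assert normalized_diff(-0.4, -0.4) == 0.0
        assert normalized_diff(0.0, 0.0) == 0.0

    def test_greedy_surpassing_gives_negative(self):
        # b_greedy = -0.25 is closer to zero (more tolerant) than b_control = -0.5
        assert normalized_diff(-0.5, -0.25) == pytest.approx(-1 / 3)

    def test_control_surpassing_gives_positive(self):
        assert normalized_diff(-0.25, -0.5) == pytest.approx(1 / 3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.floats(-10, 10, allow_nan=False),
        b=st.floats(-10, 10, allow_nan=False),
    )
    def test_antisymmetric_and_bounded(self, a, b):
        d = normalized_diff(a, b)
        assert normalized_diff(b, a) == pytest.approx(-d, abs=1e-15)
        assert -1.0 <= d <= 1.0


class TestExperimentConfig:
    def test_defaults_match_study_design(self):
        cfg = ExperimentConfig()
        assert cfg.sizes == (30, 50, 70, 100)
        assert cfg.replicates == 100
        assert cfg.connectance == 0.20
        assert cfg.natural_iters == 500
        assert cfg.short_iters == 5000
        assert cfg.greedy_fractions == (0.10, 0.30, 0.50)

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = ExperimentConfig(sizes=(5,), replicates=2, natural_iters=10, short_iters=10)
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert ExperimentConfig.from_yaml(path) == cfg

    def test_bad_values_rejected(self):
        with pytest.raises(fe.ConfigurationError):
            ExperimentConfig(replicates=0)
        with pytest.raises(fe.ConfigurationError):
            ExperimentConfig(goals=("ABS_FLOW",))  # greedy goal is not an orientor
        with pytest.raises(fe.ConfigurationError):
            ExperimentConfig.from_dict({"not_a_key": 1})


@pytest.fixture(scope="module")
def evolved():
    cfg = ExperimentConfig(
        sizes=(8,), replicates=1, goals=("TST",), natural_iters=50, short_iters=50,
        master_seed=3,
    )
    runs = fe.run_natural_history(cfg, 8, "TST")
    return runs[0][1].final


class TestBranchPair:
    def test_record_fields_and_diff_signs(self, evolved):
        rec = fe.run_branch_pair(evolved, "TST", "ABS_FLOW", 0.5, seed=11, short_iters=100)
        assert rec.size == 8
        assert -1.0 < rec.b_diff < 1.0
        assert -1.0 < rec.goal_diff < 1.0
        assert rec.b_diff == pytest.approx(normalized_diff(rec.b_control, rec.b_greedy))
        assert rec.goal_diff == pytest.approx(normalized_diff(rec.goal_control, rec.goal_greedy))
        assert rec.b_control < 0 and rec.b_greedy < 0
        assert rec.greedy_out_links >= 0

    def test_deterministic_given_seed(self, evolved):
        r1 = fe.run_branch_pair(evolved, "TST", "PROP_FLOW", 0.3, seed=5, short_iters=60)
        r2 = fe.run_branch_pair(evolved, "TST", "PROP_FLOW", 0.3, seed=5, short_iters=60)
        assert r1 == r2


class TestRunNaturalHistory:
    def test_traces_monotone_and_final_networks_valid(self):
        cfg = ExperimentConfig(
            sizes=(6,), replicates=3, goals=("TST",), natural_iters=40, short_iters=10,
            master_seed=1,
        )
        runs = fe.run_natural_history(cfg, 6, "TST")
        assert len(runs) == 3
        for _, trace in runs:
            assert (np.diff(trace.goal_values) >= 0).all()
            assert fe.validate(trace.final).is_valid

    def test_same_seed_gives_identical_ensembles(self):
        cfg = ExperimentConfig(
            sizes=(6,), replicates=2, goals=("EDIFF",), natural_iters=30, short_iters=10,
            master_seed=9,
        )
        a = fe.run_natural_history(cfg, 6, "EDIFF")
        b = fe.run_natural_history(cfg, 6, "EDIFF")
        for (_, ta), (_, tb) in zip(a, b):
            assert np.array_equal(ta.final.adjacency, tb.final.adjacency)


class TestSurpassPercentages:
    def test_counting(self):
        records = [make_record(-0.1, 0.2)] * 3 + [make_record(0.1, 0.2)] * 7
        table = fe.surpass_percentages(records)
        assert len(table) == 1
        assert table.loc[0, "pct_tolerance"] == pytest.approx(30.0)
        assert table.loc[0, "pct_both"] == pytest.approx(0.0)

    def test_all_positive_diffs_give_zero_percent(self):
        table = fe.surpass_percentages([make_record(0.3, 0.4)] * 5)
        assert table.loc[0, "pct_tolerance"] == 0.0
        assert table.loc[0, "pct_performance"] == 0.0

    def test_joint_equals_marginal_when_diffs_coincide(self):
        records = [make_record(-0.1, -0.1)] * 4 + [make_record(0.1, 0.1)] * 6
        table = fe.surpass_percentages(records)
        assert table.loc[0, "pct_both"] == table.loc[0, "pct_tolerance"] == pytest.approx(40.0)

    def test_empty_input_returns_empty_table(self):
        assert fe.surpass_percentages([]).empty


class TestDiffScatterStats:
    def test_exact_identity_line(self):
        records = [make_record(-x, -x) for x in (0.1, 0.2, 0.3, 0.4)]
        stats = fe.diff_scatter_stats(records)
        assert stats["computable"]
        assert stats["slope"] == pytest.approx(1.0)
        assert stats["r"] == pytest.approx(1.0)

    def test_half_slope_recovered(self):
        rng = np.random.default_rng(0)
        records = [
            make_record(-x, -0.5 * x + 1e-9 * rng.standard_normal())
            for x in np.linspace(0.05, 0.8, 30)
        ]
        stats = fe.diff_scatter_stats(records)
        assert stats["slope"] == pytest.approx(0.5, abs=1e-6)

    def test_not_computable_without_negative_quadrant_points(self):
        stats = fe.diff_scatter_stats([make_record(0.1, 0.1)] * 10)
        assert stats == {"computable": False, "n": 0}


class TestLinkVsDiff:
    def test_monotone_relation_gives_spearman_one(self):
        records = [make_record(-0.5 + 0.1 * k, 0.0, out_links=k) for k in range(6)]
        stats = fe.link_vs_diff_analysis(records)
        assert stats["spearman_rho"] == pytest.approx(1.0)
        assert stats["binned_mean_b_diff"][0] == pytest.approx(-0.5)

    def test_shuffled_pairing_has_small_correlation(self):
        rng = np.random.default_rng(1)
        rhos = []
        base_b = np.linspace(-0.5, 0.5, 40)
        links = np.arange(40) % 5
        for _ in range(20):
            rng.shuffle(links)
            records = [
                make_record(float(b), 0.0, out_links=int(l)) for b, l in zip(base_b, links)
            ]
            rhos.append(abs(fe.link_vs_diff_analysis(records)["spearman_rho"]))
        assert np.median(rhos) < 0.3

    def test_too_few_records_not_computable(self):
        assert not fe.link_vs_diff_analysis([make_record(0.1, 0.1)] * 2)["computable"]

    def test_constant_out_links_not_computable(self):
        records = [make_record(-0.1 * k, 0.0, out_links=2) for k in range(5)]
        assert not fe.link_vs_diff_analysis(records)["computable"]


class TestGoalCorrelationMatrix:
    def test_random_ensemble_gives_finite_symmetric_matrix(self):
        nets = [fe.random_fcdn(12, 0.3, seed=s) for s in range(10)]
        corr = fe.goal_correlation_matrix(nets)
        assert corr.shape == (6, 6)
        assert np.allclose(corr.values, corr.values.T, equal_nan=True)
        assert np.nanmax(np.abs(corr.values)) <= 1.0 + 1e-12
        assert np.allclose(np.diag(corr.values), 1.0)

    def test_identical_networks_give_undefined_correlations(self):
        nets = [fe.random_fcdn(10, 0.3, seed=4)] * 4
        corr = fe.goal_correlation_matrix(nets)
        off_diag = corr.values[~np.eye(6, dtype=bool)]
        assert np.isnan(off_diag).all()

    def test_tst_asc_identity_on_scale_varied_ami_constant_family(self, toy_cycle):
        # same topology, varying input rate: AMI constant, ASC = AMI * TST
        bundles = [fe.index_bundle(toy_cycle, input_rate=r) for r in (0.5, 1.0, 2.0, 4.0)]
        df = pd.DataFrame({"tst": [b.tst for b in bundles], "asc": [b.asc for b in bundles]})
        assert df.corr().loc["tst", "asc"] == pytest.approx(1.0)
        amis = {round(b.ami, 12) for b in bundles}
        assert len(amis) == 1


class TestRunExperimentSmoke:
    def test_tiny_grid_produces_records_and_files(self, tmp_path):
        cfg = ExperimentConfig(
            sizes=(5,),
            replicates=2,
            connectance=0.5,
            goals=("TST",),
            greedy_scenarios=("ABS_FLOW", "PROP_FINN"),
            greedy_fractions=(0.5,),
            natural_iters=20,
            short_iters=20,
            master_seed=2,
        )
        records = fe.run_experiment(cfg, out_dir=tmp_path)
        assert len(records) == 2 * 2  # replicates x scenarios
        assert (tmp_path / "records.csv").exists()
        assert (tmp_path / "summary.csv").exists()
        assert len(list((tmp_path / "networks").glob("*.tsv"))) == 2
        saved = pd.read_csv(tmp_path / "records.csv")
        assert len(saved) == len(records)

    def test_deterministic_given_master_seed(self):
        cfg = ExperimentConfig(
            sizes=(5,), replicates=2, connectance=0.5, goals=("TST",),
            greedy_scenarios=("ABS_FLOW",), greedy_fractions=(0.5,),
            natural_iters=15, short_iters=15, master_seed=6,
        )
        a = fe.run_experiment(cfg)
        b = fe.run_experiment(cfg)
        pd.testing.assert_frame_equal(a, b)
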