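"""Parameter estimation: residual scaling, descent, staging, clustering."""

import numpy as np
import pandas as pd
import pytest

from herdyn.estimate import (
    FitProblem,
    FitResult,
    SolutionSet,
    assemble_residuals,
    cluster_solutions,
    fit,
    param_receptors,
    residual_scales,
    rmse_of,
    stage_free_names,
)
from herdyn.parameters import FREE_NAMES, default_parameters
from herdyn.synthetic import Condition, MeasurementDesign, NoiseModel, generate


def _toy_dataset():
    return pd.DataFrame({
        "cell_line": ["A"] * 4,
        "egf_ng_ml": [12.0] * 4,
        "hrg_ng_ml": [0.0] * 4,
        "block": [0.0] * 4,
        "time_min": [0.0, 10.0, 0.0, 10.0],
        "measurement": ["pR1t", "pR1t", "mR1t", "mR1t"],
        "replicate": [1, 1, 1, 1],
        "value": [2.0, 4.0, 100.0, 80.0],
    })


def _predictions(values):
    df = _toy_dataset().drop(columns=["replicate"]).copy()
    df["value"] = values
    return df


class TestResidualScaling:
    def test_exact_predictions_give_zero_rmse(self):
        data = _toy_dataset()
        res = assemble_residuals(data, _predictions(data["value"]))
        assert np.all(res == 0.0) and rmse_of(res) == 0.0

    def test_off_by_one_scale_gives_unit_residual(self):
        data = _toy_dataset()
        # pR1t scale = 4 (its max); push one record off by exactly 4
        preds = _predictions([2.0 + 4.0, 4.0, 100.0, 80.0])
        res = assemble_residuals(data, preds)
        assert res[0] == pytest.approx(1.0)
        assert np.all(res[1:] == 0.0)

    def test_scale_invariance_under_joint_doubling(self):
        data = _toy_dataset()
        preds = _predictions([3.0, 5.0, 90.0, 70.0])
        base = assemble_residuals(data, preds)
        doubled_data = data.assign(value=2 * data["value"])
        doubled_preds = _predictions([6.0, 10.0, 180.0, 140.0])
        np.testing.assert_allclose(
            assemble_residuals(doubled_data, doubled_preds), base)

    def test_missing_prediction_is_hard_error(self):
        data = _toy_dataset()
        preds = _predictions(data["value"]).iloc[:2]
        with pytest.raises(ValueError, match="missing"):
            assemble_residuals(data, preds)

    def test_zero_scale_rejected(self):
        data = _toy_dataset().assign(value=[0.0, 0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="non-positive"):
            residual_scales(data)


class TestStaging:
    def test_stage1_excludes_her2_her3_parameters(self):
        names = stage_free_names("her1")
        assert "delta1" in names
        for n in names:
            assert param_receptors(n) <= {"HER1"}
        assert len(names) == 9  # 4 ku + 4 pf + delta1

    def test_stage_blocks_partition_all_47(self):
        union = (set(stage_free_names("her1"))
                 | set(stage_free_names("her1-her2"))
                 | set(stage_free_names("her1-her3"))
                 | set(stage_free_names("her2-her3")))
        assert union == set(FREE_NAMES)
        assert len(FREE_NAMES) == 47

    def test_param_receptors_examples(self):
        assert param_receptors("ku13eh_s") == {"HER1", "HER3"}
        assert param_receptors("pf21e_i") == {"HER1", "HER2"}
        assert param_receptors("pf22_s") == {"HER2"}
        assert param_receptors("delta1") == {"HER1"}


@pytest.fixture(scope="module")
def stage1_problem(params):
    design = MeasurementDesign((
        Condition("HER2-3-", 12.0, 0.0, 0.0, (0.0, 10.0, 30.0, 60.0),
                  ("pR1t", "pR1i", "mR1t")),
        Condition("HER2-3-", 1.0, 0.0, 0.0, (0.0, 30.0), ("pR1t",)),
    ), name="unit-stage1")
    data = generate(design, params, NoiseModel(cv=0.0), seed=0)
    return FitProblem(data, free_names=stage_free_names("her1"),
                      base_params=params)


class TestFit:
    def test_truth_is_a_fixed_point(self, stage1_problem, params):
        x_truth = stage1_problem.pack(
            {n: params.get_value(n) for n in stage1_problem.free_names})
        assert stage1_problem.rmse(x_truth) < 1e-5
        res = fit(stage1_problem, x_truth, max_nfev=5)
        assert res.rmse < 1e-5
        for n in stage1_problem.free_names:
            assert res.values[n] == pytest.approx(params.get_value(n), rel=0.01)

    def test_descent_contract_from_random_start(self, stage1_problem):
        rng = np.random.default_rng(5)
        x0 = stage1_problem.sample_start(rng)
        res = fit(stage1_problem, x0, max_nfev=8)
        assert res.rmse <= res.rmse_initial + 1e-15

    def test_recovery_from_perturbed_start(self, stage1_problem, params):
        """x3 / /3 perturbations of the identifiable HER1 pair are undone."""
        start = {n: params.get_value(n)
                 for n in stage1_problem.free_names}
        start["pf11ee_s"] *= 3.0
        start["ku11ee_s"] /= 3.0
        res = fit(stage1_problem, start, max_nfev=120)
        assert res.rmse < 1e-3
        assert res.values["pf11ee_s"] == pytest.approx(
            params.get_value("pf11ee_s"), rel=0.10)
        assert res.values["ku11ee_s"] == pytest.approx(
            params.get_value("ku11ee_s"), rel=0.10)

    def test_simulation_failure_is_penalized_not_fatal(self, stage1_problem):
        x = stage1_problem.pack(
            {n: np.nan for n in stage1_problem.free_names})
        res = stage1_problem.residuals(x)
        assert np.all(res == 10.0)


def _fake_solutions(problem, centers, spread, n_per, rmses, seed=0):
    rng = np.random.default_rng(seed)
    results = []
    for c, (center, rmse) in enumerate(zip(centers, rmses)):
        for _ in range(n_per):
            x = center + rng.normal(0.0, spread, len(center))
            results.append(FitResult(
                values={}, x=x, rmse=rmse + rng.uniform(0, 0.001),
                rmse_initial=1.0, converged=True, nfev=1))
    return SolutionSet(problem, results)


class TestClustering:
    def test_two_separated_blobs_recovered(self, stage1_problem):
        dim = len(stage1_problem.free_names)
        centers = [np.zeros(dim), np.full(dim, 10.0)]
        sols = _fake_solutions(stage1_problem, centers, spread=0.1,
                               n_per=8, rmses=[0.01, 0.0101])
        clustered = cluster_solutions(sols, rmse_margin=1.2)
        assert clustered.n_clusters == 2
        # representatives carry the minimum RMSE of their cluster
        for rep_idx in clustered.representatives:
            c = clustered.labels[rep_idx]
            members = [r for r, l in zip(clustered.results, clustered.labels)
                       if l == c]
            assert clustered.results[rep_idx].rmse == min(m.rmse for m in members)

    def test_identical_solutions_collapse_to_one_cluster(self, stage1_problem):
        dim = len(stage1_problem.free_names)
        sols = _fake_solutions(stage1_problem, [np.ones(dim)], spread=0.0,
                               n_per=6, rmses=[0.02])
        for r in sols.results:
            r.rmse = 0.02  # exactly identical
        clustered = cluster_solutions(sols)
        assert clustered.n_clusters == 1

    def test_rmse_margin_filters_solutions(self, stage1_problem):
        dim = len(stage1_problem.free_names)
        sols = _fake_solutions(stage1_problem, [np.zeros(dim), np.ones(dim)],
                               spread=0.05, n_per=4, rmses=[0.01, 0.5])
        clustered = cluster_solutions(sols, rmse_margin=1.2)
        best = min(r.rmse for r in clustered.results)
        assert all(r.rmse <= 1.2 * best for r in clustered.results)

    def test_too_few_solutions_raise(self, stage1_problem):
        sols = _fake_solutions(stage1_problem, [np.zeros(3)], spread=0.0,
                               n_per=1, rmses=[0.01])
        with pytest.raises(ValueError, match="at least 2"):
            cluster_solutions(sols)
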