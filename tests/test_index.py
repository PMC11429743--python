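from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from gxepred import (
    SimConfig,
    additive_grm,
    ensemble_average,
    location_weights,
    model_b_predictions,
    pair_accuracy,
    selection_index,
    simulate_marker_matrix,
)
from gxepred.index import SelectionIndexResult


@pytest.fixture(scope="module")
def unrelated_kernel():
    cfg = SimConfig(n_hybrids=120, n_markers=1000, seed=71)
    return additive_grm(simulate_marker_matrix(cfg))


class TestPairAccuracy:
    def test_identical_sets_score_one(self, unrelated_kernel):
        hy = list(unrelated_kernel.hybrids[:20])
        assert pair_accuracy(unrelated_kernel, hy, hy) == pytest.approx(1.0)

    def test_unrelated_sets_score_near_zero(self, unrelated_kernel):
        hy = list(unrelated_kernel.hybrids)
        assert pair_accuracy(unrelated_kernel, hy[:40], hy[60:100]) < 0.1

    def test_nested_sets_beat_disjoint_sets(self, unrelated_kernel):
        rng = np.random.default_rng(3)
        hy = np.array(unrelated_kernel.hybrids)
        for _ in range(20):
            k = list(rng.choice(hy, size=10, replace=False))
            rest = [h for h in hy if h not in k]
            i_nested = k + list(rng.choice(rest, size=10, replace=False))
            i_disjoint = list(rng.choice(rest, size=20, replace=False))
            a_nested = pair_accuracy(unrelated_kernel, i_nested, k)
            a_disjoint = pair_accuracy(unrelated_kernel, i_disjoint, k)
            assert a_nested >= a_disjoint - 1e-12

    def test_empty_or_unknown_hybrids_rejected(self, unrelated_kernel):
        with pytest.raises(ValueError):
            pair_accuracy(unrelated_kernel, [], ["H0001"])
        with pytest.raises(KeyError):
            pair_accuracy(unrelated_kernel, ["NOPE"], ["H0001"])


def _meta(envs, stations, states):
    return pd.DataFrame({"env_id": envs, "station": stations, "state": states})


class TestLocationWeights:
    def test_single_training_environment(self):
        meta = _meta(["T", "A"], ["s1", "s2"], ["X", "X"])
        w = location_weights(pd.Series({"A": 0.8}), meta, "T")
        assert w["A"] == pytest.approx(1.0)

    def test_hand_arithmetic_same_station_among_four(self):
        # equal accuracies; one same-station env, three different-state envs
        meta = _meta(
            ["T", "A", "B", "C", "D"],
            ["s1", "s1", "s2", "s3", "s4"],
            ["X", "X", "Y", "Y", "Z"],
        )
        acc = pd.Series({"A": 0.5, "B": 0.5, "C": 0.5, "D": 0.5})
        w = location_weights(acc, meta, "T")
        assert w["A"] == pytest.approx(1.0 / (1.0 + 3 * 0.5))  # = 0.4

    def test_weights_sum_to_one(self, rng):
        meta = _meta(
            [f"E{i}" for i in range(11)],
            [f"s{i % 4}" for i in range(11)],
            [f"st{i % 3}" for i in range(11)],
        )
        for _ in range(25):
            acc = pd.Series(rng.uniform(0, 1, 10), index=[f"E{i}" for i in range(1, 11)])
            w = location_weights(acc, meta, "E0")
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert (w >= 0).all()

    def test_all_zero_accuracies_fall_back_to_uniform(self):
        meta = _meta(["T", "A", "B"], ["s1", "s2", "s3"], ["X", "Y", "Z"])
        with pytest.warns(UserWarning, match="uniform"):
            w = location_weights(pd.Series({"A": 0.0, "B": 0.0}), meta, "T")
        assert np.allclose(w, 0.5)


def _stub_fit(g_frame):
    return SimpleNamespace(g_=g_frame)


class TestSelectionIndex:
    def _g(self, rng, envs=4, hybrids=30):
        return pd.DataFrame(
            rng.standard_normal((envs, hybrids)),
            index=[f"E{i}" for i in range(envs)],
            columns=[f"H{j}" for j in range(hybrids)],
        )

    def test_degenerate_weights_reduce_to_single_environment(self, rng):
        g = self._g(rng)
        fit = _stub_fit(g)
        w = pd.Series({"E0": 1.0, "E1": 0.0, "E2": 0.0, "E3": 0.0})
        u = selection_index(fit, w, sigma_k=2.0, hybrids_target=g.columns)
        raw = g.loc["E0"].to_numpy()
        expected = 2.0 * (raw - raw.mean()) / raw.std()
        assert np.allclose(u.to_numpy(), expected, atol=1e-12)

    def test_output_sd_equals_sigma_k(self, rng):
        g = self._g(rng)
        fit = _stub_fit(g)
        w = pd.Series(0.25, index=g.index)
        u = selection_index(fit, w, sigma_k=1.37, hybrids_target=g.columns)
        assert u.to_numpy().std() == pytest.approx(1.37, abs=1e-8)
        assert u.mean() == pytest.approx(0.0, abs=1e-8)

    def test_invariant_to_environment_level_shifts(self, rng):
        g = self._g(rng)
        w = pd.Series(0.25, index=g.index)
        u1 = selection_index(_stub_fit(g), w, 1.0, g.columns)
        g2 = g.copy()
        g2.loc["E1"] += 42.0
        u2 = selection_index(_stub_fit(g2), w, 1.0, g.columns)
        assert np.allclose(u1, u2, atol=1e-8)

    def test_zero_variance_index_rejected(self):
        g = pd.DataFrame(np.ones((2, 5)), index=["E0", "E1"],
                         columns=[f"H{j}" for j in range(5)])
        w = pd.Series({"E0": 0.5, "E1": 0.5})
        with pytest.raises(ValueError, match="zero variance"):
            selection_index(_stub_fit(g), w, 1.0, g.columns)


class TestModelB:
    def test_prediction_moments_by_construction(self, rng):
        hybrids = [f"H{j}" for j in range(25)]
        merit = pd.DataFrame(
            rng.standard_normal((2, 25)), index=["T1", "T2"], columns=hybrids
        )
        merit = merit.sub(merit.mean(axis=1), axis=0)
        merit = merit.div(merit.to_numpy().std(axis=1), axis=0)
        merit.loc["T1"] *= 1.5
        merit.loc["T2"] *= 0.9
        result = SelectionIndexResult(
            weights=pd.DataFrame(),
            sigma=pd.Series({"T1": 1.5, "T2": 0.9}),
            merit=merit,
        )
        template = pd.DataFrame(
            {"env_id": ["T1"] * 25 + ["T2"] * 25, "hybrid": hybrids * 2}
        )
        means = pd.Series({"T1": 10.0, "T2": 8.0})
        preds = model_b_predictions(means, result, template)
        by_env = preds.groupby("env_id")["yield_mg_ha"]
        assert by_env.mean()["T1"] == pytest.approx(10.0, abs=1e-8)
        assert by_env.mean()["T2"] == pytest.approx(8.0, abs=1e-8)
        assert by_env.apply(lambda s: s.to_numpy().std())["T1"] == pytest.approx(1.5, abs=1e-8)

    def test_missing_coverage_raises(self, rng):
        merit = pd.DataFrame(
            rng.standard_normal((1, 3)), index=["T1"], columns=["H0", "H1", "H2"]
        )
        result = SelectionIndexResult(pd.DataFrame(), pd.Series({"T1": 1.0}), merit)
        template = pd.DataFrame({"env_id": ["T1"], "hybrid": ["H9"]})
        with pytest.raises(KeyError, match="H9"):
            model_b_predictions(pd.Series({"T1": 9.0}), result, template)


class TestEnsemble:
    def _pred(self, rng, n=40):
        return pd.DataFrame(
            {
                "env_id": np.repeat(["A", "B"], n // 2),
                "hybrid": [f"H{j}" for j in range(n)],
                "yield_mg_ha": rng.normal(9, 2, n),
            }
        )

    def test_identity_cases(self, rng):
        p = self._pred(rng)
        assert np.allclose(
            ensemble_average([p])["yield_mg_ha"], p["yield_mg_ha"]
        )
        assert np.allclose(
            ensemble_average([p, p])["yield_mg_ha"], p["yield_mg_ha"]
        )

    def test_coverage_mismatch_listed(self, rng):
        p = self._pred(rng)
        q = p.iloc[:-1]
        with pytest.raises(ValueError, match="identical pairs"):
            ensemble_average([p, q])

    def test_per_environment_rmse_convexity(self, rng):
        """RMSE of the member mean never exceeds the mean of member RMSEs."""
        from gxepred import score

        for _ in range(100):
            truth = self._pred(rng)
            members = []
            for _ in range(3):
                m = truth.copy()
                m["yield_mg_ha"] = m["yield_mg_ha"] + rng.normal(0, 1.5, len(m))
                members.append(m)
            ens = ensemble_average(members)
            rep_ens = score(ens, truth).per_env["rmse"]
            member_rmse = [score(m, truth).per_env["rmse"] for m in members]
            mean_member = pd.concat(member_rmse, axis=1).mean(axis=1)
            assert (rep_ens <= mean_member + 1e-12).all()
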