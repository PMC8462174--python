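"""Distance-based linear model engine and the two-stage selection protocol.

Ordinary least squares (numpy lstsq) is the independent oracle: for a
univariate response under Euclidean distance the trace-based R^2 must
equal the OLS R^2.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfnet import (RunConfig, SampleMatrix, ValidationError, adjusted_r2,
                   expand_transforms, fit_r2, forward_select, gower_center,
                   permutation_p, response_gram, run_two_stage)
from mfnet.distlm import PredictorColumn, center
from mfnet.traitnet import ClusterAbundanceTable


def ols_r2(y, X):
    Xc = np.atleast_2d(X.T).T - np.atleast_2d(X.T).T.mean(axis=0)
    yc = y - y.mean()
    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    return float((Xc @ beta) @ yc / (yc @ yc))


def col(name, values, transform="raw"):
    return PredictorColumn(name, transform, center(np.asarray(values, float)))


class TestGowerCenter:
    def test_two_point_example(self):
        G = response_gram(np.array([0.0, 1.0]))
        assert np.allclose(G.G, [[0.25, -0.25], [-0.25, 0.25]], atol=1e-15)
        assert G.total_ss == pytest.approx(0.5)

    def test_zero_distance_matrix(self):
        G = gower_center(np.zeros((4, 4)))
        assert G.total_ss == 0.0 and np.allclose(G.G, 0.0)

    def test_trace_equals_sum_of_squared_deviations(self):
        y = np.random.default_rng(0).normal(size=50)
        G = response_gram(y)
        assert G.total_ss == pytest.approx((50 - 1) * y.var(ddof=1), rel=1e-12)

    def test_row_sums_vanish(self):
        y = np.random.default_rng(1).normal(size=20)
        G = response_gram(y)
        assert np.abs(G.G.sum(axis=0)).max() < 1e-9 * 20

    def test_asymmetric_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValidationError, match="symmetric"):
            gower_center(D)

    def test_negative_rejected(self):
        D = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValidationError):
            gower_center(D)


class TestFitR2:
    def test_exact_linear_relation_gives_one(self):
        x = np.arange(10.0)
        G = response_gram(2 * x)
        r2, _ = fit_r2(G, [col("x", x)])
        assert r2 == pytest.approx(1.0, abs=1e-10)

    def test_constant_column_is_rank_error(self):
        G = response_gram(np.arange(6.0))
        with pytest.raises(ValidationError, match="collinear.*c\\[raw\\]"):
            fit_r2(G, [col("c", np.ones(6))])

    def test_constant_response_is_error(self):
        G = response_gram(np.ones(6))
        with pytest.raises(ValidationError, match="constant response"):
            fit_r2(G, [col("x", np.arange(6.0))])

    def test_matches_ols_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            y = rng.normal(size=50)
            X = rng.normal(size=(50, 3))
            G = response_gram(y)
            r2, F = fit_r2(G, [col(f"x{i}", X[:, i]) for i in range(3)])
            assert abs(r2 - ols_r2(y, X)) < 1e-8
            # classical F statistic agrees too
            f_ols = (r2 / 3) / ((1 - r2) / (50 - 3 - 1))
            assert F == pytest.approx(f_ols, rel=1e-8)

    def test_monotone_in_added_columns(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=30)
        X = rng.normal(size=(30, 4))
        G = response_gram(y)
        r2s = [fit_r2(G, [col(f"x{i}", X[:, i]) for i in range(m)])[0]
               for m in range(1, 5)]
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))


class TestAdjustedR2:
    def test_perfect_fit_stays_one(self):
        assert adjusted_r2(1.0, 49, 3) == 1.0

    def test_closed_form_values(self):
        assert adjusted_r2(0.0, 49, 1) == pytest.approx(1 - 48 / 47)
        assert adjusted_r2(0.5, 49, 1) == pytest.approx(1 - 0.5 * 48 / 47)

    def test_never_exceeds_r2(self):
        assert adjusted_r2(0.3, 20, 4) <= 0.3

    def test_undefined_small_n(self):
        with pytest.raises(ValidationError):
            adjusted_r2(0.5, 5, 4)


class TestPermutation:
    def test_self_regression_gives_minimum_p(self):
        y = np.random.default_rng(0).normal(size=20)
        G = response_gram(y)
        p = permutation_p(G, [col("y", y)], n_perm=99, seed=0)
        assert p == pytest.approx(1 / 100)

    def test_determinism_same_seed(self):
        rng = np.random.default_rng(1)
        y, x = rng.normal(size=25), rng.normal(size=25)
        G = response_gram(y)
        p1 = permutation_p(G, [col("x", x)], n_perm=199, seed=5)
        p2 = permutation_p(G, [col("x", x)], n_perm=199, seed=5)
        assert p1 == p2

    def test_strong_effect_detected_with_forced_nuisance(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=40)
        x = rng.normal(size=40)
        y = z + 2 * x + 0.1 * rng.normal(size=40)
        G = response_gram(y)
        p = permutation_p(G, [col("x", x)], X_forced=[col("z", z)],
                          n_perm=199, seed=0)
        assert p <= 0.01

    def test_null_effect_given_forced_signal(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=40)
        y = z + 0.5 * rng.normal(size=40)
        noise = rng.normal(size=40)
        G = response_gram(y)
        p = permutation_p(G, [col("n", noise)], X_forced=[col("z", z)],
                          n_perm=199, seed=0)
        assert p > 0.05


class TestExpandTransforms:
    def make_env(self, values, names=None):
        values = np.asarray(values, float)
        names = names or [f"v{i}" for i in range(values.shape[1])]
        samples = [f"s{i}" for i in range(values.shape[0])]
        return SampleMatrix(samples, names, values, "environment")

    def test_three_columns_per_base(self):
        env = self.make_env(np.random.default_rng(0).random((10, 4)))
        cols = expand_transforms(env, "square")
        assert len(cols) == 12
        assert {c.transform for c in cols} == {"raw", "square", "log10p1"}

    def test_sqrt_family(self):
        env = self.make_env(np.random.default_rng(0).random((10, 1)))
        cols = expand_transforms(env, "sqrt")
        assert {c.transform for c in cols} == {"raw", "sqrt", "log10p1"}

    def test_log_values_before_centering(self):
        env = self.make_env([[0.0], [3.0], [9.0]])
        (logcol,) = [c for c in expand_transforms(env, "square")
                     if c.transform == "log10p1"]
        uncentred = logcol.values - logcol.values.min()
        assert np.allclose(uncentred, [0.0, 0.60206, 1.0], atol=1e-5)

    def test_constant_base_excluded_with_warning(self, caplog):
        env = self.make_env(np.column_stack([np.ones(5), np.arange(5.0)]),
                            names=["const", "ok"])
        with caplog.at_level("WARNING", logger="mfnet"):
            cols = expand_transforms(env, "square")
        assert {c.base_variable for c in cols} == {"ok"}
        assert "const" in caplog.text

    def test_negative_values_rejected_by_name(self):
        env = self.make_env([[-1.0], [2.0]], names=["depth"])
        with pytest.raises(ValidationError, match="depth"):
            expand_transforms(env, "square")

    def test_columns_are_centred(self):
        env = self.make_env(np.random.default_rng(1).random((20, 2)))
        for c in expand_transforms(env, "square"):
            assert abs(c.values.mean()) < 1e-12


def orthonormal_design(n, k, seed=0):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(n, k + 1)))
    q = q - q.mean(axis=0)
    q, _ = np.linalg.qr(q)
    return q[:, :k]


class TestForwardSelect:
    def test_orthogonal_candidates_selected_strongest_first(self):
        n = 100
        B = orthonormal_design(n, 3)
        y = np.sqrt(0.5) * B[:, 0] + np.sqrt(0.3) * B[:, 1] + np.sqrt(0.2) * B[:, 2]
        G = response_gram(y)
        cands = [col("a", B[:, 0]), col("b", B[:, 1])]
        steps = forward_select(G, cands)
        assert [s.column.base_variable for s in steps] == ["a", "b"]
        assert steps[0].delta_r2 == pytest.approx(0.5, abs=1e-9)
        assert steps[1].delta_r2 == pytest.approx(0.3, abs=1e-9)
        # oracle: of both one-step orders, greedy picked the higher adj R2
        r2a = adjusted_r2(fit_r2(G, [cands[0]])[0], n, 1)
        r2b = adjusted_r2(fit_r2(G, [cands[1]])[0], n, 1)
        assert steps[0].adj_r2_after == pytest.approx(max(r2a, r2b), abs=1e-12)

    def test_pure_noise_may_stop_empty(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        G = response_gram(y)
        # candidates orthogonal to y contribute nothing
        q = orthonormal_design(30, 1, seed=1)
        resid = q[:, 0] - (q[:, 0] @ center(y)) / (center(y) @ center(y)) * center(y)
        steps = forward_select(G, [col("noise", resid)])
        assert steps == []

    def test_strict_mode_blocks_log_after_raw(self):
        rng = np.random.default_rng(5)
        x = rng.random(60) * 10
        z = rng.random(60)
        y = x + np.log10(x + 1) * 3 + 0.01 * rng.normal(size=60)
        G = response_gram(y)
        cands = [col("x", x, "raw"), col("x", np.log10(x + 1), "log10p1"),
                 col("x", x * x, "square"), col("z", z, "raw")]
        steps = forward_select(G, cands, constraint="strict")
        kinds = [(s.column.base_variable, s.column.transform) for s in steps]
        has_log = ("x", "log10p1") in kinds
        has_power = any(k in kinds for k in [("x", "raw"), ("x", "square")])
        assert not (has_log and has_power)
        # lenient mode may combine them
        steps_l = forward_select(G, cands, constraint="lenient")
        kinds_l = [(s.column.base_variable, s.column.transform) for s in steps_l]
        assert ("x", "log10p1") in kinds_l and ("x", "raw") in kinds_l

    def test_sequential_additivity(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=40)
        X = rng.normal(size=(40, 5)) + 0.5 * y[:, None]
        G = response_gram(y)
        cands = [col(f"x{i}", X[:, i]) for i in range(5)]
        steps = forward_select(G, cands)
        assert len(steps) >= 1
        full_r2 = fit_r2(G, [s.column for s in steps])[0]
        assert sum(s.delta_r2 for s in steps) == pytest.approx(full_r2, abs=1e-12)
        assert all(s.delta_r2 >= 0 for s in steps)

    def test_stopping_point_beats_any_single_addition(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=35)
        X = rng.normal(size=(35, 6))
        X[:, 0] += y
        G = response_gram(y)
        cands = [col(f"x{i}", X[:, i]) for i in range(6)]
        steps = forward_select(G, cands)
        model = [s.column for s in steps]
        stop_adj = adjusted_r2(fit_r2(G, model)[0], 35, len(model))
        chosen = {s.column.label for s in steps}
        for c in cands:
            if c.label in chosen:
                continue
            adj = adjusted_r2(fit_r2(G, model + [c])[0], 35, len(model) + 1)
            assert adj <= stop_adj + 1e-12


def make_tables(n=30, seed=0):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n)]
    cl = SampleMatrix(samples, ["cA", "cB"], rng.random((n, 2)) * 10, "abundance")
    env = SampleMatrix(samples, ["mud"], rng.random((n, 1)) * 40, "environment")
    return samples, cl, env


class TestTwoStage:
    def test_zero_noise_recovers_exact_model(self):
        samples, cl, env = make_tables(n=30, seed=1)
        y = 2 * cl.column("cA") + cl.column("cB")
        fns = SampleMatrix(samples, ["f"], y[:, None], "function")
        cfg = RunConfig(n_permutations=99, seed=0)
        rep = run_two_stage(fns, cl, env, cfg)
        res = rep.results["f"]
        assert res.r2_traits == pytest.approx(1.0, abs=1e-8)
        assert res.r2_env_added == pytest.approx(0.0, abs=1e-9)
        bases = {s.column.base_variable for s in res.steps}
        assert bases == {"cA", "cB"}

    def test_stage_totals_identity(self):
        samples, cl, env = make_tables(n=40, seed=2)
        rng = np.random.default_rng(3)
        y = (0.8 * (cl.column("cA") - cl.column("cA").mean()) / cl.column("cA").std()
             + 0.7 * (env.column("mud") - env.column("mud").mean()) / env.column("mud").std()
             + rng.normal(size=40))
        fns = SampleMatrix(samples, ["f"], y[:, None], "function")
        rep = run_two_stage(fns, cl, env, RunConfig(n_permutations=99, seed=0))
        res = rep.results["f"]
        assert res.r2_total == pytest.approx(res.r2_traits + res.r2_env_added, abs=1e-12)
        cells = sum(s.delta_r2 for s in res.steps)
        assert cells == pytest.approx(res.r2_total, abs=1e-12)

    def test_sample_mismatch_is_error(self):
        samples, cl, env = make_tables()
        fns = SampleMatrix([s + "x" for s in samples], ["f"],
                           np.random.default_rng(0).random((30, 1)), "function")
        with pytest.raises(ValidationError, match="sample ids"):
            run_two_stage(fns, cl, env, RunConfig(n_permutations=1))

    def test_report_json_roundtrip(self, tmp_path):
        samples, cl, env = make_tables(n=30, seed=4)
        y = cl.column("cA") + np.random.default_rng(5).normal(size=30)
        fns = SampleMatrix(samples, ["f"], y[:, None], "function")
        rep = run_two_stage(fns, cl, env, RunConfig(n_permutations=99, seed=0))
        rep.to_json(tmp_path / "r.json")
        from mfnet.distlm import DistLMReport
        back = DistLMReport.from_json(tmp_path / "r.json")
        assert back.results["f"].r2_total == rep.results["f"].r2_total
        assert [s.to_dict() for s in back.results["f"].steps] == \
               [s.to_dict() for s in rep.results["f"].steps]

    def test_table_export_footnotes(self):
        samples, cl, env = make_tables(n=40, seed=6)
        y = cl.column("cA") ** 2 + np.random.default_rng(7).normal(size=40, scale=5)
        fns = SampleMatrix(samples, ["f"], y[:, None], "function")
        rep = run_two_stage(fns, cl, env, RunConfig(n_permutations=99, seed=0))
        table = rep.to_table()
        assert "(C) Total" in table.index
        assert list(table.columns) == ["f"]


@given(st.integers(0, 10_000))
@settings(deadline=None, derandomize=True, max_examples=25)
def test_distlm_equals_ols_property(seed):
    rng = np.random.default_rng(seed)
    n, m = 25, rng.integers(1, 4)
    y = rng.normal(size=n)
    X = rng.normal(size=(n, m))
    G = response_gram(y)
    r2, _ = fit_r2(G, [col(f"x{i}", X[:, i]) for i in range(m)])
    assert abs(r2 - ols_r2(y, X)) < 1e-8
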