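import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from volatrank import (
    AttractivenessRanking,
    ChemIndexModel,
    FitError,
    ProfileMatrix,
    SynthConfig,
    VolatileProfile,
    chem_index,
    estimate_rank,
    generate_profiles,
    origin_least_squares,
    pattern_search,
)
from volatrank.chemindex import (
    multiple_regression_slopes,
    results_from_frame,
    results_to_frame,
)


def brute_force_origin_fit(y, x):
    """Independent oracle: solve the normal equation via lstsq, then apply the
    spreadsheet no-intercept conventions with plain Python sums."""
    X = np.asarray(x, dtype=float).reshape(-1, 1)
    m = float(np.linalg.lstsq(X, np.asarray(y, dtype=float), rcond=None)[0][0])
    n = len(y)
    sse = sum((yi - m * xi) ** 2 for yi, xi in zip(y, x))
    sxx = sum(xi * xi for xi in x)
    syy = sum(yi * yi for yi in y)
    se = math.sqrt((sse / (n - 1)) / sxx)
    r2 = 1.0 - sse / syy if syy > 0 else 0.0
    return m, se, r2


finite_vec = st.lists(
    st.floats(min_value=-50, max_value=50), min_size=2, max_size=12
)


class TestOriginLeastSquares:
    def test_identity_fit(self):
        s = origin_least_squares([1, 2, 3], [1, 2, 3])
        assert (s.m, s.se_m, s.r2) == (1.0, 0.0, 1.0)

    def test_exact_scaling(self):
        s = origin_least_squares([2, 4, 6], [1, 2, 3])
        assert s.m == pytest.approx(2.0)
        assert s.se_m == pytest.approx(0.0, abs=1e-12)
        assert s.r2 == pytest.approx(1.0)

    def test_derived_example(self):
        # exact fractions: m = 17/14, se = sqrt(5/392), r2 = 289/294
        s = origin_least_squares([1, 2, 4], [1, 2, 3])
        assert s.m == pytest.approx(17 / 14, abs=1e-12)
        assert s.se_m == pytest.approx(math.sqrt(5 / 392), abs=1e-12)
        assert s.r2 == pytest.approx(289 / 294, abs=1e-12)

    def test_x_all_zero_errors(self):
        with pytest.raises(FitError, match="all zeros"):
            origin_least_squares([1, 2], [0, 0])

    def test_y_all_zero_convention(self):
        with pytest.warns(UserWarning, match="r2 set to 0"):
            s = origin_least_squares([0, 0], [1, 2])
        assert s.m == 0.0 and s.r2 == 0.0

    def test_length_mismatch(self):
        with pytest.raises(FitError, match="mismatch"):
            origin_least_squares([1, 2, 3], [1, 2])

    @given(finite_vec, st.randoms(use_true_random=False))
    @settings(max_examples=150)
    def test_agrees_with_brute_force(self, x, rng):
        if sum(v * v for v in x) < 1e-6:  # ill-conditioned: slope explodes
            return
        y = [rng.uniform(-50, 50) for _ in x]
        s = origin_least_squares(y, x)
        m, se, r2 = brute_force_origin_fit(y, x)
        assert s.m == pytest.approx(m, rel=1e-10, abs=1e-10)
        assert s.se_m == pytest.approx(se, rel=1e-10, abs=1e-10)
        if sum(v * v for v in y) > 1e-12:
            assert s.r2 == pytest.approx(r2, rel=1e-10, abs=1e-10)

    def test_grid_refinement_minimizer(self):
        # the fitted slope minimizes the residual sum of squares
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.uniform(0.1, 10, size=8)
            y = rng.uniform(0.1, 10, size=8)
            m = origin_least_squares(y, x).m
            grid = np.linspace(m - 1, m + 1, 20001)
            sse = ((y[:, None] - grid[None, :] * x[:, None]) ** 2).sum(axis=0)
            best = grid[int(np.argmin(sse))]
            assert abs(best - m) <= 2e-4  # grid resolution


class TestChemIndex:
    def test_self_similarity_is_exact_zero(self):
        x = [3.1, 0.2, 18.0, 4.4]
        assert chem_index(x, x) == 0.0

    def test_pure_scaling_penalty(self):
        assert chem_index([2, 4, 6], [1, 2, 3]) == pytest.approx(1.0, abs=1e-12)

    def test_derived_sum(self):
        expected = 3 / 14 + 5 / 294 + math.sqrt(5 / 392)
        assert chem_index([1, 2, 4], [1, 2, 3]) == pytest.approx(expected, abs=1e-12)
        assert chem_index([1, 2, 4], [1, 2, 3]) == pytest.approx(0.34424, abs=1e-5)

    @given(finite_vec, st.randoms(use_true_random=False))
    @settings(max_examples=100)
    def test_permutation_invariance(self, x, rng):
        if sum(v * v for v in x) <= 0:
            return
        y = [rng.uniform(-50, 50) for _ in x]
        perm = list(range(len(x)))
        rng.shuffle(perm)
        a = chem_index(y, x)
        b = chem_index([y[i] for i in perm], [x[i] for i in perm])
        assert b == pytest.approx(a, rel=1e-9, abs=1e-12)

    @given(
        st.floats(min_value=0.01, max_value=10),
        st.lists(st.floats(min_value=0.1, max_value=50), min_size=3, max_size=10),
    )
    @settings(max_examples=100)
    def test_scaling_law(self, c, x):
        got = chem_index([c * v for v in x], x)
        assert got == pytest.approx(abs(c - 1), abs=1e-10)


def _model(n_benchmarks=3, panel=("a", "b", "c")):
    bench = ProfileMatrix(
        pd.DataFrame(
            [[60.0, 30.0, 10.0], [40.0, 40.0, 20.0], [20.0, 30.0, 50.0]],
            index=["X", "Y", "Z"],
            columns=list(panel),
        )
    )
    return ChemIndexModel(list(panel), bench, {"X": 1, "Y": 2, "Z": 3})


class TestChemIndexModel:
    def test_rank_bijection_enforced(self):
        bench = ProfileMatrix(
            pd.DataFrame([[1.0], [2.0]], index=["X", "Y"], columns=["a"])
        )
        with pytest.raises(FitError, match="bijection"):
            ChemIndexModel(["a"], bench, {"X": 1, "Y": 3})

    def test_panel_column_mismatch(self):
        bench = ProfileMatrix(pd.DataFrame([[1.0]], index=["X"], columns=["a"]))
        with pytest.raises(FitError, match="panel"):
            ChemIndexModel(["b"], bench, {"X": 1})

    def test_save_load_round_trip(self, tmp_path):
        model = _model()
        model.save(tmp_path / "model")
        again = ChemIndexModel.load(tmp_path / "model")
        assert again.panel == model.panel
        assert again.benchmark_ranks == model.benchmark_ranks
        pd.testing.assert_frame_equal(again.benchmarks.data, model.benchmarks.data)

    def test_build_aligns_and_ranks(self, noiseless, noiseless_ranking):
        _, m, truth = noiseless
        model = ChemIndexModel.build(m, noiseless_ranking, truth.planted_panel)
        assert model.panel == truth.planted_panel
        assert model.rank_of(truth.true_ranking[0]) == 1


class TestEstimateRank:
    def test_exact_match_gets_benchmark_rank(self):
        model = _model()
        blind = VolatileProfile("blind", {"a": 20.0, "b": 30.0, "c": 50.0})
        result = estimate_rank(blind, model)
        assert result.chem_index == 0.0
        assert result.best_benchmark == "Z"
        assert result.estimated_rank == 3
        assert result.estimated_score == 1

    def test_tie_resolved_toward_better_rank_and_flagged(self):
        bench = ProfileMatrix(
            pd.DataFrame(
                [[10.0, 20.0], [20.0, 10.0]], index=["X", "Y"], columns=["a", "b"]
            )
        )
        model = ChemIndexModel(["a", "b"], bench, {"Y": 1, "X": 2})
        blind = VolatileProfile("blind", {"a": 15.0, "b": 15.0})
        with pytest.warns(UserWarning, match="tie"):
            result = estimate_rank(blind, model)
        assert result.tie
        assert result.estimated_rank == 1

    def test_missing_panel_compound_zero_filled(self):
        model = _model()
        blind = VolatileProfile("blind", {"a": 60.0, "b": 30.0})
        result = estimate_rank(blind, model)
        assert result.zero_filled == ["c"]

    def test_blind_between_ranks_4_and_5(self):
        # simulation oracle: blind planted midway between benchmark ranks 4
        # and 5 at low noise must land on one of them in >= 95% of replicates
        hits = 0
        n_rep = 200
        for s in range(n_rep):
            cfg = SynthConfig(noise_sd=0.02, n_blinds=1, seed=5000 + s)
            _, probe = generate_profiles(cfg.replace(n_blinds=0, blind_latents=None))
            mid = 0.5 * (
                probe.latent[probe.true_ranking[3]] + probe.latent[probe.true_ranking[4]]
            )
            m, truth = generate_profiles(cfg.replace(blind_latents=(mid,)))
            ranking = AttractivenessRanking.from_ranks(
                {p: i + 1 for i, p in enumerate(truth.true_ranking)}
            )
            bench = m.restrict_products(truth.benchmarks)
            panel = pattern_search(bench, truth.seeds, top_k=25, min_r=0.5)
            model = ChemIndexModel.build(bench, ranking, panel.panel)
            result = estimate_rank(m.profile("B01"), model)
            hits += result.estimated_rank in (4, 5)
        assert hits / n_rep >= 0.95

    def test_noiseless_rank_recovery_is_exact(self, noiseless, noiseless_ranking):
        _, m, truth = noiseless
        model = ChemIndexModel.build(m, noiseless_ranking, truth.planted_panel)
        for product in truth.benchmarks:
            result = estimate_rank(m.profile(product), model)
            assert result.best_benchmark == product
            assert result.chem_index == pytest.approx(0.0, abs=1e-9)

    def test_results_frame_round_trip(self):
        model = _model()
        blind = VolatileProfile("blind", {"a": 25.0, "b": 35.0, "c": 40.0})
        results = {"blind": estimate_rank(blind, model)}
        frame = results_to_frame(results)
        again = results_from_frame(frame)
        assert again["blind"].best_benchmark == results["blind"].best_benchmark
        assert again["blind"].estimated_rank == results["blind"].estimated_rank
        assert again["blind"].index_against_rank(1) == pytest.approx(
            results["blind"].index_against_rank(1)
        )

    def test_multiple_regression_variant_runs(self):
        model = _model()
        blind = VolatileProfile("blind", {"a": 40.0, "b": 40.0, "c": 20.0})
        coefs = multiple_regression_slopes(blind, model)
        assert set(coefs) == {"X", "Y", "Z"}
        # exact benchmark membership puts all weight on that benchmark
        exact = multiple_regression_slopes(
            VolatileProfile("b2", {"a": 60.0, "b": 30.0, "c": 10.0}), model
        )
        assert exact["X"] == pytest.approx(1.0, abs=1e-9)
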