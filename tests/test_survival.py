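import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexsurv.io import ValidationError
from coexsurv.survival import (
    cox_screen,
    fit_cox,
    median_split_logrank,
    permutation_group_enrichment,
    reproducible_screen,
    screen_stage_groups,
)
from coexsurv.synthetic import SurvivalSimSpec, simulate_survival_cohort
from oracles import grid_cox_beta


def _random_dataset(rng, n=10, beta=0.5):
    x = rng.standard_normal(n)
    t = rng.exponential(1.0 / (0.1 * np.exp(beta * x)))
    c = rng.exponential(30.0, n)
    return np.minimum(t, c), (t <= c).astype(int), x


class TestFitCox:
    def test_constant_expression_is_degenerate(self):
        res = fit_cox(np.arange(1.0, 7), np.ones(6, int), np.full(6, 3.3))
        assert res.degenerate and res.beta == 0.0 and res.p_value == 1.0

    def test_zero_events_rejected(self):
        with pytest.raises(ValidationError):
            fit_cox(np.arange(1.0, 5), np.zeros(4, int), np.arange(4.0))

    def test_six_sample_grid_oracle(self):
        time = np.arange(1.0, 7)
        event = np.ones(6, int)
        x = np.array([1.0, 0, 1, 0, 1, 0])
        res = fit_cox(time, event, x)
        assert abs(res.beta - grid_cox_beta(x, time, event)) < 5e-4

    def test_random_small_datasets_match_grid_oracle(self):
        rng = np.random.default_rng(50)
        for _ in range(10):
            time, event, x = _random_dataset(rng, n=int(rng.integers(6, 13)))
            if event.sum() < 2:
                continue
            res = fit_cox(time, event, x)
            if not res.converged:
                continue
            assert abs(res.beta - grid_cox_beta(x, time, event)) < 5e-4

    def test_agrees_with_lifelines(self):
        """Independent implementation cross-check (Breslow ties, Wald SE)."""
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(51)
        time, event, x = _random_dataset(rng, n=120, beta=0.6)
        res = fit_cox(time, event, x)
        cph = lifelines.CoxPHFitter().fit(
            pd.DataFrame({"T": time, "E": event, "x": x}), "T", "E"
        )
        assert res.beta == pytest.approx(cph.params_["x"], abs=1e-4)
        assert res.se == pytest.approx(cph.standard_errors_["x"], abs=1e-4)

    def test_covariate_adjustment_changes_nothing_under_independence(self):
        rng = np.random.default_rng(52)
        time, event, x = _random_dataset(rng, n=200, beta=0.7)
        cov = rng.standard_normal((200, 2))
        plain = fit_cox(time, event, x)
        adjusted = fit_cox(time, event, x, covariates=cov)
        assert adjusted.beta == pytest.approx(plain.beta, abs=0.1)

    def test_separation_flagged_not_silently_reported(self):
        # expression perfectly orders the event times: partial likelihood diverges
        time = np.arange(1.0, 11)
        x = -time
        res = fit_cox(time, np.ones(10, int), x)
        assert not res.converged


class TestMedianSplitLogrank:
    def test_identical_group_survival_gives_null(self):
        time = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        x = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
        _, chi2, p = median_split_logrank(time, event, x)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_tabulated_eight_sample_dataset(self):
        # high group (x > median) = samples with x=1: times 1, 2 (events), 5 (censored), 6 (event)
        time = np.array([1.0, 2, 5, 6, 3, 4, 7, 8])
        event = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        x = np.array([1.0, 1, 1, 1, 0, 0, 0, 0])
        # by-hand O-E tabulation over event times {1,2,3,6,7,8}
        # (censored at t=4 and t=5 leave the risk set before t=6):
        # t=1: n=8 n1=4 d=1 d1=1 -> E=1/2, V=1/4
        # t=2: n=7 n1=3 d=1 d1=1 -> E=3/7, V=12/49
        # t=3: n=6 n1=2 d=1 d1=0 -> E=1/3, V=2/9
        # t=6: n=3 n1=1 d=1 d1=1 -> E=1/3, V=2/9
        # t=7: n=2 n1=0 d=1 d1=0 -> E=0,   V=0
        # t=8: n=1 n1=0 d=1 d1=0 -> E=0,   V=0
        O = 3.0
        E = 1 / 2 + 3 / 7 + 1 / 3 + 1 / 3
        V = 1 / 4 + 12 / 49 + 2 / 9 + 2 / 9
        _, chi2, p = median_split_logrank(time, event, x)
        assert chi2 == pytest.approx((O - E) ** 2 / V, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf((O - E) ** 2 / V, 1), rel=1e-12)

    def test_matches_lifelines(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(53)
        time, event, x = _random_dataset(rng, n=100, beta=1.0)
        g, chi2, p = median_split_logrank(time, event, x)
        ref = lifelines_stats.logrank_test(
            time[g == 1], time[g == 0], event[g == 1], event[g == 0]
        )
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(54)
        time, event, x = _random_dataset(rng, n=60, beta=0.8)
        _, chi2_a, _ = median_split_logrank(time, event, x)
        _, chi2_b, _ = median_split_logrank(time, event, np.exp(3 * x))
        assert chi2_a == pytest.approx(chi2_b, rel=1e-12)

    def test_constant_expression_rejected(self):
        with pytest.raises(ValidationError):
            median_split_logrank(np.arange(1.0, 5), np.ones(4, int), np.ones(4))

    def test_power_against_planted_effect(self):
        hits = 0
        for seed in range(20):
            spec = SurvivalSimSpec(n_samples=200, gene_betas={"g": 1.5},
                                   censor_rate=0.002, seed=seed)
            expr, clin = simulate_survival_cohort(spec)
            _, _, p = median_split_logrank(clin.time, clin.event, expr.data.loc["g"].to_numpy())
            hits += p < 0.05
        assert hits >= 18  # >= 90%

    def test_direction_consistent_with_cox_sign(self):
        """Planted beta > 0: high-expression group dies faster."""
        spec = SurvivalSimSpec(n_samples=400, gene_betas={"g": 1.0},
                               censor_rate=0.0, seed=60)
        expr, clin = simulate_survival_cohort(spec)
        x = expr.data.loc["g"].to_numpy()
        cox = fit_cox(clin.time, clin.event, x)
        g, chi2, p = median_split_logrank(clin.time, clin.event, x)
        assert cox.beta > 0
        assert np.median(clin.time[g == 1]) < np.median(clin.time[g == 0])


class TestReproducibleScreen:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["gene", "beta", "p_value"]).set_index("gene")

    @pytest.mark.parametrize(
        "disc, val, expected",
        [
            (("g", 0.5, 0.01), ("g", 0.3, 0.01), ["g"]),   # concordant & significant
            (("g", 0.5, 0.01), ("g", -0.3, 0.01), []),     # sign flip
            (("g", 0.5, 0.01), ("g", 0.3, 0.20), []),      # fails validation alpha
            (("g", 0.5, 0.20), ("g", 0.3, 0.01), []),      # not significant in discovery
        ],
    )
    def test_validation_rules(self, disc, val, expected):
        assert reproducible_screen(self._frame([disc]), self._frame([val])) == expected

    def test_sign_only_mode(self):
        disc = self._frame([("g", 0.5, 0.01)])
        val = self._frame([("g", 0.3, 0.20)])
        assert reproducible_screen(disc, val, sign_only=True) == ["g"]

    def test_gene_absent_from_validation_dropped(self):
        disc = self._frame([("g", 0.5, 0.01)])
        val = self._frame([("other", 0.3, 0.01)])
        assert reproducible_screen(disc, val) == []


class TestPermutationEnrichment:
    def test_group_equal_to_universe_gives_p_one(self):
        uni = [f"g{i}" for i in range(10)]
        p = permutation_group_enrichment(uni, uni[:4], uni, n_perm=100, rng=0)
        assert p == 1.0

    def test_matches_hypergeometric_tail(self):
        uni = [f"g{i}" for i in range(20)]
        group, sig = uni[:5], uni[:4]
        n_perm = 10000
        p = permutation_group_enrichment(group, sig, uni, n_perm=n_perm, rng=1)
        exact = stats.hypergeom.sf(3, 20, 4, 5)  # P(X >= 4)
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(p - exact) <= 3 * se + 1 / n_perm

    def test_reproducible_and_never_zero(self):
        uni = [f"g{i}" for i in range(50)]
        a = permutation_group_enrichment(uni[:10], uni[:10], uni, n_perm=500, rng=7)
        b = permutation_group_enrichment(uni[:10], uni[:10], uni, n_perm=500, rng=7)
        assert a == b > 0.0

    def test_group_larger_than_universe_rejected(self):
        with pytest.raises(ValidationError):
            permutation_group_enrichment(["a", "b"], ["a"], ["a"], n_perm=10, rng=0)


class TestScreens:
    def test_type_one_error_calibrated(self):
        """Wald p < 0.05 rate under a null screen stays near nominal."""
        spec = SurvivalSimSpec(n_samples=80, gene_betas={}, censor_rate=0.003, seed=70)
        expr, clin = simulate_survival_cohort(spec, extra_genes=400)
        screen = cox_screen(expr, clin)
        rate = (screen["p_value"] < 0.05).mean()
        assert 0.02 <= rate <= 0.08

    def test_stage_group_screen_finds_planted_group(self):
        genes = {f"E{i}" for i in range(12)} | {f"L{i}" for i in range(12)}
        betas = {f"E{i}": 0.9 for i in range(6)}
        import coexsurv.io as io_mod

        def cohort(seed, n):
            r = np.random.default_rng(seed)
            samples = [f"s{seed}_{i}" for i in range(n)]
            expr = io_mod.ExpressionMatrix(
                pd.DataFrame(r.standard_normal((len(genes), n)),
                             index=sorted(genes), columns=samples),
                axis_kind="patients",
            )
            return simulate_survival_cohort(
                SurvivalSimSpec(n_samples=n, gene_betas=betas, censor_rate=0.002, seed=seed),
                expression=expr,
            )
        d_expr, d_clin = cohort(1, 150)
        v_expr, v_clin = cohort(2, 300)
        res = screen_stage_groups(
            {"early": sorted(g for g in genes if g.startswith("E")),
             "late": sorted(g for g in genes if g.startswith("L"))},
            d_expr, d_clin, v_expr, v_clin, n_perm=2000, rng=3,
        )
        assert res["early"].enrichment_p < res["late"].enrichment_p
        assert len(res["early"].validated) >= 1
        for r in res.values():
            assert set(r.validated) <= set(r.discovery_significant) <= set(r.group_genes)
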