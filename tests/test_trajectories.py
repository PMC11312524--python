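"""Age-trajectory machinery: spline fits, selection, crossover, enrichment."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import comb
from scipy.stats import kstest

from cortexdev.datasets import ExpressionDataset, GeneSetCollection
from cortexdev.synth import ExpressionSimConfig, ModuleSpec, generate_expression_dataset
from cortexdev.trajectories import (
    AgeSplineModel,
    SplineBasis,
    _penalized_fit,
    benjamini_hochberg,
    celltype_enrichment,
    celltype_mean_trajectory,
    cross_dataset_overlap,
    crossover_age,
    peak_growth_age,
    select_age_genes,
)


@pytest.fixture(scope="module")
def ages():
    return np.random.default_rng(7).uniform(0.5, 72.0, 200)


class TestAgeSpline:
    def test_noiseless_linear_trend(self, ages):
        fit = AgeSplineModel(2.0 + 0.1 * ages, ages).fit()
        np.testing.assert_allclose(fit.curve, 2.0 + 0.1 * fit.age_grid, atol=1e-3)
        assert fit.p_smooth < 1e-6

    def test_constant_expression_degenerate(self, ages):
        fit = AgeSplineModel(np.full_like(ages, 3.0), ages).fit()
        assert fit.p_smooth > 0.99
        assert np.ptp(fit.curve) < 1e-9

    def test_derivative_consistent_with_curve(self, ages):
        fit = AgeSplineModel(np.sin(ages / 10.0), ages).fit()
        fd = np.gradient(fit.curve, fit.age_grid)
        # interior finite differences track the analytic B-spline derivative
        np.testing.assert_allclose(fd[5:-5], fit.derivative[5:-5], atol=5e-3)

    def test_constant_age_rank_deficient(self):
        with pytest.raises(ValueError):
            AgeSplineModel(np.arange(20.0), np.full(20, 12.0))

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            AgeSplineModel(np.arange(8.0), np.arange(8.0))

    def test_smooth_pvalue_matches_ols_f_test(self, ages, rng):
        """The exact smooth F-test must equal the statsmodels OLS
        nested-model comparison on the same design."""
        y = 0.05 * ages + rng.normal(0, 1, ages.size)
        basis = SplineBasis(ages, 5)
        Z = basis.design(ages)
        C = np.ones((ages.size, 1))
        p_mine = _penalized_fit(y[:, None], Z, C, basis.penalty, lam=0.0)["p"][0]
        full = sm.OLS(y, np.column_stack([C, Z])).fit()
        null = sm.OLS(y, C).fit()
        _, p_sm, _ = full.compare_f_test(null)
        assert p_mine == pytest.approx(p_sm, rel=1e-8)

    def test_penalized_solution_matches_dense_ridge(self, ages, rng):
        """Demmler-Reinsch path vs a naive dense penalized solve."""
        y = np.cos(ages / 15.0) + rng.normal(0, 0.2, ages.size)
        basis = SplineBasis(ages, 5)
        Z = basis.design(ages)
        C = np.ones((ages.size, 1))
        lam = 3.7
        fit = _penalized_fit(y[:, None], Z, C, basis.penalty, lam=lam)
        X = np.column_stack([C, Z])
        P = np.zeros((X.shape[1], X.shape[1]))
        P[1:, 1:] = basis.penalty
        beta = np.linalg.solve(X.T @ X + lam * P, X.T @ y)
        np.testing.assert_allclose(fit["coefs"][:, 0], beta[1:], atol=1e-8)

    def test_null_pvalues_uniform(self):
        """Smooth-term p-values on pure noise are uniform (KS at 1%)."""
        rng = np.random.default_rng(11)
        n, G = 150, 2000
        a = rng.uniform(0.5, 72.0, n)
        Y = rng.normal(size=(n, G))
        basis = SplineBasis(a, 5)
        p = _penalized_fit(Y, basis.design(a), np.ones((n, 1)), basis.penalty, 0.0)["p"]
        assert kstest(p, "uniform").pvalue > 0.01


class TestMixedDialect:
    def test_donor_random_intercept_fit(self):
        cfg = ExpressionSimConfig(
            dialect="rnaseq-log2rpkm",
            n_genes=12,
            modules={"oligodendrocyte": ModuleSpec(6, 0.06, 3.1)},
        )
        ds, _, truth = generate_expression_dataset(cfg, seed=2)
        table = select_age_genes(ds, alpha=0.05)
        planted = truth.index[truth.is_age_gene]
        nulls = truth.index[~truth.is_age_gene]
        assert table.loc[planted, "selected"].all()
        assert table.loc[nulls, "p"].min() > 1e-4


class TestSelection:
    def test_planted_trends_recovered(self):
        cfg = ExpressionSimConfig(
            n_genes=2000,
            modules={"oligodendrocyte": ModuleSpec(100, 0.03)},
            noise_sd=1.0,
        )
        ds, _, truth = generate_expression_dataset(cfg, seed=5)
        table = select_age_genes(ds, alpha=0.05)
        planted = truth.index[truth.is_age_gene]
        assert table.loc[planted, "selected"].sum() >= 95
        false_pos = table.selected & ~truth.is_age_gene
        assert false_pos.sum() <= 0.1 * max(int(table.selected.sum()), 1)

    def test_alpha_zero_selects_nothing(self):
        ds, _, _ = generate_expression_dataset(
            ExpressionSimConfig(n_genes=50, modules={"astrocyte": ModuleSpec(10, -0.03)}),
            seed=0,
        )
        assert select_age_genes(ds, alpha=0.0).selected.sum() == 0

    def test_fdr_monotone_and_dominates_p(self):
        ds, _, _ = generate_expression_dataset(
            ExpressionSimConfig(n_genes=100, modules={"microglia": ModuleSpec(20, -0.02)}),
            seed=1,
        )
        table = select_age_genes(ds)
        assert (table.p_fdr >= table.p - 1e-15).all()
        s = table.sort_values("p")
        assert s.p_fdr.is_monotonic_increasing


class TestBenjaminiHochberg:
    def test_hand_computed_example(self):
        """Ten p-values worked through the step-up rule by hand."""
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216])
        # adjusted_i = min_{j>=i} p_(j) * m / j
        expected = np.array(
            [0.01, 0.04, 0.084, 0.084, 0.084, 0.1, 0.105714285714, 0.216, 0.216, 0.216]
        )
        np.testing.assert_allclose(benjamini_hochberg(p), expected, rtol=1e-9)


class TestOverlap:
    def test_identities(self):
        assert cross_dataset_overlap({"a", "b"}, {"a", "b"}) == (2, 1.0)
        assert cross_dataset_overlap({"a", "b"}, {"c"}) == (0, 0.0)

    def test_study_arithmetic(self):
        a = {f"g{i}" for i in range(2057)}
        b = {f"g{i}" for i in range(467)} | {f"x{i}" for i in range(100)}
        count, frac = cross_dataset_overlap(a, b)
        assert count == 467
        assert frac == pytest.approx(0.227, abs=5e-4)

    def test_empty_first_set(self):
        with pytest.raises(ValueError):
            cross_dataset_overlap(set(), {"a"})


class TestCellTypeTrajectories:
    @pytest.fixture(scope="class")
    def small_ds(self):
        cfg = ExpressionSimConfig(
            n_genes=60,
            modules={
                "oligodendrocyte": ModuleSpec(20, 0.03),
                "astrocyte": ModuleSpec(20, -0.02),
            },
        )
        return generate_expression_dataset(cfg, seed=3)

    def test_single_gene_set_equals_gene_fit(self, small_ds):
        ds, _, _ = small_ds
        g = ds.genes[0]
        sets = GeneSetCollection({"solo": {g}}, frozenset(ds.genes))
        fit = celltype_mean_trajectory(ds, sets, mode="zscore")["solo"]
        x = ds.expression.loc[g].to_numpy(float)
        z = (x - x.mean()) / x.std()
        ref = AgeSplineModel(z, ds.ages).fit().centered()
        np.testing.assert_allclose(fit.curve, ref.curve, atol=1e-10)

    def test_duplicate_gene_equivalent_to_single(self, small_ds):
        ds, _, _ = small_ds
        g = ds.genes[0]
        ds2 = ExpressionDataset(
            pd.concat([ds.expression, ds.expression.loc[[g]].rename(index={g: "dup"})]),
            ds.samples,
            ds.dialect,
        )
        sets1 = GeneSetCollection({"s": {g}}, frozenset(ds2.genes))
        sets2 = GeneSetCollection({"s": {g, "dup"}}, frozenset(ds2.genes))
        a = celltype_mean_trajectory(ds2, sets1, mode="zscore")["s"]
        b = celltype_mean_trajectory(ds2, sets2, mode="zscore")["s"]
        np.testing.assert_allclose(a.curve, b.curve, atol=1e-10)

    def test_demeaned_curve_has_zero_grid_mean(self, small_ds):
        ds, sets, _ = small_ds
        fits = celltype_mean_trajectory(ds, sets, mode="demeaned")
        for fit in fits.values():
            assert abs(fit.curve.mean()) < 1e-9

    def test_missing_set_named_in_error(self, small_ds):
        ds, _, _ = small_ds
        sets = GeneSetCollection(
            {"ghost": {"NOPE1"}}, frozenset(ds.genes) | {"NOPE1"}
        )
        with pytest.raises(ValueError, match="ghost"):
            celltype_mean_trajectory(ds, sets)


class TestPeakGrowth:
    def test_logistic_inflection(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0.5, 30.0, 300)
        y = 1.0 / (1.0 + np.exp(-(a - 12.0) / 1.5))
        pg = peak_growth_age(AgeSplineModel(y, a).fit())
        assert pg.age == pytest.approx(12.0, abs=1.5)  # k=5 smooth resolution
        assert pg.growing and not pg.boundary

    def test_constant_derivative_tie_goes_young(self):
        from cortexdev.trajectories import AgeSplineResults

        grid = np.arange(8.0, 19.01, 0.1)
        fit = AgeSplineResults(
            grid, 1.0 + 0.1 * grid, np.full_like(grid, 0.1), 0.5, 1.0, 5, 0.0, 40
        )
        pg = peak_growth_age(fit)
        assert pg.age == pytest.approx(8.0)
        assert pg.boundary and pg.growing

    def test_decreasing_curve_flagged(self, ages):
        pg = peak_growth_age(AgeSplineModel(5.0 - 0.2 * ages, ages).fit())
        assert not pg.growing

    def test_level_mode(self, ages):
        fit = AgeSplineModel(-((ages - 30.0) ** 2), ages).fit()
        pg = peak_growth_age(fit, mode="level")
        assert pg.age == pytest.approx(30.0, abs=2.0)


class TestCrossover:
    def test_analytic_line_intersection(self, ages):
        fa = AgeSplineModel(1.0 + 0.1 * ages, ages).fit()
        fb = AgeSplineModel(3.0 - 0.1 * ages, ages).fit()
        res = crossover_age(fa, fb)
        assert res.age == pytest.approx(10.0, abs=0.01)
        assert res.leads_before == "b" and res.leads_after == "a"

    def test_parallel_curves_no_crossing(self, ages):
        fa = AgeSplineModel(1.0 + 0.1 * ages, ages).fit()
        fb = AgeSplineModel(2.0 + 0.1 * ages, ages).fit()
        assert crossover_age(fa, fb).age is None

    def test_grid_mismatch_rejected(self, ages):
        fa = AgeSplineModel(ages, ages).fit()
        other = np.linspace(0, 10, 50)
        fb = AgeSplineModel(other, other).fit()
        with pytest.raises(ValueError):
            crossover_age(fa, fb)


def hypergeom_tail_bruteforce(overlap, universe, set_size, n_draw):
    """Exhaustive tail sum of the hypergeometric pmf."""
    total = comb(universe, n_draw, exact=True)
    acc = 0
    for k in range(overlap, min(set_size, n_draw) + 1):
        acc += comb(set_size, k, exact=True) * comb(
            universe - set_size, n_draw - k, exact=True
        )
    return acc / total


class TestEnrichment:
    def make_sets(self, universe, named):
        return GeneSetCollection(named, frozenset(universe))

    def test_self_enrichment_extreme(self):
        universe = {f"g{i}" for i in range(1000)}
        age = {f"g{i}" for i in range(40)}
        sets = self.make_sets(universe, {"hit": age})
        table = celltype_enrichment(age, sets)
        assert table.loc["hit", "p"] < 1e-10

    @pytest.mark.parametrize(
        "universe,set_size,n_draw,overlap",
        [(100, 20, 10, 8), (150, 30, 25, 10), (200, 50, 40, 5), (60, 10, 10, 2)],
    )
    def test_matches_bruteforce_tail(self, universe, set_size, n_draw, overlap):
        u = [f"g{i}" for i in range(universe)]
        s = set(u[:set_size])
        age = set(u[set_size - overlap : set_size]) | set(
            u[set_size : set_size + (n_draw - overlap)]
        )
        assert len(age) == n_draw and len(age & s) == overlap
        table = celltype_enrichment(age, self.make_sets(u, {"s": s}))
        oracle = hypergeom_tail_bruteforce(overlap, universe, set_size, n_draw)
        assert table.loc["s", "p"] == pytest.approx(oracle, abs=1e-12)

    def test_expected_overlap_not_enriched(self):
        # universe 200, set 40 (20%), draw 50 -> expected overlap 10
        u = [f"g{i}" for i in range(200)]
        s = set(u[:40])
        age = set(u[:10]) | set(u[40:80])
        table = celltype_enrichment(age, self.make_sets(u, {"s": s}))
        assert table.loc["s", "p"] > 0.5
        assert table.loc["s", "odds_ratio"] == pytest.approx(1.0, abs=0.3)

    def test_empty_universe(self):
        with pytest.raises(ValueError):
            celltype_enrichment(set(), GeneSetCollection({}, frozenset()))
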