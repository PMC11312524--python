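"""Cell-composition simulator of the MR apparent soma radius."""

import numpy as np
import pytest

from cortexdev.soma import (
    CellTypeSpec,
    VoxelComposition,
    age_modulated_composition,
    analytic_apparent_radius,
    apparent_soma_radius,
    default_composition,
    expression_anchored_slopes,
    sample_voxel_radii,
    simulate_rsoma_trajectory,
)


def one_type(count=1000, mu=5.0, sd=0.0, name="x"):
    return VoxelComposition((CellTypeSpec(name, count, mu, sd),))


class TestApparentRadius:
    def test_constant_sample_identity(self):
        assert apparent_soma_radius(np.full(100, 8.0)) == pytest.approx(8.0)

    def test_two_point_sample(self):
        # equal counts at 1 and 2 um: sqrt((1+32)/2 / ((1+8)/2)) = sqrt(16.5/4.5)
        r = apparent_soma_radius(np.r_[np.ones(50), np.full(50, 2.0)])
        assert r == pytest.approx(np.sqrt(16.5 / 4.5), rel=1e-12)
        assert r == pytest.approx(1.9149, abs=1e-4)

    def test_empty_and_invalid(self):
        with pytest.raises(ValueError):
            apparent_soma_radius([])
        with pytest.raises(ValueError):
            apparent_soma_radius([1.0, -2.0])


class TestAnalyticOracle:
    def test_degenerate_sd_zero(self):
        assert analytic_apparent_radius(one_type(mu=5.0, sd=0.0)) == pytest.approx(5.0)

    def test_single_gaussian_closed_form(self):
        # mu=8, sd=2: E[R^3]=608, E[R^5]=55168
        got = analytic_apparent_radius(one_type(mu=8.0, sd=2.0))
        assert got == pytest.approx(np.sqrt(55168.0 / 608.0), rel=1e-12)
        assert got == pytest.approx(9.526, abs=1e-3)

    def test_monte_carlo_agreement_baseline(self):
        comp = default_composition()
        mc = apparent_soma_radius(sample_voxel_radii(comp, seed=0))
        assert mc == pytest.approx(analytic_apparent_radius(comp), rel=3e-3)

    def test_small_radius_type_decreases_apparent_radius(self):
        base = default_composition()
        r0 = analytic_apparent_radius(base)
        for extra in (5_000, 20_000, 50_000):
            more_small = VoxelComposition(
                tuple(
                    CellTypeSpec(c.name, c.count + (extra if c.name == "microglia" else 0),
                                 c.radius_mean, c.radius_sd)
                    for c in base.cell_types
                )
            )
            r = analytic_apparent_radius(more_small)
            assert r < r0
            r0 = r


class TestSampler:
    def test_baseline_sample_size(self):
        radii = sample_voxel_radii(default_composition(), seed=1)
        assert radii.size == 6_500 + 15_700 + 12_500 + 92_000 + 32_200 == 158_900

    def test_sd_zero_exact(self):
        radii = sample_voxel_radii(one_type(count=50, mu=5.0, sd=0.0), seed=0)
        np.testing.assert_array_equal(radii, np.full(50, 5.0))

    def test_seed_determinism(self):
        comp = default_composition()
        np.testing.assert_array_equal(
            sample_voxel_radii(comp, seed=9), sample_voxel_radii(comp, seed=9)
        )

    def test_positivity(self):
        # heavy truncation regime: mean close to zero
        radii = sample_voxel_radii(one_type(count=5000, mu=0.5, sd=1.0), seed=2)
        assert np.all(radii > 0)

    def test_zero_total_count(self):
        with pytest.raises(ValueError):
            VoxelComposition((CellTypeSpec("x", 0.0, 5.0, 1.0),))


class TestAgeModulation:
    def test_zero_slopes_identity(self):
        base = default_composition()
        mod = age_modulated_composition(base, {}, age=19.0, ref_age=8.0)
        assert mod == base

    def test_linear_formula(self):
        base = default_composition()
        mod = age_modulated_composition(
            base, {"oligodendrocyte": 0.02}, age=18.0, ref_age=8.0
        )
        assert mod["oligodendrocyte"].count == pytest.approx(12_500 * 1.2)
        assert mod["astrocyte"].count == pytest.approx(15_700)

    def test_negative_count_raises(self):
        with pytest.raises(ValueError):
            age_modulated_composition(
                default_composition(), {"microglia": -0.2}, age=19.0, ref_age=8.0
            )

    def test_oligo_up_decreases_apparent_radius(self):
        """Sign of the mechanism: swelling the small-soma oligodendrocyte
        pool at fixed everything else shrinks the apparent radius."""
        base = default_composition()
        slopes = {"oligodendrocyte": 0.10}
        ages = np.linspace(8, 19, 5)
        traj = simulate_rsoma_trajectory(base, slopes, ages, mode="analytic")
        assert np.all(np.diff(traj.r_soma) < 0)
        assert traj.percent_change < 0


class TestTrajectory:
    def test_zero_slopes_zero_change_analytic(self):
        traj = simulate_rsoma_trajectory(
            default_composition(), {}, np.linspace(8, 19, 4), mode="analytic"
        )
        assert traj.percent_change == pytest.approx(0.0, abs=1e-12)

    def test_mc_matches_analytic(self):
        slopes = {"oligodendrocyte": 0.02, "astrocyte": -0.01, "endothelial": -0.01}
        ages = np.linspace(8, 19, 4)
        mc = simulate_rsoma_trajectory(
            default_composition(), slopes, ages, seed=4, mode="mc", n_replicates=3
        )
        an = simulate_rsoma_trajectory(default_composition(), slopes, ages, mode="analytic")
        np.testing.assert_allclose(mc.r_soma, an.r_soma, rtol=3e-3)

    def test_percent_change_scale_invariant(self):
        """Only proportions matter: rescaling all counts changes nothing."""
        base = default_composition()
        scaled = VoxelComposition(
            tuple(
                CellTypeSpec(c.name, 10.0 * c.count, c.radius_mean, c.radius_sd)
                for c in base.cell_types
            )
        )
        slopes = {"oligodendrocyte": 0.05, "astrocyte": -0.02}
        ages = np.linspace(8, 19, 3)
        a = simulate_rsoma_trajectory(base, slopes, ages, mode="analytic")
        b = simulate_rsoma_trajectory(scaled, slopes, ages, mode="analytic")
        assert a.percent_change == pytest.approx(b.percent_change, rel=1e-12)

    def test_ages_validated(self):
        with pytest.raises(ValueError):
            simulate_rsoma_trajectory(default_composition(), {}, [10.0])


class TestCompositionSensitivity:
    """The moment-ratio radius is pinned by the neuron pool: realistic
    glial modulations move it by hundredths of a percent."""

    def test_baseline_apparent_radius(self):
        assert analytic_apparent_radius(default_composition()) == pytest.approx(
            9.241, abs=1e-3
        )

    def test_neurons_dominate_the_moment_ratio(self):
        base = default_composition()
        neurons = one_type(92_000, 8.0, 2.0)
        assert analytic_apparent_radius(neurons) == pytest.approx(9.526, abs=1e-3)
        # neuron-only apparent radius sits above the mixture: every other
        # pool is "smaller" in moment-ratio terms, including endothelial
        endo = one_type(32_200, 9.0, 0.5)
        assert analytic_apparent_radius(endo) < analytic_apparent_radius(base)

    def test_ten_percent_oligo_rise_moves_radius_by_hundredths(self):
        ages = np.array([8.0, 19.0])
        traj = simulate_rsoma_trajectory(
            default_composition(),
            {"oligodendrocyte": 0.10 / 11.0},
            ages,
            mode="analytic",
        )
        assert -0.1 < traj.percent_change < -0.04

    def test_one_percent_decrease_needs_severalfold_oligo_rise(self):
        ages = np.array([8.0, 19.0])
        traj = simulate_rsoma_trajectory(
            default_composition(),
            {"oligodendrocyte": 3.0 / 11.0},  # +300% across the range
            ages,
            mode="analytic",
        )
        assert traj.percent_change == pytest.approx(-1.95, abs=0.1)


class TestAnchoredSlopes:
    def test_oligo_anchor(self):
        slopes = expression_anchored_slopes(
            {"oligodendrocyte": 0.03, "astrocyte": -0.02, "neuron": 0.0},
            oligo_rise=0.10,
            age_span=11.0,
        )
        assert slopes["oligodendrocyte"] == pytest.approx(0.10 / 11.0)
        # proportionality of the pattern is preserved
        assert slopes["astrocyte"] / slopes["oligodendrocyte"] == pytest.approx(
            -0.02 / 0.03
        )

    def test_zero_oligo_slope_rejected(self):
        with pytest.raises(ValueError):
            expression_anchored_slopes({"oligodendrocyte": 0.0})
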