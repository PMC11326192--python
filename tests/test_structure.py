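import math
import warnings

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from assemblypath.density import DensityGrid, cross_correlation, simulate_density
from assemblypath.structure import (
    Bead,
    BeadModel,
    McParams,
    bead_model_from_composition,
    ensemble_precision,
    excluded_volume_penalty,
    go_restraint_score,
    ks_exhaustiveness,
    mc_sample_snapshot,
    rmsd_to_reference,
    site_anchor_penalty,
    snapshot_energy,
)
from assemblypath.system import AssemblySystem, Composition, Site, SubcomplexType


def line_system(n_sites=2, spacing=3.0):
    sites = tuple(
        Site(f"s{i}", "T", (spacing * i, 0.0, 0.0)) for i in range(n_sites)
    )
    return AssemblySystem((SubcomplexType("T", {"p": 1}),), sites, symmetry_order=1)


class TestSimulateDensity:
    def test_empty_model_is_zero_grid(self, small_grid):
        out = simulate_density(BeadModel(()), small_grid)
        assert not out.data.any()

    def test_peak_at_bead_voxel(self, small_grid):
        model = BeadModel((Bead("s0", (0.0, 0.0, 0.0), 1.5, 1.0),))
        out = simulate_density(model, small_grid)
        assert np.unravel_index(np.argmax(out.data), out.shape) == (6, 6, 6)

    def test_linear_in_beads(self, small_grid):
        one = BeadModel((Bead("s0", (0.5, -1.0, 2.0), 1.2, 1.0),))
        two = BeadModel(
            (
                Bead("s0", (0.5, -1.0, 2.0), 1.2, 1.0),
                Bead("s1", (0.5, -1.0, 2.0), 1.2, 1.0),
            )
        )
        np.testing.assert_allclose(
            simulate_density(two, small_grid).data,
            2.0 * simulate_density(one, small_grid).data,
            atol=1e-14,
        )


class TestCrossCorrelation:
    def test_self_is_one_and_negation_minus_one(self, small_grid):
        rng = np.random.default_rng(0)
        g = DensityGrid(small_grid.origin, 1.0, rng.normal(size=small_grid.shape))
        neg = DensityGrid(small_grid.origin, 1.0, -g.data)
        assert cross_correlation(g, g) == pytest.approx(1.0, abs=1e-12)
        assert cross_correlation(g, neg) == pytest.approx(-1.0, abs=1e-12)

    def test_rendered_model_matches_target_from_same_beads(self, small_grid):
        model = BeadModel(
            (Bead("a", (-2.0, 0.0, 1.0), 1.2, 2.0), Bead("b", (3.0, 1.0, -1.0), 1.2, 1.0))
        )
        target = simulate_density(model, small_grid)
        assert cross_correlation(simulate_density(model, small_grid), target) >= 0.99

    def test_geometry_mismatch_raises(self, small_grid):
        other = DensityGrid(small_grid.origin + 1.0, 1.0, np.zeros(small_grid.shape))
        with pytest.raises(ValueError):
            cross_correlation(small_grid, other)

    def test_constant_grid_warns_and_returns_zero(self, small_grid):
        rng = np.random.default_rng(1)
        g = DensityGrid(small_grid.origin, 1.0, rng.normal(size=small_grid.shape))
        with pytest.warns(UserWarning):
            assert cross_correlation(small_grid, g) == 0.0


class TestRestraints:
    def test_no_overlap_no_penalty(self):
        m = BeadModel((Bead("a", (0, 0, 0), 1.0), Bead("b", (3, 0, 0), 1.0)))
        assert excluded_volume_penalty(m) == 0.0

    def test_overlap_penalty_by_hand(self):
        m = BeadModel((Bead("a", (0, 0, 0), 1.0), Bead("b", (1, 0, 0), 1.0)))
        assert excluded_volume_penalty(m, k_ev=1.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_penalties_rotation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        centers = rng.uniform(-3, 3, size=(4, 3))
        rot = Rotation.random(random_state=seed).as_matrix()
        m1 = BeadModel(tuple(Bead(f"s{i}", tuple(c), 1.5) for i, c in enumerate(centers)))
        m2 = BeadModel(
            tuple(Bead(f"s{i}", tuple(c @ rot.T), 1.5) for i, c in enumerate(centers))
        )
        assert excluded_volume_penalty(m1) == pytest.approx(excluded_volume_penalty(m2))

    def test_go_zero_at_mature_positions(self):
        system = line_system(3)
        comp = Composition.from_sites(system, "t", ("s0", "s1", "s2"))
        model = bead_model_from_composition(comp, system)
        assert go_restraint_score(model, system) == 0.0
        assert site_anchor_penalty(model, system) == 0.0

    def test_go_single_bead_is_zero(self):
        system = line_system(1)
        model = BeadModel((Bead("s0", (9.0, 9.0, 9.0), 1.0),))
        assert go_restraint_score(model, system) == 0.0

    def test_go_quadratic_in_distance_error(self):
        system = line_system(2, spacing=5.0)  # native distance 5
        model = BeadModel((Bead("s0", (0, 0, 0), 1.0), Bead("s1", (7, 0, 0), 1.0)))
        assert go_restraint_score(model, system, k_go=1.0) == pytest.approx(4.0)


class TestRmsd:
    def test_zero_at_mature(self):
        system = line_system(3)
        comp = Composition.from_sites(system, "t", ("s0", "s1", "s2"))
        assert rmsd_to_reference(bead_model_from_composition(comp, system), system) == 0.0

    def test_rigid_translation(self):
        system = line_system(3)
        comp = Composition.from_sites(system, "t", ("s0", "s1", "s2"))
        model = bead_model_from_composition(comp, system)
        shifted = model.with_centers(model.centers() + np.array([3.0, 4.0, 0.0]))
        assert rmsd_to_reference(shifted, system) == pytest.approx(5.0)

    def test_mixed_displacements(self):
        system = line_system(2, spacing=5.0)
        model = BeadModel(
            (Bead("s0", (1.0, 0.0, 0.0), 1.0), Bead("s1", (5.0, 3.0, 0.0), 1.0))
        )  # displaced by 1 and 3
        assert rmsd_to_reference(model, system) == pytest.approx(math.sqrt(5.0))

    def test_empty_model_is_undefined(self):
        with pytest.raises(ValueError):
            rmsd_to_reference(BeadModel(()), line_system(1))


class TestKsExhaustiveness:
    def test_identical_samples_pass_with_zero_d(self):
        res = ks_exhaustiveness([1.0, 2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.statistic == 0.0 and res.passed

    def test_shifted_distributions_fail(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, size=100)
        b = rng.normal(5.0, 1.0, size=100)
        res = ks_exhaustiveness(a, b)
        assert res.pvalue < 0.05 and not res.passed

    def test_small_samples_warn_but_compute(self):
        with pytest.warns(UserWarning):
            res = ks_exhaustiveness([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.small_sample


def _one_bead_setup(grid_n=13):
    system = line_system(1)  # site s0 at the origin
    grid = DensityGrid((-6.0, -6.0, -6.0), 1.0, np.zeros((grid_n,) * 3))
    comp = Composition.from_sites(system, "t", ("s0",))
    target = simulate_density(bead_model_from_composition(comp, system), grid)
    target = DensityGrid(grid.origin, grid.spacing, target.data)
    return system, comp, target


class TestMcSampling:
    def test_same_seed_bitwise_identical(self, small_grid):
        system = line_system(3)
        comp = Composition.from_sites(system, "t", ("s0", "s1"))
        target = simulate_density(bead_model_from_composition(comp, system), small_grid)
        params = McParams(n_steps=50, n_models=2)
        a = mc_sample_snapshot(comp, system, target, params, seed=9)
        b = mc_sample_snapshot(comp, system, target, params, seed=9)
        assert np.array_equal(a.energies, b.energies)
        for (ma, _), (mb, _) in zip(a.models, b.models):
            np.testing.assert_array_equal(ma.centers(), mb.centers())

    def test_energy_never_above_start_on_matching_target(self, small_grid):
        system = line_system(3)
        comp = Composition.from_sites(system, "t", ("s0", "s1", "s2"))
        model0 = bead_model_from_composition(comp, system)
        target = simulate_density(model0, small_grid)
        params = McParams(n_steps=200, n_models=2)
        e0 = snapshot_energy(model0, system, target, params)
        ens = mc_sample_snapshot(comp, system, target, params, seed=3)
        assert (ens.energies <= e0 + 1e-9).all()

    def test_empty_composition_gives_single_empty_model(self, small_grid):
        system = line_system(2)
        comp = Composition.from_sites(system, "t", ())
        params = McParams(n_steps=5, n_models=3)
        ens = mc_sample_snapshot(comp, system, small_grid, params, seed=0)
        assert len(ens.models) == 1 and len(ens.models[0][0]) == 0
        assert ens.models[0][1] == pytest.approx(params.w_cc)

    def grid_search_oracle(self, target, radius=1.2):
        """Best bead position over all voxel centers by exhaustive CC search."""
        best, best_cc = None, -np.inf
        coords = [target.axis_coords(a) for a in range(3)]
        for i, x in enumerate(coords[0]):
            for j, y in enumerate(coords[1]):
                for k, z in enumerate(coords[2]):
                    m = BeadModel((Bead("s0", (x, y, z), radius, 1.0),))
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        cc = cross_correlation(simulate_density(m, target), target)
                    if cc > best_cc:
                        best_cc, best = cc, np.array([x, y, z])
        return best

    def test_one_bead_recovery_matches_grid_search(self):
        system, comp, target = _one_bead_setup(grid_n=9)
        oracle = self.grid_search_oracle(target)
        params = McParams(
            n_steps=3000, n_models=2, init="random", k_anchor=0.0, temperature=0.3
        )
        ens = mc_sample_snapshot(comp, system, target, params, seed=11)
        found = ens.best_model.centers()[0]
        assert np.linalg.norm(found - oracle) <= target.spacing

    def test_recovery_across_seeds(self):
        # parameter-recovery property: truth found to < 1 voxel in >= 9/10 seeds
        system, comp, target = _one_bead_setup(grid_n=9)
        params = McParams(
            n_steps=3000, n_models=2, init="random", k_anchor=0.0, temperature=0.3
        )
        hits = 0
        for seed in range(10):
            ens = mc_sample_snapshot(comp, system, target, params, seed=seed)
            found = ens.best_model.centers()[0]
            hits += np.linalg.norm(found - np.zeros(3)) < target.spacing
        assert hits >= 9

    def test_ensemble_precision_shrinks_with_temperature(self, small_grid):
        system = line_system(3)
        comp = Composition.from_sites(system, "t", ("s0", "s1", "s2"))
        target = simulate_density(bead_model_from_composition(comp, system), small_grid)
        cold = McParams(n_steps=300, n_models=4, temperature=0.02, k_anchor=0.5)
        hot = McParams(n_steps=300, n_models=4, temperature=5.0, k_anchor=0.5,
                       good_fraction=1.0)
        p_cold = ensemble_precision(mc_sample_snapshot(comp, system, target, cold, seed=2))
        p_hot = ensemble_precision(mc_sample_snapshot(comp, system, target, hot, seed=2))
        assert p_cold <= p_hot
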