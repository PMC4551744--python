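"""Spatial indicators: hand-computed examples, invariants, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from conftest import make_dataset, random_instance
from spatind.indicators import (
    UndefinedIndicatorError,
    centre_of_gravity,
    equivalent_area,
    estimate_biomass,
    global_index_of_collocation,
    identify_patches,
    inertia_and_isotropy,
    packing_density,
    positive_area,
    spreading_area,
    compute_indicator_set,
)

ONES = np.ones


class TestCentreOfGravity:
    def test_single_positive_sample_is_its_own_cg(self):
        assert centre_of_gravity([3.0], [4.0], [2.0], [1.0]) == (3.0, 4.0)

    def test_hand_weighted_mean(self):
        # A=(0,0) z=2,s=1 and B=(10,0) z=1,s=2: equal weights zs=2 -> midpoint
        cg = centre_of_gravity([0.0, 10.0], [0.0, 0.0], [2.0, 1.0], [1.0, 2.0])
        assert cg == pytest.approx((5.0, 0.0))

    def test_all_zero_density_raises(self):
        with pytest.raises(UndefinedIndicatorError):
            centre_of_gravity([0.0, 1.0], [0.0, 0.0], [0.0, 0.0], [1.0, 1.0])


class TestInertiaIsotropy:
    def test_point_population_is_isotropic_with_zero_inertia(self):
        inertia, isotropy, _ = inertia_and_isotropy([5.0], [5.0], [1.0], [1.0])
        assert inertia == 0.0 and isotropy == 1.0

    def test_two_equal_masses_collinear(self):
        inertia, isotropy, axes = inertia_and_isotropy(
            [0.0, 10.0], [0.0, 0.0], ONES(2), ONES(2))
        assert inertia == pytest.approx(25.0)
        assert isotropy == pytest.approx(0.0, abs=1e-12)
        assert abs(axes[0] @ [1.0, 0.0]) == pytest.approx(1.0)

    def test_four_corners_isotropic(self):
        inertia, isotropy, _ = inertia_and_isotropy(
            [1.0, 1.0, -1.0, -1.0], [1.0, -1.0, 1.0, -1.0], ONES(4), ONES(4))
        assert inertia == pytest.approx(2.0)
        assert isotropy == pytest.approx(1.0)


class TestAreas:
    def test_positive_area_counts_only_positive_support(self):
        assert positive_area([1.0, 3.0, 0.0], [1.0, 1.0, 7.0]) == 2.0
        assert positive_area([0.0, 0.0], [5.0, 5.0]) == 0.0

    def test_spreading_area_hand_ranked_sum(self):
        # z={3,1}, s={1,1}: terms 2.5 and 0.5 -> SA = 2*3/4 = 1.5
        assert spreading_area([3.0, 1.0], [1.0, 1.0]) == pytest.approx(1.5)

    def test_single_sample_sa_ea_equal_its_area(self):
        assert spreading_area([2.0], [7.0]) == pytest.approx(7.0)
        assert equivalent_area([2.0], [7.0]) == pytest.approx(7.0)

    def test_equivalent_area_hand_value(self):
        assert equivalent_area([1.0, 3.0], [1.0, 1.0]) == pytest.approx(1.6)

    def test_uniform_field_collapses_to_positive_area(self, rng):
        s = rng.uniform(0.5, 10, 30)
        z = np.full(30, 2.7)
        total = s.sum()
        assert positive_area(z, s) == pytest.approx(total, rel=1e-12)
        assert spreading_area(z, s) == pytest.approx(total, rel=1e-9)
        assert equivalent_area(z, s) == pytest.approx(total, rel=1e-9)

    def test_zero_abundance_raises(self):
        for fn in (spreading_area, equivalent_area):
            with pytest.raises(UndefinedIndicatorError):
                fn([0.0], [1.0])

    def test_ea_not_always_below_sa(self):
        # pinned counterexample: EA = 1.6 > SA = 1.5
        z, s = [3.0, 1.0], [1.0, 1.0]
        assert equivalent_area(z, s) > spreading_area(z, s)

    def test_ea_and_sa_bounded_by_pa_on_random_sweep(self, rng):
        for _ in range(1000):
            _, _, z, s = random_instance(rng)
            pa = positive_area(z, s)
            assert equivalent_area(z, s) <= pa * (1 + 1e-12)
            assert spreading_area(z, s) <= pa * (1 + 1e-12)


class TestPatches:
    def test_single_sample_single_patch(self):
        ps = identify_patches([0.0], [0.0], [1.0], [1.0])
        assert len(ps.patches) == 1 and ps.n_major == 1

    def test_hand_traced_two_patch_assignment(self):
        # densities {10,9} at x={50,51} and {5,4,3} at x={0,1,2}; dlim=20
        x = [50.0, 51.0, 0.0, 1.0, 2.0]
        z = [10.0, 9.0, 5.0, 4.0, 3.0]
        ps = identify_patches(x, [0.0] * 5, z, [1.0] * 5, dlim=20.0)
        assert sorted(p.abundance for p in ps.patches) == [12.0, 19.0]
        assert ps.n_major == 2

    def test_distant_samples_found_separate_patches(self):
        ps = identify_patches([0.0, 50.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0], dlim=20.0)
        assert len(ps.patches) == 2

    def test_no_positive_samples_yields_empty_set(self):
        ps = identify_patches([0.0], [0.0], [0.0], [1.0])
        assert ps.patches == [] and ps.n_major == 0

    def test_abundance_conserved_and_membership_unique(self, rng):
        for _ in range(50):
            x, y, z, s = random_instance(rng)
            ps = identify_patches(x, y, z, s)
            members = sorted(i for p in ps.patches for i in p.members)
            assert members == sorted(np.flatnonzero(z > 0))
            assert sum(p.abundance for p in ps.patches) == pytest.approx(
                float((np.asarray(z) * np.asarray(s)).sum()), rel=1e-9)


class TestGIC:
    def test_point_populations_apart_give_zero(self):
        pop1 = ([0.0], [0.0], [1.0], [1.0])
        pop2 = ([10.0], [0.0], [1.0], [1.0])
        assert global_index_of_collocation(pop1, pop2) == 0.0

    def test_identical_populations_give_one(self, rng):
        x, y, z, s = random_instance(rng, n=15)
        assert global_index_of_collocation((x, y, z, s), (x, y, z, s)) == pytest.approx(1.0)

    def test_coincident_point_populations_give_one(self):
        pop = ([3.0], [4.0], [2.0], [1.0])
        assert global_index_of_collocation(pop, pop) == 1.0

    def test_hand_evaluated_partial_overlap(self):
        pop1 = ([0.0, 0.0], [0.0, 2.0], [1.0, 1.0], [1.0, 1.0])
        pop2 = ([3.0, 3.0], [0.0, 2.0], [1.0, 1.0], [1.0, 1.0])
        assert global_index_of_collocation(pop1, pop2) == pytest.approx(1 - 9 / 11)

    def test_symmetry(self, rng):
        for _ in range(20):
            p1 = random_instance(rng, n=10)
            p2 = random_instance(rng, n=10)
            assert global_index_of_collocation(p1, p2) == pytest.approx(
                global_index_of_collocation(p2, p1), abs=1e-12)

    def test_zero_abundance_population_raises(self):
        pop = ([0.0], [0.0], [0.0], [1.0])
        ref = ([0.0], [0.0], [1.0], [1.0])
        with pytest.raises(UndefinedIndicatorError):
            global_index_of_collocation(pop, ref)


class TestBiomass:
    def test_edsu_estimator_arithmetic(self):
        ds = make_dataset([0, 1], [0, 0], {"anchovy": [2.0, 3.0]}, s=[4.0, 5.0])
        assert estimate_biomass(ds, "anchovy", "edsu") == pytest.approx(23.0)

    def test_methods_agree_for_equal_areas_within_transect(self, rng):
        z = rng.lognormal(0, 1, 10)
        ds = make_dataset(np.zeros(10), np.arange(10.0), {"anchovy": z}, s=np.full(10, 5.0))
        edsu = estimate_biomass(ds, "anchovy", "edsu")
        tran = estimate_biomass(ds, "anchovy", "transect")
        assert edsu == pytest.approx(tran, rel=1e-12)

    def test_zero_field_zero_biomass(self):
        ds = make_dataset([0, 1], [0, 0], {"anchovy": [0.0, 0.0]})
        assert estimate_biomass(ds, "anchovy", "edsu") == 0.0
        assert estimate_biomass(ds, "anchovy", "transect") == 0.0

    def test_packing_density(self):
        assert packing_density(23.0, 9.0) == pytest.approx(23.0 / 9.0)
        with pytest.raises(UndefinedIndicatorError):
            packing_density(1.0, 0.0)


class TestEquivariance:
    @given(k=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=30, deadline=None)
    def test_density_scaling_leaves_geometry_invariant(self, k):
        rng = np.random.default_rng(7)
        x, y, z, s = random_instance(rng, n=15)
        base_cg = centre_of_gravity(x, y, z, s)
        base_ii = inertia_and_isotropy(x, y, z, s)[:2]
        assert centre_of_gravity(x, y, k * z, s) == pytest.approx(base_cg)
        assert inertia_and_isotropy(x, y, k * z, s)[:2] == pytest.approx(base_ii)
        assert positive_area(k * z, s) == positive_area(z, s)
        assert spreading_area(k * z, s) == pytest.approx(spreading_area(z, s), rel=1e-9)
        assert equivalent_area(k * z, s) == pytest.approx(equivalent_area(z, s), rel=1e-9)
        assert identify_patches(x, y, k * z, s).n_major == identify_patches(x, y, z, s).n_major

    @given(dx=st.floats(-50, 50), dy=st.floats(-50, 50))
    @settings(max_examples=30, deadline=None)
    def test_translation_shifts_cg_only(self, dx, dy):
        rng = np.random.default_rng(11)
        x, y, z, s = random_instance(rng, n=15)
        cg0 = centre_of_gravity(x, y, z, s)
        cg1 = centre_of_gravity(x + dx, y + dy, z, s)
        assert cg1[0] - cg0[0] == pytest.approx(dx, abs=1e-9)
        assert cg1[1] - cg0[1] == pytest.approx(dy, abs=1e-9)
        assert inertia_and_isotropy(x + dx, y + dy, z, s)[0] == pytest.approx(
            inertia_and_isotropy(x, y, z, s)[0], rel=1e-9)


class TestOracleEquivalence:
    def test_all_indicators_match_brute_force(self, rng):
        for _ in range(500):
            x, y, z, s = random_instance(rng)
            assert centre_of_gravity(x, y, z, s) == pytest.approx(
                oracles.cg_naive(x, y, z, s), rel=1e-9)
            inertia, isotropy, _ = inertia_and_isotropy(x, y, z, s)
            assert inertia == pytest.approx(oracles.inertia_naive(x, y, z, s), rel=1e-9)
            assert isotropy == pytest.approx(oracles.isotropy_naive(x, y, z, s), abs=1e-9)
            assert positive_area(z, s) == pytest.approx(oracles.pa_naive(z, s), rel=1e-9)
            assert spreading_area(z, s) == pytest.approx(oracles.sa_naive(z, s), rel=1e-9)
            assert equivalent_area(z, s) == pytest.approx(oracles.ea_naive(z, s), rel=1e-9)

    def test_gic_matches_brute_force(self, rng):
        for _ in range(100):
            p1 = random_instance(rng, n=12)
            p2 = random_instance(rng, n=12)
            assert global_index_of_collocation(p1, p2) == pytest.approx(
                oracles.gic_naive(p1, p2), abs=1e-9)

    def test_patch_assignment_matches_naive_sequential(self, rng):
        for _ in range(200):
            x, y, z, s = random_instance(rng)
            got = [sorted(p.members) for p in identify_patches(x, y, z, s)]
            want = [sorted(m) for m in oracles.patches_naive(list(x), list(y), list(z), list(s))]
            assert got == want


class TestIndicatorSet:
    def test_fields_match_component_operations(self, rng):
        x, y, z, s = random_instance(rng, n=20)
        ds = make_dataset(x, y, {"anchovy": z}, s=s)
        ind = compute_indicator_set(ds, "anchovy")
        assert (ind.cg_x, ind.cg_y) == pytest.approx(centre_of_gravity(x, y, z, s))
        assert ind.positive_area == pytest.approx(positive_area(z, s))
        assert ind.spreading_area == pytest.approx(spreading_area(z, s))
        assert ind.equivalent_area == pytest.approx(equivalent_area(z, s))
        assert ind.biomass == pytest.approx(float((z * s).sum()))
        assert ind.packing_density * ind.positive_area == pytest.approx(ind.biomass, rel=1e-9)
        assert ind.equivalent_area <= ind.positive_area
        assert ind.spreading_area <= ind.positive_area

    def test_empty_slice_raises(self):
        ds = make_dataset([0.0], [0.0], {"anchovy": [0.0]})
        with pytest.raises(UndefinedIndicatorError):
            compute_indicator_set(ds, "anchovy")
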