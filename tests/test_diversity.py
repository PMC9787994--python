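"""Taxonomic and functional diversity metrics and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from canopybird.diversity import (
    build_trait_space,
    compute_diversity_profile,
    functional_dispersion,
    functional_divergence,
    functional_evenness,
    functional_richness,
    gower_distance,
    normalize_metric,
    taxonomic_diversity,
)
from conftest import make_space


class TestTaxonomic:
    def test_uniform_community(self):
        s, h = taxonomic_diversity(np.ones(10))
        assert s == 10 and h == pytest.approx(np.log(10))

    def test_skewed_pair(self):
        _, h = taxonomic_diversity(np.array([4.0, 1.0]))
        expected = -(0.8 * np.log(0.8) + 0.2 * np.log(0.2))
        assert h == pytest.approx(expected)

    def test_single_species_and_empty(self):
        assert taxonomic_diversity(np.array([3.0]))[1] == 0.0
        s, h = taxonomic_diversity(np.zeros(4))
        assert s == 0 and np.isnan(h)

    @given(st.lists(st.floats(0.01, 100), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_entropy_bounded_by_log_richness(self, abund):
        s, h = taxonomic_diversity(np.array(abund))
        assert h <= np.log(s) + 1e-9

    def test_abundance_scale_invariance(self, rng):
        a = rng.gamma(1.0, 2.0, 20)
        assert taxonomic_diversity(a)[1] == pytest.approx(taxonomic_diversity(2 * a)[1])


class TestGower:
    def test_identical_rows_zero(self):
        t = pd.DataFrame({"mass": [5.0, 5.0], "diet": ["seed", "seed"]})
        assert gower_distance(t).iloc[0, 1] == 0.0

    def test_mixed_traits_definition(self):
        t_num = pd.DataFrame({"mass": [1.0, 3.0]}, index=["a", "b"])
        assert gower_distance(t_num).loc["a", "b"] == 1.0
        t_mixed = t_num.assign(diet=["seed", "seed"])
        assert gower_distance(t_mixed).loc["a", "b"] == 0.5

    def test_maximal_difference(self):
        t = pd.DataFrame({"mass": [0.0, 1.0], "diet": ["seed", "bug"],
                          "nest": ["ground", "canopy"]}, index=["a", "b"])
        assert gower_distance(t).loc["a", "b"] == 1.0

    def test_zero_range_trait_dropped(self):
        t = pd.DataFrame({"mass": [2.0, 2.0], "diet": ["seed", "bug"]})
        with pytest.warns(UserWarning, match="zero range"):
            d = gower_distance(t)
        assert d.iloc[0, 1] == 1.0


class TestTraitSpace:
    def test_euclidean_input_reproduced_exactly(self, rng):
        pts = rng.normal(size=(6, 2))
        from scipy.spatial.distance import pdist, squareform

        d = pd.DataFrame(squareform(pdist(pts)),
                         index=list("abcdef"), columns=list("abcdef"))
        space = build_trait_space(d, max_axes=2)
        got = squareform(pdist(space.coords.to_numpy()))
        assert np.allclose(got, d.to_numpy(), atol=1e-8)
        assert space.quality == pytest.approx(1.0)

    def test_equidistant_triplet(self):
        d = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        space = build_trait_space(d, max_axes=2)
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(space.coords.to_numpy()), 1.0, atol=1e-8)
        assert space.quality == pytest.approx(1.0)

    def test_single_axis_quality_is_leading_share(self, rng):
        pts = rng.normal(size=(8, 3))
        from scipy.spatial.distance import pdist, squareform

        d = pd.DataFrame(squareform(pdist(pts)))
        space = build_trait_space(d, max_axes=1)
        vals = space.eigenvalues
        pos = vals[vals > 1e-8]
        assert space.quality == pytest.approx(pos[0] / pos.sum())

    def test_cross_check_against_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        traits = pd.DataFrame(
            {"mass": rng.lognormal(2, 1, 8),
             "diet": rng.choice(["a", "b", "c"], 8),
             "nest": rng.choice(["x", "y"], 8)},
            index=[f"s{i}" for i in range(8)],
        )
        d = gower_distance(traits)
        space = build_trait_space(d, max_axes=3)
        dm = np.sqrt(d.to_numpy()) if space.sqrt_corrected else d.to_numpy()
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(dm))
        ref_eig = ref.eigvals.to_numpy()[: space.m]
        ours = np.sort(space.eigenvalues)[::-1][: space.m]
        assert np.allclose(ours, ref_eig, atol=1e-8)
        ref_coords = ref.samples.to_numpy()[:, : space.m]
        for j in range(space.m):  # PCoA axes are sign-indeterminate
            assert np.allclose(
                np.abs(space.coords.to_numpy()[:, j]), np.abs(ref_coords[:, j]),
                atol=1e-6,
            )


class TestFunctionalMetrics:
    def test_fric_unit_square(self, unit_square_space):
        ab = pd.Series(1.0, index=unit_square_space.coords.index)
        assert functional_richness(unit_square_space, ab) == pytest.approx(1.0, abs=1e-10)

    def test_fric_right_triangle(self):
        space = make_space([[0, 0], [1, 0], [0, 1]])
        ab = pd.Series(1.0, index=space.coords.index)
        assert functional_richness(space, ab) == pytest.approx(0.5, abs=1e-10)

    def test_fric_undefined_below_dimension(self):
        space = make_space([[0, 0], [1, 1]])
        ab = pd.Series(1.0, index=space.coords.index)
        with pytest.warns(UserWarning, match="S <= m"):
            assert np.isnan(functional_richness(space, ab))

    def test_fric_monotone_under_hull_extension(self, rng):
        pts = rng.normal(size=(8, 2))
        space = make_space(np.vstack([pts, [10.0, 10.0]]))
        idx = space.coords.index
        inner = pd.Series([1.0] * 8 + [0.0], index=idx)
        outer = pd.Series(1.0, index=idx)
        assert functional_richness(space, outer) >= functional_richness(space, inner)

    def test_feve_regular_spacing_is_one(self):
        space = make_space([[0.0], [1.0], [2.0]])
        ab = pd.Series(1.0, index=space.coords.index)
        assert functional_evenness(space, ab) == pytest.approx(1.0, abs=1e-10)

    def test_feve_collinear_013(self):
        space = make_space([[0.0], [1.0], [3.0]])
        ab = pd.Series(1.0, index=space.coords.index)
        assert functional_evenness(space, ab) == pytest.approx(2.0 / 3.0, abs=1e-10)

    def test_feve_decreases_with_abundance_skew(self):
        space = make_space([[0.0], [1.0], [2.0], [3.0]])
        idx = space.coords.index
        even = functional_evenness(space, pd.Series(1.0, index=idx))
        skewed = functional_evenness(space, pd.Series([100.0, 1, 1, 1], index=idx))
        assert skewed < even

    def test_fdiv_regular_polygon_is_one(self):
        angles = 2 * np.pi * np.arange(5) / 5
        space = make_space(np.column_stack([np.cos(angles), np.sin(angles)]))
        ab = pd.Series(1.0, index=space.coords.index)
        assert functional_divergence(space, ab) == pytest.approx(1.0, abs=1e-10)

    def test_fdiv_right_triangle_closed_form(self):
        space = make_space([[0, 0], [1, 0], [0, 1]])
        ab = pd.Series(1.0, index=space.coords.index)
        # independent closed form: centroid (1/3, 1/3)
        d = np.array([np.sqrt(2.0), np.sqrt(5.0), np.sqrt(5.0)]) / 3.0
        dg = d.mean()
        expected = dg / (np.abs(d - dg).mean() + dg)
        assert functional_divergence(space, ab) == pytest.approx(expected, abs=1e-12)

    def test_fdiv_increases_with_distant_abundance(self):
        space = make_space([[0, 0], [1, 0], [0, 1], [0.34, 0.32]])
        idx = space.coords.index
        base = functional_divergence(space, pd.Series([1, 1, 1, 5.0], index=idx))
        shifted = functional_divergence(space, pd.Series([5.0, 1, 1, 1], index=idx))
        assert shifted > base

    def test_fdis_closed_forms(self):
        space = make_space([[0.0], [2.0]])
        idx = space.coords.index
        assert functional_dispersion(space, pd.Series(1.0, index=idx)) == pytest.approx(1.0, abs=1e-12)
        space1 = make_space([[0.0], [1.0]])
        assert functional_dispersion(
            space1, pd.Series([3.0, 1.0], index=space1.coords.index)
        ) == pytest.approx(0.375, abs=1e-12)
        single = make_space([[1.0]])
        assert functional_dispersion(
            single, pd.Series([2.0], index=single.coords.index)
        ) == 0.0

    def test_fdis_rigid_motion_invariance_and_scaling(self, rng):
        pts = rng.normal(size=(7, 2))
        ab = pd.Series(rng.gamma(1, 1, 7) + 0.1, index=[f"s{i}" for i in range(7)])
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        base = functional_dispersion(make_space(pts), ab)
        moved = functional_dispersion(make_space(pts @ rot.T + [3.0, -1.0]), ab)
        scaled = functional_dispersion(make_space(2.5 * pts), ab)
        assert moved == pytest.approx(base, abs=1e-10)
        assert scaled == pytest.approx(2.5 * base, abs=1e-10)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_feve_fdiv_bounds_on_random_communities(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(3, 10))
        space = make_space(r.normal(size=(n, 2)))
        ab = pd.Series(r.gamma(1.0, 1.0, n) + 1e-3, index=space.coords.index)
        feve = functional_evenness(space, ab)
        fdiv = functional_divergence(space, ab)
        assert np.isnan(feve) or 0.0 <= feve <= 1.0 + 1e-9
        assert np.isnan(fdiv) or 0.0 <= fdiv <= 1.0 + 1e-9

    def test_all_metrics_abundance_scale_invariant(self, rng):
        space = make_space(rng.normal(size=(8, 2)))
        idx = space.coords.index
        a = pd.Series(rng.gamma(1, 1, 8) + 0.1, index=idx)
        for fn in (functional_richness, functional_evenness,
                   functional_divergence, functional_dispersion):
            assert fn(space, a) == pytest.approx(fn(space, 2 * a), nan_ok=True)


class TestNormalize:
    def test_normal_sample_passes_through(self):
        v = np.random.default_rng(0).normal(10, 2, 100)
        out, lam, p = normalize_metric(v)
        assert lam is None and p >= 0.05
        assert np.array_equal(out, v)

    def test_lognormal_recovers_log_transform(self):
        v = np.exp(np.random.default_rng(1).normal(0, 1, 200))
        _, lam, p = normalize_metric(v)
        assert p < 0.05 and abs(lam) <= 0.25

    def test_nonpositive_values_instruct_shift(self):
        v = np.r_[np.exp(np.random.default_rng(2).normal(0, 1, 100)) - 0.5]
        v[0] = -1.0
        with pytest.raises(ValueError, match="shift"):
            normalize_metric(v)

    def test_too_few_values(self):
        with pytest.raises(ValueError, match="three"):
            normalize_metric([1.0, 2.0])


class TestProfile:
    def test_profile_on_synthetic_communities(self, rng):
        n_sp, n_g = 20, 12
        traits = pd.DataFrame(
            {"body_mass_g": rng.lognormal(3, 1, n_sp),
             "diet": rng.choice(["a", "b", "c"], n_sp),
             "nest_site": rng.choice(["x", "y"], n_sp)},
            index=pd.Index([f"sp{i}" for i in range(n_sp)], name="species_id"),
        )
        ab = pd.DataFrame(
            rng.gamma(0.5, 2.0, (n_g, n_sp)) * (rng.random((n_g, n_sp)) > 0.3),
            index=[f"g{i}" for i in range(n_g)], columns=traits.index,
        ) + 0.0
        profile, meta = compute_diversity_profile(ab, traits)
        assert profile.shape[0] == n_g
        assert (profile["species_richness"] >= 0).all()
        assert 0 <= meta["trait_space_quality"] <= 1
        defined = profile["feve"].dropna()
        assert ((defined >= 0) & (defined <= 1)).all()

    def test_species_without_traits_rejected(self, rng):
        traits = pd.DataFrame({"body_mass_g": [1.0, 2.0]},
                              index=pd.Index(["a", "b"], name="species_id"))
        ab = pd.DataFrame([[1.0, 1.0, 1.0]], index=["g"], columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="without traits"):
            compute_diversity_profile(ab, traits)
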