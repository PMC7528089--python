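"""Synthetic cohort generator: template, planted effects, reproducibility."""

import numpy as np
import pytest

from lungshape.fitting import project_points
from lungshape.hermite import SURFACE_LABELS, mesh_volume
from lungshape.synthetic import (
    GeneratorConfig,
    deform_subject,
    draw_covariates,
    generate_cohort,
    reference_topology,
    sample_cloud,
    template_lung_mesh,
    transform_mesh,
)


def fissure_rows(mesh, surface):
    return sorted(
        {
            mesh.node_index(n)
            for el in mesh.elements_for_surface(surface)
            for n in el.node_ids
        }
    )


class TestTemplate:
    def test_deterministic(self):
        a = template_lung_mesh()
        b = template_lung_mesh()
        np.testing.assert_array_equal(a.node_dofs, b.node_dofs)
        assert [e.node_ids for e in a.elements] == [e.node_ids for e in b.elements]

    def test_all_five_surfaces_present(self, template):
        assert template.surfaces_present() == set(SURFACE_LABELS)

    def test_reference_topology_scale(self):
        ref = reference_topology()
        assert ref.n_nodes == 225
        assert ref.node_dofs.size == 2700

    def test_self_fit_round_trip(self, template):
        from lungshape.fitting import FitConfig, fit_mesh

        cloud = sample_cloud(template, density=4, noise_sd=0.0, seed=0)
        cfg = FitConfig(
            smooth_first=1e-8, smooth_second=1e-8, smooth_cross=1e-8,
            max_outer_iterations=3, convergence_tol=1e-9,
            initial_similarity=False,
        )
        assert fit_mesh(template, cloud, cfg).rmse < 1e-6


class TestTransformMesh:
    def test_chain_rule_against_finite_differences(self, template):
        """Derivative DoFs of a nonlinearly mapped mesh must match finite
        differences of the mapped surface."""
        from lungshape.hermite import evaluate_surface
        from lungshape.synthetic import _axis_taper

        z = template.positions()[:, 2]
        phi, jac, hess = _axis_taper(0.1, 0.2, float(z.min()), float(z.max()))
        out = transform_mesh(template, phi, jac, hess)
        el = template.elements[5].id
        h = 1e-4

        def mapped(x1, x2):
            return phi(evaluate_surface(template, el, x1, x2)[None, :])[0]

        # at an element corner the interpolant's derivatives ARE the nodal
        # DoFs, so the chain-ruled DoFs must match finite differences of the
        # mapped surface exactly (interior points additionally carry
        # interpolation error, since a nonlinear map of a bicubic patch is
        # no longer bicubic)
        d = evaluate_surface(out, el, 0.0, 0.0, order="d1")
        fd1 = (-3 * mapped(0, 0) + 4 * mapped(h, 0) - mapped(2 * h, 0)) / (2 * h)
        fd2 = (-3 * mapped(0, 0) + 4 * mapped(0, h) - mapped(0, 2 * h)) / (2 * h)
        np.testing.assert_allclose(d[0], fd1, rtol=1e-5, atol=1e-4)
        np.testing.assert_allclose(d[1], fd2, rtol=1e-5, atol=1e-4)
        # mixed second derivative via one-sided cross finite difference
        d12 = evaluate_surface(out, el, 0.0, 0.0, order="d2")[1]
        fd12 = (
            mapped(h, h) - mapped(h, 0.0) - mapped(0.0, h) + mapped(0.0, 0.0)
        ) / (h * h)
        np.testing.assert_allclose(d12, fd12, rtol=1e-2, atol=5e-2)


class TestDeformSubject:
    CFG = GeneratorConfig()

    def test_zero_effects_zero_noise_is_scaled_template(self, template):
        cfg = GeneratorConfig(
            taper_per_age_year=0.0, fissure_shift_per_age_year=0.0,
            oblique_rotation_deg_per_year=0.0, ap_change_per_bmi=0.0,
            residual_shape_sd=0.0,
        )
        v_target = 5.0
        mesh, loadings = deform_subject(
            template, 53.0, "F", cfg.bmi_mean, v_target, cfg, seed=1
        )
        s = loadings["volume_scale"]
        np.testing.assert_allclose(mesh.node_dofs, template.node_dofs * s, rtol=1e-10)
        v = mesh_volume(mesh, {"left_lung", "right_lung"}) / 1e6
        assert v == pytest.approx(v_target, rel=1e-10)

    def test_age_monotone_effects(self, template):
        """Same seed and covariates: the older subject has a smaller apical
        AP extent and a lower horizontal fissure."""
        m90, _ = deform_subject(template, 90.0, "F", 24.7, 5.0, self.CFG, seed=7)
        m20, _ = deform_subject(template, 20.0, "F", 24.7, 5.0, self.CFG, seed=7)

        def apical_ap(m):
            p = m.positions()
            top = p[:, 2] > np.percentile(p[:, 2], 80)
            return p[top, 1].max() - p[top, 1].min()

        def hfissure_z(m):
            return m.positions()[fissure_rows(m, "horizontal_fissure"), 2].mean()

        assert apical_ap(m90) < apical_ap(m20)
        assert hfissure_z(m90) < hfissure_z(m20)

    def test_same_seed_identical(self, template):
        m1, l1 = deform_subject(template, 60.0, "M", 26.0, 6.5, self.CFG, seed=3)
        m2, l2 = deform_subject(template, 60.0, "M", 26.0, 6.5, self.CFG, seed=3)
        np.testing.assert_array_equal(m1.node_dofs, m2.node_dofs)
        assert l1 == l2


class TestSampleCloud:
    def test_noise_free_points_on_surface(self, template):
        cloud = sample_cloud(template, density=3, noise_sd=0.0, seed=0)
        sel = slice(0, cloud.n_points, 13)
        _, _, d = project_points(
            template, cloud.points[sel], cloud.labels[sel]
        )
        assert d.max() < 1e-9

    def test_noisy_points_near_surface(self, template):
        sigma = 1.0
        cloud = sample_cloud(template, density=3, noise_sd=sigma, seed=1)
        sel = slice(0, cloud.n_points, 7)
        _, _, d = project_points(template, cloud.points[sel], cloud.labels[sel])
        assert d.max() < 5 * sigma

    def test_noisy_distance_statistics_on_flat_patch(self, rng):
        """On a large flat patch the point-to-surface distance of an
        isotropically displaced sample is the absolute normal component,
        a half-normal with mean sigma sqrt(2/pi)."""
        from lungshape.hermite import MeshTopology, QuadElement

        L = 200.0
        dofs = np.zeros((4, 4, 3))
        dofs[:, 0, :] = np.array(
            [[0, 0, 0], [L, 0, 0], [0, L, 0], [L, L, 0]], float
        )
        dofs[:, 1, :] = [L, 0, 0]
        dofs[:, 2, :] = [0, L, 0]
        mesh = MeshTopology(
            node_ids=[0, 1, 2, 3], node_dofs=dofs,
            elements=[QuadElement(0, (0, 1, 2, 3), "left_lung")],
        )
        sigma = 1.0
        g = rng.uniform(0.2 * L, 0.8 * L, size=(400, 2))  # interior points
        pts = np.column_stack([g, np.zeros(len(g))])
        noisy = pts + rng.normal(0, sigma, size=pts.shape)
        _, _, d = project_points(
            mesh, noisy, np.full(len(noisy), "left_lung", dtype=object)
        )
        np.testing.assert_allclose(d, np.abs(noisy[:, 2]), atol=1e-8)
        assert d.mean() == pytest.approx(sigma * np.sqrt(2 / np.pi), abs=0.12)

    def test_same_seed_identical(self, template):
        c1 = sample_cloud(template, density=3, noise_sd=1.0, seed=5)
        c2 = sample_cloud(template, density=3, noise_sd=1.0, seed=5)
        np.testing.assert_array_equal(c1.points, c2.points)

    def test_density_validation(self, template):
        with pytest.raises(ValueError):
            sample_cloud(template, density=1, noise_sd=0.0, seed=0)


class TestGenerateCohort:
    def test_covariate_distribution_defaults(self):
        cfg = GeneratorConfig(n_subjects=600, seed=0)
        rng = np.random.default_rng(0)
        cov = draw_covariates(cfg, rng)
        assert cov["age"].between(20, 93).all()
        assert cov["bmi"].lt(30).all()
        mu, sd = cfg.truncated_age_moments()
        assert cov["age"].mean() == pytest.approx(mu, abs=2.5)
        assert cov["age"].std() == pytest.approx(sd, abs=2.5)
        assert cov["bmi"].mean() == pytest.approx(24.7, abs=0.5)
        f = cov["sex"].eq("F").mean()
        assert f == pytest.approx(49 / 83, abs=0.06)
        assert cov.loc[cov.sex == "M", "volume_L"].mean() == pytest.approx(6.81, abs=0.25)
        assert cov.loc[cov.sex == "F", "volume_L"].mean() == pytest.approx(4.84, abs=0.25)

    def test_reproducible_from_seed(self):
        cfg = GeneratorConfig(n_subjects=4, seed=9)
        s1, cov1 = generate_cohort(cfg)
        s2, cov2 = generate_cohort(cfg)
        assert cov1.to_csv() == cov2.to_csv()
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.truth_mesh.node_dofs, b.truth_mesh.node_dofs)
            np.testing.assert_array_equal(a.cloud.points, b.cloud.points)
            assert a.planted_loadings == b.planted_loadings

    def test_planted_age_loading_correlation(self):
        """Monte-Carlo: at n=83 the sample correlation between the planted
        age loading and age lands near the configured population target."""
        rs = []
        for seed in range(15):
            subs, cov = generate_cohort_loadings_only(seed)
            loadings = [s for s in subs]
            rs.append(np.corrcoef(loadings, cov["age"])[0, 1])
        rs = np.array(rs)
        assert np.median(rs) == pytest.approx(-0.75, abs=0.08)
        assert ((rs > -0.88) & (rs < -0.58)).mean() >= 0.9

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_subjects=1)
        with pytest.raises(ValueError):
            GeneratorConfig(prop_female=1.4)
        with pytest.raises(ValueError):
            GeneratorConfig(age_loading_correlation=0.5)


def generate_cohort_loadings_only(seed):
    """Covariates plus planted age loadings, skipping mesh construction."""
    import math

    cfg = GeneratorConfig(seed=seed)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    cov = draw_covariates(cfg, rng)
    mu, sd = cfg.truncated_age_moments()
    noise = cfg.age_loading_noise_sd()
    norm = math.sqrt(1 + noise**2)
    child = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(cfg.n_subjects)]
    loadings = []
    for i, row in cov.iterrows():
        r = np.random.default_rng(child[i])
        eps = r.normal(0.0, noise)
        loadings.append(-((row["age"] - mu) / sd + eps) / norm)
    return loadings, cov
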