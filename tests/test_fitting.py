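"""Point projection, smoothness penalty and template fitting."""

import numpy as np
import pytest

from lungshape.fitting import (
    DataPointSet,
    FitConfig,
    SingularFitError,
    fit_mesh,
    project_point,
    project_points,
    smoothness_matrix,
)
from lungshape.hermite import (
    MeshTopology,
    QuadElement,
    evaluate_surface,
    sample_surface,
    surface_normal,
)
from lungshape.synthetic import sample_cloud


def brute_force_project(mesh, point, grid=200):
    """Dense-grid oracle: nearest of grid x grid samples over all elements."""
    best = (np.inf, None)
    g = np.linspace(0, 1, grid)
    X1, X2 = np.meshgrid(g, g)
    for el in mesh.elements:
        dofs = mesh.element_dofs(el.id)
        from lungshape.hermite import basis_weights

        pts = np.einsum(
            "nks,ksc->nc", basis_weights(X1.ravel(), X2.ravel()), dofs
        )
        d = np.linalg.norm(pts - point, axis=1).min()
        if d < best[0]:
            best = (d, el.id)
    return best


class TestProjection:
    def test_on_surface_point_recovers_coordinates(self, template):
        el = template.elements[10]
        p = evaluate_surface(template, el.id, 0.3, 0.7)
        e, xi, d = project_points(
            template, p[None, :], np.array([el.surface], dtype=object)
        )
        assert e[0] == el.id
        assert xi[0] == pytest.approx([0.3, 0.7], abs=1e-4)
        assert d[0] < 1e-8

    def test_offset_along_normal_distance(self, template):
        el = template.elements[12]
        p = evaluate_surface(template, el.id, 0.45, 0.55)
        n = surface_normal(template, el.id, 0.45, 0.55)
        offset = 2.5
        q = p + offset * n
        e, xi, d = project_points(
            template, q[None, :], np.array([el.surface], dtype=object)
        )
        d_oracle, _ = brute_force_project(template, q, grid=120)
        assert d[0] == pytest.approx(offset, abs=1e-3)
        assert d[0] <= d_oracle + 1e-6

    def test_exact_tie_prefers_lowest_element_id(self):
        # two identical flat patches, symmetric about z = 0
        dofs = np.zeros((8, 4, 3))
        corners = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        dofs[:4, 0, :] = corners + [0, 0, 1.0]
        dofs[4:, 0, :] = corners - [0, 0, 1.0]
        for blk in (slice(0, 4), slice(4, 8)):
            dofs[blk, 1, :] = [1, 0, 0]
            dofs[blk, 2, :] = [0, 1, 0]
        mesh = MeshTopology(
            node_ids=list(range(8)),
            node_dofs=dofs,
            elements=[
                QuadElement(5, (0, 1, 2, 3), "left_lung"),
                QuadElement(2, (4, 5, 6, 7), "left_lung"),
            ],
        )
        e, x1, x2, d = project_point(mesh, [0.5, 0.5, 0.0])
        assert e == 2  # equidistant: lowest element id wins
        assert d == pytest.approx(1.0, abs=1e-9)

    def test_label_restriction(self, template):
        # a fissure-labeled point never projects onto a lung element
        p = np.array([[200.0, 0.0, 0.0]])
        e, _, _ = project_points(
            template, p, np.array(["left_oblique_fissure"], dtype=object)
        )
        assert template.element(int(e[0])).surface == "left_oblique_fissure"

    def test_unknown_label_raises(self, template):
        with pytest.raises(ValueError, match="no elements labeled"):
            project_points(
                template, np.zeros((1, 3)), np.array(["pleura"], dtype=object)
            )


class TestSmoothnessMatrix:
    def test_zero_weights_give_zero_matrix(self, template):
        S = smoothness_matrix(template, 0.0, 0.0, 0.0)
        assert not S.any()

    def test_symmetric_positive_semidefinite(self, template):
        S = smoothness_matrix(template, 1.0, 0.5, 0.25)
        np.testing.assert_allclose(S, S.T, atol=1e-10)
        w = np.linalg.eigvalsh(S)
        assert w.min() > -1e-8 * w.max()

    def test_constant_patch_zero_penalty(self):
        dofs = np.zeros((4, 4, 3))
        dofs[:, 0, :] = [1.0, 2.0, 3.0]
        mesh = MeshTopology(
            node_ids=[0, 1, 2, 3], node_dofs=dofs,
            elements=[QuadElement(0, (0, 1, 2, 3), "left_lung")],
        )
        S = smoothness_matrix(mesh, 1.0, 1.0, 1.0)
        u = mesh.node_dofs.reshape(-1, 3)
        assert np.einsum("ic,ij,jc->", u, S, u) == pytest.approx(0.0, abs=1e-10)

    def test_quadratic_scaling_in_single_dof(self):
        """Penalty of a patch with one derivative DoF set to v scales as v^2,
        matching a brute-force fine-quadrature evaluation of the integrand."""
        def penalty(v):
            dofs = np.zeros((4, 4, 3))
            dofs[0, 1, 0] = v  # one d/dxi1 component
            mesh = MeshTopology(
                node_ids=[0, 1, 2, 3], node_dofs=dofs,
                elements=[QuadElement(0, (0, 1, 2, 3), "left_lung")],
            )
            S = smoothness_matrix(mesh, 1.0, 0.0, 0.0)
            u = mesh.node_dofs.reshape(-1, 3)
            return float(np.einsum("ic,ij,jc->", u, S, u))

        base = penalty(1.0)
        assert penalty(3.0) == pytest.approx(9 * base, rel=1e-10)

        # brute-force: integrate |d f/dxi1|^2 + |d f/dxi2|^2 on a fine grid
        from lungshape.hermite import basis_weights

        g = np.linspace(0, 1, 801)
        X1, X2 = np.meshgrid(g, g)
        dofs = np.zeros((4, 4, 3))
        dofs[0, 1, 0] = 1.0
        f1 = np.einsum("nks,ksc->nc", basis_weights(X1.ravel(), X2.ravel(), 1, 0), dofs)
        f2 = np.einsum("nks,ksc->nc", basis_weights(X1.ravel(), X2.ravel(), 0, 1), dofs)
        integrand = np.sum(f1**2 + f2**2, axis=1).reshape(X1.shape)
        brute = np.trapezoid(np.trapezoid(integrand, g, axis=1), g)
        assert base == pytest.approx(brute, rel=1e-5)


class TestFitMesh:
    def test_noise_free_self_fit(self, template):
        cloud = sample_cloud(template, density=5, noise_sd=0.0, seed=1)
        cfg = FitConfig(
            smooth_first=1e-8, smooth_second=1e-8, smooth_cross=1e-8,
            convergence_tol=1e-9, max_outer_iterations=5,
            initial_similarity=False,
        )
        res = fit_mesh(template, cloud, cfg)
        assert res.rmse < 1e-6
        np.testing.assert_allclose(
            res.fitted_mesh.positions(), template.positions(), atol=1e-4
        )

    def test_noisy_fit_rmse_matches_noise_level(self, template):
        sigma = 1.0
        cloud = sample_cloud(template, density=6, noise_sd=sigma, seed=2)
        res = fit_mesh(template, cloud, FitConfig(max_outer_iterations=4))
        assert 0.8 * sigma <= res.rmse <= 1.2 * sigma

    def test_stronger_smoothing_never_reduces_misfit(self, template):
        cloud = sample_cloud(template, density=4, noise_sd=1.0, seed=3)
        lo = fit_mesh(template, cloud, FitConfig(max_outer_iterations=3))
        hi = fit_mesh(
            template, cloud,
            FitConfig(smooth_first=1.0, smooth_second=0.1, smooth_cross=0.1,
                      max_outer_iterations=3),
        )
        assert lo.rmse <= hi.rmse + 1e-9

    def test_energy_monotone_over_outer_iterations(self, template):
        cloud = sample_cloud(template, density=4, noise_sd=1.0, seed=4)
        res = fit_mesh(template, cloud, FitConfig(max_outer_iterations=5))
        e = np.array(res.energy_history)
        assert np.all(np.diff(e) <= 1e-10 * max(1.0, e[0]))

    def test_rigid_equivariance(self, template):
        """Rigidly transforming data and template leaves the RMSE unchanged."""
        from scipy.spatial.transform import Rotation

        cloud = sample_cloud(template, density=4, noise_sd=0.8, seed=5)
        R = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        t = np.array([40.0, -25.0, 60.0])
        cloud_r = DataPointSet(
            points=cloud.points @ R.T + t, labels=cloud.labels,
        )
        dofs_r = np.einsum("ij,nsj->nsi", R, template.node_dofs)
        dofs_r[:, 0, :] += t
        template_r = template.with_dofs(dofs_r)
        cfg = FitConfig(max_outer_iterations=2)
        r1 = fit_mesh(template, cloud, cfg)
        r2 = fit_mesh(template_r, cloud_r, cfg)
        assert r1.rmse == pytest.approx(r2.rmse, abs=1e-8)

    def test_zero_smoothing_rank_deficiency_raises(self, template):
        # far too few points to determine all DoFs, and no regularisation
        cloud = sample_cloud(template, density=2, noise_sd=0.0, seed=6)
        few = DataPointSet(
            points=cloud.points[:40], labels=cloud.labels[:40],
        )
        cfg = FitConfig(smooth_first=0.0, smooth_second=0.0, smooth_cross=0.0,
                        max_outer_iterations=1)
        with pytest.raises(SingularFitError, match="smoothing"):
            fit_mesh(template, few, cfg)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            DataPointSet(points=np.zeros((0, 3)), labels=np.array([]))
        with pytest.raises(ValueError):
            DataPointSet(
                points=np.zeros((2, 3)),
                labels=np.array(["left_lung", "left_lung"], dtype=object),
                weights=np.array([1.0, -1.0]),
            )
        with pytest.raises(ValueError):
            FitConfig(smooth_first=-1.0)
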