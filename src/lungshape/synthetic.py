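"""Synthetic lung-shape cohort generator.

Emulates the study material the pipeline consumes: per-subject ground-truth
bi-lung + fissure Hermite meshes, noisy labeled surface point clouds, and a
covariate table (age, sex, BMI, imaged lung volume).  The geometry is an
idealised surface of revolution per lung (smooth ellipsoid-like closed
surface, shallow asymmetric base standing in for the diaphragm dome) with
an oblique fissure sheet in each lung and a horizontal fissure in the
right lung — deliberately schematic so that every planted effect can be
measured analytically.

Covariate-linked shape effects, applied in a fixed order:

1. isotropic scale to the subject's target lung volume (volume is drawn by
   sex, so size also carries the sex effect);
2. an age-linked apical taper: the antero-posterior (and, half as
   strongly, mediolateral) extent shrinks towards the apex in older
   subjects;
3. age-linked fissure displacement: the horizontal fissure translates
   towards the base and the oblique fissures rotate posteriorly;
4. a BMI-linked uniform antero-posterior change;
5. a smooth random residual deformation (quadratic polynomial displacement
   field, rescaled to an exact RMS amplitude).

Effects 2 and 3 share a single scalar "age loading": a standardised age
signal plus Gaussian noise, with the noise level chosen so the population
correlation between the loading and age equals a configurable target
(default -0.75).  The loading is returned with each subject so recovery
tests can check the pipeline finds it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .fitting import DataPointSet
from .hermite import MeshTopology, QuadElement, mesh_volume, sample_surface

LUNG_LABELS = {"left_lung", "right_lung"}


# ---------------------------------------------------------------------------
# configuration


@dataclass
class GeneratorConfig:
    """Cohort-level generator settings.

    Covariate distributions default to the study conditions: n = 83,
    age 53 +/- 22 years (range-clipped 20-93), BMI 24.7 +/- 2.7 kg/m^2
    (clipped below 30, the exclusion threshold), 49 F / 34 M expected
    proportions, and imaged lung volumes of 6.81 +/- 1.16 L (M) and
    4.84 +/- 0.85 L (F).
    """

    n_subjects: int = 83
    seed: int = 0
    # covariate distributions
    age_mean: float = 53.0
    age_sd: float = 22.0
    age_range: tuple[float, float] = (20.0, 93.0)
    bmi_mean: float = 24.7
    bmi_sd: float = 2.7
    bmi_range: tuple[float, float] = (17.0, 30.0)
    prop_female: float = 49 / 83
    volume_mean_F: float = 4.84
    volume_sd_F: float = 0.85
    volume_mean_M: float = 6.81
    volume_sd_M: float = 1.16
    # planted effect sizes
    taper_per_age_year: float = 0.004  # fractional AP change per year, at apex
    mediolateral_taper_ratio: float = 0.5
    fissure_shift_per_age_year: float = 0.3  # mm/yr basal shift, horizontal fissure
    oblique_rotation_deg_per_year: float = 0.08  # posterior rotation, oblique fissures
    ap_change_per_bmi: float = 0.006  # fractional AP change per kg/m^2
    age_loading_correlation: float = -0.75  # target corr(age loading, age)
    residual_shape_sd: float = 1.0  # mm RMS of the smooth random deformation
    # point-cloud sampling
    cloud_density: int = 5  # xi-grid points per element edge
    cloud_noise_sd: float = 1.0  # mm isotropic

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0 <= self.prop_female <= 1:
            raise ValueError("prop_female must be in [0, 1]")
        for sd in (self.age_sd, self.bmi_sd, self.volume_sd_F, self.volume_sd_M,
                   self.residual_shape_sd, self.cloud_noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")
        if not -1 < self.age_loading_correlation < 0:
            raise ValueError("age_loading_correlation must be in (-1, 0)")

    def truncated_age_moments(self) -> tuple[float, float]:
        """Mean and SD of the range-clipped age distribution."""
        a = (self.age_range[0] - self.age_mean) / self.age_sd
        b = (self.age_range[1] - self.age_mean) / self.age_sd
        d = scipy.stats.truncnorm(a, b, loc=self.age_mean, scale=self.age_sd)
        return float(d.mean()), float(d.std())

    def age_loading_noise_sd(self) -> float:
        """Noise SD (on the unit-SD age signal) realising the target correlation."""
        r = abs(self.age_loading_correlation)
        return math.sqrt(1.0 / r**2 - 1.0)


@dataclass
class SyntheticSubject:
    subject_id: str
    age: float
    sex: str
    bmi: float
    volume_L: float
    truth_mesh: MeshTopology
    cloud: DataPointSet
    planted_loadings: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# template geometry


def _revolution_surface_nodes(
    n_circ: int, n_rings: int, center, a: float, b: float,
    c_up: float, c_down: float, start_id: int,
):
    """Closed surface of revolution with collapsed pole rings.

    z(phi) = c1 sin(phi) + c2 sin^2(phi) blends the apical and basal
    semi-heights smoothly; interior rings are uniform in latitude.  Pole
    rings repeat the pole position once per circumferential column (ids
    stay distinct) with a vanishing circumferential derivative, so the
    collapsed element edges degenerate cleanly to the pole point.
    """
    cx, cy, cz = center
    c1 = (c_up + c_down) / 2.0
    c2 = (c_up - c_down) / 2.0
    dtheta = 2 * np.pi / n_circ
    dphi = np.pi / (n_rings + 1)
    node_ids, dofs = [], []
    nid = start_id
    rows = []
    for j in range(n_rings + 2):  # j=0 base pole ... j=n_rings+1 apex pole
        phi = -np.pi / 2 + j * dphi
        sphi, cphi = np.sin(phi), np.cos(phi)
        row = []
        for i in range(n_circ):
            theta = i * dtheta
            st, ct = np.sin(theta), np.cos(theta)
            pos = np.array([cx + a * cphi * ct, cy + b * cphi * st,
                            cz + c1 * sphi + c2 * sphi**2])
            d_th = np.array([-a * cphi * st, b * cphi * ct, 0.0]) * dtheta
            d_ph = np.array([-a * sphi * ct, -b * sphi * st,
                             c1 * cphi + 2 * c2 * sphi * cphi]) * dphi
            d_mix = np.array([a * sphi * st, -b * sphi * ct, 0.0]) * dtheta * dphi
            dofs.append(np.stack([pos, d_th, d_ph, d_mix]))
            node_ids.append(nid)
            row.append(nid)
            nid += 1
        rows.append(row)
    return node_ids, dofs, rows


def _grid_patch_nodes(nu: int, nv: int, point_fn, du_fn, dv_fn, start_id: int):
    """Open quad-grid sheet from analytic P(u, v) and its partials."""
    node_ids, dofs, rows = [], [], []
    nid = start_id
    su, sv = 1.0 / (nu - 1), 1.0 / (nv - 1)
    for j in range(nv):
        v = j * sv
        row = []
        for i in range(nu):
            u = i * su
            pos = np.asarray(point_fn(u, v), dtype=float)
            d1 = np.asarray(du_fn(u, v), dtype=float) * su
            d2 = np.asarray(dv_fn(u, v), dtype=float) * sv
            # mixed partials of the analytic sheets below are dominated by
            # the separable dome term; finite-difference them for generality
            h = 1e-5
            dmix = (
                np.asarray(du_fn(u, min(v + h, 1.0)), dtype=float)
                - np.asarray(du_fn(u, max(v - h, 0.0)), dtype=float)
            ) / (min(v + h, 1.0) - max(v - h, 0.0)) * su * sv
            dofs.append(np.stack([pos, d1, d2, dmix]))
            node_ids.append(nid)
            row.append(nid)
            nid += 1
        rows.append(row)
    return node_ids, dofs, rows


def _band_elements(rows, surface, wrap: bool, start_eid: int):
    els = []
    eid = start_eid
    for j in range(len(rows) - 1):
        ncol = len(rows[j])
        rng = range(ncol) if wrap else range(ncol - 1)
        for i in rng:
            i2 = (i + 1) % ncol if wrap else i + 1
            els.append(QuadElement(
                eid, (rows[j][i], rows[j][i2], rows[j + 1][i], rows[j + 1][i2]),
                surface,
            ))
            eid += 1
    return els, eid


def _oblique_fissure_fns(cx, a, b, c_up, c_down):
    """Slanted sheet from posterior-superior to anterior-inferior."""
    y0, y1 = -0.60 * b, 0.55 * b
    z0, z1 = 0.45 * c_up, -0.50 * c_down
    w = 0.80 * a
    dome = 6.0

    def P(u, v):
        return (
            cx + w * (u - 0.5),
            y0 + (y1 - y0) * v,
            z0 + (z1 - z0) * v + dome * np.sin(np.pi * u) * np.sin(np.pi * v),
        )

    def Pu(u, v):
        return (w, 0.0, dome * np.pi * np.cos(np.pi * u) * np.sin(np.pi * v))

    def Pv(u, v):
        return (0.0, y1 - y0,
                (z1 - z0) + dome * np.pi * np.sin(np.pi * u) * np.cos(np.pi * v))

    return P, Pu, Pv


def _horizontal_fissure_fns(cx, a, b, c_up):
    """Roughly horizontal sheet in the anterior upper right lung."""
    zh = 0.25 * c_up
    w = 0.70 * a
    y0, y1 = 0.05 * b, 0.60 * b
    dome = 4.0

    def P(u, v):
        return (
            cx + w * (u - 0.5),
            y0 + (y1 - y0) * v,
            zh + dome * np.sin(np.pi * u) * np.sin(np.pi * v),
        )

    def Pu(u, v):
        return (w, 0.0, dome * np.pi * np.cos(np.pi * u) * np.sin(np.pi * v))

    def Pv(u, v):
        return (0.0, y1 - y0, dome * np.pi * np.sin(np.pi * u) * np.cos(np.pi * v))

    return P, Pu, Pv


# Idealised thorax dimensions (mm).  Frame: +x to the subject's left,
# +y posterior -> anterior, +z caudal -> cranial.
_LEFT = dict(center=(60.0, 0.0, 0.0), a=50.0, b=70.0, c_up=125.0, c_down=85.0)
_RIGHT = dict(center=(-60.0, 0.0, 0.0), a=55.0, b=75.0, c_up=130.0, c_down=90.0)


def template_lung_mesh(
    left_circ: int = 6,
    left_rings: int = 4,
    right_circ: int = 6,
    right_rings: int = 5,
    oblique_grid: tuple[int, int] = (3, 3),
    horizontal_grid: tuple[int, int] = (3, 2),
) -> MeshTopology:
    """The fixed idealised bi-lung + three-fissure template.

    Deterministic; both lungs are closed surfaces of revolution, each lung
    carries its oblique fissure sheet and the right lung additionally the
    horizontal fissure.  Node and element counts follow from the grid
    arguments; the defaults approximate the scale of a coarse anatomical
    lung template.
    """
    node_ids: list[int] = []
    dofs: list[np.ndarray] = []
    elements: list[QuadElement] = []
    eid = 0

    def add_surface(ids, dd, rows, surface, wrap):
        nonlocal eid
        node_ids.extend(ids)
        dofs.extend(dd)
        els, eid2 = _band_elements(rows, surface, wrap, eid)
        elements.extend(els)
        eid = eid2

    ids, dd, rows = _revolution_surface_nodes(
        left_circ, left_rings, _LEFT["center"], _LEFT["a"], _LEFT["b"],
        _LEFT["c_up"], _LEFT["c_down"], start_id=0,
    )
    add_surface(ids, dd, rows, "left_lung", wrap=True)

    ids, dd, rows = _revolution_surface_nodes(
        right_circ, right_rings, _RIGHT["center"], _RIGHT["a"], _RIGHT["b"],
        _RIGHT["c_up"], _RIGHT["c_down"], start_id=len(node_ids),
    )
    add_surface(ids, dd, rows, "right_lung", wrap=True)

    P, Pu, Pv = _oblique_fissure_fns(
        _LEFT["center"][0], _LEFT["a"], _LEFT["b"], _LEFT["c_up"], _LEFT["c_down"]
    )
    ids, dd, rows = _grid_patch_nodes(*oblique_grid, P, Pu, Pv, len(node_ids))
    add_surface(ids, dd, rows, "left_oblique_fissure", wrap=False)

    P, Pu, Pv = _oblique_fissure_fns(
        _RIGHT["center"][0], _RIGHT["a"], _RIGHT["b"], _RIGHT["c_up"], _RIGHT["c_down"]
    )
    ids, dd, rows = _grid_patch_nodes(*oblique_grid, P, Pu, Pv, len(node_ids))
    add_surface(ids, dd, rows, "right_oblique_fissure", wrap=False)

    P, Pu, Pv = _horizontal_fissure_fns(
        _RIGHT["center"][0], _RIGHT["a"], _RIGHT["b"], _RIGHT["c_up"]
    )
    ids, dd, rows = _grid_patch_nodes(*horizontal_grid, P, Pu, Pv, len(node_ids))
    add_surface(ids, dd, rows, "horizontal_fissure", wrap=False)

    landmarks = ["pseudo"] * len(node_ids)
    # pole nodes of each lung act as anatomical landmarks (apices, base)
    for k in range(left_circ):
        landmarks[k] = "anatomical"
    return MeshTopology(
        node_ids=node_ids,
        node_dofs=np.stack(dofs),
        elements=elements,
        landmarks=landmarks,
    )


def reference_topology() -> MeshTopology:
    """Fixture topology at the full-description scale: 225 nodes, so a
    shape vector of 225 x 12 = 2700 parameters."""
    return template_lung_mesh(
        left_circ=5, left_rings=10,
        right_circ=5, right_rings=13,
        oblique_grid=(5, 6),
        horizontal_grid=(5, 6),
    )


# ---------------------------------------------------------------------------
# mesh transformation with exact DoF chain rule


def transform_mesh(mesh: MeshTopology, phi, jac, hess=None) -> MeshTopology:
    """Apply a smooth spatial map to all 12 DoFs of every node.

    phi(pos) -> (n, 3) new positions; jac(pos) -> (n, 3, 3) Jacobians
    d phi_i / d x_j; hess(pos) -> (n, 3, 3, 3) second derivatives
    d^2 phi_i / d x_j d x_k (needed for the mixed-derivative DoF when the
    map is nonlinear).
    """
    pos = mesh.node_dofs[:, 0, :]
    J = jac(pos)
    new = np.empty_like(mesh.node_dofs)
    new[:, 0, :] = phi(pos)
    for slot in (1, 2):
        new[:, slot, :] = np.einsum("nij,nj->ni", J, mesh.node_dofs[:, slot, :])
    d12 = np.einsum("nij,nj->ni", J, mesh.node_dofs[:, 3, :])
    if hess is not None:
        H = hess(pos)
        d12 += np.einsum(
            "nijk,nj,nk->ni", H, mesh.node_dofs[:, 1, :], mesh.node_dofs[:, 2, :]
        )
    new[:, 3, :] = d12
    return mesh.with_dofs(new)


def _isotropic_scale(s: float):
    return (
        lambda p: s * p,
        lambda p: np.broadcast_to(s * np.eye(3), (p.shape[0], 3, 3)),
        None,
    )


def _axis_taper(gx: float, gy: float, z_lo: float, z_hi: float):
    """x, y scaled by (1 + g ztilde) with ztilde the normalised height."""
    rng = z_hi - z_lo

    def phi(p):
        zt = (p[:, 2] - z_lo) / rng
        out = p.copy()
        out[:, 0] *= 1 + gx * zt
        out[:, 1] *= 1 + gy * zt
        return out

    def jac(p):
        zt = (p[:, 2] - z_lo) / rng
        J = np.zeros((p.shape[0], 3, 3))
        J[:, 0, 0] = 1 + gx * zt
        J[:, 1, 1] = 1 + gy * zt
        J[:, 2, 2] = 1.0
        J[:, 0, 2] = p[:, 0] * gx / rng
        J[:, 1, 2] = p[:, 1] * gy / rng
        return J

    def hess(p):
        H = np.zeros((p.shape[0], 3, 3, 3))
        H[:, 0, 0, 2] = H[:, 0, 2, 0] = gx / rng
        H[:, 1, 1, 2] = H[:, 1, 2, 1] = gy / rng
        return H

    return phi, jac, hess


def _ap_scale(g: float):
    D = np.diag([1.0, 1.0 + g, 1.0])

    def phi(p):
        return p @ D.T

    def jac(p):
        return np.broadcast_to(D, (p.shape[0], 3, 3))

    return phi, jac, None


def _quadratic_field(rng: np.random.Generator, nodes: np.ndarray, rms: float,
                     length_scale: float = 150.0):
    """Smooth random displacement field, rescaled to an exact nodal RMS."""
    A = rng.normal(size=3)
    B = rng.normal(size=(3, 3))
    C = rng.normal(size=(3, 3, 3))
    C = 0.5 * (C + np.swapaxes(C, 1, 2))  # symmetric in the two x slots
    center = nodes.mean(axis=0)

    def raw_u(p):
        xt = (p - center) / length_scale
        return (
            A[None, :]
            + np.einsum("ij,nj->ni", B, xt)
            + np.einsum("ijk,nj,nk->ni", C, xt, xt)
        )

    scale0 = np.sqrt(np.mean(np.sum(raw_u(nodes) ** 2, axis=1)))
    s = 0.0 if scale0 == 0 else rms / scale0

    def phi(p):
        return p + s * raw_u(p)

    def jac(p):
        xt = (p - center) / length_scale
        J = np.broadcast_to(np.eye(3), (p.shape[0], 3, 3)).copy()
        J += s * (B[None, :, :] + 2 * np.einsum("ijk,nk->nij", C, xt)) / length_scale
        return J

    def hess(p):
        H = np.broadcast_to(2 * s * C / length_scale**2, (p.shape[0], 3, 3, 3))
        return H

    return phi, jac, hess


def _rotate_about_x(mesh: MeshTopology, node_rows: np.ndarray, beta: float,
                    center: np.ndarray) -> None:
    """In-place proper rotation of a node subset about a mediolateral axis."""
    cb, sb = np.cos(beta), np.sin(beta)
    R = np.array([[1, 0, 0], [0, cb, -sb], [0, sb, cb]], dtype=float)
    blocks = mesh.node_dofs[node_rows]
    blocks = np.einsum("ij,nsj->nsi", R, blocks)
    blocks[:, 0, :] += center - R @ center
    mesh.node_dofs[node_rows] = blocks


def _fissure_node_rows(mesh: MeshTopology, surface: str) -> np.ndarray:
    rows = set()
    for el in mesh.elements_for_surface(surface):
        rows.update(mesh.node_index(nid) for nid in el.node_ids)
    return np.array(sorted(rows), dtype=int)


# ---------------------------------------------------------------------------
# subject generation


def deform_subject(
    template: MeshTopology,
    age: float,
    sex: str,
    bmi: float,
    volume_L: float,
    config: GeneratorConfig,
    seed: int,
) -> tuple[MeshTopology, dict[str, float]]:
    """Deform the template into one subject's ground-truth mesh.

    Returns the mesh and the planted per-effect scalar loadings
    (age loading, BMI deviation, volume scale factor).
    """
    rng = np.random.default_rng(seed)
    mu_age, sd_age = config.truncated_age_moments()
    eps = rng.normal(0.0, config.age_loading_noise_sd())
    # loading is positive-young by construction; corr(loading, age) equals
    # the configured target in the population
    norm = math.sqrt(1.0 + config.age_loading_noise_sd() ** 2)
    age_loading = -((age - mu_age) / sd_age + eps) / norm

    mesh = template.copy()

    # 1. isotropic scale to the target volume
    v_template = mesh_volume(mesh, LUNG_LABELS) / 1e6  # litres
    s = (volume_L / v_template) ** (1.0 / 3.0)
    mesh = transform_mesh(mesh, *_isotropic_scale(s))

    # 2. apical taper (AP strongly, mediolateral at half strength)
    z = mesh.positions()[:, 2]
    g = config.taper_per_age_year * sd_age * norm * age_loading
    mesh = transform_mesh(
        mesh, *_axis_taper(config.mediolateral_taper_ratio * g, g,
                           float(z.min()), float(z.max()))
    )

    # 3. fissure displacement: horizontal translates basally, obliques
    # rotate posteriorly about their lung's centre
    dz = config.fissure_shift_per_age_year * sd_age * norm * age_loading
    hrows = _fissure_node_rows(mesh, "horizontal_fissure")
    mesh.node_dofs[hrows, 0, 2] += dz
    beta = -np.deg2rad(config.oblique_rotation_deg_per_year * sd_age * norm) * age_loading
    for surface, side in (("left_oblique_fissure", _LEFT), ("right_oblique_fissure", _RIGHT)):
        rows = _fissure_node_rows(mesh, surface)
        center = s * np.asarray(side["center"], dtype=float)
        _rotate_about_x(mesh, rows, beta, center)

    # 4. BMI-linked AP change
    bmi_loading = bmi - config.bmi_mean
    mesh = transform_mesh(mesh, *_ap_scale(config.ap_change_per_bmi * bmi_loading))

    # 5. smooth residual deformation
    if config.residual_shape_sd > 0:
        mesh = transform_mesh(
            mesh, *_quadratic_field(rng, mesh.positions(), config.residual_shape_sd)
        )

    loadings = {
        "age": float(age_loading),
        "bmi": float(bmi_loading),
        "volume_scale": float(s),
    }
    return mesh, loadings


def sample_cloud(
    truth_mesh: MeshTopology, density: int, noise_sd: float, seed: int
) -> DataPointSet:
    """Noisy labeled surface samples standing in for a CT segmentation."""
    if density < 2:
        raise ValueError("density must be >= 2")
    rng = np.random.default_rng(seed)
    points, prov = sample_surface(truth_mesh, density)
    labels = np.array(
        [truth_mesh.element(e).surface for e, _, _ in prov], dtype=object
    )
    if noise_sd > 0:
        points = points + rng.normal(0.0, noise_sd, size=points.shape)
    return DataPointSet(points=points, labels=labels)


def draw_covariates(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sample the cohort covariate table."""
    n = config.n_subjects
    a = (config.age_range[0] - config.age_mean) / config.age_sd
    b = (config.age_range[1] - config.age_mean) / config.age_sd
    age = scipy.stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    sex = np.where(rng.random(n) < config.prop_female, "F", "M")
    lo = (config.bmi_range[0] - config.bmi_mean) / config.bmi_sd
    hi = (config.bmi_range[1] - config.bmi_mean) / config.bmi_sd
    bmi = scipy.stats.truncnorm.rvs(
        lo, hi, loc=config.bmi_mean, scale=config.bmi_sd, size=n, random_state=rng
    )
    vol_mean = np.where(sex == "F", config.volume_mean_F, config.volume_mean_M)
    vol_sd = np.where(sex == "F", config.volume_sd_F, config.volume_sd_M)
    volume = np.clip(rng.normal(vol_mean, vol_sd), 2.0, None)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "volume_L": volume,
        }
    )


def generate_cohort(
    config: GeneratorConfig | None = None,
    template: MeshTopology | None = None,
) -> tuple[list[SyntheticSubject], pd.DataFrame]:
    """Draw covariates and build every subject's truth mesh and cloud.

    Fully reproducible from ``config.seed``; per-subject randomness uses
    spawned substreams so subjects are independent of each other.
    """
    config = config or GeneratorConfig()
    template = template or template_lung_mesh()
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    cov = draw_covariates(config, rng)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_subjects)]
    subjects = []
    for i, row in cov.iterrows():
        mesh, loadings = deform_subject(
            template, row["age"], row["sex"], row["bmi"], row["volume_L"],
            config, seed=child_seeds[i],
        )
        cloud = sample_cloud(
            mesh, config.cloud_density, config.cloud_noise_sd,
            seed=child_seeds[i] + 1,
        )
        subjects.append(
            SyntheticSubject(
                subject_id=row["subject_id"],
                age=float(row["age"]),
                sex=str(row["sex"]),
                bmi=float(row["bmi"]),
                volume_L=float(row["volume_L"]),
                truth_mesh=mesh,
                cloud=cloud,
                planted_loadings=loadings,
            )
        )
    return subjects, cov
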