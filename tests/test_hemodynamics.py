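import numpy as np
import pytest

from flowpost import hemodynamics as hd
from flowpost import segmentation as seg
from flowpost.io_grids.types import BinaryMask, GridGeometry, ScalarVolume, TriMesh, VelocityField
from flowpost.synthetic import PhantomSpec, gen_phantom

from conftest import linear_field, uniform_field


def single_face_mesh(z=5.0):
    """One triangle in the z = const plane with outward normal +z."""
    verts = np.array([[2.0, 2.0, z], [4.0, 2.0, z], [2.0, 4.0, z]])
    mesh = TriMesh(vertices=verts, faces=np.array([[0, 1, 2]]))
    assert np.allclose(mesh.face_normals[0], [0, 0, 1])
    return mesh


@pytest.fixture
def grid_10mm():
    return GridGeometry(shape=(11, 11, 11), spacing=(1.0, 1.0, 1.0))


# ---------------------------------------------------------------------------
# sample_inner_velocity
# ---------------------------------------------------------------------------

def test_sample_uniform_field(grid_10mm):
    field = uniform_field(grid_10mm, (0.1, 0.0, 0.0))
    sampled = hd.sample_inner_velocity(single_face_mesh(), field, depth=5e-4)
    assert np.allclose(sampled, [[0.1, 0.0, 0.0]])


def test_sample_linear_field_exact(grid_10mm):
    a = np.array([[10.0, 2.0, 0.0], [0.0, -3.0, 1.0], [4.0, 0.0, 7.0]])
    field = linear_field(grid_10mm, a)
    mesh = single_face_mesh()
    depth = 7e-4
    sampled = hd.sample_inner_velocity(mesh, field, depth=depth)
    point_m = (mesh.face_centers[0] - depth * 1e3 * mesh.face_normals[0]) * 1e-3
    assert np.allclose(sampled[0], a @ point_m, atol=1e-10)


def test_sample_zero_field(grid_10mm):
    sampled = hd.sample_inner_velocity(single_face_mesh(),
                                       uniform_field(grid_10mm, (0, 0, 0)),
                                       depth=5e-4)
    assert np.allclose(sampled, 0.0)


def test_sample_outside_grid_flagged(grid_10mm):
    field = uniform_field(grid_10mm, (0.1, 0.0, 0.0))
    # sampling deeper than the grid extent leaves the volume
    sampled = hd.sample_inner_velocity(single_face_mesh(z=0.0), field, depth=0.02)
    assert np.isnan(sampled).all()


def test_sample_rejects_nonpositive_depth(grid_10mm):
    with pytest.raises(ValueError):
        hd.sample_inner_velocity(single_face_mesh(),
                                 uniform_field(grid_10mm, (0, 0, 0)), depth=0.0)


# ---------------------------------------------------------------------------
# compute_wss
# ---------------------------------------------------------------------------

def test_wss_zero_field(grid_10mm):
    wss = hd.compute_wss(single_face_mesh(), uniform_field(grid_10mm, (0, 0, 0)))
    assert np.allclose(wss.vectors, 0.0)


def test_wss_single_face_hand_value(grid_10mm):
    # mu * v_t / depth = 0.004 * 0.1 / 0.0005 = 0.8 Pa along +x
    field = uniform_field(grid_10mm, (0.1, 0.0, 0.0))
    wss = hd.compute_wss(single_face_mesh(), field, depth=5e-4)
    assert wss.magnitude[0] == pytest.approx(0.8, rel=1e-12)
    assert np.allclose(wss.vectors[0], [0.8, 0.0, 0.0], atol=1e-12)


def test_wss_tangential_to_normal(poiseuille_1mm):
    field, mask, _ = poiseuille_1mm
    mesh = seg.smooth_laplacian(seg.extract_surface(mask), 4, 0.5)
    wss = hd.compute_wss(mesh, field)
    dots = np.abs(np.einsum("ij,ij->i", wss.vectors[wss.valid],
                            mesh.face_normals[wss.valid]))
    assert (dots <= 1e-6 * np.maximum(wss.magnitude[wss.valid], 1e-300)).all()


def test_wss_poiseuille_oracle(poiseuille_1mm):
    field, mask, truth = poiseuille_1mm
    mesh = seg.smooth_laplacian(seg.extract_surface(mask), 4, 0.5)
    wss = hd.compute_wss(mesh, field)
    assert wss.area_averaged_magnitude() == pytest.approx(truth.wss_pa, rel=0.20)


def test_wss_all_faces_excluded(grid_10mm):
    field = uniform_field(grid_10mm, (0.1, 0.0, 0.0))
    mesh = single_face_mesh(z=0.0)
    with pytest.raises(ValueError):
        hd.compute_wss(mesh, field, depth=0.05)  # sample leaves the grid


def test_wss_invalid_frame(grid_10mm):
    with pytest.raises(IndexError):
        hd.compute_wss(single_face_mesh(), uniform_field(grid_10mm, (0, 0, 0)),
                       frame=2)


# ---------------------------------------------------------------------------
# strain_rate
# ---------------------------------------------------------------------------

def full_mask(geometry):
    return BinaryMask(geometry, np.ones(geometry.shape, dtype=bool))


def test_strain_uniform_translation(grid_10mm):
    field = uniform_field(grid_10mm, (0.2, -0.1, 0.05))
    strain = hd.strain_rate(field, 0, full_mask(grid_10mm))
    assert np.allclose(strain.tensor, 0.0, atol=1e-12)


def test_strain_rigid_rotation(grid_10mm):
    omega = np.array([0.0, 0.0, 50.0])  # rad/s
    a = np.array([[0, -omega[2], 0], [omega[2], 0, 0], [0, 0, 0]], dtype=float)
    field = linear_field(grid_10mm, a)
    strain = hd.strain_rate(field, 0, full_mask(grid_10mm))
    assert np.allclose(strain.tensor[strain.valid], 0.0, atol=1e-8)


def test_strain_simple_shear(grid_10mm):
    gamma = 100.0  # u_x = gamma * y
    a = np.zeros((3, 3))
    a[0, 1] = gamma
    strain = hd.strain_rate(linear_field(grid_10mm, a), 0, full_mask(grid_10mm))
    s = strain.tensor[strain.valid]
    assert np.allclose(s[:, 0, 1], 50.0, atol=1e-8)
    assert np.allclose(s[:, 1, 0], 50.0, atol=1e-8)
    zero = [(0, 0), (1, 1), (2, 2), (0, 2), (2, 0), (1, 2), (2, 1)]
    for i, j in zero:
        assert np.allclose(s[:, i, j], 0.0, atol=1e-8)


def test_strain_symmetric_by_construction(grid_10mm):
    rng = np.random.default_rng(0)
    values = rng.normal(size=(1, *grid_10mm.shape, 3))
    field = VelocityField(geometry=grid_10mm, values=values)
    strain = hd.strain_rate(field, 0, full_mask(grid_10mm))
    assert np.array_equal(strain.tensor, np.swapaxes(strain.tensor, -1, -2))


def test_strain_geometry_mismatch(grid_10mm, unit_grid):
    field = uniform_field(grid_10mm, (0, 0, 0))
    with pytest.raises(ValueError):
        hd.strain_rate(field, 0, full_mask(unit_grid))


# ---------------------------------------------------------------------------
# eddy viscosities
# ---------------------------------------------------------------------------

def test_rng_zero_k(unit_grid):
    k = ScalarVolume(unit_grid, np.zeros(unit_grid.shape), unit="m^2/s^2")
    eps = ScalarVolume(unit_grid, np.full(unit_grid.shape, 0.1), unit="m^2/s^3")
    assert not hd.eddy_viscosity_rng(k, eps).values.any()


def test_rng_hand_value(unit_grid):
    # Cmu * rho * k^2 / eps = 0.0845 * 1060 * 1e-4 / 0.1
    k = ScalarVolume(unit_grid, np.full(unit_grid.shape, 0.01), unit="m^2/s^2")
    eps = ScalarVolume(unit_grid, np.full(unit_grid.shape, 0.1), unit="m^2/s^3")
    mu_t = hd.eddy_viscosity_rng(k, eps)
    assert np.allclose(mu_t.values, 0.0845 * 1060 * 1e-4 / 0.1, rtol=1e-12)


def test_rng_k_squared_scaling(unit_grid):
    eps = ScalarVolume(unit_grid, np.full(unit_grid.shape, 0.3), unit="m^2/s^3")
    k1 = ScalarVolume(unit_grid, np.full(unit_grid.shape, 0.02), unit="m^2/s^2")
    k2 = ScalarVolume(unit_grid, np.full(unit_grid.shape, 0.04), unit="m^2/s^2")
    assert np.allclose(hd.eddy_viscosity_rng(k2, eps).values,
                       4.0 * hd.eddy_viscosity_rng(k1, eps).values)


def test_rng_epsilon_floor(unit_grid):
    k = ScalarVolume(unit_grid, np.full(unit_grid.shape, 0.01), unit="m^2/s^2")
    eps = ScalarVolume(unit_grid, np.zeros(unit_grid.shape), unit="m^2/s^3")
    assert not hd.eddy_viscosity_rng(k, eps).values.any()


def test_rng_rejects_wrong_units(unit_grid):
    k = ScalarVolume(unit_grid, np.zeros(unit_grid.shape), unit="a.u.")
    eps = ScalarVolume(unit_grid, np.ones(unit_grid.shape), unit="m^2/s^3")
    with pytest.raises(ValueError):
        hd.eddy_viscosity_rng(k, eps)


def test_les_uniform_flow(grid_10mm):
    strain = hd.strain_rate(uniform_field(grid_10mm, (0.3, 0, 0)), 0,
                            full_mask(grid_10mm))
    assert np.allclose(hd.eddy_viscosity_les(strain).values, 0.0, atol=1e-20)


def test_les_simple_shear_hand_value(grid_10mm):
    # |S| = sqrt(2*(50^2+50^2)) = 100 /s; mu_t = (0.1 * 1e-3)^2 * 100 = 1e-6
    a = np.zeros((3, 3))
    a[0, 1] = 100.0
    strain = hd.strain_rate(linear_field(grid_10mm, a), 0, full_mask(grid_10mm))
    model = hd.ClosureModel(kind="les_smagorinsky", delta=1e-3)
    mu_t = hd.eddy_viscosity_les(strain, model)
    assert np.allclose(mu_t.values[strain.valid], 1e-6, rtol=1e-10)


def test_les_rigid_rotation_zero(grid_10mm):
    a = np.array([[0, -40.0, 0], [40.0, 0, 0], [0, 0, 0]])
    strain = hd.strain_rate(linear_field(grid_10mm, a), 0, full_mask(grid_10mm))
    mu_t = hd.eddy_viscosity_les(strain)
    assert np.allclose(mu_t.values[strain.valid], 0.0, atol=1e-12)


# ---------------------------------------------------------------------------
# boundary_layer_mask
# ---------------------------------------------------------------------------

def test_boundary_layer_thin_slab(unit_grid):
    values = np.zeros(unit_grid.shape, dtype=bool)
    values[:, :, 3] = True
    shell = hd.boundary_layer_mask(BinaryMask(unit_grid, values))
    assert np.array_equal(shell.values, values)


def test_boundary_layer_cube_count():
    geometry = GridGeometry(shape=(9, 9, 9), spacing=(1, 1, 1))
    values = np.zeros((9, 9, 9), dtype=bool)
    values[2:7, 2:7, 2:7] = True
    shell = hd.boundary_layer_mask(BinaryMask(geometry, values))
    assert shell.count == 5**3 - 3**3  # == 98


def test_boundary_layer_erosion_oracle():
    rng = np.random.default_rng(9)
    geometry = GridGeometry(shape=(12, 12, 12), spacing=(1, 1, 1))
    values = rng.random((12, 12, 12)) > 0.4
    shell = hd.boundary_layer_mask(BinaryMask(geometry, values))
    # brute force: voxel is boundary iff some 6-neighbor is false/outside
    expected = np.zeros_like(values)
    for x in range(12):
        for y in range(12):
            for z in range(12):
                if not values[x, y, z]:
                    continue
                nbs = [(x + 1, y, z), (x - 1, y, z), (x, y + 1, z),
                       (x, y - 1, z), (x, y, z + 1), (x, y, z - 1)]
                expected[x, y, z] = any(
                    not (0 <= i < 12 and 0 <= j < 12 and 0 <= k < 12)
                    or not values[i, j, k] for i, j, k in nbs)
    assert np.array_equal(shell.values, expected)


def test_boundary_layer_partition(ball_mask):
    shell = hd.boundary_layer_mask(ball_mask)
    core = ball_mask.values & ~shell.values
    assert np.array_equal(shell.values | core, ball_mask.values)
    assert not (shell.values & core).any()


def test_boundary_layer_empty_mask(unit_grid):
    with pytest.raises(ValueError):
        hd.boundary_layer_mask(BinaryMask(unit_grid, np.zeros(unit_grid.shape, bool)))


# ---------------------------------------------------------------------------
# compute_el
# ---------------------------------------------------------------------------

def test_el_uniform_translation(grid_10mm):
    result = hd.compute_el(uniform_field(grid_10mm, (0.3, 0.1, 0)), 0,
                           full_mask(grid_10mm))
    assert result.el_total <= 1e-10


def test_el_rigid_rotation_phantom():
    spec = PhantomSpec(kind="rigid_rotation", radius=10, length=50,
                       spacing=(1, 1, 1))
    field, mask, _ = gen_phantom(spec)
    result = hd.compute_el(field, 0, mask)
    assert result.el_total <= 1e-10


def test_el_poiseuille_oracle():
    spec = PhantomSpec(kind="poiseuille", radius=10, length=100,
                       flow_rate_lpm=5, spacing=(0.5, 0.5, 0.5))
    field, mask, truth = gen_phantom(spec)
    result = hd.compute_el(field, 0, mask)
    assert result.el_total == pytest.approx(truth.el_w, rel=0.20)


def naive_el(field, mask, mu, spacing_m):
    """Independent triple-loop dissipation integral with the same stencils."""
    u = field.frame(0)
    m = mask.values
    nx, ny, nz = m.shape
    total = 0.0
    dv = spacing_m[0] * spacing_m[1] * spacing_m[2]

    def d(comp, axis, idx):
        h = spacing_m[axis]
        step = [0, 0, 0]
        step[axis] = 1
        ip = tuple(np.add(idx, step))
        im = tuple(np.subtract(idx, step))
        ipp = tuple(np.add(idx, np.multiply(step, 2)))
        imm = tuple(np.subtract(idx, np.multiply(step, 2)))

        def inside(j):
            return all(0 <= j[a] < m.shape[a] for a in range(3)) and m[j]

        if inside(ip) and inside(im):
            return (u[ip][comp] - u[im][comp]) / (2 * h)
        if inside(ip) and inside(ipp):
            return (-3 * u[idx][comp] + 4 * u[ip][comp] - u[ipp][comp]) / (2 * h)
        if inside(im) and inside(imm):
            return (3 * u[idx][comp] - 4 * u[im][comp] + u[imm][comp]) / (2 * h)
        return None

    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not m[x, y, z]:
                    continue
                grad = np.empty((3, 3))
                ok = True
                for axis in range(3):
                    for comp in range(3):
                        g = d(comp, axis, (x, y, z))
                        if g is None:
                            ok = False
                            break
                        grad[comp, axis] = g
                    if not ok:
                        break
                if not ok:
                    continue
                phi = 0.0
                for i in range(3):
                    for j in range(3):
                        phi += 0.5 * (grad[i, j] + grad[j, i]) ** 2
                total += mu * phi * dv
    return total


def test_el_matches_brute_force():
    rng = np.random.default_rng(123)
    geometry = GridGeometry(shape=(6, 6, 6), spacing=(1, 1, 1))
    mask = BinaryMask(geometry, rng.random((6, 6, 6)) > 0.3)
    values = rng.normal(scale=0.1, size=(1, 6, 6, 6, 3))
    field = VelocityField(geometry=geometry, values=values)
    result = hd.compute_el(field, 0, mask)
    expected = naive_el(field, mask, 0.004, geometry.spacing_m)
    assert result.el_total == pytest.approx(expected, rel=1e-12)


def test_el_compartments_sum(poiseuille_1mm):
    field, mask, _ = poiseuille_1mm
    result = hd.compute_el(field, 0, mask)
    assert result.el_total == pytest.approx(
        result.el_boundary_layer + result.el_core, rel=1e-9)
    assert result.el_boundary_layer >= 0 and result.el_core >= 0


def test_el_closure_monotonicity(poiseuille_1mm):
    field, mask, _ = poiseuille_1mm
    laminar = hd.compute_el(field, 0, mask)
    les = hd.compute_el(field, 0, mask,
                        model=hd.ClosureModel(kind="les_smagorinsky"))
    k = ScalarVolume(field.geometry, np.full(field.geometry.shape, 1e-3),
                     unit="m^2/s^2")
    eps = ScalarVolume(field.geometry, np.full(field.geometry.shape, 0.05),
                       unit="m^2/s^3")
    mu_t = hd.eddy_viscosity_rng(k, eps)
    rng_el = hd.compute_el(field, 0, mask,
                           model=hd.ClosureModel(kind="rng_k_epsilon"), mu_t=mu_t)
    assert laminar.el_total <= les.el_total
    assert laminar.el_total <= rng_el.el_total


def test_el_rng_requires_mu_t(poiseuille_1mm):
    field, mask, _ = poiseuille_1mm
    with pytest.raises(ValueError):
        hd.compute_el(field, 0, mask, model=hd.ClosureModel(kind="rng_k_epsilon"))


def test_el_convergence_with_resolution():
    errors = []
    for spacing in (1.0, 0.5):
        spec = PhantomSpec(kind="poiseuille", radius=10, length=100,
                           flow_rate_lpm=5, spacing=(spacing,) * 3)
        field, mask, truth = gen_phantom(spec)
        result = hd.compute_el(field, 0, mask)
        errors.append(abs(result.el_total - truth.el_w) / truth.el_w)
    assert errors[1] < errors[0]


# ---------------------------------------------------------------------------
# flow_rate
# ---------------------------------------------------------------------------

def test_flow_zero_field(grid_10mm):
    field = uniform_field(grid_10mm, (0, 0, 0))
    q, mdot = hd.flow_rate(field, 0, full_mask(grid_10mm), (5, 5, 5), (0, 0, 1))
    assert q == 0.0 and mdot == 0.0


def test_flow_poiseuille_oracle(poiseuille_1mm):
    field, mask, truth = poiseuille_1mm
    q, mdot = hd.flow_rate(field, 0, mask, (0, 0, 50), (0, 0, 1))
    assert q == pytest.approx(truth.q_m3s, rel=0.05)
    assert mdot == pytest.approx(1060 * truth.q_m3s, rel=0.05)


def test_flow_normal_flip_antisymmetry(poiseuille_1mm):
    field, mask, _ = poiseuille_1mm
    q_pos, m_pos = hd.flow_rate(field, 0, mask, (0, 0, 50), (0, 0, 1))
    q_neg, m_neg = hd.flow_rate(field, 0, mask, (0, 0, 50), (0, 0, -1))
    assert q_neg == -q_pos
    assert m_neg == -m_pos


def test_flow_plane_misses_mask(poiseuille_1mm):
    field, mask, _ = poiseuille_1mm
    with pytest.raises(ValueError):
        hd.flow_rate(field, 0, mask, (0, 0, 500), (0, 0, 1))


# ---------------------------------------------------------------------------
# interpolate_waveform
# ---------------------------------------------------------------------------

def test_waveform_constant():
    f = hd.interpolate_waveform([0, 0.1, 0.2, 0.3, 0.4], [2.0] * 5)
    for t in (0.0, 0.05, 0.21, 0.4):
        assert f(t) == pytest.approx(2.0, abs=1e-12)


def test_waveform_hits_knots_exactly():
    rng = np.random.default_rng(4)
    times = np.linspace(0, 1, 10)
    flows = rng.normal(size=10)
    f = hd.interpolate_waveform(times, flows)
    for t, q in zip(times, flows):
        assert f(t) == pytest.approx(q, abs=1e-12)


def test_waveform_sine_accuracy():
    times = np.linspace(0, 1, 20)
    f = hd.interpolate_waveform(times, np.sin(2 * np.pi * times))
    mids = 0.5 * (times[:-1] + times[1:])
    errors = np.abs(f(mids) - np.sin(2 * np.pi * mids))
    assert errors.max() < 0.01


def test_waveform_out_of_range():
    f = hd.interpolate_waveform([0, 1, 2, 3], [0, 1, 0, 1])
    with pytest.raises(ValueError):
        f(3.5)


def test_waveform_too_few_samples():
    with pytest.raises(ValueError):
        hd.interpolate_waveform([0, 1, 2], [0, 1, 0])


def test_waveform_nonmonotone_times():
    with pytest.raises(ValueError):
        hd.interpolate_waveform([0, 2, 1, 3], [0, 1, 0, 1])
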