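"""Finite-element solver: assembly, stepping, physics invariants, convergence."""

import numpy as np
import pytest

from dcevox.aif import AIFModel
from dcevox.fem_solver import (
    SolverConfig,
    assemble,
    choose_time_step,
    compute_transfer_coefficient,
    run_simulation,
    step,
)
from dcevox.geometry import TissueDomain
from dcevox.meshing import TriMesh, mesh_ees


@pytest.fixture(scope="module")
def flat_aif():
    """AIF that is identically zero (no delivery)."""
    return AIFModel(kind="tabulated", t_s=np.array([0.0, 1e4]), cp_mM=np.zeros(2))


class TestTransferCoefficient:
    def test_reference_arithmetic(self):
        # K^trans = 0.4 1/min, S = 0.93 mm, V = (0.25 mm)^2
        P = compute_transfer_coefficient(0.4, 0.93, 0.0625)
        assert P == pytest.approx(4.48e-4, rel=1e-3)

    def test_zero_ktrans(self):
        assert compute_transfer_coefficient(0.0, 1.0, 1.0) == 0.0

    def test_inverse_proportionality_in_S(self):
        p1 = compute_transfer_coefficient(0.4, 1.0, 0.0625)
        p2 = compute_transfer_coefficient(0.4, 2.0, 0.0625)
        assert p1 == pytest.approx(2 * p2)

    def test_zero_surface_rejected(self):
        with pytest.raises(ValueError):
            compute_transfer_coefficient(0.4, 0.0, 1.0)


class TestAssembly:
    def test_single_reference_triangle_stiffness(self):
        mesh = TriMesh(
            nodes=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
            triangles=np.array([[0, 1, 2]]),
            boundary_edges=[(0, 1, "outer", -1), (1, 2, "outer", -1), (2, 0, "outer", -1)],
            target_edge=1.0,
        )
        mats = assemble(mesh, SolverConfig(D=1.0))
        K_hand = 0.5 * np.array([[2.0, -1.0, -1.0], [-1.0, 1.0, 0.0], [-1.0, 0.0, 1.0]])
        np.testing.assert_allclose(mats.K.toarray(), K_hand, atol=1e-14)
        M_hand = (0.5 / 12.0) * np.array([[2, 1, 1], [1, 2, 1], [1, 1, 2]])
        np.testing.assert_allclose(mats.M.toarray(), M_hand, atol=1e-14)

    def test_constant_field_in_stiffness_null_space(self, square_mesh):
        mats = assemble(square_mesh, SolverConfig(D=1.0))
        ones = np.ones(square_mesh.n_nodes)
        assert np.abs(mats.K @ ones).max() < 1e-12

    def test_mass_matrix_spd(self, square_mesh):
        mats = assemble(square_mesh, SolverConfig(D=1.0))
        M = mats.M
        assert abs(M - M.T).max() < 1e-15
        rng = np.random.default_rng(0)
        for _ in range(3):
            v = rng.normal(size=square_mesh.n_nodes)
            assert v @ (M @ v) > 0

    def test_no_vessels_no_boundary_terms(self, square_mesh):
        mats = assemble(square_mesh, SolverConfig(D=1.0, P=0.5))
        assert mats.B.nnz == 0
        assert np.all(mats.b == 0.0)

    def test_vessel_rows_only_on_vessel_nodes(self, reference_mesh):
        mats = assemble(reference_mesh, SolverConfig(D=1.0, P=1.0))
        vessel_nodes = {
            n
            for i, j, t, _ in reference_mesh.boundary_edges
            if t == "vessel"
            for n in (i, j)
        }
        nonzero_rows = set(np.unique(mats.B.tocoo().row))
        assert nonzero_rows == vessel_nodes
        assert set(np.flatnonzero(mats.b)) == vessel_nodes


class TestStep:
    def test_zero_stays_zero(self, square_mesh, flat_aif):
        cfg = SolverConfig(D=1e-4, P=1e-3, dt=0.1)
        mats = assemble(square_mesh, cfg)
        C = step(mats, cfg, np.zeros(square_mesh.n_nodes), 0.0, flat_aif)
        assert np.abs(C).max() == 0.0

    def test_cosine_mode_decay_factor(self, square_domain, square_mesh, flat_aif):
        a = square_domain.voxel_side
        D, dt = 1e-4, 0.05
        cfg = SolverConfig(D=D, P=0.0, dt=dt)
        mats = assemble(square_mesh, cfg)
        C = np.cos(np.pi * square_mesh.nodes[:, 0] / a)
        C1 = step(mats, cfg, C, 0.0, flat_aif)
        lam = D * np.pi**2 / a**2
        ratio = (C1 @ C) / (C @ C)
        assert ratio == pytest.approx(np.exp(-lam * dt), rel=2e-3)

    def test_uniform_field_in_equilibrium_with_matching_plasma(self, reference_mesh):
        level = 1.7
        aif = AIFModel(kind="tabulated", t_s=np.array([0.0, 1e4]),
                       cp_mM=np.array([level, level]))
        cfg = SolverConfig(D=2e-4, P=4e-4, dt=0.1)
        mats = assemble(reference_mesh, cfg)
        C = np.full(reference_mesh.n_nodes, level)
        C1 = step(mats, cfg, C, 100.0, aif)
        np.testing.assert_allclose(C1, C, atol=1e-10)


class TestChooseTimeStep:
    def test_scaling_rule(self, aif):
        mesh = TriMesh(
            nodes=np.array([[0.0, 0.0], [2e-3, 0.0], [0.0, 2e-3]]),
            triangles=np.array([[0, 1, 2]]),
            boundary_edges=[],
            target_edge=2e-3,
        )
        # h = mean edge of the single triangle
        h = mesh.mean_edge_length
        assert choose_time_step(mesh, D=h * h / 0.04) == pytest.approx(0.04)

    def test_clamps(self, square_mesh, aif):
        assert choose_time_step(square_mesh, D=10.0) == pytest.approx(1e-3)
        assert choose_time_step(square_mesh, D=1e-12) == pytest.approx(0.1)


class TestSimulation:
    def test_sealed_domain_stays_empty(self, square_domain, square_mesh, aif):
        cfg = SolverConfig(D=1e-4, P=0.0, dt=0.1, duration=5.0)
        ctc = run_simulation(square_domain, square_mesh, cfg, aif)
        assert np.abs(ctc.voxel_mean).max() == 0.0

    def test_mass_conserved_without_vessels(self, square_domain, square_mesh, flat_aif):
        cfg = SolverConfig(D=2e-4, P=0.0, dt=0.1, duration=660.0, store_every=600)
        x = square_mesh.nodes[:, 0] / square_domain.voxel_side
        ctc = run_simulation(
            square_domain, square_mesh, cfg, flat_aif, initial=1.0 + 0.5 * np.cos(np.pi * x)
        )
        m0, m1 = ctc.total_mass(0), ctc.total_mass()
        assert abs(m1 - m0) / m0 < 1e-8

    def test_influx_strictly_positive_on_first_steps(self, reference_domain,
                                                     reference_mesh, aif):
        cfg = SolverConfig(D=2e-4, P=4e-4, dt=0.1, duration=2.0)
        ctc = run_simulation(reference_domain, reference_mesh, cfg, aif)
        masses = ctc.element_mean @ reference_mesh.element_areas
        assert masses[-1] > masses[0]
        assert (np.diff(ctc.voxel_mean[1:]) > 0).all()

    def test_concentration_never_significantly_negative(self, reference_domain,
                                                        reference_mesh, aif):
        cfg = SolverConfig(D=2e-4, P=4e-4, dt=0.1, duration=60.0)
        ctc = run_simulation(reference_domain, reference_mesh, cfg, aif)
        assert ctc.nodal.min() > -1e-6


class TestConvergence:
    def test_spatial_order_two(self, square_domain, flat_aif):
        a = square_domain.voxel_side
        D, T = 1e-4, 10.0
        lam = D * np.pi**2 / a**2
        errs, hs = [], []
        for te in (10e-3, 5e-3, 2.5e-3):
            m = mesh_ees(square_domain, target_edge=te)
            cfg = SolverConfig(D=D, P=0.0, dt=0.01, duration=T, store_every=10**9)
            C0 = np.cos(np.pi * m.nodes[:, 0] / a)
            ctc = run_simulation(square_domain, m, cfg, flat_aif, initial=C0)
            mats = assemble(m, cfg)
            e = ctc.nodal[-1] - np.exp(-lam * T) * C0
            errs.append(np.sqrt(e @ (mats.M @ e)))
            hs.append(m.mean_edge_length)
        order = np.polyfit(np.log(hs), np.log(errs), 1)[0]
        assert 1.7 <= order <= 2.3

    def test_temporal_order_two(self, square_domain, square_mesh, flat_aif):
        a = square_domain.voxel_side
        C0 = np.cos(np.pi * square_mesh.nodes[:, 0] / a)

        def final(dt):
            cfg = SolverConfig(D=1e-4, P=0.0, dt=dt, duration=10.0, store_every=10**9)
            return run_simulation(
                square_domain, square_mesh, cfg, flat_aif, initial=C0
            ).nodal[-1]

        ref = final(0.025)
        e1 = np.linalg.norm(final(0.4) - ref)
        e2 = np.linalg.norm(final(0.2) - ref)
        assert 1.8 <= np.log2(e1 / e2) <= 2.2

    def test_cosine_decay_error_below_one_percent(self, square_domain, square_mesh,
                                                  flat_aif):
        a = square_domain.voxel_side
        D, T = 1e-4, 20.0
        cfg = SolverConfig(D=D, P=0.0, dt=0.05, duration=T, store_every=10**9)
        C0 = np.cos(np.pi * square_mesh.nodes[:, 0] / a)
        ctc = run_simulation(square_domain, square_mesh, cfg, flat_aif, initial=C0)
        exact = np.exp(-D * np.pi**2 / a**2 * T) * C0
        mats = assemble(square_mesh, cfg)
        e = ctc.nodal[-1] - exact
        rel = np.sqrt(e @ (mats.M @ e)) / np.sqrt(exact @ (mats.M @ exact))
        assert rel < 0.01


def test_time_course_writer_round_trips_voxel_summary(tmp_path, square_domain,
                                                      square_mesh, aif):
    import h5py

    from dcevox.fem_solver import save_time_course

    cfg = SolverConfig(D=1e-4, P=0.0, dt=0.5, duration=5.0)
    x = square_mesh.nodes[:, 0]
    ctc = run_simulation(square_domain, square_mesh, cfg, aif, initial=1.0 + x)
    stem = tmp_path / "run"
    save_time_course(ctc, stem)
    with h5py.File(stem.with_suffix(".h5")) as f:
        np.testing.assert_allclose(f["voxel_mean"][:], ctc.voxel_mean)
        assert f["nodal"].shape == ctc.nodal.shape
    lines = (tmp_path / "run_voxel.csv").read_text().strip().splitlines()
    assert len(lines) == len(ctc.times) + 1
    t0, c0 = lines[1].split(",")
    assert float(c0) == ctc.voxel_mean[0]


def _union_jack_mesh_with_hole(n: int = 8) -> TriMesh:
    """Structured union-jack square mesh with a central 2x2-cell hole.

    The triangulation alternates diagonal direction like a checkerboard, so
    it is exactly symmetric under 90-degree rotation about the centre; the
    hole edges are tagged as vessel.
    """
    xs = np.linspace(0.0, 1.0, n + 1)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])
    nid = lambda i, j: i * (n + 1) + j
    hole = {(i, j) for i in (n // 2 - 1, n // 2) for j in (n // 2 - 1, n // 2)}
    tris = []
    for i in range(n):
        for j in range(n):
            if (i, j) in hole:
                continue
            a, b = nid(i, j), nid(i + 1, j)
            c, d = nid(i + 1, j + 1), nid(i, j + 1)
            if (i + j) % 2 == 0:
                tris += [[a, b, c], [a, c, d]]
            else:
                tris += [[a, b, d], [b, c, d]]
    tris = np.array(tris)
    # drop nodes not referenced by any triangle (the hole interior)
    used = np.unique(tris)
    remap = -np.ones(len(nodes), dtype=int)
    remap[used] = np.arange(len(used))
    nodes = nodes[used]
    tris = remap[tris]
    # boundary edges = edges adjacent to exactly one triangle
    e = np.sort(np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]]), axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    edges = []
    for a, b in uniq[counts == 1]:
        mid = 0.5 * (nodes[a] + nodes[b])
        outer = min(mid[0], mid[1], 1 - mid[0], 1 - mid[1]) < 1e-12
        edges.append((int(a), int(b), "outer" if outer else "vessel", -1))
    return TriMesh(nodes=nodes, triangles=tris, boundary_edges=edges, target_edge=1 / n)


def test_four_fold_symmetric_field(aif):
    """A 4-fold-symmetric domain must give a 4-fold-symmetric field."""
    mesh = _union_jack_mesh_with_hole(8)
    dom = TissueDomain(voxel_side=1.0, ve_achieved=1.0, vp_achieved=0.0,
                       veis_achieved=0.0)
    cfg = SolverConfig(D=1e-2, P=1e-3, dt=0.5, duration=30.0, store_every=10**9)
    ctc = run_simulation(dom, mesh, cfg, aif)
    C = ctc.nodal[-1]
    # node permutation under (x, y) -> (y, 1 - x)
    rotated = np.column_stack([mesh.nodes[:, 1], 1.0 - mesh.nodes[:, 0]])
    from scipy.spatial import cKDTree

    d, perm = cKDTree(mesh.nodes).query(rotated)
    assert d.max() < 1e-12
    np.testing.assert_allclose(C[perm], C, atol=1e-9)
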