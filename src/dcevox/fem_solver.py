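"""Galerkin finite-element solver for contrast-agent diffusion in the EES.

The concentration field C(x, y, t) obeys the diffusion equation
``dC/dt = D laplacian(C)`` on the meshed extracellular space.  Cell and
outer boundaries are impermeable (zero flux); vessel boundaries carry a
Robin influx ``D dC/dn = P (C_p(t) - C)`` where ``P`` is the vessel-wall
transfer coefficient and ``C_p`` the arterial input function, uniform in
every vessel.  Linear (P1) Lagrange elements with a consistent mass
matrix; time stepping is the theta scheme with the Crank-Nicolson default
(theta = 0.5), solved with a sparse LU factorization of the constant
left-hand side that is reused across all steps.

Units: mm, s, mM; K^trans is accepted in 1/min and converted internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .aif import AIFModel, evaluate_aif
from .meshing import TriMesh, VESSEL

__all__ = [
    "SolverConfig",
    "SystemMatrices",
    "ConcentrationTimeCourse",
    "compute_transfer_coefficient",
    "assemble",
    "step",
    "choose_time_step",
    "run_simulation",
    "save_time_course",
]


@dataclass
class SolverConfig:
    """Physical and numerical parameters of one diffusion run.

    ``D`` in mm^2/s, ``P`` in mm/s, ``dt`` in s (None = choose from the
    mesh), ``theta`` the implicitness weight (0.5 = Crank-Nicolson),
    ``duration`` in s, ``store_every`` the stride (in steps) at which full
    nodal fields are retained.
    """

    D: float = 2e-4
    P: float = 0.0
    dt: float | None = None
    theta: float = 0.5
    duration: float = 660.0
    store_every: int | None = None

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("D must be positive")
        if self.P < 0:
            raise ValueError("P must be non-negative")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class SystemMatrices:
    """Assembled P1 system: mass M, stiffness K (unscaled by D), vessel
    boundary mass B and vessel load pattern b."""

    M: sp.csr_matrix
    K: sp.csr_matrix
    B: sp.csr_matrix
    b: np.ndarray
    n_nodes: int
    _cache: dict = field(default_factory=dict, repr=False)


@dataclass
class ConcentrationTimeCourse:
    """Trajectory of one simulation.

    ``times`` is the full step grid; ``voxel_mean`` the EES mean
    concentration of the voxel of interest at every step.  Nodal fields and
    element means are stored at the decimated ``stored_times``.
    """

    times: np.ndarray
    voxel_mean: np.ndarray
    stored_times: np.ndarray
    nodal: np.ndarray  # (n_stored, n_nodes)
    element_mean: np.ndarray  # (n_stored, n_elements)
    mesh: TriMesh | None = None

    def total_mass(self, k: int | None = None) -> float:
        """Total EES solute mass (mM * mm^2) at stored step ``k`` (default last)."""
        em = self.element_mean[-1 if k is None else k]
        return float(em @ self.mesh.element_areas)


def save_time_course(ctc: ConcentrationTimeCourse, stem) -> None:
    """Write a trajectory: ``<stem>.h5`` (full fields) + ``<stem>_voxel.csv``.

    The HDF5 container holds the stored nodal fields and element means; the
    CSV mirror carries the full-resolution voxel summary (t_s, C_mM).
    """
    from pathlib import Path

    import h5py

    stem = Path(stem)
    with h5py.File(stem.with_suffix(".h5"), "w") as f:
        f.create_dataset("times", data=ctc.times)
        f.create_dataset("voxel_mean", data=ctc.voxel_mean)
        f.create_dataset("stored_times", data=ctc.stored_times)
        f.create_dataset("nodal", data=ctc.nodal, compression="gzip")
        f.create_dataset("element_mean", data=ctc.element_mean, compression="gzip")
    with open(f"{stem}_voxel.csv", "w") as f:
        f.write("t_s,C_mM\n")
        for t, c in zip(ctc.times, ctc.voxel_mean):
            f.write(f"{float(t)!r},{float(c)!r}\n")


def compute_transfer_coefficient(Ktrans: float, S: float, V: float) -> float:
    """Vessel-wall transfer coefficient P = (K^trans / 60) * V / S in mm/s.

    ``Ktrans`` is in 1/min; ``S`` is the total vessel boundary length of one
    voxel (mm) and ``V`` the voxel area (mm^2) — the 2-D analogues of vessel
    surface area and voxel volume.  This calibration makes the total influx
    ``P * S * (C_p - C)`` equal ``K^trans * V * (C_p - C)``, so in the
    well-mixed (high diffusion) limit the voxel obeys the standard
    two-compartment model with the nominal K^trans.
    """
    if S <= 0:
        raise ValueError("vessel boundary length S must be positive")
    if V <= 0:
        raise ValueError("voxel area V must be positive")
    if Ktrans < 0:
        raise ValueError("Ktrans must be non-negative")
    return (Ktrans / 60.0) * V / S


def assemble(mesh: TriMesh, config: SolverConfig) -> SystemMatrices:
    """Assemble mass, stiffness and vessel-boundary matrices for P1 elements.

    The stiffness matrix is returned unscaled (multiply by D); the boundary
    matrix ``B`` and load pattern ``b`` come from the line integral of the
    Robin condition over vessel-tagged edges only — cell and outer edges
    contribute nothing (zero flux).

    Raises
    ------
    ValueError
        If the mesh carries an unknown boundary tag.
    """
    nodes, tris = mesh.nodes, mesh.triangles
    n = len(nodes)
    p = nodes[tris]  # (m, 3, 2)
    x, y = p[..., 0], p[..., 1]
    # gradients of the barycentric basis functions
    b_ = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c_ = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    area2 = x[:, 0] * b_[:, 0] + x[:, 1] * b_[:, 1] + x[:, 2] * b_[:, 2]  # = 2A
    area = 0.5 * area2

    rows, cols = np.broadcast_arrays(tris[:, :, None], tris[:, None, :])
    ke = (
        (b_[:, :, None] * b_[:, None, :] + c_[:, :, None] * c_[:, None, :])
        / (2.0 * area2)[:, None, None]
    )
    me_local = np.array([[2, 1, 1], [1, 2, 1], [1, 1, 2]]) / 12.0
    me = area[:, None, None] * me_local[None]

    K = sp.coo_matrix((ke.ravel(), (rows.ravel(), cols.ravel())), shape=(n, n)).tocsr()
    M = sp.coo_matrix((me.ravel(), (rows.ravel(), cols.ravel())), shape=(n, n)).tocsr()

    # vessel boundary line integrals
    bi, bj, bv, load_i, load_v = [], [], [], [], []
    for i, j, tag, _sid in mesh.boundary_edges:
        if tag not in ("vessel", "cell", "outer"):
            raise ValueError(f"unknown boundary tag {tag!r}")
        if tag != VESSEL:
            continue
        ell = float(np.hypot(*(nodes[i] - nodes[j])))
        for a, bnode, w in ((i, i, 2.0), (i, j, 1.0), (j, i, 1.0), (j, j, 2.0)):
            bi.append(a)
            bj.append(bnode)
            bv.append(w * ell / 6.0)
        load_i.extend([i, j])
        load_v.extend([ell / 2.0, ell / 2.0])
    B = sp.coo_matrix((bv, (bi, bj)), shape=(n, n)).tocsr()
    b = np.zeros(n)
    np.add.at(b, load_i, load_v)
    return SystemMatrices(M=M, K=K, B=B, b=b, n_nodes=n)


def _factorized_step(matrices: SystemMatrices, config: SolverConfig, dt: float):
    """LU-factorized theta-scheme operators, cached on the matrices object."""
    key = (dt, config.theta, config.D, config.P)
    if key not in matrices._cache:
        A = config.D * matrices.K + config.P * matrices.B
        lhs = (matrices.M + config.theta * dt * A).tocsc()
        rhs = (matrices.M - (1.0 - config.theta) * dt * A).tocsr()
        matrices._cache.clear()  # one configuration at a time is enough
        matrices._cache[key] = (splu(lhs), rhs)
    return matrices._cache[key]


def step(
    matrices: SystemMatrices,
    config: SolverConfig,
    C_now: np.ndarray,
    t_now: float,
    aif: AIFModel,
    dt: float | None = None,
) -> np.ndarray:
    """Advance the nodal concentration one theta-scheme step.

    Solves ``(M + theta dt A) C+ = (M - (1-theta) dt A) C + dt [theta f(t+dt)
    + (1-theta) f(t)]`` with ``A = D K + P B`` and vessel load
    ``f(t) = P C_p(t) b``; unconditionally stable for theta >= 0.5.
    """
    if dt is None:
        dt = config.dt
        if dt is None:
            raise ValueError("no time step given")
    lu, rhs = _factorized_step(matrices, config, dt)
    f_now = config.P * evaluate_aif(aif, t_now) * matrices.b
    f_next = config.P * evaluate_aif(aif, t_now + dt) * matrices.b
    r = rhs @ C_now + dt * (config.theta * f_next + (1.0 - config.theta) * f_now)
    return lu.solve(r)


def choose_time_step(
    mesh: TriMesh,
    D: float,
    aif: AIFModel | None = None,
    *,
    c: float = 1.0,
    dt_min: float = 1e-3,
    dt_max: float = 0.1,
    bolus_cap: float = 0.25,
) -> float:
    """Pick a time step from the mesh scale and diffusivity.

    ``dt = clamp(c h^2 / D, dt_min, dt_max)`` with ``h`` the mean edge
    length, additionally capped at ``bolus_cap`` so the arterial first pass
    stays well resolved.  The scheme itself (theta = 0.5) is unconditionally
    stable; this rule bounds the temporal discretization error.
    """
    h = mesh.mean_edge_length
    dt = min(max(c * h * h / D, dt_min), dt_max, bolus_cap)
    return dt


def run_simulation(
    domain,
    mesh: TriMesh,
    config: SolverConfig,
    aif: AIFModel,
    initial: np.ndarray | None = None,
) -> ConcentrationTimeCourse:
    """Run a full diffusion simulation and summarize the voxel of interest.

    The voxel EES mean concentration (area-weighted element mean over the
    central tile) is recorded at every step; nodal fields and element means
    are stored every ``config.store_every`` steps (default: about every
    10 s of simulated time).
    """
    matrices = assemble(mesh, config)
    dt = config.dt if config.dt is not None else choose_time_step(mesh, config.D, aif)
    n_steps = int(np.ceil(config.duration / dt))

    # central-voxel element selection and averaging weights
    x0, y0, x1, y1 = domain.central_window
    cent = mesh.element_centroids()
    central = (
        (cent[:, 0] >= x0) & (cent[:, 0] < x1) & (cent[:, 1] >= y0) & (cent[:, 1] < y1)
    )
    w_central = mesh.element_areas[central]
    w_central = w_central / w_central.sum()
    tri_central = mesh.triangles[central]

    store_every = config.store_every
    if store_every is None:
        store_every = max(1, int(round(10.0 / dt)))

    C = np.zeros(matrices.n_nodes) if initial is None else np.asarray(initial, float).copy()
    times = np.empty(n_steps + 1)
    voxel_mean = np.empty(n_steps + 1)
    stored_times, nodal, elem_means = [], [], []

    def record(k: int, t: float, C: np.ndarray) -> None:
        times[k] = t
        voxel_mean[k] = (C[tri_central].mean(axis=1) * w_central).sum()
        if k % store_every == 0 or k == n_steps:
            stored_times.append(t)
            nodal.append(C.copy())
            elem_means.append(C[mesh.triangles].mean(axis=1))

    record(0, 0.0, C)
    t = 0.0
    for k in range(1, n_steps + 1):
        dt_k = min(dt, config.duration - t)
        C = step(matrices, config, C, t, aif, dt=dt_k)
        t += dt_k
        record(k, t, C)
    return ConcentrationTimeCourse(
        times=times,
        voxel_mean=voxel_mean,
        stored_times=np.asarray(stored_times),
        nodal=np.asarray(nodal),
        element_mean=np.asarray(elem_means),
        mesh=mesh,
    )
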