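"""Independent reference solvers used to validate the finite-element path.

Two cross-checks, deliberately different in construction from the FEM:

* a masked-grid finite-difference solver: the voxel is rasterized into
  square pixels labelled EES / cell / vessel, the diffusion equation is
  discretized with the 5-point stencil on EES pixels (no-flux at cell and
  wall faces, Robin influx ``P (C_p - C)`` at vessel-adjacent faces) and
  stepped with the same theta scheme;
* the closed-form well-mixed (high-diffusion) limit, where the voxel EES
  concentration follows the standard Tofts impulse response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .aif import AIFModel, evaluate_aif
from .geometry import TissueDomain
from .pk_models import standard_tofts

__all__ = ["MaskedGrid", "rasterize_domain", "fd_solve", "high_d_limit"]

EES, CELL, VES = 0, 1, 2


@dataclass
class MaskedGrid:
    """Pixelized single-tile domain: occupancy mask and pixel size (mm)."""

    pixel: float
    mask: np.ndarray  # (n, n) int8 with EES/CELL/VES labels

    @property
    def fractions(self) -> tuple[float, float, float]:
        """(ve, vp, veis) pixel-count fractions."""
        n = self.mask.size
        return (
            float((self.mask == EES).sum()) / n,
            float((self.mask == VES).sum()) / n,
            float((self.mask == CELL).sum()) / n,
        )

    @property
    def vessel_interface_length(self) -> float:
        """Total length of EES|vessel pixel faces (mm) — the discrete vessel
        boundary this rasterization exposes to flux."""
        m = self.mask
        faces = 0
        for ax, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
            nb = np.roll(m, shift, axis=ax)
            edge = (m == EES) & (nb == VES)
            # roll wraps around; forbid wrap faces
            if ax == 0:
                edge[0 if shift == 1 else -1, :] = False
            else:
                edge[:, 0 if shift == 1 else -1] = False
            faces += int(edge.sum())
        return faces * self.pixel


def rasterize_domain(domain: TissueDomain, pixel: float = 1e-3) -> MaskedGrid:
    """Label pixel centres of a single-tile domain as EES, cell or vessel."""
    if domain.tiles != 1:
        raise ValueError("the oracle rasterizes single-tile domains")
    L = domain.voxel_side
    n = int(round(L / pixel))
    ax = (np.arange(n) + 0.5) * pixel
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    mask = np.zeros((n, n), dtype=np.int8)
    for c in domain.cells:
        dx, dy = X - c.center[0], Y - c.center[1]
        ca, sa = np.cos(c.angle), np.sin(c.angle)
        u = ca * dx + sa * dy
        v = -sa * dx + ca * dy
        inside = (u / c.semi_axes[0]) ** 2 + (v / c.semi_axes[1]) ** 2 <= 1.0
        mask[inside] = CELL
    for ves in domain.vessels:
        inside = (X - ves.center[0]) ** 2 + (Y - ves.center[1]) ** 2 <= ves.radius**2
        mask[inside] = VES
    return MaskedGrid(pixel=pixel, mask=mask)


def fd_solve(
    grid: MaskedGrid,
    D: float,
    P: float,
    aif: AIFModel,
    dt: float,
    duration: float,
    theta: float = 0.5,
    initial: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Masked-grid diffusion solve.

    Returns ``(times, EES mean concentration, final EES pixel field)``.
    EES pixels exchange with 4-neighbours at rate ``D / px^2``; faces toward
    cells and the outer wall are sealed, faces toward vessel pixels carry the
    Robin flux ``P (C_p - C) / px``.  The theta scheme (default
    Crank-Nicolson) with a sparse LU factorization advances the system.
    ``initial`` optionally seeds the EES pixel vector (flattened over the
    EES pixels in row-major mask order).
    """
    m = grid.mask
    px = grid.pixel
    ees = m == EES
    idx = -np.ones(m.shape, dtype=int)
    idx[ees] = np.arange(int(ees.sum()))
    n = int(ees.sum())

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    load = np.zeros(n)
    ii, jj = np.nonzero(ees)
    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        ni, nj = ii + di, jj + dj
        inb = (ni >= 0) & (ni < m.shape[0]) & (nj >= 0) & (nj < m.shape[1])
        # neighbour labels; out-of-bounds = sealed wall
        lab = np.full(len(ii), CELL, dtype=np.int8)
        lab[inb] = m[ni[inb], nj[inb]]
        k = idx[ii, jj]
        is_ees = inb & (lab == EES)
        rows.extend(k[is_ees])
        cols.extend(idx[ni[is_ees], nj[is_ees]])
        vals.extend(np.full(int(is_ees.sum()), D / px**2))
        diag[k[is_ees]] -= D / px**2
        is_ves = inb & (lab == VES)
        diag[k[is_ves]] -= P / px
        load[k[is_ves]] += P / px

    A = sp.coo_matrix(
        (np.concatenate([vals, diag]),
         (np.concatenate([rows, np.arange(n)]),
          np.concatenate([cols, np.arange(n)]))),
        shape=(n, n),
    ).tocsc()

    eye = sp.identity(n, format="csc")
    lu = splu((eye - theta * dt * A).tocsc())
    rhs_op = (eye + (1.0 - theta) * dt * A).tocsr()

    n_steps = int(np.ceil(duration / dt))
    C = np.zeros(n) if initial is None else np.asarray(initial, dtype=float).copy()
    times = np.empty(n_steps + 1)
    mean = np.empty(n_steps + 1)
    times[0], mean[0] = 0.0, C.mean()
    t = 0.0
    for k in range(1, n_steps + 1):
        f0 = load * evaluate_aif(aif, min(t, aif.duration))
        f1 = load * evaluate_aif(aif, min(t + dt, aif.duration))
        C = lu.solve(rhs_op @ C + dt * (theta * f1 + (1.0 - theta) * f0))
        t += dt
        times[k] = t
        mean[k] = C.mean()
    return times, mean, C


def high_d_limit(
    Ktrans: float, ve: float, aif: AIFModel, t: np.ndarray
) -> np.ndarray:
    """Well-mixed EES concentration ``C_e(t) = C_t(t) / v_e`` (mM).

    This is the limit the diffusion simulation approaches once the agent
    distributes through the EES much faster than the vessel wall delivers
    it (D larger than about 1e-3 mm^2/s for these geometries).
    """
    if ve <= 0:
        raise ValueError("ve must be positive")
    return standard_tofts(Ktrans, ve, aif, t) / ve
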