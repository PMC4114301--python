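"""3D intracellular calcium dynamics: vertex-centered finite volumes.

The model is diffusion of free calcium c and free mobile buffer b on the
tetrahedral cytosol mesh,

    dc/dt = div(D grad c) - B(c, b)          in Omega
    db/dt = D_B laplace b  - B(c, b)         in Omega
    dc/dn = Phi(V_m, x, t)                   on the membrane

with the mass-action buffer reaction B = k_on c b - k_off (B_total - b);
the bound complex CaB = B_total - b is never stored independently, so the
buffer conservation law holds identically.  Anisotropic diffusion enters
through a 3x3 tensor D.

Discretization: vertex-centered control volumes (the barycentric dual of
the tetrahedral mesh).  For piecewise-linear nodal functions the resulting
stiffness matrix is assembled element-wise as the P1 control-volume
finite-element operator; the control-volume measures are the lumped
barycentric dual volumes |T|/4.  Channel fluxes enter as a boundary
integral lumped onto membrane vertices (one third of each incident face
area).  Time stepping is implicit Euler; the coupled nonlinear system per
step is solved by a Newton outer loop with a frozen factorized Jacobian
(re-linearized automatically if convergence stalls), mirroring the
inner/outer solver split of large-scale multigrid implementations at desk
scale.

Units: um, ms, uM; fluxes in uM*um/ms; diffusion coefficients in um^2/ms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConfigError, SolverError
from .meshgen import REGION_MEMBRANE, VolumeMesh

logger = logging.getLogger(__name__)


def diffusion_tensor(d) -> np.ndarray:
    """Normalize scalar / diagonal / full 3x3 input to a SPD 3x3 tensor."""
    d = np.asarray(d, float)
    if d.ndim == 0:
        D = np.eye(3) * float(d)
    elif d.shape == (3,):
        D = np.diag(d)
    elif d.shape == (3, 3):
        D = 0.5 * (d + d.T)
    else:
        raise ConfigError("diffusion tensor must be scalar, length-3 or 3x3")
    if np.any(np.linalg.eigvalsh(D) < -1e-12):
        raise ConfigError("diffusion tensor must be positive semi-definite")
    return D


@dataclass(frozen=True)
class BufferParams:
    """Mobile (or stationary, D_B = 0) calcium buffer."""

    k_on: float = 0.09      # 1/(uM*ms)
    k_off: float = 0.24     # 1/ms
    d_b: float = 0.043      # um^2/ms
    b_total: float = 20.0   # uM

    def __post_init__(self):
        if min(self.k_on, self.k_off, self.d_b, self.b_total) < 0:
            raise ConfigError("buffer parameters must be non-negative")

    @property
    def k_d(self) -> float:
        return self.k_off / self.k_on if self.k_on > 0 else np.inf


def buffer_equilibrium(c, params: BufferParams):
    """Free buffer b and bound complex CaB at chemical equilibrium.

    Solves k_on c b = k_off (B_total - b); the unique root in [0, B_total]
    is b = B_total K_d / (K_d + c).
    """
    c = np.asarray(c, float)
    if np.any(c < 0):
        raise ConfigError("concentration must be non-negative")
    if params.k_on == 0:
        b = np.broadcast_to(params.b_total, c.shape).copy()
    else:
        b = params.b_total * params.k_d / (params.k_d + c)
    return b, params.b_total - b


@dataclass
class Field3D:
    """Nodal concentration state: free calcium c and free buffer b [uM]."""

    c: np.ndarray
    b: np.ndarray
    t: float = 0.0

    @property
    def cab(self) -> np.ndarray:
        """Bound buffer via the conservation law (never stored)."""
        return self._b_total - self.b

    _b_total: float = 0.0

    @classmethod
    def uniform(cls, n: int, c0: float, buffers: BufferParams | None
                ) -> "Field3D":
        c = np.full(n, float(c0))
        if buffers is None or buffers.b_total == 0:
            f = cls(c=c, b=np.zeros(n))
            f._b_total = 0.0
            return f
        b, _ = buffer_equilibrium(c, buffers)
        f = cls(c=c, b=b)
        f._b_total = buffers.b_total
        return f


def assemble(mesh: VolumeMesh, D) -> tuple[sp.csr_matrix, np.ndarray]:
    """Stiffness matrix A (for -div(D grad)) and lumped mass vector M.

    A is symmetric for symmetric D with zero row sums (constants span the
    pure-Neumann null space); M_i is the barycentric dual (control volume)
    measure, summing exactly to the mesh volume.
    """
    D = diffusion_tensor(D)
    verts, tets = mesh.vertices, mesh.tets
    p = verts[tets]
    vol = mesh.tet_volumes()
    if np.any(vol <= 0):
        bad = int(np.argmax(vol <= 0))
        raise SolverError(f"degenerate tetrahedron {bad} (volume "
                          f"{vol[bad]:.3g})")
    # gradients of the four barycentric basis functions per tet
    e = p[:, 1:] - p[:, :1]                      # (n, 3, 3)
    inv = np.linalg.inv(e)                       # rows: grad of lam1..3
    g = np.empty((len(tets), 4, 3))
    g[:, 1:, :] = np.transpose(inv, (0, 2, 1))
    g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
    Dg = g @ D.T
    Ke = np.einsum("tid,tjd,t->tij", g, Dg, vol)
    rows = np.repeat(tets, 4, axis=1).reshape(-1)
    cols = np.tile(tets, (1, 4)).reshape(-1)
    A = sp.coo_matrix((Ke.reshape(-1), (rows, cols)),
                      shape=(len(verts),) * 2).tocsr()
    M = np.zeros(len(verts))
    np.add.at(M, tets.reshape(-1), np.repeat(vol / 4.0, 4))
    return A, M


def total_calcium(field: Field3D, M: np.ndarray,
                  buffers: BufferParams | None = None) -> float:
    """Total calcium amount int(c + CaB) [uM*um^3] via the lumped mass."""
    amount = float(M @ field.c)
    if buffers is not None and buffers.b_total > 0:
        amount += float(M @ (buffers.b_total - field.b))
    return amount


class CalciumSolver:
    """Implicit-Euler stepper for the coupled calcium/buffer system."""

    def __init__(self, mesh: VolumeMesh, D, buffers: BufferParams | None,
                 newton_tol_uM: float = 1.0e-9, newton_maxit: int = 40):
        self.mesh = mesh
        self.D = diffusion_tensor(D)
        self.buffers = buffers if (buffers and buffers.b_total > 0) else None
        self.A_c, self.M = assemble(mesh, self.D)
        if self.buffers is not None:
            self.A_b, _ = assemble(mesh, np.eye(3) * self.buffers.d_b) \
                if self.buffers.d_b > 0 else (self.A_c * 0.0, None)
        self.newton_tol_uM = newton_tol_uM
        self.newton_maxit = newton_maxit
        self._last_delta = None   # extrapolation predictor between steps
        self.clip_events = 0

    # -- linear operators --------------------------------------------------

    def _factorize(self, dt: float, c_lin: np.ndarray, b_lin: np.ndarray):
        n = len(self.M)
        Mdt = sp.diags(self.M / dt)
        if self.buffers is None:
            J = (Mdt + self.A_c).tocsc()
        else:
            kon, koff = self.buffers.k_on, self.buffers.k_off
            dBdc = sp.diags(self.M * kon * b_lin)
            dBdb = sp.diags(self.M * (kon * c_lin + koff))
            J = sp.bmat([[Mdt + self.A_c + dBdc, dBdb],
                         [dBdc, Mdt + self.A_b + dBdb]]).tocsc()
        return spla.splu(J)

    def _residual(self, c, b, c0, b0, dt, f_ext):
        Mdt = self.M / dt
        r_c = Mdt * (c - c0) + self.A_c @ c - f_ext
        if self.buffers is None:
            return r_c, None
        kon, koff = self.buffers.k_on, self.buffers.k_off
        B = kon * c * b - koff * (self.buffers.b_total - b)
        r_c = r_c + self.M * B
        r_b = Mdt * (b - b0) + self.A_b @ b + self.M * B
        return r_c, r_b

    # -- stepping ----------------------------------------------------------

    def prepare(self, dt: float, field: Field3D) -> None:
        """Factorize the (frozen) Jacobian for repeated steps at ``dt``."""
        self._factor = self._factorize(dt, field.c, field.b)
        self._factor_dt = dt

    def step(self, field: Field3D, phi: np.ndarray | None, dt: float
             ) -> Field3D:
        """Advance one implicit-Euler step.

        ``phi``: molar influx density [uM*um/ms] per mesh vertex (zero off
        the membrane), already lumped-ready; it is multiplied by the
        boundary vertex areas internally if given per-area, see
        ``boundary_source``.
        """
        if dt <= 0:
            raise ConfigError("dt must be positive")
        if getattr(self, "_factor", None) is None or \
                getattr(self, "_factor_dt", None) != dt:
            self.prepare(dt, field)
        f_ext = np.zeros(len(self.M)) if phi is None else phi
        c0, b0 = field.c, field.b
        c, b = c0.copy(), b0.copy()
        n = len(c)
        # extrapolation predictor from the previous step's update
        if self._last_delta is not None and len(self._last_delta) == \
                (n if self.buffers is None else 2 * n):
            if self.buffers is None:
                c = np.clip(c - self._last_delta, 0.0, None)
            else:
                c = np.clip(c - self._last_delta[:n], 0.0, None)
                b = np.clip(b - self._last_delta[n:], 0.0,
                            self.buffers.b_total)
        # residual measured in concentration units: |r| dt / M  [uM]
        inv_scale = dt / self.M
        for it in range(self.newton_maxit):
            r_c, r_b = self._residual(c, b, c0, b0, dt, f_ext)
            res = np.max(np.abs(r_c) * inv_scale)
            if r_b is not None:
                res = max(res, np.max(np.abs(r_b) * inv_scale))
            if res < self.newton_tol_uM:
                break
            if it in (8, 16, 24):
                # convergence stalling: re-linearize at the current state
                self._factor = self._factorize(dt, c, b)
            rhs = r_c if r_b is None else np.concatenate([r_c, r_b])
            delta = self._factor.solve(rhs)
            if r_b is None:
                c = c - delta
            else:
                c = c - delta[:n]
                b = b - delta[n:]
        else:
            raise SolverError(
                f"Newton did not converge in {self.newton_maxit} iterations "
                f"(residual {res:.3e} uM, tol {self.newton_tol_uM:.3e})")
        # store -(state change) so next step's predictor extrapolates it
        if self.buffers is None:
            self._last_delta = c0 - c
        else:
            self._last_delta = np.concatenate([c0 - c, b0 - b])
        neg = c < 0
        if neg.any():
            self.clip_events += int(neg.sum())
            c = np.clip(c, 0.0, None)
        if self.buffers is not None:
            b = np.clip(b, 0.0, self.buffers.b_total)
        out = Field3D(c=c, b=b, t=field.t + dt)
        out._b_total = field._b_total
        return out

    def boundary_source(self, phi_per_area: np.ndarray,
                        region: int = REGION_MEMBRANE) -> np.ndarray:
        """Lump a per-area flux density Phi [uM*um/ms] on boundary vertices
        into the nodal source vector f_i = Phi_i * |dOmega_i| used by
        :meth:`step`."""
        w = self.mesh.boundary_vertex_areas(region)
        return phi_per_area * w


def probe_locator(mesh: VolumeMesh, points) -> tuple[np.ndarray, np.ndarray]:
    """Barycentric interpolation weights for probe points.

    Returns (vertex_indices (m,4), weights (m,4)); points outside the mesh
    fall back to the nearest vertex with a logged warning.  Interpolation
    is exact for nodal-linear fields.
    """
    points = np.atleast_2d(np.asarray(points, float))
    verts, tets = mesh.vertices, mesh.tets
    p = verts[tets]
    e = p[:, 1:] - p[:, :1]
    inv = np.linalg.inv(e)
    idx_out = np.zeros((len(points), 4), np.int64)
    w_out = np.zeros((len(points), 4))
    for m, q in enumerate(points):
        # barycentric lam_1..3 solve (q - p0) = sum_j lam_j e_j
        lam = np.einsum("tji,tj->ti", inv, (q - p[:, 0]))
        lam0 = 1.0 - lam.sum(axis=1)
        bary = np.column_stack([lam0, lam])
        ok = np.all(bary >= -1e-9, axis=1)
        if ok.any():
            t = int(np.argmax(ok))
            idx_out[m] = tets[t]
            w_out[m] = np.clip(bary[t], 0.0, 1.0)
            w_out[m] /= w_out[m].sum()
        else:
            d = np.linalg.norm(verts - q, axis=1)
            j = int(np.argmin(d))
            logger.warning("probe %s outside the mesh; using nearest vertex "
                           "%d at distance %.3g um", q, j, d[j])
            idx_out[m, :] = j
            w_out[m] = np.array([1.0, 0, 0, 0])
    return idx_out, w_out


def probe(field_values: np.ndarray, locator) -> np.ndarray:
    """Evaluate nodal values at pre-located probe points."""
    idx, w = locator
    return (field_values[idx] * w).sum(axis=1)
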