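"""Hyperelastic finite-element simulation of lung-section inflation.

Total-Lagrangian formulation on straight-sided quadratic tetrahedra.  The
material is the two-parameter Mooney-Rivlin model on the isochoric
invariants with a quadratic volumetric term,

    W = c1 (I1_bar - 3) + c2 (I2_bar - 3) + kappa (J - 1)^2,
    c1 = c2 = G / 4,      kappa = 2 G (1 + nu) / (3 (1 - 2 nu)),

with the second Piola-Kirchhoff stress derived consistently from W.  Loads
and boundary conditions mirror tidal breathing of an imaged lung section:

* rolling (in-plane only) motion on the apical and basal cut planes,
* a linear spring foundation on the mediastinal surface,
  kn = Es (1 - nu_t) / (ds (1 + nu_t)(1 - 2 nu_t)), ks = Es / (2 ds (1 + nu_t)),
* a follower vacuum pressure on the remaining outer surface, ramping
  sinusoidally from 0 to the peak -p over half a respiratory cycle.

Newton's method uses tangents obtained by complex-step differentiation of
the element residuals, exact to machine precision, so convergence is
quadratic.  The peak pressure is calibrated by secant iteration so the
deformed-to-reference volume ratio hits a physiologic target (1.167 for a
healthy adult tidal breath, 1.083 for the 50%-reduced CF tidal volume).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import LungSectionModel, TetMesh, face_normals_areas

# --------------------------------------------------------------------------
# quadrature and shape functions
# --------------------------------------------------------------------------

_A4, _B4 = 0.5854101966249685, 0.1381966011250105
TET_GP4 = np.array([[_A4, _B4, _B4], [_B4, _A4, _B4],
                    [_B4, _B4, _A4], [_B4, _B4, _B4]])
TET_W4 = np.full(4, 0.25)

TET_GP5 = np.array([[0.25, 0.25, 0.25],
                    [0.5, 1 / 6, 1 / 6], [1 / 6, 0.5, 1 / 6],
                    [1 / 6, 1 / 6, 0.5], [1 / 6, 1 / 6, 1 / 6]])
TET_W5 = np.array([-0.8, 0.45, 0.45, 0.45, 0.45])

_TA, _TWA = 0.445948490915965, 0.223381589678011
_TB, _TWB = 0.091576213509771, 0.109951743655322
TRI_GP6 = np.array([[_TA, _TA], [1 - 2 * _TA, _TA], [_TA, 1 - 2 * _TA],
                    [_TB, _TB], [1 - 2 * _TB, _TB], [_TB, 1 - 2 * _TB]])
TRI_W6 = np.array([_TWA, _TWA, _TWA, _TWB, _TWB, _TWB])


def tet10_shape(xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Values and reference gradients of the 10 shape functions at points
    ``xi`` (n, 3).  Returns (N (n,10), dN (n,10,3))."""
    xi = np.atleast_2d(xi)
    l1, l2, l3 = xi[:, 0], xi[:, 1], xi[:, 2]
    l0 = 1.0 - l1 - l2 - l3
    L = np.stack([l0, l1, l2, l3], axis=1)
    dL = np.array([[-1.0, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]])

    n = xi.shape[0]
    N = np.empty((n, 10))
    dN = np.empty((n, 10, 3))
    for i in range(4):
        N[:, i] = L[:, i] * (2 * L[:, i] - 1)
        dN[:, i] = (4 * L[:, i] - 1)[:, None] * dL[i]
    edges = ((0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3))
    for j, (a, b) in enumerate(edges):
        N[:, 4 + j] = 4 * L[:, a] * L[:, b]
        dN[:, 4 + j] = 4 * (L[:, a][:, None] * dL[b] + L[:, b][:, None] * dL[a])
    return N, dN


def tri6_shape(rs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rs = np.atleast_2d(rs)
    r, s = rs[:, 0], rs[:, 1]
    t = 1.0 - r - s
    L = np.stack([t, r, s], axis=1)
    dL = np.array([[-1.0, -1], [1, 0], [0, 1]])
    n = rs.shape[0]
    N = np.empty((n, 6))
    dN = np.empty((n, 6, 2))
    for i in range(3):
        N[:, i] = L[:, i] * (2 * L[:, i] - 1)
        dN[:, i] = (4 * L[:, i] - 1)[:, None] * dL[i]
    for j, (a, b) in enumerate(((0, 1), (1, 2), (2, 0))):
        N[:, 3 + j] = 4 * L[:, a] * L[:, b]
        dN[:, 3 + j] = 4 * (L[:, a][:, None] * dL[b] + L[:, b][:, None] * dL[a])
    return N, dN


def _tet10_mass_reference() -> np.ndarray:
    """Exact integrals of N_a N_b over the reference tetrahedron.

    Shape functions are quadratic polynomials in barycentric coordinates;
    monomials integrate as a! b! c! d! / (a+b+c+d+3)!.
    """
    # polynomial of N_a: dict exponent-tuple -> coefficient
    polys = []
    def bary(i):
        e = [0, 0, 0, 0]
        e[i] = 1
        return tuple(e)
    for i in range(4):
        e1 = bary(i)
        e2 = tuple(2 * x for x in e1)
        polys.append({e2: 2.0, e1: -1.0})
    for (a, b) in ((0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3)):
        e = [0, 0, 0, 0]
        e[a] += 1
        e[b] += 1
        polys.append({tuple(e): 4.0})

    def integral(exp):
        num = 1.0
        for e in exp:
            num *= math.factorial(e)
        return num / math.factorial(sum(exp) + 3)

    M = np.zeros((10, 10))
    for a in range(10):
        for b in range(10):
            total = 0.0
            for ea, ca in polys[a].items():
                for eb, cb in polys[b].items():
                    total += ca * cb * integral(tuple(x + y for x, y in zip(ea, eb)))
            M[a, b] = total
    return M


_MASS_REF = _tet10_mass_reference()


def _det3(m: np.ndarray) -> np.ndarray:
    return (m[..., 0, 0] * (m[..., 1, 1] * m[..., 2, 2] - m[..., 1, 2] * m[..., 2, 1])
            - m[..., 0, 1] * (m[..., 1, 0] * m[..., 2, 2] - m[..., 1, 2] * m[..., 2, 0])
            + m[..., 0, 2] * (m[..., 1, 0] * m[..., 2, 1] - m[..., 1, 1] * m[..., 2, 0]))


def _inv3(m: np.ndarray, det: np.ndarray) -> np.ndarray:
    inv = np.empty_like(m)
    inv[..., 0, 0] = m[..., 1, 1] * m[..., 2, 2] - m[..., 1, 2] * m[..., 2, 1]
    inv[..., 0, 1] = m[..., 0, 2] * m[..., 2, 1] - m[..., 0, 1] * m[..., 2, 2]
    inv[..., 0, 2] = m[..., 0, 1] * m[..., 1, 2] - m[..., 0, 2] * m[..., 1, 1]
    inv[..., 1, 0] = m[..., 1, 2] * m[..., 2, 0] - m[..., 1, 0] * m[..., 2, 2]
    inv[..., 1, 1] = m[..., 0, 0] * m[..., 2, 2] - m[..., 0, 2] * m[..., 2, 0]
    inv[..., 1, 2] = m[..., 0, 2] * m[..., 1, 0] - m[..., 0, 0] * m[..., 1, 2]
    inv[..., 2, 0] = m[..., 1, 0] * m[..., 2, 1] - m[..., 1, 1] * m[..., 2, 0]
    inv[..., 2, 1] = m[..., 0, 1] * m[..., 2, 0] - m[..., 0, 0] * m[..., 2, 1]
    inv[..., 2, 2] = m[..., 0, 0] * m[..., 1, 1] - m[..., 0, 1] * m[..., 1, 0]
    return inv / det[..., None, None]


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialParams:
    """Mooney-Rivlin parameters derived from the shear modulus G and nu."""

    G: float | np.ndarray      # Pa; scalar or per-node field
    nu: float
    rho_tissue: float = 500.0  # kg/m^3, used only in dynamic runs

    @property
    def c1(self):
        return np.asarray(self.G) / 4.0

    @property
    def c2(self):
        return np.asarray(self.G) / 4.0

    @property
    def kappa(self):
        return 2.0 * np.asarray(self.G) * (1 + self.nu) / (3 * (1 - 2 * self.nu))


def make_material(G: float | np.ndarray, nu: float = 0.2,
                  rho_tissue: float = 500.0) -> MaterialParams:
    if np.any(np.asarray(G) <= 0):
        raise ValueError("shear modulus must be positive")
    if not (0 <= nu < 0.5):
        raise ValueError("Poisson's ratio must lie in [0, 0.5) "
                         "(bulk modulus unbounded at 0.5)")
    return MaterialParams(G=G, nu=nu, rho_tissue=rho_tissue)


@dataclass(frozen=True)
class SpringFoundationParams:
    """Linear spring foundation emulating the mediastinal tissue bed."""

    Es: float    # Pa
    nu_t: float
    ds: float    # m
    kn: float    # Pa/m, normal
    ks: float    # Pa/m, tangential


def make_spring_foundation(Es: float = 8e5, nu_t: float = 0.4,
                           ds: float = 0.1) -> SpringFoundationParams:
    if Es <= 0 or ds <= 0:
        raise ValueError("Es and ds must be positive")
    if not (0 <= nu_t < 0.5):
        raise ValueError("nu_t must lie in [0, 0.5)")
    kn = Es * (1 - nu_t) / (ds * (1 + nu_t) * (1 - 2 * nu_t))
    ks = Es / (ds * 2 * (1 + nu_t))
    return SpringFoundationParams(Es=Es, nu_t=nu_t, ds=ds, kn=kn, ks=ks)


@dataclass(frozen=True)
class LoadSpec:
    """Sinusoidal vacuum pressure, 0 at end expiration to -p at peak."""

    peak_vacuum_pressure: float      # Pa, magnitude p >= 0
    respiratory_frequency: float = 0.2  # Hz

    def __post_init__(self):
        if self.peak_vacuum_pressure < 0:
            raise ValueError("peak vacuum pressure must be >= 0")
        if self.respiratory_frequency <= 0:
            raise ValueError("respiratory frequency must be positive")

    @property
    def t_peak(self) -> float:
        return 0.5 / self.respiratory_frequency

    def factor(self, t: float) -> float:
        """Load fraction at time t: sin^2(pi f t), peaking at t_peak."""
        return math.sin(math.pi * self.respiratory_frequency * t) ** 2


@dataclass
class SolverOptions:
    newton_rtol: float = 1e-8
    newton_atol: float = 1e-12
    newton_maxit: int = 30
    max_subdivisions: int = 10      # load-ramp bisections on non-convergence
    pressure_labels: tuple[str, ...] = ("outer-lateral",)
    spring_labels: tuple[str, ...] = ("mediastinal",)
    inplane_labels: tuple[str, ...] = ("apical", "basal")
    pin_rigid_body: bool = False
    line_search: bool = True


@dataclass
class SimulationResult:
    times: np.ndarray
    displacements: list[np.ndarray]       # (n_nodes, 3) per output time
    strains: list[np.ndarray]             # Green-Lagrange (n_el, 3, 3)
    volume_ratio: np.ndarray              # per output time
    converged: bool
    p_peak: float
    residual_history: list[float] = field(default_factory=list)
    mode: str = "quasi-static"


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, residual_history: list[float]):
        super().__init__(message)
        self.residual_history = residual_history


# --------------------------------------------------------------------------
# assembled problem
# --------------------------------------------------------------------------

_CSTEP = 1e-20


class InflationProblem:
    """Pre-assembled FE system for one mesh/material/BC configuration."""

    def __init__(self, model: LungSectionModel, material: MaterialParams,
                 springs: SpringFoundationParams | None = None,
                 options: SolverOptions | None = None):
        self.model = model
        self.material = material
        self.springs = springs
        self.options = options or SolverOptions()
        mesh = model.mesh
        self.mesh = mesh
        self.n_dof = mesh.n_nodes * 3

        conn = mesh.elements
        x = mesh.nodes[conn[:, :4]]
        jac = np.stack([x[:, 1] - x[:, 0], x[:, 2] - x[:, 0],
                        x[:, 3] - x[:, 0]], axis=-1)  # dX/dxi columns
        det = _det3(jac)
        if np.any(det <= 0):
            raise ValueError("mesh contains inverted elements")
        self.det_j = det
        inv_jac = _inv3(jac, det)

        def grads_at(points):
            _, dN = tet10_shape(points)
            # dN/dX = inv(J)^T applied: dN_a/dX_i = dN_a/dxi_k * invJ[k,i]
            return np.einsum("gak,eki->geai", dN, inv_jac)

        self.dndx4 = grads_at(TET_GP4)          # (4, n_el, 10, 3)
        self.wdet4 = TET_W4[:, None] * det[None] / 6.0
        self.dndx5 = grads_at(TET_GP5)
        self.wdet5 = TET_W5[:, None] * det[None] / 6.0

        n4, _ = tet10_shape(TET_GP4)
        g_nodal = np.broadcast_to(np.asarray(material.G, dtype=float),
                                  (mesh.n_nodes,))
        g_elem = g_nodal[conn]                   # (n_el, 10)
        self.g_gp4 = np.einsum("ga,ea->ge", n4, g_elem)
        nu = material.nu
        self.kap_gp4 = 2.0 * self.g_gp4 * (1 + nu) / (3 * (1 - 2 * nu))

        # pressure faces
        labels = mesh.face_labels
        pf = [labels[name] for name in self.options.pressure_labels
              if name in labels and len(labels[name])]
        self.pressure_faces = (np.vstack(pf)[:, :6] if pf
                               else np.empty((0, 6), dtype=np.int64))
        self._tri_N, self._tri_dN = tri6_shape(TRI_GP6)

        # spring foundation matrix (reference configuration, total u)
        self.k_spring = self._assemble_springs() if springs is not None else None

        # dirichlet dofs
        fixed = np.zeros((mesh.n_nodes, 3), dtype=bool)
        for name in self.options.inplane_labels:
            if name in labels and len(labels[name]):
                nodes = np.unique(labels[name][:, :6])
                fixed[nodes, 2] = True
        if self.options.pin_rigid_body:
            for node, comps in _rigid_body_pins(mesh):
                for c in comps:
                    fixed[node, c] = True
        self.fixed = fixed.reshape(-1)
        self.free = ~self.fixed

        self._mass = None

    # -- element-level kernels ---------------------------------------------

    def _gather(self, u_flat: np.ndarray) -> np.ndarray:
        u = u_flat.reshape(-1, 3)
        return u[self.mesh.elements]             # (n_el, 10, 3)

    def _internal_force_elem(self, u_el: np.ndarray) -> np.ndarray:
        """Element internal nodal forces for (possibly complex) element
        displacements (..., n_el, 10, 3); leading axes are batched."""
        f = np.zeros_like(u_el)
        eye = np.eye(3, dtype=u_el.dtype)
        for i in range(4):
            dndx = self.dndx4[i]
            H = np.einsum("...eaj,eak->...ejk", u_el, dndx)
            F = eye + H
            C = np.einsum("...eji,...ejk->...eik", F, F)
            J = _det3(F)
            Cinv = _inv3(C, J * J)
            I1 = np.trace(C, axis1=-2, axis2=-1)
            CC = np.einsum("...eij,...ejk->...eik", C, C)
            I2 = 0.5 * (I1 ** 2 - np.trace(CC, axis1=-2, axis2=-1))
            Jm23 = J ** (-2.0 / 3.0)
            Jm43 = Jm23 * Jm23
            c1 = self.g_gp4[i] / 4.0
            kap = self.kap_gp4[i]
            S = (2 * (c1 * Jm23)[..., None, None]
                 * (eye - (I1 / 3.0)[..., None, None] * Cinv)
                 + 2 * (c1 * Jm43)[..., None, None]
                 * (I1[..., None, None] * eye - C
                    - (2.0 * I2 / 3.0)[..., None, None] * Cinv)
                 + (kap * (J - 1) * J)[..., None, None] * Cinv)
            P = np.einsum("...eij,...ejk->...eik", F, S)
            f += self.wdet4[i][..., None, None] * np.einsum(
                "...eik,eak->...eai", P, dndx)
        return f

    def _tangent_internal(self, u_el: np.ndarray) -> np.ndarray:
        n_el = u_el.shape[0]
        # one batched complex-step sweep over the 30 local dofs
        up = np.broadcast_to(u_el.astype(complex),
                             (30,) + u_el.shape).copy()
        pert = (1j * _CSTEP) * np.eye(30).reshape(30, 10, 3)
        up += pert[:, None, :, :]
        f = self._internal_force_elem(up)          # (30, n_el, 10, 3)
        K = (f.imag / _CSTEP).reshape(30, n_el, 30)
        return np.moveaxis(K, 0, 2)                # (n_el, 30, 30) columns=dof

    def _pressure_force_faces(self, u_face: np.ndarray, p: float) -> np.ndarray:
        """Follower-load nodal forces on pressure faces; u_face (n_f, 6, 3)."""
        xf = self.mesh.nodes[self.pressure_faces] + u_face
        f = np.zeros_like(u_face)
        for i in range(TRI_GP6.shape[0]):
            dn = self._tri_dN[i]                 # (6, 2)
            xr = np.einsum("a,...fai->...fi", dn[:, 0], xf)
            xs = np.einsum("a,...fai->...fi", dn[:, 1], xf)
            nvec = np.cross(xr, xs)              # outward, area-weighted
            f += (0.5 * TRI_W6[i] * p) * self._tri_N[i][:, None] \
                * nvec[..., None, :]
        return f

    def _pressure_force(self, u_flat: np.ndarray, p: float) -> np.ndarray:
        out = np.zeros(self.n_dof, dtype=u_flat.dtype)
        if len(self.pressure_faces) == 0 or p == 0.0:
            return out
        u_face = u_flat.reshape(-1, 3)[self.pressure_faces]
        f = self._pressure_force_faces(u_face, p)
        idx = (3 * self.pressure_faces[..., None]
               + np.arange(3)[None, None, :]).reshape(-1)
        np.add.at(out, idx, f.reshape(-1).astype(out.dtype))
        return out

    def _tangent_pressure(self, u_flat: np.ndarray, p: float):
        nf = len(self.pressure_faces)
        if nf == 0 or p == 0.0:
            return None
        u_face = u_flat.reshape(-1, 3)[self.pressure_faces].astype(complex)
        up = np.broadcast_to(u_face, (18,) + u_face.shape).copy()
        up += (1j * _CSTEP) * np.eye(18).reshape(18, 6, 3)[:, None, :, :]
        f = self._pressure_force_faces(up, p)        # (18, nf, 6, 3)
        K = np.moveaxis((f.imag / _CSTEP).reshape(18, nf, 18), 0, 2)
        dof = (3 * self.pressure_faces[:, :, None]
               + np.arange(3)[None, None, :]).reshape(nf, 18)
        rows = np.repeat(dof, 18, axis=1).reshape(-1)
        cols = np.tile(dof, (1, 18)).reshape(-1)
        # pressure force is external: enters residual with minus sign
        return sp.coo_matrix((-K.reshape(-1), (rows, cols)),
                             shape=(self.n_dof, self.n_dof))

    def _assemble_springs(self) -> sp.csr_matrix:
        labels = self.mesh.face_labels
        fl = [labels[name] for name in self.options.spring_labels
              if name in labels and len(labels[name])]
        if not fl:
            return sp.csr_matrix((self.n_dof, self.n_dof))
        faces = np.vstack(fl)[:, :6]
        normals, areas = face_normals_areas(self.mesh.nodes, faces)
        kn, ks = self.springs.kn, self.springs.ks
        # direction tensor kn n n^T + ks (I - n n^T), constant per flat face
        D = (ks * np.eye(3)[None]
             + (kn - ks) * np.einsum("fi,fj->fij", normals, normals))
        N, _ = tri6_shape(TRI_GP6)
        A = np.einsum("g,ga,gb->ab", TRI_W6, N, N)  # integral basis products
        nf = faces.shape[0]
        Kf = np.einsum("ab,fij->faibj", A, D).reshape(nf, 18, 18) \
            * areas[:, None, None]
        dof = (3 * faces[:, :, None] + np.arange(3)[None, None, :]).reshape(nf, 18)
        rows = np.repeat(dof, 18, axis=1).reshape(-1)
        cols = np.tile(dof, (1, 18)).reshape(-1)
        return sp.coo_matrix((Kf.reshape(-1), (rows, cols)),
                             shape=(self.n_dof, self.n_dof)).tocsr()

    def _assemble_mass(self) -> sp.csr_matrix:
        conn = self.mesh.elements
        rho = self.material.rho_tissue
        Me = rho * self.det_j[:, None, None] * _MASS_REF[None]
        n_el = conn.shape[0]
        K = np.zeros((n_el, 30, 30))
        for i in range(3):
            K[:, i::3, i::3] = Me
        dof = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(n_el, 30)
        rows = np.repeat(dof, 30, axis=1).reshape(-1)
        cols = np.tile(dof, (1, 30)).reshape(-1)
        return sp.coo_matrix((K.reshape(-1), (rows, cols)),
                             shape=(self.n_dof, self.n_dof)).tocsr()

    @property
    def mass(self) -> sp.csr_matrix:
        if self._mass is None:
            self._mass = self._assemble_mass()
        return self._mass

    # -- global residual / tangent -----------------------------------------

    def residual(self, u_flat: np.ndarray, p: float) -> np.ndarray:
        f_el = self._internal_force_elem(self._gather(u_flat))
        r = np.zeros(self.n_dof, dtype=u_flat.dtype)
        idx = (3 * self.mesh.elements[..., None]
               + np.arange(3)[None, None, :]).reshape(-1)
        np.add.at(r, idx, f_el.reshape(-1))
        if self.k_spring is not None:
            r += self.k_spring @ u_flat
        r -= self._pressure_force(u_flat, p)
        return r

    def external_norm(self, u_flat: np.ndarray, p: float) -> float:
        return float(np.linalg.norm(self._pressure_force(u_flat, p)[self.free]))

    def tangent(self, u_flat: np.ndarray, p: float) -> sp.csr_matrix:
        conn = self.mesh.elements
        n_el = conn.shape[0]
        Ke = self._tangent_internal(self._gather(u_flat))
        dof = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(n_el, 30)
        rows = np.repeat(dof, 30, axis=1).reshape(-1)
        cols = np.tile(dof, (1, 30)).reshape(-1)
        K = sp.coo_matrix((Ke.reshape(-1), (rows, cols)),
                          shape=(self.n_dof, self.n_dof)).tocsr()
        if self.k_spring is not None:
            K = K + self.k_spring
        Kp = self._tangent_pressure(u_flat, p)
        if Kp is not None:
            K = K + Kp.tocsr()
        return K

    # -- solves --------------------------------------------------------------

    def _newton(self, u: np.ndarray, p: float,
                extra_residual=None, extra_tangent=None,
                history: list[float] | None = None) -> np.ndarray:
        opts = self.options
        free = self.free
        u = u.copy()
        ref = max(self.external_norm(u, p), opts.newton_atol)

        def res_norm(uu):
            with np.errstate(invalid="ignore", divide="ignore"):
                r = self.residual(uu, p)
                if extra_residual is not None:
                    r = r + extra_residual(uu)
            n = np.linalg.norm(r[free])
            return r, (float(n) if np.isfinite(n) else np.inf)

        r, rn = res_norm(u)
        if not np.isfinite(rn) or rn == np.inf:
            raise ConvergenceError("non-finite residual at start state",
                                   history or [])
        for it in range(opts.newton_maxit):
            if history is not None:
                history.append(rn)
            if rn <= opts.newton_rtol * ref or rn <= opts.newton_atol:
                return u
            K = self.tangent(u, p)
            if extra_tangent is not None:
                K = K + extra_tangent()
            Kff = K[free][:, free].tocsc()
            du = np.zeros(self.n_dof)
            # minimum-degree on K + K^T: the tangent is structurally
            # symmetric, which SuperLU's default ordering does not exploit
            du[free] = -splu(Kff, permc_spec="MMD_AT_PLUS_A").solve(r[free])
            step = 1.0
            for _ in range(6):
                u_try = u + step * du
                r_try, rn_try = res_norm(u_try)
                if rn_try < np.inf and ((not opts.line_search) or rn_try < rn
                                        or rn_try <= opts.newton_rtol * ref):
                    break
                step *= 0.5
            if rn_try == np.inf:
                # inverted elements at every step length: load too large
                raise ConvergenceError("element inversion during line search",
                                       history or [])
            u, r, rn = u_try, r_try, rn_try
        if rn <= 1e-4 * ref:  # stagnated but essentially solved
            return u
        raise ConvergenceError(
            f"Newton did not converge (|R| = {rn:.3e}, ref = {ref:.3e})",
            history or [])

    def solve_static(self, p: float, u0: np.ndarray | None = None,
                     history: list[float] | None = None) -> np.ndarray:
        """Quasi-static solve at pressure magnitude p, with automatic load
        subdivision from the warm start on Newton failure."""
        u = np.zeros(self.n_dof) if u0 is None else u0.copy()
        targets = [p]
        depth = 0
        p_done = None
        while targets:
            p_try = targets[-1]
            try:
                u = self._newton(u, p_try, history=history)
                p_done = p_try
                targets.pop()
            except ConvergenceError:
                depth += 1
                if depth > self.options.max_subdivisions:
                    raise
                base = p_done if p_done is not None else 0.0
                targets.append(0.5 * (base + p_try))
        return u

    # -- field extraction ----------------------------------------------------

    def strain_elements(self, u_flat: np.ndarray) -> np.ndarray:
        """Green-Lagrange strain tensor per element (mean over the 4 Gauss
        points)."""
        u_el = self._gather(u_flat)
        eye = np.eye(3)
        E = np.zeros((u_el.shape[0], 3, 3))
        for i in range(4):
            H = np.einsum("eaj,eak->ejk", u_el, self.dndx4[i])
            F = eye + H
            C = np.einsum("eji,ejk->eik", F, F)
            E += 0.25 * 0.5 * (C - eye)
        return E

    def volume_ratio(self, u_flat: np.ndarray) -> float:
        u_el = self._gather(u_flat)
        eye = np.eye(3)
        v = 0.0
        for i in range(5):
            H = np.einsum("eaj,eak->ejk", u_el, self.dndx5[i])
            J = _det3(eye + H)
            v += float(np.sum(self.wdet5[i] * J))
        return v / float(np.sum(self.det_j) / 6.0)


def _rigid_body_pins(mesh: TetMesh) -> list[tuple[int, tuple[int, ...]]]:
    """3-2-1 pinning of the six rigid modes for meshes without Dirichlet
    faces (e.g. the free sphere benchmark)."""
    x = mesh.nodes
    c = x.mean(axis=0)
    a = int(np.argmin(np.linalg.norm(x - c, axis=1)))
    penalty = np.abs(x[:, 1] - x[a, 1]) + np.abs(x[:, 2] - x[a, 2])
    b = int(np.argmax(np.abs(x[:, 0] - x[a, 0]) - 1e3 * penalty))
    penalty_c = np.abs(x[:, 2] - x[a, 2])
    cn = int(np.argmax(np.abs(x[:, 1] - x[a, 1]) - 1e3 * penalty_c))
    return [(a, (0, 1, 2)), (b, (1, 2)), (cn, (2,))]


# --------------------------------------------------------------------------
# public drivers
# --------------------------------------------------------------------------

def evaluate_state(model: LungSectionModel, material: MaterialParams,
                   u: np.ndarray) -> dict[str, np.ndarray]:
    """Per-element (Gauss-averaged) E, S, W, J for a displacement field.

    Used for invariance checks (e.g. rigid-body motion leaves W and S at
    zero) and debugging.
    """
    prob = InflationProblem(model, material,
                            options=SolverOptions(pressure_labels=(),
                                                  spring_labels=(),
                                                  inplane_labels=()))
    u_el = prob._gather(np.asarray(u, dtype=float).reshape(-1))
    eye = np.eye(3)
    n_el = u_el.shape[0]
    out = {"E": np.zeros((n_el, 3, 3)), "S": np.zeros((n_el, 3, 3)),
           "W": np.zeros(n_el), "J": np.zeros(n_el)}
    for i in range(4):
        H = np.einsum("eaj,eak->ejk", u_el, prob.dndx4[i])
        F = eye + H
        C = np.einsum("eji,ejk->eik", F, F)
        J = _det3(F)
        Cinv = _inv3(C, J * J)
        I1 = np.trace(C, axis1=-2, axis2=-1)
        CC = np.einsum("eij,ejk->eik", C, C)
        I2 = 0.5 * (I1 ** 2 - np.trace(CC, axis1=-2, axis2=-1))
        Jm23 = J ** (-2.0 / 3.0)
        I1b = Jm23 * I1
        I2b = Jm23 ** 2 * I2
        c1 = prob.g_gp4[i] / 4.0
        kap = prob.kap_gp4[i]
        W = c1 * (I1b - 3) + c1 * (I2b - 3) + kap * (J - 1) ** 2
        S = (2 * c1[:, None, None] * Jm23[:, None, None]
             * (eye - (I1 / 3.0)[:, None, None] * Cinv)
             + 2 * c1[:, None, None] * (Jm23 ** 2)[:, None, None]
             * (I1[:, None, None] * eye - C
                - (2.0 * I2 / 3.0)[:, None, None] * Cinv)
             + (kap * (J - 1) * J)[:, None, None] * Cinv)
        out["E"] += 0.25 * 0.5 * (C - eye)
        out["S"] += 0.25 * S
        out["W"] += 0.25 * W
        out["J"] += 0.25 * J
    return out


def solve_inflation(model: LungSectionModel, material: MaterialParams,
                    springs: SpringFoundationParams | None = None,
                    load: LoadSpec | None = None,
                    mode: str = "quasi-static",
                    output_times: Sequence[float] | None = None,
                    options: SolverOptions | None = None,
                    problem: InflationProblem | None = None
                    ) -> SimulationResult:
    """Simulate inflation of the lung section under the vacuum load.

    ``quasi-static`` solves the equilibrium problem at each output time's
    load value (breathing at 0.2 Hz is quasi-static to high accuracy);
    ``dynamic`` integrates the inertial term with Newmark (average
    acceleration), retained for verifying that inertia is negligible.
    """
    load = load or LoadSpec(0.0)
    if problem is None:
        problem = InflationProblem(model, material, springs, options)
    if output_times is None:
        output_times = [load.t_peak]
    times = np.asarray(output_times, dtype=float)

    history: list[float] = []
    displacements, strains, vols = [], [], []

    if mode == "quasi-static":
        u = np.zeros(problem.n_dof)
        for t in times:
            p_t = load.peak_vacuum_pressure * load.factor(t)
            u = problem.solve_static(p_t, u0=u, history=history)
            displacements.append(u.reshape(-1, 3).copy())
            strains.append(problem.strain_elements(u))
            vols.append(problem.volume_ratio(u))
    elif mode == "dynamic":
        M = problem.mass
        beta, gamma = 0.25, 0.5
        n_sub = 8
        t_grid = [0.0]
        for t in times:
            t_grid.extend(np.linspace(t_grid[-1], t, n_sub + 1)[1:])
        u = np.zeros(problem.n_dof)
        v = np.zeros_like(u)
        a = np.zeros_like(u)
        out_iter = iter(times)
        next_out = next(out_iter, None)
        for t_prev, t in zip(t_grid[:-1], t_grid[1:]):
            dt = t - t_prev
            p_t = load.peak_vacuum_pressure * load.factor(t)
            u_n, v_n, a_n = u.copy(), v.copy(), a.copy()

            def extra_res(uu):
                acc = (uu - u_n - dt * v_n) / (beta * dt * dt) \
                    - (0.5 / beta - 1.0) * a_n
                return M @ acc

            scale = 1.0 / (beta * dt * dt)

            def extra_tan():
                return M * scale

            u = problem._newton(u, p_t, extra_residual=extra_res,
                                extra_tangent=extra_tan, history=history)
            a = (u - u_n - dt * v_n) / (beta * dt * dt) \
                - (0.5 / beta - 1.0) * a_n
            v = v_n + dt * ((1 - gamma) * a_n + gamma * a)
            if next_out is not None and abs(t - next_out) < 1e-12:
                displacements.append(u.reshape(-1, 3).copy())
                strains.append(problem.strain_elements(u))
                vols.append(problem.volume_ratio(u))
                next_out = next(out_iter, None)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return SimulationResult(times=times, displacements=displacements,
                            strains=strains,
                            volume_ratio=np.asarray(vols),
                            converged=True,
                            p_peak=load.peak_vacuum_pressure,
                            residual_history=history, mode=mode)


@dataclass
class CalibrationResult:
    p: float
    volume_ratio: float
    result: SimulationResult
    n_evaluations: int


class CalibrationError(RuntimeError):
    pass


def calibrate_pressure(model: LungSectionModel, material: MaterialParams,
                       springs: SpringFoundationParams | None,
                       target_volume_ratio: float,
                       tol: float = 1e-3,
                       p_init: float = 100.0,
                       max_iter: int = 30,
                       options: SolverOptions | None = None,
                       problem: InflationProblem | None = None
                       ) -> CalibrationResult:
    """Find the peak vacuum pressure p giving the target volume ratio.

    Secant iteration on the (monotone, smooth) volume-ratio response, warm
    starting each equilibrium solve from the previous one.  The deformed
    volume integrates the element Jacobians of the converged solution.
    """
    if target_volume_ratio < 1:
        raise ValueError("target volume ratio must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if problem is None:
        problem = InflationProblem(model, material, springs, options)

    if target_volume_ratio == 1.0:
        res = SimulationResult(times=np.array([0.0]),
                               displacements=[np.zeros((problem.mesh.n_nodes, 3))],
                               strains=[np.zeros((problem.mesh.n_elements, 3, 3))],
                               volume_ratio=np.array([1.0]), converged=True,
                               p_peak=0.0)
        return CalibrationResult(p=0.0, volume_ratio=1.0, result=res,
                                 n_evaluations=0)

    u = np.zeros(problem.n_dof)
    evals = 0

    def vr_at(p, u0):
        nonlocal evals
        evals += 1
        uu = problem.solve_static(p, u0=u0)
        return problem.volume_ratio(uu), uu

    p_prev, vr_prev = 0.0, 1.0
    p_cur = p_init
    vr_cur, u = vr_at(p_cur, u)
    if vr_cur <= 1.0:
        raise CalibrationError(
            "volume ratio did not increase with pressure; response is not "
            "bracketable")

    for _ in range(max_iter):
        if abs(vr_cur - target_volume_ratio) <= tol:
            load = LoadSpec(p_cur)
            res = SimulationResult(
                times=np.array([load.t_peak]),
                displacements=[u.reshape(-1, 3).copy()],
                strains=[problem.strain_elements(u)],
                volume_ratio=np.array([vr_cur]), converged=True,
                p_peak=p_cur)
            return CalibrationResult(p=p_cur, volume_ratio=vr_cur,
                                     result=res, n_evaluations=evals)
        slope = (vr_cur - vr_prev) / (p_cur - p_prev)
        if slope <= 0:
            raise CalibrationError("non-monotone volume-ratio response")
        p_next = p_cur + (target_volume_ratio - vr_cur) / slope
        p_next = float(np.clip(p_next, 0.1 * p_cur, 10.0 * p_cur))
        p_prev, vr_prev = p_cur, vr_cur
        p_cur = p_next
        vr_cur, u = vr_at(p_cur, u)
    raise CalibrationError(
        f"calibration did not reach |VR - target| <= {tol} in "
        f"{max_iter} iterations (last VR = {vr_cur:.5f})")


def sensitivity_sweep(model: LungSectionModel,
                      target_volume_ratio: float,
                      parameter_ranges: dict[str, Sequence[float]],
                      nu: float = 0.2,
                      spring_kwargs: dict | None = None,
                      calibration_tol: float = 1e-3,
                      options: SolverOptions | None = None,
                      flag_threshold: float = 0.10):
    """One calibrated run per parameter value; reports median strain and
    strain-gradient statistics and flags parameters whose variation moves
    the median first-principal strain by more than ``flag_threshold``.

    Supported parameters: ``nu`` (Poisson's ratio), ``Es`` (mediastinal
    spring stiffness, Pa), ``G_outer`` (outer-shell shear modulus, Pa) and
    ``p`` (boundary load in Pa, run directly without calibration).
    """
    import pandas as pd

    from .strain import principal_strain, element_to_nodal, strain_gradient

    spring_kwargs = dict(spring_kwargs or {})
    mesh = model.mesh

    def run(nu_v, es_v, g_outer, p_direct=None):
        nodal_g = model.nodal_G.copy()
        if g_outer is not None:
            outer_only = np.setdiff1d(
                np.unique(mesh.elements[mesh.domain == 1]),
                np.unique(mesh.elements[mesh.domain == 0]))
            nodal_g[outer_only] = g_outer
        mdl = LungSectionModel(mesh=mesh, nodal_G=nodal_g,
                               mean_G=model.mean_G)
        mat = make_material(nodal_g, nu=nu_v)
        spr = make_spring_foundation(**{**spring_kwargs, "Es": es_v})
        if p_direct is None:
            cal = calibrate_pressure(mdl, mat, spr, target_volume_ratio,
                                     tol=calibration_tol, options=options)
            p_val, vr, res = cal.p, cal.volume_ratio, cal.result
        else:
            res = solve_inflation(mdl, mat, spr, LoadSpec(p_direct),
                                  options=options)
            p_val, vr = p_direct, float(res.volume_ratio[-1])
        ep1 = principal_strain(res.strains[-1])
        nodal = element_to_nodal(mesh, ep1)
        grad, excl = strain_gradient(nodal, mesh)
        inner = (mesh.domain == 0) & ~excl
        vols = mesh.element_volumes()
        from .strain import weighted_quantile
        med_e = weighted_quantile(ep1[inner], 0.5, vols[inner])
        iqr_e = (weighted_quantile(ep1[inner], 0.75, vols[inner])
                 - weighted_quantile(ep1[inner], 0.25, vols[inner]))
        med_g = weighted_quantile(grad[inner], 0.5, vols[inner])
        iqr_g = (weighted_quantile(grad[inner], 0.75, vols[inner])
                 - weighted_quantile(grad[inner], 0.25, vols[inner]))
        return dict(p=p_val, volume_ratio=vr, median_ep1=med_e,
                    iqr_ep1=iqr_e, median_grad=med_g, iqr_grad=iqr_g)

    es_base = spring_kwargs.pop("Es", 8e5)
    rows = []
    base = run(nu, es_base, None)
    rows.append(dict(parameter="baseline", value=np.nan, converged=True, **base))
    flags = {}
    for name, values in parameter_ranges.items():
        medians = [base["median_ep1"]]
        for v in values:
            try:
                if name == "nu":
                    r = run(v, es_base, None)
                elif name == "Es":
                    r = run(nu, v, None)
                elif name == "G_outer":
                    r = run(nu, es_base, v)
                elif name == "p":
                    r = run(nu, es_base, None, p_direct=v)
                else:
                    raise ValueError(f"unknown sweep parameter {name!r}")
                rows.append(dict(parameter=name, value=v, converged=True, **r))
                medians.append(r["median_ep1"])
            except (ConvergenceError, CalibrationError) as exc:
                rows.append(dict(parameter=name, value=v, converged=False,
                                 p=np.nan, volume_ratio=np.nan,
                                 median_ep1=np.nan, iqr_ep1=np.nan,
                                 median_grad=np.nan, iqr_grad=np.nan))
        if name == "p":
            flags[name] = False  # load is the control, not a material nuisance
        else:
            m = np.asarray(medians)
            flags[name] = bool(np.nanmax(np.abs(m / base["median_ep1"] - 1))
                               > flag_threshold)
    return pd.DataFrame(rows), flags
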