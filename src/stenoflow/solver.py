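"""Steady incompressible finite-volume RANS solver (SIMPLE, k-epsilon).

Colocated pressure-velocity coupling with Rhie-Chow face-flux
interpolation on the body-fitted structured grid.  Turbulence closure
is the standard k-epsilon eddy-viscosity model (C_mu = 0.09,
C_eps1 = 1.44, C_eps2 = 1.92, sigma_k = 1.0, sigma_eps = 1.3) with
equilibrium wall functions on the no-slip walls.  Convection is
first-order upwind implicitly with an optional limited second-order
upwind deferred correction; diffusion is central with explicit
non-orthogonal correction.

Boundary conditions are fixed by the study design: Dirichlet velocity /
k / eps on the inlet, zero reference pressure with zero-gradient
velocity on the outlet, no-slip walls, and (axisymmetric mode) a
symmetry axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .boundary import C_MU, InletSpec
from .errors import NonConvergenceError, NumericalFailureError, ValidationError
from .mesh import StructuredMesh

# standard k-epsilon constants
C_EPS1 = 1.44
C_EPS2 = 1.92
SIGMA_K = 1.0
SIGMA_EPS = 1.3
KAPPA = 0.41
E_WALL = 9.8
YPLUS_LAM = 11.225  # log-law / linear-sublayer crossover
EPS_FLOOR = 1e-12
K_FLOOR = 1e-14


@dataclass(frozen=True)
class FluidProperties:
    """Incompressible Newtonian fluid. Blood defaults live in the config."""

    density: float  # kg/m^3
    dynamic_viscosity: float  # Pa s

    def __post_init__(self):
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValidationError("density and viscosity must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.dynamic_viscosity / self.density


@dataclass
class SolverSettings:
    relax_u: float = 0.7
    relax_p: float = 0.3
    relax_turb: float = 0.7
    max_iterations: int = 4000
    residual_tolerance: float = 1.0e-4
    convection_scheme: str = "second-order-upwind-limited"
    turbulence_enabled: bool = True
    kato_launder_production: bool = False
    linear_solver_tolerance: float = 1e-10  # direct solves; kept for the record
    min_iterations: int = 5

    def __post_init__(self):
        for name in ("relax_u", "relax_p", "relax_turb"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValidationError(f"{name} must lie in (0, 1], got {v}")
        if self.residual_tolerance <= 0:
            raise ValidationError("residual_tolerance must be positive")
        if self.convection_scheme not in ("first-order-upwind", "second-order-upwind-limited"):
            raise ValidationError(f"unknown convection scheme {self.convection_scheme!r}")


@dataclass
class FlowField:
    """Cell-centred solver state plus the face mass fluxes."""

    U: np.ndarray
    V: np.ndarray
    p: np.ndarray
    k: np.ndarray
    eps: np.ndarray
    mu_t: np.ndarray
    Fx: np.ndarray  # (ni+1, nj) i-face mass fluxes, positive in +i
    Fy: np.ndarray  # (ni, nj+1) j-face mass fluxes, positive in +j
    fluid: FluidProperties

    def velocity_magnitude(self) -> np.ndarray:
        return np.hypot(self.U, self.V)

    def copy(self) -> "FlowField":
        return FlowField(
            *(getattr(self, n).copy() for n in ("U", "V", "p", "k", "eps", "mu_t", "Fx", "Fy")),
            fluid=self.fluid,
        )


@dataclass
class ConvergenceReport:
    residuals: dict
    converged: bool
    iterations_used: int
    tolerance: float

    def final_residuals(self) -> dict:
        return {k: (v[-1] if len(v) else np.nan) for k, v in self.residuals.items()}


@dataclass
class LinearSystem:
    """Assembled transport equation in structured-diagonal form."""

    aP: np.ndarray
    aE: np.ndarray
    aW: np.ndarray
    aN: np.ndarray
    aS: np.ndarray
    b: np.ndarray
    field_name: str = ""

    def matrix(self) -> sparse.csc_matrix:
        ni, nj = self.aP.shape
        return sparse.diags(
            [
                self.aP.ravel(),
                self.aE[:-1].ravel(),
                self.aW[1:].ravel(),
                self.aN.ravel()[:-1],
                self.aS.ravel()[1:],
            ],
            [0, nj, -nj, 1, -1],
            format="csc",
        )

    def solve(self) -> np.ndarray:
        x = splu(self.matrix()).solve(self.b.ravel())
        return x.reshape(self.aP.shape)


def compute_eddy_viscosity(k, eps, fluid: FluidProperties, c_mu: float = C_MU):
    """Boussinesq eddy viscosity mu_t = rho C_mu k^2 / eps (eps floored)."""
    k = np.maximum(np.asarray(k, dtype=float), 0.0)
    eps = np.maximum(np.asarray(eps, dtype=float), EPS_FLOOR)
    return fluid.density * c_mu * k**2 / eps


def compute_residuals(system: LinearSystem, solution: np.ndarray) -> float:
    """Normalized L1 residual |A x - b|_1 / (sum |aP x| + sum |b|)."""
    A = system.matrix()
    x = np.asarray(solution, dtype=float).ravel()
    r = np.abs(A @ x - system.b.ravel()).sum()
    scale = np.abs(system.aP.ravel() * x).sum() + np.abs(system.b).sum()
    if scale == 0.0:
        return float(r)
    return float(r / scale)


# ---------------------------------------------------------------------------
# assembly helpers (vectorized over the structured grid)
# ---------------------------------------------------------------------------
def _green_gauss(mesh, phi, bc_in=None, bc_out=None, wall_value=None):
    """Cell gradients via Green-Gauss; uses (phi_f - phi_P) to stay exact
    for constants on r-weighted (axisymmetric) face areas.

    ``bc_in``/``bc_out`` are inlet/outlet face values (None = zero
    gradient); ``wall_value`` is a scalar Dirichlet value on walls
    (None = zero gradient).
    """
    ni, nj = phi.shape
    # face values
    fx = np.empty((ni + 1, nj))
    fx[1:-1] = (1.0 - mesh.wx) * phi[:-1] + mesh.wx * phi[1:]
    fx[0] = phi[0] if bc_in is None else bc_in
    fx[-1] = phi[-1] if bc_out is None else bc_out
    fy = np.empty((ni, nj + 1))
    fy[:, 1:-1] = (1.0 - mesh.wy) * phi[:, :-1] + mesh.wy * phi[:, 1:]
    if wall_value is None:
        fy[:, 0] = phi[:, 0]
        fy[:, -1] = phi[:, -1]
    else:
        fy[:, -1] = wall_value
        fy[:, 0] = wall_value if mesh.mode == "planar" else phi[:, 0]

    gx = np.zeros((ni, nj))
    gy = np.zeros((ni, nj))
    for arr, A, ax in ((fx, mesh.Ax, 0), (fy, mesh.Ay, 1)):
        if ax == 0:
            dphi_hi, dphi_lo = arr[1:] - phi, arr[:-1] - phi
            gx += dphi_hi * A[1:, :, 0] - dphi_lo * A[:-1, :, 0]
            gy += dphi_hi * A[1:, :, 1] - dphi_lo * A[:-1, :, 1]
        else:
            dphi_hi, dphi_lo = arr[:, 1:] - phi, arr[:, :-1] - phi
            gx += dphi_hi * A[:, 1:, 0] - dphi_lo * A[:, :-1, 0]
            gy += dphi_hi * A[:, 1:, 1] - dphi_lo * A[:, :-1, 1]
    return gx / mesh.vol, gy / mesh.vol


def _bj_limiter(mesh, phi, gx, gy):
    """Barth-Jespersen slope limiter, one factor per cell."""
    ni, nj = phi.shape
    big = np.full_like(phi, -np.inf)
    small = np.full_like(phi, np.inf)
    pmax, pmin = big.copy(), small.copy()
    pmax[:-1] = np.maximum(pmax[:-1], phi[1:])
    pmin[:-1] = np.minimum(pmin[:-1], phi[1:])
    pmax[1:] = np.maximum(pmax[1:], phi[:-1])
    pmin[1:] = np.minimum(pmin[1:], phi[:-1])
    pmax[:, :-1] = np.maximum(pmax[:, :-1], phi[:, 1:])
    pmin[:, :-1] = np.minimum(pmin[:, :-1], phi[:, 1:])
    pmax[:, 1:] = np.maximum(pmax[:, 1:], phi[:, :-1])
    pmin[:, 1:] = np.minimum(pmin[:, 1:], phi[:, :-1])
    dmax = np.maximum(pmax - phi, 0.0)
    dmin = np.minimum(pmin - phi, 0.0)

    psi = np.ones_like(phi)
    cc = np.stack([mesh.xc, mesh.yc], axis=-1)
    eps0 = 1e-300
    for fmid, sl in (
        (mesh.fmid_x[:-1], np.s_[:, :]),  # west faces
        (mesh.fmid_x[1:], np.s_[:, :]),  # east faces
        (mesh.fmid_y[:, :-1], np.s_[:, :]),  # south faces
        (mesh.fmid_y[:, 1:], np.s_[:, :]),  # north faces
    ):
        r = fmid - cc
        d = gx * r[..., 0] + gy * r[..., 1]
        lim = np.where(
            d > 0, np.minimum(1.0, dmax / (d + eps0)), np.minimum(1.0, dmin / (d - eps0))
        )
        lim = np.where(np.abs(d) < 1e-300, 1.0, lim)
        psi = np.minimum(psi, lim)
    return np.clip(psi, 0.0, 1.0)


def _assemble_scalar(
    mesh,
    Fx,
    Fy,
    gam,
    phi,
    grad,
    inlet_value,
    second_order: bool,
    wall_coeff=None,
    name: str = "",
) -> LinearSystem:
    """Convection-diffusion coefficients for one transport equation.

    ``wall_coeff``: per-column implicit wall conductance (N, and S in
    planar mode) toward a zero wall value (used for momentum); None
    means zero-flux walls (scalars).  Inlet is Dirichlet at
    ``inlet_value``; outlet is zero-gradient (convective outflow
    implicit).  Returns the unrelaxed system with source terms still to
    be added by the caller.
    """
    ni, nj = phi.shape
    aP = np.zeros((ni, nj))
    aE = np.zeros((ni, nj))
    aW = np.zeros((ni, nj))
    aN = np.zeros((ni, nj))
    aS = np.zeros((ni, nj))
    b = np.zeros((ni, nj))
    gx, gy = grad

    # internal i-faces
    gam_f = (1.0 - mesh.wx) * gam[:-1] + mesh.wx * gam[1:]
    D = gam_f * mesh.gf_x
    m = Fx[1:-1]
    aE[:-1] -= D + np.maximum(-m, 0.0)
    aW[1:] -= D + np.maximum(m, 0.0)
    aP[:-1] += D + np.maximum(m, 0.0)
    aP[1:] += D + np.maximum(-m, 0.0)
    # non-orthogonal diffusion correction (explicit)
    gfx = (1.0 - mesh.wx)[..., None] * np.stack([gx[:-1], gy[:-1]], -1) + mesh.wx[
        ..., None
    ] * np.stack([gx[1:], gy[1:]], -1)
    tvec = mesh.Ax[1:-1] - mesh.gf_x[..., None] * mesh.dvec_x
    corr = gam_f * np.sum(gfx * tvec, axis=-1)
    b[:-1] += corr
    b[1:] -= corr
    if second_order:
        psi = _bj_limiter(mesh, phi, gx, gy)
        cc = np.stack([mesh.xc, mesh.yc], axis=-1)
        rup = mesh.fmid_x[1:-1] - np.where((m > 0)[..., None], cc[:-1], cc[1:])
        gup = np.where(
            (m > 0)[..., None],
            (psi[:-1] * np.stack([gx[:-1], gy[:-1]], -1).transpose(2, 0, 1)).transpose(1, 2, 0),
            (psi[1:] * np.stack([gx[1:], gy[1:]], -1).transpose(2, 0, 1)).transpose(1, 2, 0),
        )
        dc = m * np.sum(gup * rup, axis=-1)
        b[:-1] -= dc
        b[1:] += dc

    # internal j-faces
    gam_f = (1.0 - mesh.wy) * gam[:, :-1] + mesh.wy * gam[:, 1:]
    D = gam_f * mesh.gf_y
    m = Fy[:, 1:-1]
    aN[:, :-1] -= D + np.maximum(-m, 0.0)
    aS[:, 1:] -= D + np.maximum(m, 0.0)
    aP[:, :-1] += D + np.maximum(m, 0.0)
    aP[:, 1:] += D + np.maximum(-m, 0.0)
    gfy = (1.0 - mesh.wy)[..., None] * np.stack([gx[:, :-1], gy[:, :-1]], -1) + mesh.wy[
        ..., None
    ] * np.stack([gx[:, 1:], gy[:, 1:]], -1)
    tvec = mesh.Ay[:, 1:-1] - mesh.gf_y[..., None] * mesh.dvec_y
    corr = gam_f * np.sum(gfy * tvec, axis=-1)
    b[:, :-1] += corr
    b[:, 1:] -= corr
    if second_order:
        cc = np.stack([mesh.xc, mesh.yc], axis=-1)
        rup = mesh.fmid_y[:, 1:-1] - np.where((m > 0)[..., None], cc[:, :-1], cc[:, 1:])
        gup = np.where(
            (m > 0)[..., None],
            (psi[:, :-1] * np.stack([gx[:, :-1], gy[:, :-1]], -1).transpose(2, 0, 1)).transpose(
                1, 2, 0
            ),
            (psi[:, 1:] * np.stack([gx[:, 1:], gy[:, 1:]], -1).transpose(2, 0, 1)).transpose(
                1, 2, 0
            ),
        )
        dc = m * np.sum(gup * rup, axis=-1)
        b[:, :-1] -= dc
        b[:, 1:] += dc

    # inlet: Dirichlet (convective inflow + diffusion to the boundary value)
    m_in = Fx[0]  # > 0 into the domain
    D_in = gam[0] * mesh.gf_in
    aP[0] += D_in + np.maximum(-m_in, 0.0)
    b[0] += (D_in + np.maximum(m_in, 0.0)) * inlet_value
    # outlet: zero-gradient, convective outflow implicit
    m_out = Fx[-1]
    aP[-1] += np.maximum(m_out, 0.0)
    b[-1] += np.maximum(-m_out, 0.0) * phi[-1]  # re-entry guard, explicit

    # walls
    if wall_coeff is not None:
        cN, cS = wall_coeff
        aP[:, -1] += cN
        if cS is not None:
            aP[:, 0] += cS
    return LinearSystem(aP, aE, aW, aN, aS, b, name)


def assemble_transport_equation(
    field_name: str,
    mesh: StructuredMesh,
    flow: FlowField,
    fluid: FluidProperties,
    settings: SolverSettings,
    inlet: InletSpec | None = None,
) -> LinearSystem:
    """Assemble the (unrelaxed) linear system for one conserved variable.

    Exposed for verification; the iteration loop uses the same kernels.
    ``field_name`` is one of ``u``, ``v``, ``k``, ``eps``.
    """
    if field_name not in ("u", "v", "k", "eps"):
        raise ValidationError(f"unknown field {field_name!r}")
    mu_eff = fluid.dynamic_viscosity + flow.mu_t
    second = settings.convection_scheme == "second-order-upwind-limited"
    if inlet is None:
        nj = mesh.nj
        zeros = np.zeros(nj)
        inlet = InletSpec("uniform_TI", zeros, zeros, zeros, zeros + EPS_FLOOR, 1.0)
    wall = _wall_model(mesh, flow, fluid, settings.turbulence_enabled)
    if field_name == "u":
        phi, bc, gam = flow.U, inlet.u, mu_eff
        grad = _green_gauss(mesh, phi, bc_in=inlet.u, wall_value=0.0)
        sys_ = _assemble_scalar(mesh, flow.Fx, flow.Fy, gam, phi, grad, bc, second,
                                wall_coeff=(wall["cN"], wall["cS"]), name="u")
    elif field_name == "v":
        phi, bc, gam = flow.V, inlet.v, mu_eff
        grad = _green_gauss(mesh, phi, bc_in=inlet.v, wall_value=0.0)
        sys_ = _assemble_scalar(mesh, flow.Fx, flow.Fy, gam, phi, grad, bc, second,
                                wall_coeff=(wall["cN"], wall["cS"]), name="v")
        if mesh.mode == "axisymmetric":
            sys_.aP += mu_eff * mesh.vol / np.maximum(mesh.yc, 1e-300) ** 2
    elif field_name == "k":
        gam = fluid.dynamic_viscosity + flow.mu_t / SIGMA_K
        phi, bc = flow.k, inlet.k
        grad = _green_gauss(mesh, phi, bc_in=inlet.k)
        sys_ = _assemble_scalar(mesh, flow.Fx, flow.Fy, gam, phi, grad, bc, second, name="k")
    else:
        gam = fluid.dynamic_viscosity + flow.mu_t / SIGMA_EPS
        phi, bc = flow.eps, inlet.eps
        grad = _green_gauss(mesh, phi, bc_in=inlet.eps)
        sys_ = _assemble_scalar(mesh, flow.Fx, flow.Fy, gam, phi, grad, bc, second, name="eps")
    if np.any(sys_.aP == 0.0):
        ij = np.argwhere(sys_.aP == 0.0)[0]
        raise NumericalFailureError(f"zero diagonal in {field_name} equation at cell {tuple(ij)}")
    return sys_


# ---------------------------------------------------------------------------
# wall treatment
# ---------------------------------------------------------------------------
def _wall_model(mesh: StructuredMesh, flow: FlowField, fluid: FluidProperties,
                turbulent: bool) -> dict:
    """Per-wall-column conductances and wall-cell k/eps source data.

    Turbulent: equilibrium wall functions — friction velocity from the
    wall-cell k, log-law shear above the sublayer crossover, linear
    below.  Laminar: plain one-sided diffusion to the no-slip wall.
    Returns conductances c (N per (m/s), i.e. tau_w * area / |u_p|).
    """
    mu, rho = fluid.dynamic_viscosity, fluid.density
    out = {}
    for side, jcell, dist, A in (
        ("N", -1, mesh.dist_wall_n, mesh.Ay[:, -1]),
        ("S", 0, mesh.dist_wall_s, mesh.Ay[:, 0]),
    ):
        if dist is None or (side == "S" and mesh.mode == "axisymmetric"):
            out[f"c{side}"] = None
            continue
        area = np.linalg.norm(A, axis=-1)
        if not turbulent:
            gf = mesh.gf_n if side == "N" else mesh.gf_s
            out[f"c{side}"] = mu * gf
            out[f"tau{side}"] = None
            continue
        kcell = np.maximum(flow.k[:, jcell], K_FLOOR)
        ustar = C_MU**0.25 * np.sqrt(kcell)
        yplus = rho * ustar * dist / mu
        up = np.hypot(flow.U[:, jcell], flow.V[:, jcell])
        loglaw = yplus > YPLUS_LAM
        c_unit = np.where(
            loglaw,
            rho * ustar * KAPPA / np.log(np.maximum(E_WALL * yplus, 1.0 + 1e-9)),
            mu / dist,
        )
        c = c_unit * area
        tau_w = c_unit * up  # wall shear stress magnitude
        # turbulent production vanishes in the viscous sublayer
        pk = np.where(loglaw, tau_w * ustar / (KAPPA * dist), 0.0)
        eps_wall = C_MU**0.75 * kcell**1.5 / (KAPPA * dist)
        out[f"c{side}"] = c
        out[f"tau{side}"] = tau_w
        out[f"pk{side}"] = pk
        out[f"eps{side}"] = eps_wall
        out[f"yplus{side}"] = yplus
    return out


def apply_wall_functions(mesh: StructuredMesh, flow: FlowField, fluid: FluidProperties) -> dict:
    """Public wall-function evaluation (shear, y+, wall-cell sources)."""
    return _wall_model(mesh, flow, fluid, turbulent=True)


def wall_law_uplus(yplus: float, kappa: float = KAPPA, E: float = E_WALL) -> float:
    """Dimensionless wall-law velocity: linear sublayer or log law."""
    if yplus <= YPLUS_LAM:
        return float(yplus)
    return float(np.log(E * yplus) / kappa)


# ---------------------------------------------------------------------------
# production term
# ---------------------------------------------------------------------------
def _production(mesh, flow, grad_u, grad_v, kato_launder: bool = False):
    """Turbulence production from the mean velocity gradients.

    Standard form P_k = mu_t * 2 S_ij S_ij, or the Kato-Launder variant
    P_k = mu_t * S * Omega (strain-rate times vorticity magnitude),
    which suppresses the spurious production of the Boussinesq closure
    in strongly accelerated, nearly irrotational regions such as the
    stenosis contraction while leaving genuine shear layers unchanged.
    """
    ux, uy = grad_u
    vx, vy = grad_v
    s2 = 2.0 * (ux**2 + vy**2) + (uy + vx) ** 2
    if mesh.mode == "axisymmetric":
        s2 = s2 + 2.0 * (flow.V / np.maximum(mesh.yc, 1e-300)) ** 2
    if kato_launder:
        return flow.mu_t * np.sqrt(s2) * np.abs(uy - vx)
    return flow.mu_t * s2


# ---------------------------------------------------------------------------
# main driver
# ---------------------------------------------------------------------------
def _initial_field(mesh, inlet, fluid, settings) -> FlowField:
    ni, nj = mesh.ni, mesh.nj
    area = np.linalg.norm(mesh.Ax[0], axis=-1)
    u0 = float(np.sum(inlet.u * area) / area.sum())
    k0 = max(float(np.sum(inlet.k * area) / area.sum()), K_FLOOR)
    e0 = max(float(np.sum(inlet.eps * area) / area.sum()), EPS_FLOOR)
    U = np.full((ni, nj), u0)
    V = np.zeros((ni, nj))
    p = np.zeros((ni, nj))
    k = np.full((ni, nj), k0)
    eps = np.full((ni, nj), e0)
    mu_t = compute_eddy_viscosity(k, eps, fluid) if settings.turbulence_enabled else np.zeros_like(k)
    flow = FlowField(U, V, p, k, eps, mu_t, np.zeros((ni + 1, nj)), np.zeros((ni, nj + 1)),
                     fluid)
    _update_face_fluxes_init(mesh, flow, inlet)
    return flow


def _inlet_mass_flux(mesh, inlet, fluid):
    A = mesh.Ax[0]
    return fluid.density * (inlet.u * A[:, 0] + inlet.v * A[:, 1])


def _update_face_fluxes_init(mesh, flow, inlet):
    rho = flow.fluid.density
    ubar = (1.0 - mesh.wx) * flow.U[:-1] + mesh.wx * flow.U[1:]
    vbar = (1.0 - mesh.wx) * flow.V[:-1] + mesh.wx * flow.V[1:]
    flow.Fx[1:-1] = rho * (ubar * mesh.Ax[1:-1, :, 0] + vbar * mesh.Ax[1:-1, :, 1])
    flow.Fx[0] = _inlet_mass_flux(mesh, inlet, flow.fluid)
    flow.Fx[-1] = rho * (flow.U[-1] * mesh.Ax[-1, :, 0] + flow.V[-1] * mesh.Ax[-1, :, 1])
    # scale outlet to balance
    tot_out = flow.Fx[-1].sum()
    if tot_out > 0:
        flow.Fx[-1] *= flow.Fx[0].sum() / tot_out
    flow.Fy[:] = 0.0
    ub = (1.0 - mesh.wy) * flow.U[:, :-1] + mesh.wy * flow.U[:, 1:]
    vb = (1.0 - mesh.wy) * flow.V[:, :-1] + mesh.wy * flow.V[:, 1:]
    flow.Fy[:, 1:-1] = rho * (ub * mesh.Ay[:, 1:-1, 0] + vb * mesh.Ay[:, 1:-1, 1])


def solve_steady_rans(
    mesh: StructuredMesh,
    inlet_spec: InletSpec,
    fluid: FluidProperties,
    settings: SolverSettings | None = None,
    initial: FlowField | None = None,
) -> tuple[FlowField, ConvergenceReport]:
    """Iterate SIMPLE to a steady solution.

    Returns the flow field and a convergence report with normalized
    residual histories for u, v, continuity (and k, eps when the
    turbulence model is active).  ``initial`` warm-starts the iteration
    from a previous solution on the same mesh.
    """
    settings = settings or SolverSettings()
    inlet = inlet_spec
    if len(inlet.u) != mesh.nj:
        raise ValidationError("inlet spec length does not match the mesh inlet face count")
    rho, mu = fluid.density, fluid.dynamic_viscosity
    turb = settings.turbulence_enabled
    second = settings.convection_scheme == "second-order-upwind-limited"

    flow = initial.copy() if initial is not None else _initial_field(mesh, inlet, fluid, settings)
    flow.Fx[0] = _inlet_mass_flux(mesh, inlet, fluid)
    m_in_total = float(flow.Fx[0].sum())
    if m_in_total <= 0:
        raise ValidationError("inlet mass flux must be positive")

    names = ["u", "v", "continuity"] + (["k", "eps"] if turb else [])
    hist = {n: [] for n in names}
    converged = False
    it = 0
    for it in range(1, settings.max_iterations + 1):
        grad_u = _green_gauss(mesh, flow.U, bc_in=inlet.u, wall_value=0.0)
        grad_v = _green_gauss(mesh, flow.V, bc_in=inlet.v, wall_value=0.0)
        grad_p = _green_gauss(mesh, flow.p, bc_out=np.zeros(mesh.nj))
        wall = _wall_model(mesh, flow, fluid, turb)
        mu_eff = mu + flow.mu_t

        # --- momentum ---------------------------------------------------
        su = _assemble_scalar(mesh, flow.Fx, flow.Fy, mu_eff, flow.U, grad_u, inlet.u,
                              second, wall_coeff=(wall["cN"], wall["cS"]), name="u")
        sv = _assemble_scalar(mesh, flow.Fx, flow.Fy, mu_eff, flow.V, grad_v, inlet.v,
                              second, wall_coeff=(wall["cN"], wall["cS"]), name="v")
        su.b += -grad_p[0] * mesh.vol
        sv.b += -grad_p[1] * mesh.vol
        if mesh.mode == "axisymmetric":
            sv.aP += mu_eff * mesh.vol / np.maximum(mesh.yc, 1e-300) ** 2
        ru = compute_residuals(su, flow.U)
        rv = compute_residuals(sv, flow.V)
        # implicit under-relaxation
        for s_, phi_old in ((su, flow.U), (sv, flow.V)):
            s_.b += (1.0 - settings.relax_u) / settings.relax_u * s_.aP * phi_old
            s_.aP = s_.aP / settings.relax_u
        same_matrix = mesh.mode == "planar"
        if same_matrix:
            lu = splu(su.matrix())
            Ustar = lu.solve(su.b.ravel()).reshape(flow.U.shape)
            Vstar = lu.solve(sv.b.ravel()).reshape(flow.V.shape)
        else:
            Ustar = su.solve()
            Vstar = sv.solve()
        dP = mesh.vol / su.aP  # relaxed diagonal

        # --- face fluxes (Rhie-Chow) ------------------------------------
        ubar = (1.0 - mesh.wx) * Ustar[:-1] + mesh.wx * Ustar[1:]
        vbar = (1.0 - mesh.wx) * Vstar[:-1] + mesh.wx * Vstar[1:]
        d_f = (1.0 - mesh.wx) * dP[:-1] + mesh.wx * dP[1:]
        gpx_f = (1.0 - mesh.wx) * grad_p[0][:-1] + mesh.wx * grad_p[0][1:]
        gpy_f = (1.0 - mesh.wx) * grad_p[1][:-1] + mesh.wx * grad_p[1][1:]
        dp_face = flow.p[1:] - flow.p[:-1]
        gp_dot_d = gpx_f * mesh.dvec_x[..., 0] + gpy_f * mesh.dvec_x[..., 1]
        Fx = np.empty_like(flow.Fx)
        Fx[1:-1] = rho * (
            ubar * mesh.Ax[1:-1, :, 0]
            + vbar * mesh.Ax[1:-1, :, 1]
            - d_f * mesh.gf_x * (dp_face - gp_dot_d)
        )
        Fx[0] = flow.Fx[0]
        # outlet: zero-gradient velocity + fixed-pressure Rhie-Chow term
        dxo = mesh.fmid_x[-1] - np.stack([mesh.xc[-1], mesh.yc[-1]], axis=-1)
        gp_dot_do = grad_p[0][-1] * dxo[:, 0] + grad_p[1][-1] * dxo[:, 1]
        Fx[-1] = rho * (
            Ustar[-1] * mesh.Ax[-1, :, 0]
            + Vstar[-1] * mesh.Ax[-1, :, 1]
            - dP[-1] * mesh.gf_out * (0.0 - flow.p[-1] - gp_dot_do)
        )
        Fy = np.zeros_like(flow.Fy)
        ub = (1.0 - mesh.wy) * Ustar[:, :-1] + mesh.wy * Ustar[:, 1:]
        vb = (1.0 - mesh.wy) * Vstar[:, :-1] + mesh.wy * Vstar[:, 1:]
        d_fy = (1.0 - mesh.wy) * dP[:, :-1] + mesh.wy * dP[:, 1:]
        gpx_fy = (1.0 - mesh.wy) * grad_p[0][:, :-1] + mesh.wy * grad_p[0][:, 1:]
        gpy_fy = (1.0 - mesh.wy) * grad_p[1][:, :-1] + mesh.wy * grad_p[1][:, 1:]
        dpy = flow.p[:, 1:] - flow.p[:, :-1]
        gp_dot_dy = gpx_fy * mesh.dvec_y[..., 0] + gpy_fy * mesh.dvec_y[..., 1]
        Fy[:, 1:-1] = rho * (
            ub * mesh.Ay[:, 1:-1, 0]
            + vb * mesh.Ay[:, 1:-1, 1]
            - d_fy * mesh.gf_y * (dpy - gp_dot_dy)
        )

        # --- pressure correction ----------------------------------------
        tE = rho * d_f * mesh.gf_x  # internal i-faces
        tN = rho * d_fy * mesh.gf_y
        t_out = rho * dP[-1] * mesh.gf_out
        aP = np.zeros_like(flow.p)
        aP[:-1] += tE
        aP[1:] += tE
        aP[:, :-1] += tN
        aP[:, 1:] += tN
        aP[-1] += t_out
        aE = np.zeros_like(aP)
        aW = np.zeros_like(aP)
        aN = np.zeros_like(aP)
        aS = np.zeros_like(aP)
        aE[:-1] = -tE
        aW[1:] = -tE
        aN[:, :-1] = -tN
        aS[:, 1:] = -tN
        div = (Fx[1:] - Fx[:-1]) + (Fy[:, 1:] - Fy[:, :-1])
        sp = LinearSystem(aP, aE, aW, aN, aS, -div, "p")
        rc = float(np.abs(div).sum() / m_in_total)
        pprime = sp.solve()

        # --- corrections -------------------------------------------------
        Fx[1:-1] += -tE * (pprime[1:] - pprime[:-1])
        Fx[-1] += t_out * pprime[-1]
        Fy[:, 1:-1] += -tN * (pprime[:, 1:] - pprime[:, :-1])
        gpp = _green_gauss(mesh, pprime, bc_out=np.zeros(mesh.nj))
        flow.U = Ustar - dP * gpp[0]
        flow.V = Vstar - dP * gpp[1]
        flow.p = flow.p + settings.relax_p * pprime
        flow.Fx, flow.Fy = Fx, Fy

        hist["u"].append(ru)
        hist["v"].append(rv)
        hist["continuity"].append(rc)

        # --- turbulence --------------------------------------------------
        if turb:
            pk = _production(mesh, flow, grad_u, grad_v, settings.kato_launder_production)
            pk = np.minimum(pk, 10.0 * rho * np.maximum(flow.eps, EPS_FLOOR))
            if wall["cN"] is not None and "pkN" in wall:
                pk[:, -1] = wall["pkN"]
            if wall["cS"] is not None and wall.get("pkS") is not None:
                pk[:, 0] = wall["pkS"]
            kguard = np.maximum(flow.k, K_FLOOR)

            gam_k = mu + flow.mu_t / SIGMA_K
            gk = _green_gauss(mesh, flow.k, bc_in=inlet.k)
            sk = _assemble_scalar(mesh, flow.Fx, flow.Fy, gam_k, flow.k, gk, inlet.k,
                                  second, name="k")
            sk.b += pk * mesh.vol
            sk.aP += rho * np.maximum(flow.eps, EPS_FLOOR) / kguard * mesh.vol
            rk = compute_residuals(sk, flow.k)
            sk.b += (1.0 - settings.relax_turb) / settings.relax_turb * sk.aP * flow.k
            sk.aP = sk.aP / settings.relax_turb
            knew = np.maximum(sk.solve(), 0.0)

            gam_e = mu + flow.mu_t / SIGMA_EPS
            ge = _green_gauss(mesh, flow.eps, bc_in=inlet.eps)
            se = _assemble_scalar(mesh, flow.Fx, flow.Fy, gam_e, flow.eps, ge, inlet.eps,
                                  second, name="eps")
            ts = np.maximum(flow.eps, EPS_FLOOR) / kguard  # eps/k time scale
            se.b += C_EPS1 * ts * pk * mesh.vol
            se.aP += C_EPS2 * rho * ts * mesh.vol
            # wall-adjacent cells: eps pinned to the equilibrium value
            fixed_scale = se.aP[:, -1].copy()
            if wall["cN"] is not None and "epsN" in wall:
                se.aE[:, -1] = se.aW[:, -1] = se.aN[:, -1] = se.aS[:, -1] = 0.0
                se.aP[:, -1] = fixed_scale
                se.b[:, -1] = fixed_scale * wall["epsN"]
            if wall["cS"] is not None and wall.get("epsS") is not None:
                fs = se.aP[:, 0].copy()
                se.aE[:, 0] = se.aW[:, 0] = se.aN[:, 0] = se.aS[:, 0] = 0.0
                se.aP[:, 0] = fs
                se.b[:, 0] = fs * wall["epsS"]
            re_ = compute_residuals(se, flow.eps)
            se.b += (1.0 - settings.relax_turb) / settings.relax_turb * se.aP * flow.eps
            se.aP = se.aP / settings.relax_turb
            enew = np.maximum(se.solve(), EPS_FLOOR)

            flow.k, flow.eps = knew, enew
            mt = compute_eddy_viscosity(flow.k, flow.eps, fluid)
            mt = np.minimum(mt, 1e5 * mu)
            flow.mu_t = (
                settings.relax_turb * mt + (1.0 - settings.relax_turb) * flow.mu_t
            )
            hist["k"].append(rk)
            hist["eps"].append(re_)

        # --- sanity & convergence ---------------------------------------
        if not (np.isfinite(flow.U).all() and np.isfinite(flow.p).all()
                and np.isfinite(flow.k).all()):
            raise NumericalFailureError(f"NaN/Inf in solver fields at iteration {it}")
        finals = [hist[n][-1] for n in names]
        if max(finals) > 1e8:
            report = ConvergenceReport({n: np.array(v) for n, v in hist.items()}, False, it,
                                       settings.residual_tolerance)
            raise NonConvergenceError(f"residual blow-up at iteration {it}", report)
        if it >= settings.min_iterations and max(finals) <= settings.residual_tolerance:
            converged = True
            break

    report = ConvergenceReport(
        {n: np.array(v) for n, v in hist.items()}, converged, it, settings.residual_tolerance
    )
    return flow, report
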