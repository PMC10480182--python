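"""Inlet boundary-condition construction.

Two families of inlet specification are supported, mirroring the study
design:

* ``uniform_TI`` — turbulence prescribed from a scalar turbulence
  intensity ``I``: k = (3/2)(U I)^2, with the dissipation rate set from
  a mixing length, eps = C_mu^(3/4) k^(3/2) / l.
* ``mapped_profile`` — velocity and turbulent-kinetic-energy profiles
  extracted from a converged solution on a cut plane of a larger domain
  and imposed directly on a sub-model inlet (the "measured TKE"
  condition); eps is rebuilt pointwise from the mapped k and the
  sub-model mixing length.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .geometry import CutPlane
from .mesh import StructuredMesh

#: Standard k-epsilon closure coefficient.
C_MU = 0.09


# ---------------------------------------------------------------------------
# scalar relations
# ---------------------------------------------------------------------------
def k_from_intensity(U, I):
    """Turbulent kinetic energy from mean velocity and turbulence intensity.

    k = (3/2) (U I)^2, the isotropic-fluctuation estimate used when a
    measured turbulence profile is unavailable.
    """
    U = np.asarray(U, dtype=float)
    I = np.asarray(I, dtype=float)
    if np.any(U < 0) or np.any(I < 0):
        raise ValidationError("k_from_intensity requires U >= 0 and I >= 0")
    return 1.5 * (U * I) ** 2


def intensity_from_reynolds(Re_dh):
    """Core turbulence intensity of fully developed duct flow.

    I = 0.16 Re^(-1/8), with Re based on the hydraulic diameter.
    """
    Re_dh = np.asarray(Re_dh, dtype=float)
    if np.any(Re_dh <= 0):
        raise ValidationError("intensity_from_reynolds requires Re > 0")
    return 0.16 * Re_dh ** (-0.125)


def eps_from_mixing_length(k, l):
    """Dissipation rate from TKE and a mixing length: C_mu^(3/4) k^(3/2) / l."""
    k = np.asarray(k, dtype=float)
    if l <= 0:
        raise ValidationError(f"mixing length must be positive, got {l}")
    if np.any(k < 0):
        raise ValidationError("eps_from_mixing_length requires k >= 0")
    return C_MU**0.75 * k**1.5 / l


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass
class InletSpec:
    """Per-inlet-face boundary values for a solver run.

    ``u``/``v`` are Cartesian velocity components at inlet face
    midpoints (for a straight channel ``u`` is the normal component),
    ``k`` the TKE and ``eps`` the dissipation rate; all arrays have one
    entry per inlet face.
    """

    mode: str  # "uniform_TI" | "mapped_profile"
    u: np.ndarray
    v: np.ndarray
    k: np.ndarray
    eps: np.ndarray
    mixing_length: float
    intensity: float | None = None

    def __post_init__(self):
        for name in ("u", "v", "k", "eps"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"inlet {name} contains non-finite values")
        if np.any(self.k < 0):
            raise ValidationError("inlet k must be non-negative")
        if self.mixing_length <= 0:
            raise ValidationError("mixing length must be positive")

    def copy(self) -> "InletSpec":
        return replace(
            self, u=self.u.copy(), v=self.v.copy(), k=self.k.copy(), eps=self.eps.copy()
        )


@dataclass
class PlaneProfile:
    """Velocity and TKE sampled along a cut plane of a converged solution.

    ``positions`` are transverse coordinates of the face midpoints on
    the cut column, ``u_normal`` the plane-normal velocity recovered
    from the face mass fluxes (so the profile's integrated mass flux
    equals the donor solution's flux at that station exactly),
    ``u_transverse`` the in-plane velocity component, and ``k`` the TKE.
    """

    station_label: str
    positions: np.ndarray
    u_normal: np.ndarray
    u_transverse: np.ndarray
    k: np.ndarray
    face_areas: np.ndarray
    mass_flux: float
    lumen_halfwidth: float

    def __post_init__(self):
        if not np.all(np.diff(self.positions) > 0):
            raise ValidationError("profile positions must be strictly increasing")
        n = len(self.positions)
        for name in ("u_normal", "u_transverse", "k", "face_areas"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"profile field {name} length mismatch")

    @property
    def area_mean_velocity(self) -> float:
        """Area-averaged normal velocity over the plane."""
        return float(np.sum(self.u_normal * self.face_areas) / np.sum(self.face_areas))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "position": self.positions,
                "u_normal": self.u_normal,
                "u_transverse": self.u_transverse,
                "k": self.k,
            }
        )


# ---------------------------------------------------------------------------
# extraction and mapping
# ---------------------------------------------------------------------------
def extract_plane_profile(flow, mesh: StructuredMesh, cut_plane: CutPlane) -> PlaneProfile:
    """Sample normal velocity, transverse velocity and TKE on a cut plane.

    The plane must coincide with a grid column.  The normal velocity is
    reconstructed from the converged face mass fluxes, which makes the
    profile's mass flux identical to the donor run's flux through that
    station; cell-centred quantities (transverse velocity, k) are
    distance-weighted averages of the two adjacent cell columns.
    """
    s_nodes = mesh.axial_nodes
    pos = cut_plane.axial_position
    if_ = int(np.argmin(np.abs(s_nodes - pos)))
    dxn = s_nodes[1] - s_nodes[0]
    if abs(s_nodes[if_] - pos) > 0.25 * dxn:
        raise ValidationError(
            f"cut plane at {pos} m does not coincide with a grid column"
        )
    A = mesh.Ax[if_]  # (nj, 2), pointing +i
    area = np.linalg.norm(A, axis=-1)
    mdot = flow.Fx[if_]  # mass flux through the column faces
    rho = flow.fluid.density
    u_normal = mdot / (rho * area)

    def _face_avg(field):
        if if_ == 0:
            return field[0].copy()
        if if_ == mesh.ni:
            return field[-1].copy()
        w = mesh.wx[if_ - 1]
        return (1.0 - w) * field[if_ - 1] + w * field[if_]

    v_t = _face_avg(flow.V)
    k = np.maximum(_face_avg(flow.k), 0.0)
    positions = mesh.fmid_x[if_, :, 1].copy()
    halfwidth = 0.5 * (mesh.Y[if_, -1] - mesh.Y[if_, 0])
    return PlaneProfile(
        station_label=cut_plane.station_label,
        positions=positions,
        u_normal=u_normal,
        u_transverse=v_t,
        k=k,
        face_areas=area,
        mass_flux=float(mdot.sum()),
        lumen_halfwidth=float(halfwidth),
    )


def map_profile_to_inlet(
    profile: PlaneProfile, submesh: StructuredMesh, mixing_length: float
) -> InletSpec:
    """Impose an extracted plane profile on a sub-model inlet.

    When the sub-model inlet faces coincide with the profile sample
    points (the default, node-coincident extraction) the mapping is an
    exact copy.  Otherwise values are linearly interpolated in the
    transverse coordinate and the normal velocity is rescaled by a
    single multiplicative factor so the mapped mass flux matches the
    profile's.
    """
    targets = submesh.fmid_x[0, :, 1]
    lo, hi = profile.positions[0], profile.positions[-1]
    span = profile.positions[-1] - profile.positions[0]
    tol = 1e-9 * max(span, 1.0)
    if targets[0] < lo - span * 0.6 or targets[-1] > hi + span * 0.6:
        raise ValidationError(
            "profile lumen does not span the sub-model inlet; extrapolation refused"
        )
    if len(targets) == len(profile.positions) and np.allclose(
        targets, profile.positions, rtol=0, atol=tol
    ):
        u = profile.u_normal.copy()
        v = profile.u_transverse.copy()
        k = profile.k.copy()
    else:
        u = np.interp(targets, profile.positions, profile.u_normal)
        v = np.interp(targets, profile.positions, profile.u_transverse)
        k = np.interp(targets, profile.positions, profile.k)
        area = np.linalg.norm(submesh.Ax[0], axis=-1)
        flux = np.sum(u * area)
        if flux != 0.0:
            u *= profile.mass_flux / flux
    k = np.maximum(k, 0.0)
    return InletSpec(
        mode="mapped_profile",
        u=u,
        v=v,
        k=k,
        eps=eps_from_mixing_length(k, mixing_length),
        mixing_length=mixing_length,
    )


def build_uniform_ti_inlet(
    U: float, I: float, mixing_length: float, submesh: StructuredMesh
) -> InletSpec:
    """Fully uniform inlet: plug velocity U with k = (3/2)(U I)^2."""
    if U <= 0:
        raise ValidationError(f"inlet velocity must be positive, got {U}")
    nj = submesh.nj
    k = float(k_from_intensity(U, I))
    kk = np.full(nj, k)
    return InletSpec(
        mode="uniform_TI",
        u=np.full(nj, float(U)),
        v=np.zeros(nj),
        k=kk,
        eps=eps_from_mixing_length(kk, mixing_length),
        mixing_length=mixing_length,
        intensity=float(I),
    )


def ti_inlet_from_profile(
    profile: PlaneProfile,
    I: float,
    mixing_length: float,
    submesh: StructuredMesh,
    uniform_velocity: bool = False,
) -> InletSpec:
    """Turbulence-intensity inlet for a sub-model cut plane.

    By default the velocity profile is mapped from the donor plane and
    only the turbulence quantities are replaced by the intensity
    estimate, k = (3/2)(|u| I)^2 with the *local* mean velocity — the
    way flow solvers implement the turbulent-intensity inlet — so that
    differences against the mapped-TKE runs are attributable to the
    turbulence boundary condition alone.  ``uniform_velocity=True``
    restores a fully uniform plug inlet at the profile's area-mean
    velocity (with the correspondingly constant k).
    """
    if uniform_velocity:
        return build_uniform_ti_inlet(
            abs(profile.area_mean_velocity), I, mixing_length, submesh
        )
    mapped = map_profile_to_inlet(profile, submesh, mixing_length)
    kk = np.asarray(k_from_intensity(np.hypot(mapped.u, mapped.v), I))
    return InletSpec(
        mode="local_TI",
        u=mapped.u,
        v=mapped.v,
        k=kk,
        eps=eps_from_mixing_length(kk, mixing_length),
        mixing_length=mixing_length,
        intensity=float(I),
    )


def inlet_from_k_profile(
    profile: PlaneProfile,
    k_profile: np.ndarray,
    mixing_length: float,
    submesh: StructuredMesh,
) -> InletSpec:
    """Mapped-velocity inlet with an externally supplied (degraded) k profile."""
    spec = map_profile_to_inlet(profile, submesh, mixing_length)
    k = np.maximum(np.asarray(k_profile, dtype=float), 0.0)
    if len(k) != submesh.nj:
        raise ValidationError("k profile length must match the inlet face count")
    spec.k = k
    spec.eps = eps_from_mixing_length(k, mixing_length)
    return spec
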