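"""Body-fitted structured meshing of the stenosis channel.

The grid is transfinite: axial node stations are uniform, transverse
nodes follow the wall contour with optional geometric clustering toward
the walls.  Two modes are supported:

* ``planar`` — a 2-D channel of unit depth; both j-boundaries are walls.
* ``axisymmetric`` — a straight pipe section in (x, r); the j=0 boundary
  is the axis of symmetry, the j=nj boundary the wall.  Face areas and
  cell volumes carry the full 2*pi revolution factor, so the inlet area
  of an unconstricted pipe is pi*(D/2)^2.

All finite-volume geometry (face area vectors, volumes, centroid
distances, non-orthogonal factors, wall distances) is precomputed here
so the solver is purely algebraic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MeshingError, ValidationError
from .geometry import CutPlane, StenosisGeometry

MODES = ("planar", "axisymmetric")


def _stretched_eta(nj: int, ratio: float, mode: str) -> np.ndarray:
    """Normalized transverse node distribution in [0, 1].

    Planar: symmetric two-sided geometric clustering toward both walls
    (nj must be even).  Axisymmetric: one-sided clustering toward the
    wall (eta=1); eta=0 is the axis.
    """
    if ratio < 1.0:
        raise ValidationError(f"wall_stretch_ratio must be >= 1, got {ratio}")
    if mode == "planar":
        if nj % 2:
            raise ValidationError("planar meshes need an even transverse cell count")
        m = nj // 2
        if ratio == 1.0:
            h = np.full(m, 0.5 / m)
        else:
            h0 = 0.5 * (ratio - 1.0) / (ratio**m - 1.0)
            h = h0 * ratio ** np.arange(m)
        lower = np.concatenate(([0.0], np.cumsum(h)))
        upper = 1.0 - lower[::-1][1:]
        eta = np.concatenate((lower, upper))
    else:
        if ratio == 1.0:
            h = np.full(nj, 1.0 / nj)
        else:
            h0 = (ratio - 1.0) / (ratio**nj - 1.0)
            h = h0 * ratio ** np.arange(nj)
        # heights measured from the wall inward; accumulate from the axis
        eta = np.concatenate(([0.0], np.cumsum(h[::-1])))
    eta[-1] = 1.0
    return eta


@dataclass
class StructuredMesh:
    """Structured quadrilateral grid with precomputed FV geometry.

    Index convention: cells are (ni, nj); i runs streamwise, j
    transverse.  i-faces (``Ax``) separate columns and point in +i;
    j-faces (``Ay``) separate rows and point in +j.  Axisymmetric
    quantities include the 2*pi revolution factor.
    """

    mode: str
    X: np.ndarray  # (ni+1, nj+1) node x
    Y: np.ndarray  # (ni+1, nj+1) node y (or radius)
    axial_nodes: np.ndarray  # (ni+1,) pre-bend axial station of each column
    geometry: StenosisGeometry | None = None

    # derived, filled by _finalize
    ni: int = field(init=False)
    nj: int = field(init=False)
    xc: np.ndarray = field(init=False)
    yc: np.ndarray = field(init=False)
    vol: np.ndarray = field(init=False)
    Ax: np.ndarray = field(init=False)  # (ni+1, nj, 2)
    Ay: np.ndarray = field(init=False)  # (ni, nj+1, 2)
    fmid_x: np.ndarray = field(init=False)  # i-face midpoints (ni+1, nj, 2)
    fmid_y: np.ndarray = field(init=False)  # j-face midpoints (ni, nj+1, 2)
    wall_distance: np.ndarray = field(init=False)
    axial_station: np.ndarray = field(init=False)  # (ni,) per cell column

    def __post_init__(self):
        self._finalize()

    # ------------------------------------------------------------------
    def _finalize(self):
        X, Y = self.X, self.Y
        self.ni = X.shape[0] - 1
        self.nj = X.shape[1] - 1
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}")

        # cell corner coordinates (counter-clockwise)
        x00, y00 = X[:-1, :-1], Y[:-1, :-1]
        x10, y10 = X[1:, :-1], Y[1:, :-1]
        x11, y11 = X[1:, 1:], Y[1:, 1:]
        x01, y01 = X[:-1, 1:], Y[:-1, 1:]

        # shoelace area and centroid of each quad
        xs = np.stack([x00, x10, x11, x01], axis=-1)
        ys = np.stack([y00, y10, y11, y01], axis=-1)
        xn = np.roll(xs, -1, axis=-1)
        yn = np.roll(ys, -1, axis=-1)
        cross = xs * yn - xn * ys
        area = 0.5 * np.sum(cross, axis=-1)
        if np.any(area <= 0):
            i, j = np.argwhere(area <= 0)[0]
            raise MeshingError(f"inverted or degenerate cell at (i={i}, j={j})")
        self.cell_area = area  # planar area, both modes
        self.xc = np.sum((xs + xn) * cross, axis=-1) / (6.0 * area)
        self.yc = np.sum((ys + yn) * cross, axis=-1) / (6.0 * area)

        # i-faces: between nodes (i, j) and (i, j+1), normal -> +i
        dx = X[:, 1:] - X[:, :-1]
        dy = Y[:, 1:] - Y[:, :-1]
        Ax = np.stack([dy, -dx], axis=-1)
        fx = np.stack([0.5 * (X[:, 1:] + X[:, :-1]), 0.5 * (Y[:, 1:] + Y[:, :-1])], axis=-1)
        # j-faces: between nodes (i, j) and (i+1, j), normal -> +j
        dx2 = X[1:, :] - X[:-1, :]
        dy2 = Y[1:, :] - Y[:-1, :]
        Ay = np.stack([-dy2, dx2], axis=-1)
        fy = np.stack([0.5 * (X[1:, :] + X[:-1, :]), 0.5 * (Y[1:, :] + Y[:-1, :])], axis=-1)

        if self.mode == "axisymmetric":
            two_pi = 2.0 * np.pi
            Ax = Ax * (two_pi * fx[..., 1:2])
            Ay = Ay * (two_pi * fy[..., 1:2])
            self.vol = two_pi * area * self.yc
        else:
            self.vol = area.copy()
        self.Ax, self.Ay = Ax, Ay
        self.fmid_x, self.fmid_y = fx, fy

        # centroid-to-centroid vectors across internal faces
        self.dvec_x = np.stack(
            [self.xc[1:, :] - self.xc[:-1, :], self.yc[1:, :] - self.yc[:-1, :]], axis=-1
        )  # (ni-1, nj, 2) across i-face i+1
        self.dvec_y = np.stack(
            [self.xc[:, 1:] - self.xc[:, :-1], self.yc[:, 1:] - self.yc[:, :-1]], axis=-1
        )  # (ni, nj-1, 2) across j-face j+1

        def _gf(A, d):
            # zero-area faces (the axis in axisymmetric mode) carry no flux
            num = np.sum(A * A, axis=-1)
            den = np.sum(A * d, axis=-1)
            out = np.zeros_like(num)
            np.divide(num, den, out=out, where=np.abs(den) > 0)
            return out

        # internal-face diffusion metric |A|^2 / (A . d) and interp weights
        self.gf_x = _gf(Ax[1:-1], self.dvec_x)
        self.gf_y = _gf(Ay[:, 1:-1], self.dvec_y)
        dPf = np.linalg.norm(
            fx[1:-1] - np.stack([self.xc[:-1], self.yc[:-1]], axis=-1), axis=-1
        )
        dfE = np.linalg.norm(
            fx[1:-1] - np.stack([self.xc[1:], self.yc[1:]], axis=-1), axis=-1
        )
        self.wx = dPf / (dPf + dfE)  # weight of the +i cell at i-faces
        dPf = np.linalg.norm(
            fy[:, 1:-1] - np.stack([self.xc[:, :-1], self.yc[:, :-1]], axis=-1), axis=-1
        )
        dfN = np.linalg.norm(
            fy[:, 1:-1] - np.stack([self.xc[:, 1:], self.yc[:, 1:]], axis=-1), axis=-1
        )
        self.wy = dPf / (dPf + dfN)

        # boundary-face metrics: centroid -> face midpoint.  Taken in
        # magnitude: stored area vectors point in +i/+j regardless of
        # which side of the domain the boundary lies on.
        cc0 = np.stack([self.xc, self.yc], axis=-1)
        self.gf_in = np.abs(_gf(Ax[0], fx[0] - cc0[0]))
        self.gf_out = np.abs(_gf(Ax[-1], fx[-1] - cc0[-1]))
        self.gf_s = np.abs(_gf(Ay[:, 0], fy[:, 0] - cc0[:, 0]))
        self.gf_n = np.abs(_gf(Ay[:, -1], fy[:, -1] - cc0[:, -1]))

        # wall-adjacent normal distances (perpendicular to the wall face)
        def _perp_dist(A, fmid, cc):
            n = A / np.linalg.norm(A, axis=-1, keepdims=True)
            return np.abs(np.sum((fmid - cc) * n, axis=-1))

        self.dist_wall_n = _perp_dist(Ay[:, -1], fy[:, -1], cc0[:, -1])
        if self.mode == "planar":
            self.dist_wall_s = _perp_dist(Ay[:, 0], fy[:, 0], cc0[:, 0])
        else:
            self.dist_wall_s = None

        self.wall_distance = self._compute_wall_distance()
        self.axial_station = 0.5 * (self.axial_nodes[:-1] + self.axial_nodes[1:])

    def _compute_wall_distance(self) -> np.ndarray:
        """Per-cell minimum distance to the wall polylines."""
        walls = [np.stack([self.X[:, -1], self.Y[:, -1]], axis=-1)]
        if self.mode == "planar":
            walls.append(np.stack([self.X[:, 0], self.Y[:, 0]], axis=-1))
        pts = np.stack([self.xc.ravel(), self.yc.ravel()], axis=-1)
        best = np.full(pts.shape[0], np.inf)
        for poly in walls:
            a, b = poly[:-1], poly[1:]
            ab = b - a  # (ns, 2)
            denom = np.sum(ab * ab, axis=-1)
            ap = pts[:, None, :] - a[None, :, :]
            t = np.clip(np.sum(ap * ab[None], axis=-1) / denom[None], 0.0, 1.0)
            proj = a[None] + t[..., None] * ab[None]
            d = np.linalg.norm(pts[:, None, :] - proj, axis=-1).min(axis=1)
            best = np.minimum(best, d)
        return best.reshape(self.ni, self.nj)

    # ------------------------------------------------------------------
    @property
    def inlet_area(self) -> float:
        """Total inlet boundary 'area' (width per unit depth, or annulus)."""
        return float(np.linalg.norm(self.Ax[0], axis=-1).sum())

    @property
    def total_volume(self) -> float:
        return float(self.vol.sum())

    def n_cells(self) -> int:
        return self.ni * self.nj


def generate_mesh(
    geometry: StenosisGeometry,
    ni: int,
    nj: int,
    wall_stretch_ratio: float = 1.0,
    mode: str = "planar",
) -> StructuredMesh:
    """Generate a body-fitted transfinite grid of the whole channel.

    ``ni`` axial cells (uniform station spacing) by ``nj`` transverse
    cells (geometrically clustered toward the walls with ratio
    ``wall_stretch_ratio``).
    """
    if ni < 8 or nj < 8:
        raise ValidationError(f"ni and nj must be >= 8, got ({ni}, {nj})")
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}")
    if mode == "axisymmetric" and geometry.bend_angle != 0.0:
        raise ValidationError("bend_angle requires planar mode")

    s = np.linspace(0.0, geometry.total_length, ni + 1)
    eta = _stretched_eta(nj, wall_stretch_ratio, mode)
    h = geometry.half_width(s)  # (ni+1,)
    if mode == "planar":
        tlo, thi = -h, h
    else:
        tlo, thi = np.zeros_like(h), h
    toff = tlo[:, None] + eta[None, :] * (thi - tlo)[:, None]  # transverse offsets

    if geometry.bend_angle == 0.0:
        X = np.repeat(s[:, None], nj + 1, axis=1)
        Y = toff
    else:
        # swept bend: the centreline direction ramps linearly over one
        # diameter downstream of the stenosis, then stays at bend_angle;
        # nodes are offset perpendicular to the local direction.
        theta = np.deg2rad(geometry.bend_angle)
        ramp = geometry.diameter_D
        phi = theta * np.clip((s - geometry.stenosis_end) / ramp, 0.0, 1.0)
        from scipy.integrate import cumulative_trapezoid

        cx = np.concatenate(([0.0], cumulative_trapezoid(np.cos(phi), s)))
        cy = np.concatenate(([0.0], cumulative_trapezoid(np.sin(phi), s)))
        X = cx[:, None] - toff * np.sin(phi)[:, None]
        Y = cy[:, None] + toff * np.cos(phi)[:, None]

    return StructuredMesh(mode=mode, X=X, Y=Y, axial_nodes=s, geometry=geometry)


def extract_submodel_mesh(full_mesh: StructuredMesh, cut_plane: CutPlane) -> StructuredMesh:
    """Truncate the full mesh at a cut plane, keeping stations >= the cut.

    The sub-model inlet coincides node-for-node with a grid column of the
    full mesh, so mapped boundary data need no geometric interpolation.
    """
    s_nodes = full_mesh.axial_nodes
    pos = cut_plane.axial_position
    if pos < 0 or pos >= s_nodes[-1] - 1e-12:
        raise ValidationError(
            f"cut plane at {pos} m lies outside the domain [0, {s_nodes[-1]}) m"
        )
    icut = int(np.argmin(np.abs(s_nodes - pos)))
    dxn = s_nodes[1] - s_nodes[0]
    if abs(s_nodes[icut] - pos) > 0.25 * dxn:
        raise ValidationError(
            f"cut plane {cut_plane.station_label} at {pos} m does not coincide "
            f"with a grid column (nearest {s_nodes[icut]} m); choose an axial "
            "cell count that places a node at the cut station"
        )
    return StructuredMesh(
        mode=full_mesh.mode,
        X=full_mesh.X[icut:].copy(),
        Y=full_mesh.Y[icut:].copy(),
        axial_nodes=s_nodes[icut:].copy(),
        geometry=full_mesh.geometry,
    )
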