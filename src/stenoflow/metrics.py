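"""Error metrics between sub-model and ground-truth solutions.

Fields are compared on a fixed region of interest (ROI) downstream of
the sub-model inlet: a deterministic lattice of sample points spanning
the full lumen, at which both solutions are interpolated.  Summary
statistics are the mean absolute error (MAE), the maximum absolute
error, and the MAE expressed as a percentage of the ground-truth field
maximum over the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LinearNDInterpolator

from .errors import ValidationError
from .mesh import StructuredMesh


@dataclass(frozen=True)
class ComparisonROI:
    """Axial extent (m, relative to the sub-model inlet) and lattice size."""

    start_offset: float  # downstream standoff from the sub-model inlet
    end_offset: float
    n_axial: int = 64
    n_transverse: int = 32

    def __post_init__(self):
        if self.end_offset <= self.start_offset:
            raise ValidationError("ROI end must lie downstream of its start")
        if self.n_axial < 2 or self.n_transverse < 2:
            raise ValidationError("ROI lattice needs at least 2x2 points")


def default_roi(diameter_D: float) -> ComparisonROI:
    """Default ROI: 0.1D to 4D downstream of the sub-model inlet.

    The 0.1D standoff keeps inlet-plane boundary artifacts out of the
    comparison.
    """
    return ComparisonROI(0.1 * diameter_D, 4.0 * diameter_D)


@dataclass
class ErrorSummary:
    mae_velocity: float
    mae_tke: float
    max_err_velocity: float
    max_err_tke: float
    mae_velocity_pct_of_max: float
    mae_tke_pct_of_max: float
    n: int
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "mae_velocity": self.mae_velocity,
            "mae_tke": self.mae_tke,
            "max_err_velocity": self.max_err_velocity,
            "max_err_tke": self.max_err_tke,
            "mae_velocity_pct_of_max": self.mae_velocity_pct_of_max,
            "mae_tke_pct_of_max": self.mae_tke_pct_of_max,
            "n": self.n,
        }


# ---------------------------------------------------------------------------
def mae(values_sub, values_ori) -> float:
    """Mean absolute error between matched sample lists."""
    a = np.asarray(values_sub, dtype=float)
    b = np.asarray(values_ori, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValidationError("mae requires equal-length, non-empty inputs")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("mae requires finite inputs")
    return float(np.mean(np.abs(a - b)))


def max_abs_error(values_sub, values_ori) -> float:
    """Maximum absolute error between matched sample lists."""
    a = np.asarray(values_sub, dtype=float)
    b = np.asarray(values_ori, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValidationError("max_abs_error requires equal-length, non-empty inputs")
    return float(np.max(np.abs(a - b)))


# ---------------------------------------------------------------------------
def _roi_points(submesh: StructuredMesh, roi: ComparisonROI) -> np.ndarray:
    """Deterministic ROI sample lattice in physical coordinates.

    Axial stations are spaced uniformly over the ROI extent; at each
    station the transverse points span the local lumen wall-to-wall.
    """
    s0 = submesh.axial_nodes[0]
    geom = submesh.geometry
    s = np.linspace(s0 + roi.start_offset, s0 + roi.end_offset, roi.n_axial)
    if s[-1] > submesh.axial_nodes[-1] + 1e-12:
        raise ValidationError("ROI extends beyond the sub-model outlet")
    eta = np.linspace(0.0, 1.0, roi.n_transverse)
    h = geom.half_width(s)
    if submesh.mode == "planar":
        ylo, yhi = -h, h
    else:
        ylo, yhi = np.zeros_like(h), h
    S, ETA = np.meshgrid(s, eta, indexing="ij")
    Yp = ylo[:, None] + ETA * (yhi - ylo)[:, None]
    return np.stack([S.ravel(), Yp.ravel()], axis=-1)


def sample_field_on_roi(
    flow,
    mesh: StructuredMesh,
    roi: ComparisonROI,
    field: str = "velocity",
    points: np.ndarray | None = None,
) -> np.ndarray:
    """Interpolate a cell-centred field at the ROI lattice points.

    Piecewise-linear interpolation over cell centres augmented with
    boundary face midpoints carrying the boundary values (no-slip walls
    for velocity, zero-gradient for k), so every in-lumen point is
    inside the interpolation hull.  ``points`` overrides the lattice
    (used to sample two different meshes at identical physical points);
    by default the ROI is anchored at this mesh's own inlet.
    """
    if field == "velocity":
        values = flow.velocity_magnitude()
        wall_values = 0.0
    elif field == "tke":
        values = flow.k
        wall_values = None  # zero-gradient
    elif field == "pressure":
        values = flow.p
        wall_values = None
    else:
        raise ValidationError(f"unknown comparison field {field!r}")

    pts = [np.stack([mesh.xc.ravel(), mesh.yc.ravel()], axis=-1)]
    vals = [values.ravel()]
    # north wall faces
    pts.append(mesh.fmid_y[:, -1])
    vals.append(np.full(mesh.ni, wall_values) if wall_values is not None else values[:, -1])
    # south boundary (wall in planar mode, axis in axisymmetric mode)
    pts.append(mesh.fmid_y[:, 0])
    if mesh.mode == "planar" and wall_values is not None:
        vals.append(np.full(mesh.ni, wall_values))
    else:
        vals.append(values[:, 0])
    # inlet / outlet columns (zero-gradient extension)
    pts.append(mesh.fmid_x[0])
    vals.append(values[0])
    pts.append(mesh.fmid_x[-1])
    vals.append(values[-1])

    interp = LinearNDInterpolator(np.concatenate(pts), np.concatenate(vals))
    targets = _roi_points(mesh, roi) if points is None else points
    out = interp(targets)
    if np.any(np.isnan(out)):
        # points marginally outside the hull from round-off: nearest fill
        from scipy.interpolate import NearestNDInterpolator

        nearest = NearestNDInterpolator(np.concatenate(pts), np.concatenate(vals))
        bad = np.isnan(out)
        out[bad] = nearest(targets[bad])
    return out


def summarize_errors(
    flow_sub,
    flow_ori,
    submesh: StructuredMesh,
    orimesh: StructuredMesh,
    roi: ComparisonROI,
) -> ErrorSummary:
    """MAE / max-error summary of a sub-model run against the ground truth.

    Velocity magnitude and TKE are sampled at the identical ROI lattice
    on both meshes; percentages are normalized by the ground-truth field
    maximum over the ROI.
    """
    out = {}
    n = roi.n_axial * roi.n_transverse
    pts = _roi_points(submesh, roi)  # anchored at the sub-model inlet for both
    for name, key in (("velocity", "velocity"), ("tke", "tke")):
        vs = sample_field_on_roi(flow_sub, submesh, roi, key, points=pts)
        vo = sample_field_on_roi(flow_ori, orimesh, roi, key, points=pts)
        out[f"mae_{name}"] = mae(vs, vo)
        out[f"max_err_{name}"] = max_abs_error(vs, vo)
        ref = float(np.max(np.abs(vo)))
        out[f"mae_{name}_pct_of_max"] = 100.0 * out[f"mae_{name}"] / ref if ref > 0 else 0.0
    return ErrorSummary(
        mae_velocity=out["mae_velocity"],
        mae_tke=out["mae_tke"],
        max_err_velocity=out["max_err_velocity"],
        max_err_tke=out["max_err_tke"],
        mae_velocity_pct_of_max=out["mae_velocity_pct_of_max"],
        mae_tke_pct_of_max=out["mae_tke_pct_of_max"],
        n=n,
    )
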