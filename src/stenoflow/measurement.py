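"""Synthetic 4D-flow-MRI-like degradation of TKE boundary data.

A converged TKE profile on an inlet plane is degraded in two stages
that emulate the dominant artifacts of intravoxel turbulence mapping:

1. **Voxel sampling** — the lumen is tiled with voxels whose edge is a
   fixed fraction of the (unconstricted) lumen diameter; each voxel
   records the average of the profile over its in-lumen extent
   (intravoxel averaging).
2. **Additive Gaussian noise** — zero-mean, with standard deviation
   sigma = max(TKE)/SNR, i.e. the signal-to-noise ratio is defined on
   the peak TKE of the sampled map.  Negative noisy values are clipped
   to zero (TKE is non-negative); the clipped count is recorded.

The degraded map is then interpolated back onto the sub-model inlet
faces to serve as the measured-TKE boundary condition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .boundary import PlaneProfile
from .errors import ValidationError
from .mesh import StructuredMesh


@dataclass
class TKEMap:
    """Voxel-sampled (optionally noisy) TKE values on an inlet plane."""

    voxel_centers: np.ndarray  # transverse positions (m)
    voxel_size_fraction: float  # voxel edge / lumen diameter
    k_values: np.ndarray  # per-voxel TKE (m^2/s^2)
    snr: float = np.inf
    seed: int | None = None
    n_clipped: int = 0

    def __post_init__(self):
        self.voxel_centers = np.asarray(self.voxel_centers, dtype=float)
        self.k_values = np.asarray(self.k_values, dtype=float)
        if not 0 < self.voxel_size_fraction <= 1:
            raise ValidationError("voxel_size_fraction must lie in (0, 1]")
        if len(self.voxel_centers) != len(self.k_values):
            raise ValidationError("voxel centres / values length mismatch")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"voxel_center": self.voxel_centers, "k": self.k_values})


def voxel_sample(
    profile: PlaneProfile, voxel_size_fraction: float, lumen_diameter: float
) -> TKEMap:
    """Tile the plane's lumen with voxels and record voxel-average TKE.

    ``lumen_diameter`` is the reference diameter the voxel fraction is
    expressed against (the unconstricted diameter D of the vessel, as
    the measurement resolution is a scanner property, not a property of
    the cut plane).  Partial edge voxels average over their in-lumen
    portion only.
    """
    if not 0 < voxel_size_fraction <= 1:
        raise ValidationError("voxel_size_fraction must lie in (0, 1]")
    edge = voxel_size_fraction * lumen_diameter
    lo = profile.positions[0] - 0.5 * (profile.positions[1] - profile.positions[0])
    hi = profile.positions[-1] + 0.5 * (profile.positions[-1] - profile.positions[-2])
    span = hi - lo
    n_vox = max(int(np.ceil(span / edge - 1e-9)), 1)
    # centre the voxel grid on the lumen: the two edge voxels are equal
    # partial voxels, averaged over their in-lumen portion only
    start = lo - 0.5 * (n_vox * edge - span)
    edges = np.clip(start + edge * np.arange(n_vox + 1), lo, hi)
    edges[0], edges[-1] = lo, hi

    # dense trapezoidal evaluation of the piecewise-linear profile
    centers = np.empty(n_vox)
    values = np.empty(n_vox)
    for i in range(n_vox):
        a, b = edges[i], edges[i + 1]
        if b - a <= 0:
            a = max(hi - edge, lo)
            b = hi
        xs = np.linspace(a, b, 33)
        ys = np.interp(xs, profile.positions, profile.k)
        values[i] = np.trapezoid(ys, xs) / (b - a)
        centers[i] = 0.5 * (a + b)
    return TKEMap(centers, voxel_size_fraction, np.maximum(values, 0.0))


def add_noise(tke_map: TKEMap, snr: float, seed: int) -> TKEMap:
    """Add zero-mean Gaussian noise with sigma = max(TKE)/SNR, clip at 0.

    ``snr = inf`` returns the map unchanged.  Deterministic under a
    fixed seed.
    """
    if not snr > 0:
        raise ValidationError(f"snr must be positive (or inf), got {snr}")
    if np.isinf(snr):
        return replace(tke_map, snr=np.inf, seed=seed, k_values=tke_map.k_values.copy())
    sigma = float(np.max(tke_map.k_values)) / snr
    rng = np.random.default_rng(seed)
    noisy = tke_map.k_values + rng.normal(0.0, sigma, size=tke_map.k_values.shape)
    n_clipped = int(np.sum(noisy < 0))
    return replace(
        tke_map,
        k_values=np.maximum(noisy, 0.0),
        snr=float(snr),
        seed=seed,
        n_clipped=n_clipped,
    )


def reconstruct_inlet_k(tke_map: TKEMap, submesh: StructuredMesh) -> np.ndarray:
    """Interpolate a TKE map onto sub-model inlet face midpoints.

    Piecewise-linear in the transverse coordinate, held constant beyond
    the outermost voxel centres; clipped non-negative.  With native
    voxel spacing and no noise this is the identity up to interpolation
    error.
    """
    if len(tke_map.k_values) == 0:
        raise ValidationError("empty TKE map")
    targets = submesh.fmid_x[0, :, 1]
    if len(tke_map.k_values) == 1:
        return np.full(len(targets), max(float(tke_map.k_values[0]), 0.0))
    k = np.interp(targets, tke_map.voxel_centers, tke_map.k_values)
    return np.maximum(k, 0.0)


def degrade_profile_k(
    profile: PlaneProfile,
    voxel_size_fraction: float,
    snr: float,
    seed: int,
    lumen_diameter: float,
    submesh: StructuredMesh,
) -> tuple[np.ndarray, TKEMap]:
    """Full degradation pipeline: sample -> noise -> reconstruct."""
    m = voxel_sample(profile, voxel_size_fraction, lumen_diameter)
    m = add_noise(m, snr, seed)
    return reconstruct_inlet_k(m, submesh), m
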