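"""Parametric stenosis-channel geometry.

The channel is a straight duct of diameter ``D`` carrying a smooth,
symmetric constriction ("stenosis") whose throat occludes a configurable
fraction of the diameter.  Axial station ``s`` is measured in metres from
the inlet plane; the wall contour is returned as the local half-width
(planar mode) or radius (axisymmetric mode) as a function of ``s``.

Severity follows the clinical diameter convention: a severity of 0.5
means the lumen diameter at the throat is half the nominal diameter, so
the throat width is ``(1 - severity) * D``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, ValidationError

THROAT_PROFILES = ("cosine", "smooth-step")

#: Cut-plane labels used throughout the study, in downstream order.
CUT_STATIONS = ("apex", "0.5D", "1.0D")


@dataclass(frozen=True)
class StenosisGeometry:
    """Parametric description of the stenosed channel.

    Lengths ``inlet_run``, ``stenosis_length`` and ``outlet_run`` are in
    multiples of the diameter ``diameter_D`` (metres); ``bend_angle`` is
    an in-plane bend (degrees) applied rigidly downstream of the
    stenosis, 0 for a straight channel.
    """

    diameter_D: float
    severity: float = 0.5
    inlet_run: float = 6.0
    stenosis_length: float = 2.0
    outlet_run: float = 8.0
    bend_angle: float = 0.0
    throat_profile: str = "cosine"

    def __post_init__(self):
        if self.diameter_D <= 0:
            raise ValidationError(f"diameter_D must be positive, got {self.diameter_D}")
        if not 0.0 <= self.severity < 1.0:
            raise GeometryError(
                f"severity must lie in [0, 1); got {self.severity} "
                "(severity >= 1 closes the lumen)"
            )
        for name in ("inlet_run", "stenosis_length", "outlet_run"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive, got {getattr(self, name)}")
        if self.throat_profile not in THROAT_PROFILES:
            raise ValidationError(
                f"throat_profile must be one of {THROAT_PROFILES}, got {self.throat_profile!r}"
            )

    # -- derived stations (metres) -------------------------------------
    @property
    def stenosis_start(self) -> float:
        return self.inlet_run * self.diameter_D

    @property
    def stenosis_end(self) -> float:
        return (self.inlet_run + self.stenosis_length) * self.diameter_D

    @property
    def apex_station(self) -> float:
        """Axial position of the throat (mid-stenosis)."""
        return (self.inlet_run + 0.5 * self.stenosis_length) * self.diameter_D

    @property
    def total_length(self) -> float:
        return (self.inlet_run + self.stenosis_length + self.outlet_run) * self.diameter_D

    @property
    def throat_width(self) -> float:
        return (1.0 - self.severity) * self.diameter_D

    # -- wall contour ---------------------------------------------------
    def occlusion_fraction(self, s):
        """Bump shape b(s) in [0, 1]: 0 outside the stenosis, 1 at the apex.

        C1-continuous across the segment ends for both throat profiles.
        """
        s = np.asarray(s, dtype=float)
        t = (s - self.stenosis_start) / (self.stenosis_end - self.stenosis_start)
        t = np.clip(t, 0.0, 1.0)
        if self.throat_profile == "cosine":
            b = np.sin(np.pi * t) ** 2
        else:  # smooth-step up then mirrored down
            u = 1.0 - np.abs(2.0 * t - 1.0)  # 0 -> 1 -> 0, piecewise linear
            b = u * u * (3.0 - 2.0 * u)
        return b

    def half_width(self, s):
        """Local half-width (planar) / radius (axisymmetric) at station ``s``."""
        b = self.occlusion_fraction(s)
        return 0.5 * self.diameter_D * (1.0 - self.severity * b)

    def width(self, s):
        return 2.0 * self.half_width(s)

    def analytic_area(self) -> float:
        """Cross-section-integrated channel area (planar, per unit depth).

        Integral of width over length, via high-order quadrature of the
        wall-contour function; used as the mesh-area oracle.
        """
        from scipy.integrate import quad

        val, _ = quad(lambda s: float(self.width(s)), 0.0, self.total_length, limit=400)
        return val


@dataclass(frozen=True)
class CutPlane:
    """A transverse plane at which the full model is cut into a sub-model."""

    station_label: str
    axial_position: float
    transverse_samples: tuple = field(default=(), compare=False)


def build_geometry(
    diameter_D: float,
    severity: float,
    inlet_run: float = 6.0,
    stenosis_length: float = 2.0,
    outlet_run: float = 8.0,
    bend_angle: float = 0.0,
    throat_profile: str = "cosine",
) -> StenosisGeometry:
    """Validate parameters and return a :class:`StenosisGeometry`."""
    return StenosisGeometry(
        diameter_D=diameter_D,
        severity=severity,
        inlet_run=inlet_run,
        stenosis_length=stenosis_length,
        outlet_run=outlet_run,
        bend_angle=bend_angle,
        throat_profile=throat_profile,
    )


def make_cut_planes(geometry: StenosisGeometry) -> dict[str, CutPlane]:
    """The study's three cut planes: throat apex, 0.5D and 1.0D distal to it."""
    D = geometry.diameter_D
    apex = geometry.apex_station
    return {
        "apex": CutPlane("apex", apex),
        "0.5D": CutPlane("0.5D", apex + 0.5 * D),
        "1.0D": CutPlane("1.0D", apex + 1.0 * D),
    }
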