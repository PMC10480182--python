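"""Study configuration: one object drives the whole experiment matrix."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass
class StudyConfig:
    """Every knob of the boundary-condition sensitivity study.

    The defaults reproduce the reference experiment matrix: a 50%
    (diameter) stenosis in a D = 2 cm vessel at inlet velocity
    0.66 m/s (Re ~ 4000 for blood: rho = 1060 kg/m^3, mu = 3.5 cP),
    full-model inlet turbulence intensity 5% with mixing length
    0.0014 m, sub-model mixing length 0.000375 m; three cut planes
    (throat apex, +0.5D, +1.0D); TI levels {5, 10, 15}%; voxel sizes
    {1, 5, 10, 15}% of D; SNR levels {1, 5, 10, 30, 50}.
    """

    # geometry
    diameter_D: float = 0.02
    severity: float = 0.5
    inlet_run: float = 6.0
    stenosis_length: float = 2.0
    outlet_run: float = 8.0
    bend_angle: float = 0.0
    throat_profile: str = "cosine"
    mode: str = "axisymmetric"

    # fluid
    density: float = 1060.0
    dynamic_viscosity: float = 0.0035

    # mesh (cells_per_D must be even so the 0.5D cut lands on a node)
    cells_per_D: int = 6
    nj: int = 20
    wall_stretch_ratio: float = 1.15

    # solver
    residual_tolerance: float = 1.0e-4
    max_iterations: int = 4000
    relax_u: float = 0.7
    relax_p: float = 0.3
    relax_turb: float = 0.7
    convection_scheme: str = "second-order-upwind-limited"
    kato_launder_production: bool = True

    # inlet / study conditions
    inlet_velocity: float = 0.66
    full_model_intensity: float = 0.05
    full_model_mixing_length: float = 0.0014
    submodel_mixing_length: float = 0.000375
    cut_planes: tuple = ("apex", "0.5D", "1.0D")
    ti_levels: tuple = (0.05, 0.10, 0.15)
    ti_uniform_velocity: bool = False  # True: plug inlet for TI runs
    voxel_fractions: tuple = (0.01, 0.05, 0.10, 0.15)
    snr_levels: tuple = (1.0, 5.0, 10.0, 30.0, 50.0)
    replicates: int = 3
    root_seed: int = 20260919

    # comparison ROI (relative to the sub-model inlet, in diameters)
    roi_start_D: float = 0.1
    roi_end_D: float = 4.0
    roi_n_axial: int = 64
    roi_n_transverse: int = 32

    output_dir: str = "results"

    def __post_init__(self):
        if self.cells_per_D % 2 or self.cells_per_D < 2:
            raise ValidationError("cells_per_D must be an even integer >= 2")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        self.cut_planes = tuple(self.cut_planes)
        self.ti_levels = tuple(float(t) for t in self.ti_levels)
        self.voxel_fractions = tuple(float(v) for v in self.voxel_fractions)
        self.snr_levels = tuple(float(s) for s in self.snr_levels)

    # ------------------------------------------------------------------
    @property
    def ni(self) -> int:
        total_D = self.inlet_run + self.stenosis_length + self.outlet_run
        n = self.cells_per_D * total_D
        if abs(n - round(n)) > 1e-9:
            raise ValidationError("cells_per_D x total length must be an integer")
        return int(round(n))

    def scaled(self, scale: float) -> "StudyConfig":
        """Return a copy with the grid resolution multiplied by ``scale``
        (rounded to keep the cut planes on grid nodes)."""
        if scale <= 0:
            raise ValidationError("scale must be positive")
        cpd = max(2, 2 * round(self.cells_per_D * scale / 2))
        nj = max(8, 2 * round(self.nj * scale / 2))
        return replace(self, cells_per_D=cpd, nj=nj)

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("cut_planes", "ti_levels", "voxel_fractions", "snr_levels"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
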