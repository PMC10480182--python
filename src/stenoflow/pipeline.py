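"""Orchestration of the boundary-condition sensitivity study.

The study proceeds in four stages, all driven by one
:class:`~stenoflow.config.StudyConfig`:

1. **Ground truth** — solve the full stenosis model with the
   turbulence-intensity inlet and extract velocity/TKE profiles at the
   three cut planes.
2. **Mapping verification** — solve each sub-model with the exactly
   mapped velocity + TKE inlet and quantify the agreement with the full
   model over the ROI (mode ``mapped_exact``).
3. **Turbulence-intensity study** — 3 sub-models x TI levels with the
   intensity-based turbulence inlet (mode ``uniform_TI``).
4. **Degradation study** — 3 sub-models x voxel sizes x SNR levels
   (x replicate noise seeds): degrade each sub-model's own inlet-plane
   TKE through the measurement emulator, rebuild the inlet and re-solve
   (mode ``mapped_degraded``).

Every result row carries the configuration hash and the seed needed to
regenerate it exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boundary import (
    InletSpec,
    PlaneProfile,
    extract_plane_profile,
    inlet_from_k_profile,
    map_profile_to_inlet,
    ti_inlet_from_profile,
)
from .config import StudyConfig
from .errors import NonConvergenceError, StenoflowError
from .geometry import CUT_STATIONS, StenosisGeometry, build_geometry, make_cut_planes
from .measurement import add_noise, reconstruct_inlet_k, voxel_sample
from .mesh import StructuredMesh, extract_submodel_mesh, generate_mesh
from .metrics import ComparisonROI, summarize_errors
from .solver import FluidProperties, SolverSettings, solve_steady_rans

log = logging.getLogger("stenoflow")

#: Sub-model numbering follows the cut-plane order: 1 = apex, 2 = 0.5D, 3 = 1.0D.
MODEL_OF_STATION = {label: i + 1 for i, label in enumerate(CUT_STATIONS)}

RESULT_COLUMNS = [
    "model", "station", "mode", "ti", "voxel_fraction", "snr", "replicate", "seed",
    "mae_velocity", "mae_tke", "max_err_velocity", "max_err_tke",
    "mae_velocity_pct_of_max", "mae_tke_pct_of_max", "n",
    "converged", "iterations", "config_hash",
]


def fluid_from_config(config: StudyConfig) -> FluidProperties:
    return FluidProperties(config.density, config.dynamic_viscosity)


def solver_settings_from_config(config: StudyConfig) -> SolverSettings:
    return SolverSettings(
        relax_u=config.relax_u,
        relax_p=config.relax_p,
        relax_turb=config.relax_turb,
        max_iterations=config.max_iterations,
        residual_tolerance=config.residual_tolerance,
        convection_scheme=config.convection_scheme,
        kato_launder_production=config.kato_launder_production,
    )


def roi_from_config(config: StudyConfig) -> ComparisonROI:
    D = config.diameter_D
    return ComparisonROI(
        config.roi_start_D * D, config.roi_end_D * D,
        config.roi_n_axial, config.roi_n_transverse,
    )


def reynolds_number(config: StudyConfig) -> float:
    """Re = rho U D / mu on the unconstricted inlet diameter."""
    return (
        config.density * config.inlet_velocity * config.diameter_D
        / config.dynamic_viscosity
    )


@dataclass
class GroundTruth:
    """Converged full-model solution plus everything the studies reuse."""

    geometry: StenosisGeometry
    full_mesh: StructuredMesh
    flow: "object"
    report: "object"
    profiles: dict  # station label -> PlaneProfile
    submeshes: dict  # station label -> StructuredMesh
    mapped_specs: dict = field(default_factory=dict)
    mapped_flows: dict = field(default_factory=dict)  # warm-start cache
    config_hash: str = ""


# ---------------------------------------------------------------------------
def run_ground_truth(config: StudyConfig) -> GroundTruth:
    """Solve the full model and extract the three cut-plane profiles."""
    geom = build_geometry(
        config.diameter_D, config.severity, config.inlet_run,
        config.stenosis_length, config.outlet_run, config.bend_angle,
        config.throat_profile,
    )
    mesh = generate_mesh(geom, config.ni, config.nj, config.wall_stretch_ratio, config.mode)
    fluid = fluid_from_config(config)
    settings = solver_settings_from_config(config)
    from .boundary import build_uniform_ti_inlet

    inlet = build_uniform_ti_inlet(
        config.inlet_velocity, config.full_model_intensity,
        config.full_model_mixing_length, mesh,
    )
    log.info("ground truth: %s grid %dx%d", config.mode, config.ni, config.nj)
    flow, report = solve_steady_rans(mesh, inlet, fluid, settings)
    if not report.converged:
        raise NonConvergenceError(
            f"full model failed to converge in {report.iterations_used} iterations",
            report,
        )
    cps = make_cut_planes(geom)
    profiles, submeshes = {}, {}
    for label in config.cut_planes:
        profiles[label] = extract_plane_profile(flow, mesh, cps[label])
        submeshes[label] = extract_submodel_mesh(mesh, cps[label])
    return GroundTruth(
        geometry=geom, full_mesh=mesh, flow=flow, report=report,
        profiles=profiles, submeshes=submeshes, config_hash=config.config_hash(),
    )


def _solve_submodel(config, gt, label, inlet_spec, warm_start=None):
    fluid = fluid_from_config(config)
    settings = solver_settings_from_config(config)
    return solve_steady_rans(
        gt.submeshes[label], inlet_spec, fluid, settings, initial=warm_start
    )


def _row(config, gt, label, mode, flow, report, *, ti=np.nan, voxel=np.nan,
         snr=np.nan, replicate=-1, seed=-1):
    roi = roi_from_config(config)
    es = summarize_errors(flow, gt.flow, gt.submeshes[label], gt.full_mesh, roi)
    return {
        "model": MODEL_OF_STATION[label], "station": label, "mode": mode,
        "ti": ti, "voxel_fraction": voxel, "snr": snr,
        "replicate": replicate, "seed": seed,
        **es.as_dict(),
        "converged": bool(report.converged),
        "iterations": int(report.iterations_used),
        "config_hash": gt.config_hash,
    }


def run_baseline_mapping_verification(config: StudyConfig, gt: GroundTruth) -> pd.DataFrame:
    """Sub-models with exactly mapped velocity + TKE inlets (Table-1 analogue)."""
    rows = []
    for label in config.cut_planes:
        spec = map_profile_to_inlet(
            gt.profiles[label], gt.submeshes[label], config.submodel_mixing_length
        )
        flow, report = _solve_submodel(config, gt, label, spec)
        gt.mapped_specs[label] = spec
        gt.mapped_flows[label] = flow
        rows.append(_row(config, gt, label, "mapped_exact", flow, report))
        log.info("mapped_exact %s: maeK%%=%.2f", label, rows[-1]["mae_tke_pct_of_max"])
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _ensure_baseline(config, gt):
    if not gt.mapped_flows:
        run_baseline_mapping_verification(config, gt)


def run_ti_study(config: StudyConfig, gt: GroundTruth) -> pd.DataFrame:
    """Sub-models x turbulence-intensity levels (9 runs by default)."""
    _ensure_baseline(config, gt)
    rows = []
    for label in config.cut_planes:
        for I in config.ti_levels:
            spec = ti_inlet_from_profile(
                gt.profiles[label], I, config.submodel_mixing_length,
                gt.submeshes[label], uniform_velocity=config.ti_uniform_velocity,
            )
            try:
                flow, report = _solve_submodel(
                    config, gt, label, spec, warm_start=gt.mapped_flows.get(label)
                )
            except StenoflowError as exc:
                log.warning("TI run %s I=%.2f failed: %s", label, I, exc)
                rows.append(_failed_row(config, gt, label, "uniform_TI", ti=I))
                continue
            rows.append(_row(config, gt, label, "uniform_TI", flow, report, ti=I))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _failed_row(config, gt, label, mode, **kw):
    base = {c: np.nan for c in RESULT_COLUMNS}
    base.update({
        "model": MODEL_OF_STATION[label], "station": label, "mode": mode,
        "replicate": kw.pop("replicate", -1), "seed": kw.pop("seed", -1),
        "converged": False, "iterations": -1, "config_hash": gt.config_hash,
    })
    base.update(kw)
    return base


def replicate_seed(root_seed: int, model: int, i_voxel: int, rep: int) -> int:
    """Deterministic per-run noise seed, below 2^31.

    The seed is shared across SNR levels of the same (model, voxel,
    replicate) cell: the same noise realization is scaled to each SNR
    (paired / common-random-numbers design), so SNR comparisons are not
    masked by realization-to-realization scatter.  Voxel sizes get
    independent realizations (their voxel counts differ).
    """
    ss = np.random.SeedSequence([int(root_seed), model, i_voxel, rep])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def sampling_profile(profile: PlaneProfile, mode: str) -> PlaneProfile:
    """Profile as the scanner sees the plane: a line across the lumen.

    In axisymmetric mode the solved profile spans [0, R]; the measured
    line crosses the full diameter, so the profile is mirrored about the
    axis before voxel tiling (each side is then degraded by independent
    voxel noise, as separate pixels are).
    """
    if mode == "planar":
        return profile
    pos = np.concatenate([-profile.positions[::-1], profile.positions])
    mirr = lambda a: np.concatenate([a[::-1], a])  # noqa: E731
    return PlaneProfile(
        station_label=profile.station_label,
        positions=pos,
        u_normal=mirr(profile.u_normal),
        u_transverse=mirr(profile.u_transverse),
        k=mirr(profile.k),
        face_areas=mirr(profile.face_areas),
        mass_flux=profile.mass_flux,
        lumen_halfwidth=profile.lumen_halfwidth,
    )


def run_degradation_study(config: StudyConfig, gt: GroundTruth) -> pd.DataFrame:
    """Sub-models x voxel sizes x SNR levels x replicates.

    Each sub-model degrades its own inlet plane: the TKE profile is
    voxel-sampled at the given fraction of the lumen diameter, Gaussian
    noise at the given SNR is added, and the inlet k is rebuilt from the
    degraded map (velocity passes through undegraded).
    """
    _ensure_baseline(config, gt)
    rows = []
    D = config.diameter_D
    for label in config.cut_planes:
        model = MODEL_OF_STATION[label]
        line = sampling_profile(gt.profiles[label], config.mode)
        submesh = gt.submeshes[label]
        for iv, voxel in enumerate(config.voxel_fractions):
            sampled = voxel_sample(line, voxel, D)
            for snr in config.snr_levels:
                for rep in range(config.replicates):
                    seed = replicate_seed(config.root_seed, model, iv, rep)
                    noisy = add_noise(sampled, snr, seed)
                    k_inlet = reconstruct_inlet_k(noisy, submesh)
                    spec = inlet_from_k_profile(
                        gt.profiles[label], k_inlet,
                        config.submodel_mixing_length, submesh,
                    )
                    try:
                        flow, report = _solve_submodel(
                            config, gt, label, spec,
                            warm_start=gt.mapped_flows.get(label),
                        )
                    except StenoflowError as exc:
                        log.warning(
                            "degradation run m%d v=%.2f snr=%g rep=%d failed: %s",
                            model, voxel, snr, rep, exc,
                        )
                        rows.append(_failed_row(
                            config, gt, label, "mapped_degraded",
                            voxel_fraction=voxel, snr=snr, replicate=rep, seed=seed,
                        ))
                        continue
                    rows.append(_row(
                        config, gt, label, "mapped_degraded", flow, report,
                        voxel=voxel, snr=snr, replicate=rep, seed=seed,
                    ))
        log.info("degradation study: model %d done", model)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


# ---------------------------------------------------------------------------
def compare_ti_vs_mapping(study_result: pd.DataFrame, ti_reference: float = 0.05
                          ) -> pd.DataFrame:
    """Per (model, voxel, snr): does the degraded-mapped run beat the TI run?

    Flags compare the median-over-replicates degraded MAE against the
    TI-``ti_reference`` MAE of the same sub-model, separately for
    velocity and TKE.  Missing cells are flagged with NaN.
    """
    ti = study_result[
        (study_result["mode"] == "uniform_TI")
        & np.isclose(study_result["ti"].astype(float), ti_reference)
    ].set_index("model")
    deg = study_result[study_result["mode"] == "mapped_degraded"]
    rows = []
    for (model, voxel, snr), grp in deg.groupby(["model", "voxel_fraction", "snr"]):
        ok = grp["converged"].fillna(False).astype(bool)
        med_v = grp.loc[ok, "mae_velocity"].median()
        med_k = grp.loc[ok, "mae_tke"].median()
        if model in ti.index:
            ref_v = ti.loc[model, "mae_velocity"]
            ref_k = ti.loc[model, "mae_tke"]
            beats_v = bool(med_v < ref_v) if np.isfinite(med_v) else np.nan
            beats_k = bool(med_k < ref_k) if np.isfinite(med_k) else np.nan
        else:
            ref_v = ref_k = beats_v = beats_k = np.nan
        rows.append({
            "model": model, "voxel_fraction": voxel, "snr": snr,
            "median_mae_velocity": med_v, "median_mae_tke": med_k,
            "ti_reference": ti_reference,
            "ti_mae_velocity": ref_v, "ti_mae_tke": ref_k,
            "mapped_beats_TI_velocity": beats_v, "mapped_beats_TI_tke": beats_k,
        })
    return pd.DataFrame(rows)


def enumerate_runs(config: StudyConfig) -> pd.DataFrame:
    """The planned run matrix, without solving anything (for --dry-run)."""
    rows = [{"mode": "ground_truth", "model": 0, "ti": np.nan,
             "voxel_fraction": np.nan, "snr": np.nan, "replicate": -1}]
    for label in config.cut_planes:
        model = MODEL_OF_STATION[label]
        rows.append({"mode": "mapped_exact", "model": model, "ti": np.nan,
                     "voxel_fraction": np.nan, "snr": np.nan, "replicate": -1})
    for label in config.cut_planes:
        for I in config.ti_levels:
            rows.append({"mode": "uniform_TI", "model": MODEL_OF_STATION[label],
                         "ti": I, "voxel_fraction": np.nan, "snr": np.nan,
                         "replicate": -1})
    for label in config.cut_planes:
        for voxel in config.voxel_fractions:
            for snr in config.snr_levels:
                for rep in range(config.replicates):
                    rows.append({"mode": "mapped_degraded",
                                 "model": MODEL_OF_STATION[label], "ti": np.nan,
                                 "voxel_fraction": voxel, "snr": snr,
                                 "replicate": rep})
    return pd.DataFrame(rows)


def run_all(config: StudyConfig) -> dict:
    """Execute the complete study; returns all result tables."""
    gt = run_ground_truth(config)
    baseline = run_baseline_mapping_verification(config, gt)
    ti = run_ti_study(config, gt)
    deg = run_degradation_study(config, gt)
    combined = pd.concat([baseline, ti, deg], ignore_index=True)
    comparison = compare_ti_vs_mapping(combined)
    return {
        "ground_truth": gt,
        "mapping_verification": baseline,
        "ti_study": ti,
        "degradation_study": deg,
        "results": combined,
        "comparison": comparison,
    }
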