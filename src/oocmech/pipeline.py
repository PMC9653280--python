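"""End-to-end orchestration: build -> solve -> analyze -> sweep-infer.

The stiffness ratios are defined operationally:

* ``k_HB`` — tabulated bundle stiffness at ``x`` (mN/m per cell);
* ``k_TM`` — radial end-to-end stiffness of the TM root+body in series per
  10 um section;
* ``k_OHC``, ``k_DC`` — EA/L of the row-1 OHC soma and Deiters-cell base.

A ratio sweep rescales exactly one property set (e.g. the TM moduli so that
``r_TM = k_TM/k_HB`` equals each grid value), solves the coupled model at
the stated frequency and records the deformation ratios and direction
angles.  Measured deformation ratios are then matched to the sweep curve by
log-log interpolation to infer the stiffness ratio and its uncertainty.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import assembly, fluid, materials, solver, vibrometry

__all__ = ["ModelConfig", "build_model", "default_r_tm", "default_r_dc",
           "sweep_ratio", "infer_ratio", "SweepResult",
           "calibrate_bm_modulus", "run_report", "OutOfRangeError"]

SWEEP_RATIOS = ("rtm", "rdc", "kphp", "krl", "cdc")


@dataclass(frozen=True)
class ModelConfig:
    """All tunables of a coupled-model run (lengths in the units noted)."""

    x_mm: float = 8.5            # section of interest, mm from the base
    span_mm: float = 0.6         # longitudinal model span
    spacing_um: float = 10.0     # section spacing
    php_span: int = 3            # phalangeal-process span, in sections
    hb_axial_factor: float = 100.0
    bm_scale: float = 1.0        # Young's-modulus multipliers
    tm_scale: float = 1.0
    dc_scale: float = 1.0
    rl_scale: float = 1.0
    php_scale: float = 1.0
    cdc_scale: float = 1.0       # OHC/DC damping multiplier
    alpha: float = 0.0           # Rayleigh mass coefficient, 1/s
    beta: float | None = None    # Rayleigh stiffness coefficient, s
    membrane_damping_per_area: float = 1000.0  # N s/m^3, BM and TM drag
    subtectorial_damping: float = 100e-9  # N s/m per 10 um section, shear
    subtectorial_squeeze: float = 1e-4    # N s/m per 10 um section, normal
    tm_loss_eta: float = 0.3              # TM gel loss tangent at 1 kHz
    chamber_length_mm: float = 10.0
    channel_height_mm: float = 1.0
    chamber_depth_mm: float = 4.0   # must seat the ~3 mm cochlear turn
    far_cell_mm: float = 0.5
    fluid_refinement: float = 5.0   # far-field-to-slit cell-size ratio
    fluid_3d: bool = True           # resolve the slit strip across the depth
    stimulus_pa: float = 1.0
    with_fluid: bool = True
    seed: int = 0

    def sections_x(self) -> np.ndarray:
        """Longitudinal positions (mm) of the model's radial sections."""
        n = max(int(round(self.span_mm * 1e3 / self.spacing_um)) + 1, 3)
        return self.x_mm + (np.arange(n) - (n - 1) / 2.0) \
            * self.spacing_um * 1e-3


def build_model(cfg: ModelConfig,
                mats: materials.MaterialTable | None = None,
                landmarks_by_section=None
                ) -> tuple[assembly.AssembledSystem,
                           fluid.CouplingOperators | None]:
    """Build the structural system and (optionally) its chamber coupling."""
    mats = mats or materials.MaterialTable()
    xs = cfg.sections_x()
    secs = []
    for i, x in enumerate(xs):
        lm = landmarks_by_section[i] if landmarks_by_section else None
        secs.append(materials.build_section(
            float(x), mats, landmarks=lm, spacing_um=cfg.spacing_um,
            tm_scale=cfg.tm_scale, dc_scale=cfg.dc_scale,
            bm_scale=cfg.bm_scale, rl_scale=cfg.rl_scale,
            php_scale=cfg.php_scale, hb_axial_factor=cfg.hb_axial_factor,
            php_span=cfg.php_span))
    system = assembly.assemble_structure(
        secs, cfg.spacing_um, alpha=cfg.alpha, beta=cfg.beta, materials=mats,
        php_span=cfg.php_span, damping_scale_dc=cfg.cdc_scale,
        membrane_damping_per_area=cfg.membrane_damping_per_area,
        subtectorial_damping=cfg.subtectorial_damping,
        subtectorial_squeeze=cfg.subtectorial_squeeze,
        tm_loss_eta=cfg.tm_loss_eta)
    system.slit_x0 = (cfg.chamber_length_mm / 2 - cfg.span_mm / 2) * 1e-3
    system.interface = assembly._interface_patches(system)
    if not cfg.with_fluid:
        return system, None
    slit_width = (system.sections[system.mid_section].bm_width * 1e-3
                  if cfg.fluid_3d else None)
    mesh = fluid.build_fluid_mesh(
        chamber_length_mm=cfg.chamber_length_mm,
        channel_height_mm=cfg.channel_height_mm,
        slit_span_mm=cfg.span_mm, refinement=cfg.fluid_refinement,
        far_cell_mm=cfg.far_cell_mm, depth_mm=cfg.chamber_depth_mm,
        slit_width_mm=slit_width)
    coupling = fluid.assemble_coupling(mesh, system.interface, system.n_dofs)
    return system, coupling


def full_span_config(x_probe_mm: float = 8.5, **overrides) -> ModelConfig:
    """Configuration of the full excised-turn model (4 mm span).

    The reduced turn spans roughly 6-10 mm from the base; the model is
    centered at 8 mm so the measured site at ``x_probe_mm`` lies inside.
    """
    defaults = dict(x_mm=8.0, span_mm=4.0, spacing_um=20.0)
    defaults.update(overrides)
    return ModelConfig(**defaults)


def frequency_response(cfg: ModelConfig, frequencies: np.ndarray,
                       probe_x_mm: float = 8.5,
                       hydrophone: bool = True,
                       mats: materials.MaterialTable | None = None):
    """BM midpoint response across a frequency band.

    The probe is the transverse DOF of the first-row Deiters-cell root
    (radial middle of the BM) at the section nearest ``probe_x_mm``.  With
    ``hydrophone`` the response is normalized by the pressure at a
    hydrophone cell in the chamber floor beneath the tissue, emulating the
    experimental normalization; otherwise by the port stimulus pressure.

    Returns ``(frequencies, complex response)`` with the response in m/Pa.
    """
    system, coupling = build_model(cfg, mats)
    if coupling is None:
        raise ValueError("frequency response requires the fluid chamber")
    s = system.section_at(probe_x_mm)
    probe = system.dof(s, materials.DC_ROOTS[0], 1)
    hydro = fluid.hydrophone_cell(coupling.mesh) if hydrophone else None
    out = []
    for f in np.asarray(frequencies, dtype=float):
        field, pressure = solver.solve_frequency(
            system, coupling, f, cfg.stimulus_pa, with_pressure=True)
        ref = pressure[hydro] if hydro is not None else cfg.stimulus_pa
        out.append(field.values[probe] / ref)
    return np.asarray(frequencies, dtype=float), np.asarray(out)


# ---------------------------------------------------------------------------
# Operational stiffness definitions
# ---------------------------------------------------------------------------

def k_hb(mats: materials.MaterialTable, x: float) -> float:
    return mats.value("hb_stiffness", x)


def k_tm(mats: materials.MaterialTable, x: float,
         spacing_um: float = 10.0) -> float:
    """Radial series stiffness of TM root+body per section, mN/m."""
    w = mats.value("tm_width", x)
    l_root, l_body = w / 3.0, 2.0 * w / 3.0
    k_root = materials._axial_k(mats.value("tm_root_modulus", x),
                                mats.value("tm_root_thickness", x) * spacing_um,
                                l_root)
    k_body = materials._axial_k(mats.value("tm_body_modulus", x),
                                mats.value("tm_body_thickness", x) * spacing_um,
                                l_body)
    return 1.0 / (1.0 / k_root + 1.0 / k_body)


def k_ohc(mats: materials.MaterialTable, x: float) -> float:
    d = mats.value("ohc_diameter", x)
    return materials._axial_k(mats.value("ohc_modulus", x),
                              math.pi * d * d / 4,
                              mats.value("ohc_length", x))


def k_dc(mats: materials.MaterialTable, x: float) -> float:
    lm = materials.default_landmarks(x, mats)
    root = np.array([0.5 * mats.value("bm_width", x), 0.0])
    l_dc = float(np.linalg.norm(np.asarray(lm["ohc1_bottom"]) - root))
    d = mats.value("dc_base_diameter", x)
    return materials._axial_k(mats.value("dc_base_modulus", x),
                              math.pi * d * d / 4, l_dc)


def default_r_tm(mats: materials.MaterialTable, x: float,
                 spacing_um: float = 10.0) -> float:
    return k_tm(mats, x, spacing_um) / k_hb(mats, x)


def default_r_dc(mats: materials.MaterialTable, x: float) -> float:
    return k_dc(mats, x) / k_ohc(mats, x)


# ---------------------------------------------------------------------------
# Sweeps and inference
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Deformation ratios and angles along a stiffness-ratio sweep."""

    ratio_name: str
    grid: np.ndarray
    ratio_tm: np.ndarray
    theta_tm: np.ndarray
    ratio_dc: np.ndarray
    theta_dc: np.ndarray
    frequency: float
    config: ModelConfig

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("sweep grid must be strictly increasing")

    def curve(self) -> np.ndarray:
        return self.ratio_tm if self.ratio_name == "rtm" else self.ratio_dc


def default_grid(n: int = 9) -> np.ndarray:
    return np.logspace(-1.0, 1.0, n)


def sweep_ratio(cfg: ModelConfig, ratio_name: str,
                grid: np.ndarray | None = None,
                frequency: float = 1000.0,
                mats: materials.MaterialTable | None = None) -> SweepResult:
    """Solve the coupled model over a log-spaced grid of one stiffness ratio.

    Exactly one property set is rescaled per grid value; everything else,
    including all masses, stays at its default.  Solver failures at a grid
    point are recorded as NaN and the sweep continues.
    """
    if ratio_name not in SWEEP_RATIOS:
        raise ValueError(f"unsupported ratio {ratio_name!r}")
    mats = mats or materials.MaterialTable()
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("grid values must be positive")
    r_tm0 = default_r_tm(mats, cfg.x_mm, cfg.spacing_um)
    r_dc0 = default_r_dc(mats, cfg.x_mm)

    out = {k: [] for k in ("ratio_tm", "theta_tm", "ratio_dc", "theta_dc")}
    # geometry (hence the interface map and fluid mesh) is identical across
    # the sweep: assemble and factorize the chamber operators once
    coupling = None
    if cfg.with_fluid:
        _, coupling = build_model(cfg, mats)
    for g in grid:
        if ratio_name == "rtm":
            run_cfg = replace(cfg, tm_scale=g / r_tm0)
        elif ratio_name == "rdc":
            run_cfg = replace(cfg, dc_scale=g / r_dc0)
        elif ratio_name == "kphp":
            run_cfg = replace(cfg, php_scale=g)
        elif ratio_name == "krl":
            run_cfg = replace(cfg, rl_scale=g)
        else:  # cdc
            run_cfg = replace(cfg, cdc_scale=g)
        run_cfg = replace(run_cfg, with_fluid=False)
        try:
            system, _ = build_model(run_cfg, mats)
            if coupling is not None:
                field = solver.solve_frequency(system, coupling, frequency,
                                               cfg.stimulus_pa)
            else:
                field = solver.solve_static(system, cfg.stimulus_pa)
            rt, tt = vibrometry.deformation_ratio_tm(field)
            rd, td = vibrometry.deformation_ratio_dc(field)
        except (RuntimeError, ZeroDivisionError):
            rt = tt = rd = td = float("nan")
        out["ratio_tm"].append(rt)
        out["theta_tm"].append(tt)
        out["ratio_dc"].append(rd)
        out["theta_dc"].append(td)
    return SweepResult(ratio_name=ratio_name, grid=grid,
                       ratio_tm=np.asarray(out["ratio_tm"]),
                       theta_tm=np.asarray(out["theta_tm"]),
                       ratio_dc=np.asarray(out["ratio_dc"]),
                       theta_dc=np.asarray(out["theta_dc"]),
                       frequency=frequency, config=cfg)


class OutOfRangeError(ValueError):
    def __init__(self, measured: float, nearest: float):
        super().__init__(f"measured value {measured} outside the sweep "
                         f"output range; nearest endpoint {nearest}")
        self.nearest = nearest


def infer_ratio(sweep: SweepResult, measured: float, sd: float = 0.0
                ) -> tuple[float, float, float]:
    """Stiffness ratio matching a measured deformation ratio, with bounds.

    Interpolates the sweep curve in log-log coordinates at ``measured`` and
    ``measured -/+ sd``.  The deformation ratio decreases with the
    stiffness ratio, so the +sd bound maps to the lower stiffness ratio.
    """
    curve = sweep.curve()
    ok = np.isfinite(curve)
    lg, lc = np.log(sweep.grid[ok]), np.log(curve[ok])

    def solve_one(value: float) -> float:
        lv = math.log(value)
        lo, hi = min(lc[0], lc[-1]), max(lc[0], lc[-1])
        if not (lo <= lv <= hi):
            nearest = float(np.exp(lc[0] if abs(lv - lc[0]) < abs(lv - lc[-1])
                                   else lc[-1]))
            raise OutOfRangeError(value, nearest)
        # np.interp needs ascending x; the curve falls with the grid
        order = np.argsort(lc)
        return float(np.exp(np.interp(lv, lc[order], lg[order])))

    center = solve_one(measured)
    if sd == 0:
        return center, center, center
    lo = solve_one(measured + sd) if measured + sd <= np.exp(lc).max() \
        else float(sweep.grid[0])
    hi = solve_one(measured - sd) if measured - sd >= np.exp(lc).min() \
        else float(sweep.grid[-1])
    return center, min(lo, hi), max(lo, hi)


def loglog_slope(sweep: SweepResult, lo: float = 0.3, hi: float = 3.0
                 ) -> float:
    """Fitted log-log slope of the deformation ratio over grid in [lo, hi]."""
    sel = (sweep.grid >= lo) & (sweep.grid <= hi) & np.isfinite(sweep.curve())
    if sel.sum() < 2:
        raise ValueError("need at least two grid points in the fit range")
    return float(np.polyfit(np.log(sweep.grid[sel]),
                            np.log(sweep.curve()[sel]), 1)[0])


# ---------------------------------------------------------------------------
# Volume-compliance calibration
# ---------------------------------------------------------------------------

def calibrate_bm_modulus(cfg: ModelConfig, target_mm4_per_n: float = 16.1,
                         dp: float = 5.6, tol: float = 5e-3,
                         max_iter: int = 12,
                         mats: materials.MaterialTable | None = None
                         ) -> tuple[ModelConfig, float]:
    """Scale the BM fiber-layer modulus to match a measured volume compliance.

    The static volume compliance is nearly inversely proportional to the BM
    modulus scale, so fixed-point iteration converges in a few steps.
    Returns the calibrated config and the achieved compliance (mm^4/N).
    """
    cal = replace(cfg, with_fluid=False)
    scale = cal.bm_scale
    achieved = float("nan")
    for _ in range(max_iter):
        cal = replace(cal, bm_scale=scale)
        system, _ = build_model(cal, mats)
        fld = solver.solve_static(system, dp)
        profile = vibrometry.bm_profile(fld, pressure_pa=dp)
        _, achieved = vibrometry.volume_compliance(profile)
        if abs(achieved - target_mm4_per_n) / target_mm4_per_n < tol:
            break
        scale *= achieved / target_mm4_per_n
    return replace(cfg, bm_scale=cal.bm_scale), achieved


# ---------------------------------------------------------------------------
# Declarative runs
# ---------------------------------------------------------------------------

_KNOWN_STAGES = ("build", "calibrate", "static", "freq_sweep",
                 "sweep_rtm", "sweep_rdc", "infer_rtm", "infer_rdc")


def run_report(config: dict, out_dir) -> dict:
    """Execute the declared stages and write tables, JSON and a run log.

    ``config`` keys: ``model`` (ModelConfig field overrides), ``stages``
    (ordered list from the known set), plus optional stage parameters.
    The configuration is schema-checked before any compute.
    """
    stages = config.get("stages", [])
    unknown = [s for s in stages if s not in _KNOWN_STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; known: {_KNOWN_STAGES}")
    model_overrides = config.get("model", {})
    bad = [k for k in model_overrides
           if k not in {f.name for f in dataclasses.fields(ModelConfig)}]
    if bad:
        raise ValueError(f"unknown model options {bad}")
    cfg = ModelConfig(**model_overrides)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True).encode()
    cfg_hash = hashlib.sha256(blob).hexdigest()[:16]
    results: dict = {"config_hash": cfg_hash, "seed": cfg.seed}
    log_lines = [f"config hash {cfg_hash}", f"seed {cfg.seed}"]

    system = coupling = None
    sweeps: dict[str, SweepResult] = {}
    for stage in stages:
        if stage == "build":
            system, coupling = build_model(cfg)
            sec = system.sections[system.mid_section]
            (out / "section.json").write_text(materials.section_to_json(sec))
            results["n_dofs"] = system.n_dofs
        elif stage == "calibrate":
            cfg, achieved = calibrate_bm_modulus(
                cfg, config.get("calibrate_target", 16.1))
            results["calibrated_bm_scale"] = cfg.bm_scale
            results["volume_compliance_mm4_per_N"] = achieved
            system = coupling = None
        elif stage == "static":
            if system is None:
                system, coupling = build_model(cfg)
            dp = config.get("dp", 5.6)
            fld = solver.solve_static(system, dp)
            prof = vibrometry.bm_profile(fld, pressure_pa=dp)
            peak, vol = vibrometry.volume_compliance(prof)
            results["static"] = {
                "peak_compliance_nm_per_Pa": peak,
                "volume_compliance_mm4_per_N": vol,
                "fwhm_fraction": vibrometry.fwhm_fraction(prof)}
            _write_profile(out / "static_profile.csv", prof)
        elif stage == "freq_sweep":
            freqs = np.geomspace(config.get("fmin", 300.0),
                                 config.get("fmax", 5000.0),
                                 config.get("points", 15))
            _, amps = frequency_response(cfg, freqs, probe_x_mm=cfg.x_mm)
            results["freq_sweep"] = {
                "corner_hz": vibrometry.corner_frequency(freqs, amps),
                "phase_span_deg": vibrometry.phase_accumulation_deg(freqs,
                                                                    amps)}
            _write_response(out / "freq_response.csv", freqs, amps)
        elif stage in ("sweep_rtm", "sweep_rdc"):
            name = stage.split("_")[1]
            sw = sweep_ratio(cfg, name,
                             frequency=config.get("sweep_frequency", 1000.0))
            sweeps[name] = sw
            _write_sweep(out / f"sweep_{name}.csv", sw)
        elif stage in ("infer_rtm", "infer_rdc"):
            name = stage.split("_")[1]
            if name not in sweeps:
                sweeps[name] = sweep_ratio(
                    cfg, name, frequency=config.get("sweep_frequency", 1000.0))
            measured = config[f"measured_{name}"]
            sd = config.get(f"measured_{name}_sd", 0.0)
            center, lo, hi = infer_ratio(sweeps[name], measured, sd)
            results[f"inferred_{name}"] = {"value": center, "lower": lo,
                                           "upper": hi}
        log_lines.append(f"stage {stage}: done")

    (out / "results.json").write_text(json.dumps(results, indent=1))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return results


def _write_profile(path, prof: vibrometry.DeflectionProfile) -> None:
    import pandas as pd
    pd.DataFrame({"r_um": prof.positions_um,
                  "displacement_nm": prof.displacement_nm}).to_csv(
        path, index=False)


def _write_response(path, freqs, amps) -> None:
    import pandas as pd
    pd.DataFrame({"frequency_hz": freqs, "re": np.real(amps),
                  "im": np.imag(amps), "amplitude_m": np.abs(amps),
                  "phase_rad": np.angle(amps)}).to_csv(path, index=False)


def _write_sweep(path, sw: SweepResult) -> None:
    import pandas as pd
    pd.DataFrame({"ratio": sw.grid, "dtm_over_dhb": sw.ratio_tm,
                  "theta_tm_deg": sw.theta_tm, "ddc_over_dohc": sw.ratio_dc,
                  "theta_dc_deg": sw.theta_dc}).to_csv(path, index=False)
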