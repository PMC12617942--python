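"""End-to-end orchestration: phantom -> mesh -> pressure -> vibration
sweep -> FRFs -> similarity -> optional parametric studies.

The stages mirror the two-model validation pipeline: an acoustic
pressure stage supplies the plane-wave loading on the wetted surface,
and the harmonic vibration stage sweeps the reduced modal system
across the measurement band to produce sensor FRFs, which are scored
against a reference (synthetic "experiment") with the similarity
metrics.

Pressure loading modes
----------------------
``fdtd``      time-domain scattering solve on the coarse frequency grid
              (default 100-1000 Hz, step 100) with linear interpolation
              in frequency to each sweep point.
``incident``  analytic incident plane wave only (no scattering).  At
              phantom scale the skull is far smaller than the acoustic
              wavelength, so scattering perturbs the loading weakly;
              this mode trades that perturbation for large speed-ups
              and is the default for studies that re-run the sweep many
              times.

Modal bases are cached in-process keyed by everything that affects the
undamped eigenproblem (geometry, stiffness, density, sensor masses) —
loss factors enter only after projection, so damping-only studies
re-use the basis.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import hva, materials as mats, meshing, metrics, press
from .doe import FactorialDesign, StudyResult, full_factorial, run_study
from .frf import FRFSet, default_sweep
from .phantom import (PhantomConfig, SyntheticFRFSpec, VoxelPhantom,
                      default_reference_spec, generate_phantom,
                      generate_reference_frf, place_sensors)


@dataclass
class PressConfig:
    mode: str = "fdtd"  # "fdtd" | "incident"
    f_lo: float = 100.0
    f_hi: float = 1000.0
    f_step: float = 100.0
    periods: int = 4
    stations: int = 11
    cfl: float = 0.5
    margin: int = 3
    sponge: int = 8
    direction: tuple = (0.0, 0.0, 1.0)  # along the AP axis
    amplitude: float = 1.0  # Pa; unit amplitude makes FRFs per-unit-pressure

    @property
    def coarse_grid(self) -> np.ndarray:
        return np.arange(self.f_lo, self.f_hi + 0.5 * self.f_step, self.f_step)


@dataclass
class SweepConfig:
    f_lo: float = 170.0
    f_hi: float = 1000.0
    n: int = 416
    safety: float = 1.5  # modal cutoff = safety * f_hi

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.f_lo, self.f_hi, self.n)


@dataclass
class SmoothConfig:
    iterations: int = 10
    lam: float = 0.5
    mu: float = -0.53


@dataclass
class MetricConfig:
    f_lo: float = 170.0
    f_hi: float = 1000.0
    smoothing_window: int = 1
    frfsm_sigma0: float = 6.0


@dataclass
class RunConfig:
    """Everything needed for a reproducible validation run."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    smooth: SmoothConfig = field(default_factory=SmoothConfig)
    press: PressConfig = field(default_factory=PressConfig)
    sweep: SweepConfig = field(default_factory=SweepConfig)
    metric: MetricConfig = field(default_factory=MetricConfig)
    material_preset: str = "natural"  # "natural" | "replica"
    seed: int = 0
    outdir: str | None = None

    def materials(self) -> dict:
        if self.material_preset == "natural":
            return mats.natural_preset()
        if self.material_preset == "replica":
            return mats.replica_preset()
        raise ValueError(f"unknown material preset {self.material_preset!r}; "
                         "expected 'natural' or 'replica'")

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        kw = dict(doc)
        for key, sub in (("phantom", PhantomConfig), ("smooth", SmoothConfig),
                         ("press", PressConfig), ("sweep", SweepConfig),
                         ("metric", MetricConfig)):
            if key in kw and isinstance(kw[key], dict):
                sub_kw = dict(kw[key])
                for tup_key in ("shape", "direction"):
                    if tup_key in sub_kw and isinstance(sub_kw[tup_key], list):
                        sub_kw[tup_key] = tuple(sub_kw[tup_key])
                kw[key] = sub(**sub_kw)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})


# ---------------------------------------------------------------------------
# modal-basis cache

_BASIS_CACHE: dict = {}


def _basis_key(config: RunConfig, materials: dict) -> tuple:
    mat_key = tuple((lab, m.rho, m.E, m.nu) for lab, m in sorted(materials.items()))
    return (tuple(sorted(asdict(config.phantom).items(), key=str)),
            tuple(sorted(asdict(config.smooth).items())),
            config.sweep.f_hi, config.sweep.safety, config.seed, mat_key)


def clear_cache() -> None:
    _BASIS_CACHE.clear()


def build_model(config: RunConfig, materials: dict | None = None):
    """Phantom -> (smoothed) mesh -> sensors -> system -> modal basis.

    Returns (phantom, mesh, sensors, system, basis); the basis is
    cached on everything that affects the undamped eigenproblem.
    """
    materials = materials or config.materials()
    key = _basis_key(config, materials)
    if key in _BASIS_CACHE:
        return _BASIS_CACHE[key]
    ph = generate_phantom(config.phantom, config.seed)
    mesh = meshing.voxels_to_tetmesh(ph)
    if config.smooth.iterations > 0:
        mesh = meshing.taubin_smooth(mesh, config.smooth.lam, config.smooth.mu,
                                     config.smooth.iterations)
    sensors = place_sensors(ph)
    system = hva.assemble_system(mesh, materials, sensors)
    basis = hva.compute_modal_basis(system, config.sweep.f_hi,
                                    config.sweep.safety)
    _BASIS_CACHE[key] = (ph, mesh, sensors, system, basis)
    return _BASIS_CACHE[key]


def coarse_pressure_fields(config: RunConfig, phantom: VoxelPhantom,
                           materials: dict) -> list:
    """Complex pressure fields on the coarse frequency grid."""
    pc = config.press
    scene = press.scene_from_phantom(phantom, materials, pc.direction,
                                     pc.amplitude, pc.margin, pc.sponge)
    fields = []
    for f in pc.coarse_grid:
        if pc.mode == "incident":
            fields.append(press.incident_field(scene, f))
        elif pc.mode == "fdtd":
            fields.append(press.simulate_pressure(scene, f, pc.periods,
                                                  pc.stations, pc.cfl))
        else:
            raise ValueError(f"unknown pressure mode {pc.mode!r}")
    return fields


def sweep_loads(config: RunConfig, fields: list, system) -> "callable":
    """Per-frequency load vectors for the sweep.

    The coarse fields are sampled once at the wetted-surface nodes;
    frequency interpolation is then done on the surface values (linear
    interpolation and linear trilinear sampling commute, so this equals
    interpolating the volume field first).
    """
    fields = sorted(fields, key=lambda f: f.frequency)
    freqs = np.array([f.frequency for f in fields])
    surf_vals = [press.sample_surface_pressure(f, system.surface, system.mesh)
                 for f in fields]
    node_ids = surf_vals[0].node_indices
    table = np.vstack([sv.values for sv in surf_vals])  # (n_coarse, n_nodes)

    def get_load(f_hz: float) -> np.ndarray:
        if not freqs[0] - 1e-9 <= f_hz <= freqs[-1] + 1e-9:
            raise ValueError(f"sweep frequency {f_hz} Hz outside pressure "
                             f"grid [{freqs[0]}, {freqs[-1]}] Hz")
        hi = int(np.clip(np.searchsorted(freqs, f_hz), 1, len(freqs) - 1))
        lo = hi - 1
        w = (f_hz - freqs[lo]) / (freqs[hi] - freqs[lo])
        vals = (1.0 - w) * table[lo] + w * table[hi]
        sp_field = press.SurfacePressure(node_ids, vals, f_hz)
        return hva.apply_pressure_load(system, sp_field)

    return get_load


def model_frfs(config: RunConfig, materials: dict | None = None) -> FRFSet:
    """Run the forward pipeline and return the model FRF set."""
    materials = materials or config.materials()
    ph, _mesh, sensors, system, basis = build_model(config, materials)
    fields = coarse_pressure_fields(config, ph, materials)
    loads = sweep_loads(config, fields, system)
    return hva.frf_sweep(basis, loads, materials, sensors,
                         config.sweep.grid, config.press.amplitude)


@dataclass
class ValidationBundle:
    """Everything a validation run produces."""

    model: FRFSet
    reference: FRFSet
    report: metrics.SimilarityReport
    amplification_ratios: dict
    amplification_average: np.ndarray
    log: dict


def run_validation(config: RunConfig, reference: FRFSet | None = None,
                   reference_spec: SyntheticFRFSpec | None = None
                   ) -> ValidationBundle:
    """Execute all stages and score the model against a reference.

    If no reference is supplied, a synthetic "experimental" FRF set is
    generated from the default modal recipe (seeded from the run seed),
    standing in for pool measurements.  Outputs (FRF CSVs, similarity
    JSON, amplification CSV, run log) are written to ``config.outdir``
    when set.
    """
    t0 = time.perf_counter()
    materials = config.materials()
    stage = "model"
    try:
        ph, mesh, sensors, system, basis = build_model(config, materials)
        stage = "pressure"
        fields = coarse_pressure_fields(config, ph, materials)
        stage = "sweep"
        loads = sweep_loads(config, fields, system)
        frfs = hva.frf_sweep(basis, loads, materials, sensors,
                             config.sweep.grid, config.press.amplitude)
        stage = "reference"
        if reference is None:
            spec = reference_spec or default_reference_spec(config.sweep.grid)
            reference = generate_reference_frf(spec, config.seed + 1)
        stage = "metrics"
        report = metrics.compare_frf_sets(
            reference, frfs, config.metric.f_lo, config.metric.f_hi,
            config.metric.smoothing_window, config.metric.frfsm_sigma0)
        ratios, average, _flagged = hva.amplification(frfs)
    except Exception as err:
        raise RuntimeError(f"validation failed in stage {stage!r}: {err}") from err

    log = {
        "seed": config.seed,
        "material_preset": config.material_preset,
        "materials": {str(lab): {"rho": m.rho, "E": m.E, "nu": m.nu, "eta": m.eta}
                      for lab, m in materials.items()},
        "phantom_voxels": int(ph.nonempty_count),
        "n_nodes": int(mesh.n_nodes),
        "n_tets": int(mesh.n_tets),
        "n_modes": int(basis.n_modes),
        "n_rigid_modes": int(basis.n_rigid),
        "modal_cutoff_hz": float(basis.cutoff_hz),
        "press_mode": config.press.mode,
        "coarse_grid_hz": config.press.coarse_grid.tolist(),
        "sweep": [config.sweep.f_lo, config.sweep.f_hi, config.sweep.n],
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    bundle = ValidationBundle(frfs, reference, report, ratios, average, log)
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        frfs.to_csv(out / "model_frfs.csv")
        reference.to_csv(out / "reference_frfs.csv")
        report.to_json(out / "similarity.json")
        amp_cols = {"frequency_Hz": frfs.freq, "average": average}
        amp_cols.update({k.replace("/", "_"): v for k, v in ratios.items()})
        import pandas as pd

        pd.DataFrame(amp_cols).to_csv(out / "amplification.csv", index=False)
        with open(out / "run_log.json", "w") as f:
            json.dump(log, f, indent=2)
    return bundle


def run_refinement_study(config: RunConfig, levels=(1, 2, 4)) -> list:
    """Mesh-refinement convergence: FRFs computed on phantoms
    regenerated at each refinement level, scored between consecutive
    levels.

    Returns one row per consecutive pair: a dict with the pair label
    and the (median, 2*MAD) summary per metric.
    """
    levels = list(levels)
    if len(levels) < 2:
        raise ValueError("need at least 2 refinement levels")
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError(f"levels must be strictly increasing, got {levels}")
    frf_sets = []
    for lv in levels:
        cfg = RunConfig(phantom=config.phantom.scaled(int(lv)),
                        smooth=config.smooth, press=config.press,
                        sweep=config.sweep, metric=config.metric,
                        material_preset=config.material_preset,
                        seed=config.seed, outdir=None)
        frf_sets.append(model_frfs(cfg))
    rows = []
    for (la, fa), (lb, fb) in zip(zip(levels, frf_sets),
                                  zip(levels[1:], frf_sets[1:])):
        report = metrics.compare_frf_sets(fa, fb, config.metric.f_lo,
                                          config.metric.f_hi)
        rows.append({"pair": f"{la}x->{lb}x",
                     **{m: report.summary[m] for m in report.summary}})
    return rows


def material_study(config: RunConfig, reference: FRFSet,
                   factors=None) -> StudyResult:
    """Two-level full factorial study over material parameters.

    The response is the median FRFSM between the model and the given
    reference across the sensor channels.  Factor sets follow the
    preset: the replica varies {E, rho}, the natural skull varies
    {Esk, Etp, rhosk, rhotp, lfs, lft}.
    """
    if factors is None:
        ranges = (mats.REPLICA_STUDY_FACTORS if config.material_preset == "replica"
                  else mats.NATURAL_STUDY_FACTORS)
        factors = [(fr.name, fr.low, fr.high) for fr in ranges]
    design = full_factorial(factors)
    to_materials = (mats.replica_from_factors if config.material_preset == "replica"
                    else mats.natural_from_factors)

    def evaluate(values: dict) -> float:
        m = to_materials(values)
        frfs = model_frfs(config, m)
        report = metrics.compare_frf_sets(reference, frfs, config.metric.f_lo,
                                          config.metric.f_hi,
                                          config.metric.smoothing_window,
                                          config.metric.frfsm_sigma0)
        return report.summary["FRFSM"][0]

    return run_study(design, evaluate)


def suspension_inertia_orders(f_hz: float = 170.0,
                              f_suspension_hz: float = 0.4) -> float:
    """Orders of magnitude by which inertial force dominates the
    suspension-fixture restoring force at drive frequency ``f_hz``.

    For a mass on a soft suspension the force ratio at frequency f is
    (f / f_0)^2; the suspended-skull fixture resonates near 0.4 Hz,
    far below the measurement band, which justifies neglecting the
    fixture stiffness entirely.
    """
    if f_hz <= 0 or f_suspension_hz <= 0:
        raise ValueError("frequencies must be positive")
    return float(2.0 * np.log10(f_hz / f_suspension_hz))
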