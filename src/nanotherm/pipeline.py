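"""End-to-end treatment simulation: phantom -> optics -> fluence -> bioheat -> damage.

A :class:`TreatmentPlan` captures one of the three study arms
(``laser_only``, ``IP``, ``IT``), the laser settings, the thermal and
damage parameters and the phantom geometry.  :func:`run_treatment`
executes the chain deterministically for a given seed and produces a
:class:`RunReport` plus (optionally) on-disk field volumes, probe series
CSVs and a JSON report, one directory per run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .light import (
    LaserSource,
    TissueOptics,
    assemble_optics,
    external_heat,
    solve_fluence,
)
from .phantom import Phantom, ProbeSet, default_probes, make_phantom
from .thermal import (
    ArrheniusParams,
    TemperatureField,
    ThermalProps,
    arrhenius_damage,
    probe_timeseries,
    solve_bioheat,
)

log = logging.getLogger(__name__)

__all__ = [
    "PhantomConfig",
    "TreatmentPlan",
    "RunReport",
    "run_treatment",
    "surface_temperature_map",
    "compare_to_measurement",
]


@dataclass(frozen=True)
class PhantomConfig:
    body_semiaxes_mm: tuple = (10.0, 10.0, 14.0)
    tumor_center_mm: tuple = (0.0, 8.0, 0.0)
    tumor_semiaxes_mm: tuple = (4.0, 4.0, 4.0)
    spacing_mm: float = 0.5
    shape: tuple = (64, 64, 64)
    blob_fraction: float = 0.3
    blob_offset: float = 0.5
    f_v_it: float = 1.0e-7
    f_v_ip: float = 5.0e-9


@dataclass(frozen=True)
class TreatmentPlan:
    """Fully-specified simulation of one treatment arm."""

    scenario: str = "IT"
    seed: int = 0
    laser: LaserSource = field(default_factory=LaserSource)
    thermal: ThermalProps = field(default_factory=ThermalProps)
    arrhenius: ArrheniusParams = field(default_factory=ArrheniusParams)
    phantom_cfg: PhantomConfig = field(default_factory=PhantomConfig)
    tissue: TissueOptics = field(default_factory=TissueOptics)
    mu_an_ref_cm1: float = 54.0
    mu_sn_ref_cm1: float = 7.0e-4
    f_v_ref: float = 1.0e-7
    boundary_mode: str = "dirichlet"
    dt_s: float = 0.5
    store_every_s: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "TreatmentPlan":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        for key, sub in (
            ("laser", LaserSource),
            ("thermal", ThermalProps),
            ("arrhenius", ArrheniusParams),
            ("phantom_cfg", PhantomConfig),
            ("tissue", TissueOptics),
        ):
            if key in raw:
                section = raw.pop(key)
                section = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
                }
                kw[key] = sub(**section)
        kw.update(raw)
        return cls(**kw)

    def resolved(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        return d


@dataclass
class RunReport:
    scenario: str
    seed: int
    max_surface_dT_K: float
    time_to_max_s: float
    max_T_C: float
    max_omega: float
    probe_final_T_C: dict
    probe_final_omega: dict
    fluence_max_W_cm2: float
    solver_diagnostics: dict
    parameters: dict

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")


def run_treatment(plan: TreatmentPlan, outdir=None, probes: ProbeSet | None = None):
    """Run one treatment arm end to end.

    Returns ``(report, fields)`` where ``fields`` is a dict with the
    phantom, fluence, Q_ext, temperature and damage volumes.  With
    ``outdir`` set, writes ``fields/*.nii.gz``, ``probes/*.csv`` and
    ``report.json``; refuses to overwrite an existing run directory.
    """
    cfg = plan.phantom_cfg
    log.info("stage phantom: scenario=%s seed=%d", plan.scenario, plan.seed)
    phantom = make_phantom(
        body_semiaxes_mm=cfg.body_semiaxes_mm,
        tumor_center_mm=cfg.tumor_center_mm,
        tumor_semiaxes_mm=cfg.tumor_semiaxes_mm,
        scenario=plan.scenario,
        spacing_mm=cfg.spacing_mm,
        seed=plan.seed,
        shape=cfg.shape,
        blob_fraction=cfg.blob_fraction,
        blob_offset=cfg.blob_offset,
        blob_axis=plan.laser.axis,
        blob_sign=-plan.laser.direction,
        f_v_it=cfg.f_v_it,
        f_v_ip=cfg.f_v_ip,
    )
    probes = probes or default_probes(phantom, beam_axis=plan.laser.axis, beam_dir=plan.laser.direction)

    log.info("stage optics")
    props = assemble_optics(
        phantom,
        plan.tissue,
        mu_an_ref_cm1=plan.mu_an_ref_cm1,
        mu_sn_ref_cm1=plan.mu_sn_ref_cm1,
        f_v_ref=plan.f_v_ref,
    )
    log.info("stage fluence: mode=%s irradiance=%.3g W/cm2", plan.boundary_mode, plan.laser.irradiance_W_cm2)
    fluence = solve_fluence(phantom, props, plan.laser, mode=plan.boundary_mode)
    q_ext = external_heat(props, fluence)

    log.info("stage bioheat: %.0f s, dt=%.2g s", plan.laser.duration_s, plan.dt_s)
    tfield = solve_bioheat(
        phantom,
        plan.thermal,
        q_ext,
        duration_s=plan.laser.duration_s,
        dt_s=plan.dt_s,
        store_every_s=plan.store_every_s,
    )
    log.info("stage damage: A=%.3g 1/s Ea=%.3g J/mol", plan.arrhenius.a_per_s, plan.arrhenius.ea_J_mol)
    dfield = arrhenius_damage(tfield, plan.arrhenius)

    t_probes = probe_timeseries(tfield, probes, phantom)
    o_probes = probe_timeseries(dfield, probes, phantom)

    smap = surface_temperature_map(tfield, phantom, axis=plan.laser.axis, direction=plan.laser.direction)
    smax = np.nanmax(smap.reshape(len(tfield.times_s), -1), axis=1)
    d_t = smax - plan.thermal.t_init_C
    i_max = int(np.argmax(d_t))

    report = RunReport(
        scenario=plan.scenario,
        seed=plan.seed,
        max_surface_dT_K=float(d_t[i_max]),
        time_to_max_s=float(tfield.times_s[i_max]),
        max_T_C=float(np.nanmax(tfield.data_C)),
        max_omega=float(np.nanmax(dfield.omega[-1])),
        probe_final_T_C={k: float(t_probes[f"T_{k}"].iloc[-1]) for k in probes.names()},
        probe_final_omega={k: float(o_probes[f"Omega_{k}"].iloc[-1]) for k in probes.names()},
        fluence_max_W_cm2=float(fluence.u_W_cm2.max()),
        solver_diagnostics=dict(fluence.diagnostics),
        parameters=plan.resolved(),
    )

    fields = {
        "phantom": phantom,
        "fluence": fluence,
        "q_ext_W_m3": q_ext,
        "temperature": tfield,
        "damage": dfield,
        "probes": probes,
        "probe_T": t_probes,
        "probe_omega": o_probes,
        "surface_map": smap,
    }

    if outdir is not None:
        outdir = Path(outdir)
        if outdir.exists() and any(outdir.iterdir()):
            raise FileExistsError(f"refusing to overwrite non-empty run directory {outdir}")
        (outdir / "fields").mkdir(parents=True, exist_ok=True)
        (outdir / "probes").mkdir(parents=True, exist_ok=True)
        phantom.save(outdir / "fields")
        import nibabel as nib

        nib.save(nib.Nifti1Image(fluence.u_W_cm2.astype(np.float32), phantom.affine),
                 outdir / "fields" / "fluence.nii.gz")
        nib.save(nib.Nifti1Image(tfield.data_C[-1], phantom.affine),
                 outdir / "fields" / "temperature_final.nii.gz")
        nib.save(nib.Nifti1Image(dfield.omega[-1], phantom.affine),
                 outdir / "fields" / "damage_final.nii.gz")
        t_probes.to_csv(outdir / "probes" / "temperature.csv", index=False)
        o_probes.to_csv(outdir / "probes" / "damage.csv", index=False)
        report.to_json(outdir / "report.json")
    return report, fields


def surface_temperature_map(
    tfield: TemperatureField, phantom: Phantom, axis: int = 1, direction: int = -1
) -> np.ndarray:
    """Simulated IR-camera view: first-body-voxel temperature along each ray.

    Returns an array of shape (nt, n1, n2) over the two transverse axes;
    rays that never meet the body are NaN.  The image maximum at the last
    frame is the study's "hottest point on the surface".
    """
    if axis not in (0, 1, 2):
        raise ValueError("view axis must be 0, 1 or 2")
    if direction not in (-1, 1):
        raise ValueError("direction must be -1 or +1")
    body = tfield.mask
    arr = body if direction > 0 else np.flip(body, axis=axis)
    first = np.argmax(arr, axis=axis)
    has = body.any(axis=axis)
    n_ax = body.shape[axis]
    depth = first if direction > 0 else n_ax - 1 - first

    nt = len(tfield.times_s)
    idx_grid = np.indices(has.shape)
    out_shape = (nt,) + has.shape
    smap = np.full(out_shape, np.nan, dtype=np.float32)
    sel = [None, None, None]
    other = [a for a in range(3) if a != axis]
    sel[axis] = depth[has]
    sel[other[0]] = idx_grid[0][has]
    sel[other[1]] = idx_grid[1][has]
    for i in range(nt):
        frame = np.full(has.shape, np.nan, dtype=np.float32)
        frame[has] = tfield.data_C[i][tuple(sel)]
        smap[i] = frame
    return smap


def compare_to_measurement(sim: pd.DataFrame, measured: pd.DataFrame, sim_column: str | None = None) -> dict:
    """Residual summary between a simulated and a measured probe series.

    ``sim`` needs columns ``time_s`` and one temperature column (or name
    it with ``sim_column``); ``measured`` needs ``time_s`` and ``temp_C``
    (an ``sd_C`` column is carried through if present).  The simulation
    is interpolated onto the measurement times; positive bias means the
    simulation overestimates.
    """
    if sim_column is None:
        candidates = [c for c in sim.columns if c != "time_s"]
        if len(candidates) != 1:
            raise ValueError("ambiguous simulation column; pass sim_column")
        sim_column = candidates[0]
    t_sim = sim["time_s"].to_numpy()
    t_meas = measured["time_s"].to_numpy()
    lo, hi = max(t_sim.min(), t_meas.min()), min(t_sim.max(), t_meas.max())
    if hi <= lo:
        raise ValueError("simulation and measurement time ranges do not overlap")
    inside = (t_meas >= lo) & (t_meas <= hi)
    t = t_meas[inside]
    sim_on_meas = np.interp(t, t_sim, sim[sim_column].to_numpy())
    resid = sim_on_meas - measured["temp_C"].to_numpy()[inside]
    return {
        "bias_K": float(resid.mean()),
        "rmse_K": float(np.sqrt(np.mean(resid**2))),
        "max_abs_K": float(np.abs(resid).max()),
        "n_points": int(inside.sum()),
    }
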