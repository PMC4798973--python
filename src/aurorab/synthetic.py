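"""Seeded synthetic-data generators for every analysis stage.

Each generator runs the corresponding forward model and optionally applies
a noise model: multiplicative Gaussian of stated CV for fluorimetry-like
concentration data, additive Gaussian on normalized signals for FRET-like
fields.  Generators are pure functions of (configuration, seed); with
noise_cv = 0 the output is exactly the model curve.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np

from .autoactivation import simulate_progress_curve, simulate_uncoupled_activation
from .coupled import steady_state_scan
from .enzyme_kinetics import StandardCurve
from .fitting import ExperimentTable
from .params import OneSiteParams
from . import spatial as _spatial

DEFAULT_NOISE_CV = 0.02


def _mult_noise(values: np.ndarray, cv: float,
                rng: np.random.Generator) -> np.ndarray:
    if cv == 0:
        return values
    return values * (1.0 + cv * rng.standard_normal(values.shape))


def gen_progress_curves(
    params: OneSiteParams,
    concs: Sequence[float],
    S0: float,
    times: Sequence[float],
    noise_cv: float = DEFAULT_NOISE_CV,
    seed: int | None = None,
    standard_curve: StandardCurve | None = None,
) -> list[ExperimentTable]:
    """Noisy chemosensor progress curves at several kinase concentrations.

    With ``standard_curve`` the values are rendered as raw fluorescence
    (cps) through the two-slope calibration; otherwise they are product
    concentrations (µM).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    tables = []
    for A0 in concs:
        traj = simulate_progress_curve(params, A0, S0, float(times[-1]),
                                       sample_dt=1.0)
        P = np.interp(times, traj.times, traj["P"])
        values = (standard_curve.to_fluorescence(P, S0)
                  if standard_curve is not None else P)
        tables.append(ExperimentTable(
            times, _mult_noise(values, noise_cv, rng), "progress_curve",
            conditions={"A0": float(A0), "S0": float(S0)},
            name=f"progress_{A0:g}uM"))
    return tables


def gen_activation_timecourse(
    params: OneSiteParams,
    A0: float,
    times: Sequence[float],
    noise_cv: float = DEFAULT_NOISE_CV,
    seed: int | None = None,
    active_frac0: float = 0.0,
) -> ExperimentTable:
    """Noisy substrate-free activation time course (active kinase, µM)."""
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    traj = simulate_uncoupled_activation(params, A0, active_frac0,
                                         float(times[-1]), sample_dt=1.0)
    act = np.interp(times, traj.times, traj.active_kinase())
    return ExperimentTable(
        times, _mult_noise(act, noise_cv, rng), "activation",
        conditions={"A0": float(A0), "active_frac0": float(active_frac0)},
        name=f"activation_{A0:g}uM")


def gen_steady_state_scan(
    params: OneSiteParams,
    Atot: float,
    ppase_list: Sequence[float],
    init_labels: Sequence[str] = ("initially_high", "initially_low"),
    noise_cv: float = DEFAULT_NOISE_CV,
    seed: int | None = None,
    t_end: float = 5400.0,
) -> dict[str, np.ndarray]:
    """Steady-state active fraction vs phosphatase from both preparations."""
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {"ppase": np.asarray(ppase_list, float)}
    for init in init_labels:
        clean = steady_state_scan(params, Atot, ppase_list, init, t_end)
        out[init] = _mult_noise(clean, noise_cv, rng)
    return out


def gen_sensor_field(
    sp: "_spatial.SpatialParams",
    scenario: Literal["washout_wave", "hysteresis"],
    noise_cv: float = DEFAULT_NOISE_CV,
    seed: int | None = None,
    **overrides,
) -> dict:
    """Spatio-temporal chromatin-sensor datasets.

    'washout_wave' returns the normalized phosphorylation field P(x, t)/S0
    with additive Gaussian noise of SD ``noise_cv``, plus the clean field
    and the 50%-crossing analysis of the clean field.  'hysteresis'
    returns the two inhibitor-scan branches with the same noise model.
    """
    rng = np.random.default_rng(seed)
    if scenario == "washout_wave":
        profile = overrides.get("profile") or _spatial.generate_profile(
            "chromosome-arm", sp, grid_dx=sp.grid_dx)
        sub = overrides.get("substrate") or _spatial.SubstrateParams()
        Atot = overrides.get("Atotal") or _spatial.physiological_loading(profile)
        wave = _spatial.simulate_wave(
            sp, profile, sub, overrides.get("t_end", 30000.0), Atot,
            PPase_total=overrides.get("PPase_total", 0.012),
            n_samples=overrides.get("n_samples", 120))
        # per-position min-max normalization, as in FRET-ratio analysis
        clean = wave["P"] / np.maximum(wave["P"][-1], 1e-300)
        noisy = clean + (noise_cv * rng.standard_normal(clean.shape)
                         if noise_cv else 0.0)
        analysis = _spatial.half_max_time_profile(
            wave["P"], wave["times"], wave["positions"])
        return {"times": wave["times"], "positions": wave["positions"],
                "signal": noisy, "clean": clean, "t50_analysis": analysis}
    if scenario == "hysteresis":
        profile = overrides.get("profile") or _spatial.generate_profile(
            "centromere-axis", sp, grid_dx=0.05)
        Atot = overrides.get("Atotal") or _spatial.physiological_loading(profile)
        z = np.asarray(overrides.get("z_values",
                                     np.arange(0.0, 2.0001, 0.1)))
        scan = _spatial.cell_hysteresis_scan(
            sp, profile, overrides.get("PPase_total", 0.1), Atot, z,
            t_max=overrides.get("t_max", 1000.0))
        out = {"z": scan["z"]}
        for branch in ("added", "washout"):
            clean = scan[branch]
            out[branch + "_clean"] = clean
            out[branch] = clean + (noise_cv * rng.standard_normal(clean.shape)
                                   if noise_cv else 0.0)
        return out
    raise ValueError(f"unknown scenario {scenario!r}")
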