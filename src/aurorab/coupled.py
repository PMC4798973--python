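"""Steady-state and bistability analysis of the coupled kinase-phosphatase
system.

At steady state the two Michaelis complexes equilibrate exactly
([AA*] = A·A*/KMa, [A*PPase] = A*·PPase/KMp, using kf·KM = kr + kcat), and
the remaining activation/deactivation balance

    A·kcis + (kcata/KMa)·A·A*  =  (kcatp/KMp)·A*·PPase

together with the kinase and phosphatase conservation laws reduces the
whole system to a single explicit relation Ptot(A*): the total phosphatase
concentration at which a given free active-kinase level A* is stationary.
Steady states at a prescribed phosphatase total are the roots of
Ptot(A*) = Ptot; the system is bistable exactly where Ptot(A*) is
non-monotone (a fold), which gives sharp bistability windows and thresholds
without grid artifacts.  Stability is classified from the Jacobian
eigenvalues of the reduced 3-species dynamics; the dynamic-relaxation
oracle used in the tests is kept independent of this machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from .kinetics import (
    HomogeneousState,
    Trajectory,
    build_coupled_rhs,
    integrate_adaptive,
)
from .params import OneSiteParams

Stability = Literal["stable", "unstable"]

_ASTAR_GRID_N = 4000


class SteadyStateError(RuntimeError):
    """Raised when the root finder cannot resolve the steady-state set."""


def ppase_total_at_steady_state(
    params: OneSiteParams, Atot: float, astar: np.ndarray | float
) -> np.ndarray | float:
    """Total phosphatase making free active kinase ``astar`` stationary.

    Vectorized in ``astar``; valid for 0 < astar < Atot.  Returns NaN where
    no admissible (non-negative) phosphatase exists.
    """
    a = np.asarray(astar, dtype=float)
    alpha = params.kcis + params.kcata * a / params.KMa
    beta = params.kcatp * a / params.KMp
    gamma = 1.0 + 2.0 * a / params.KMa
    denom = gamma * beta + alpha * a / params.KMp
    with np.errstate(divide="ignore", invalid="ignore"):
        pp_free = alpha * (Atot - a) / denom
        ptot = pp_free * (1.0 + a / params.KMp)
    ptot = np.where((a <= 0) | (a >= Atot) | (pp_free < 0), np.nan, ptot)
    return float(ptot) if ptot.ndim == 0 else ptot


def _reconstruct_state(
    params: OneSiteParams, Atot: float, Ptot: float, astar: float
) -> HomogeneousState:
    Q = astar * Ptot / (params.KMp + astar)
    pp_free = Ptot - Q
    A = (Atot - astar - Q) / (1.0 + 2.0 * astar / params.KMa)
    C = A * astar / params.KMa
    return HomogeneousState(A=A, Astar=astar, AAstar=C, AstarPPase=Q,
                            PPase=pp_free)


def _reduced_rhs(params: OneSiteParams, Atot: float, Ptot: float
                 ) -> Callable[[np.ndarray], np.ndarray]:
    """RHS in the conservation-eliminated coordinates (A*, [AA*], [A*PPase])."""
    p = params

    def rhs(v: np.ndarray) -> np.ndarray:
        As, C, Q = v
        A = Atot - As - 2 * C - Q
        PP = Ptot - Q
        return np.array([
            A * p.kcis + C * (2 * p.kcata + p.kra) + Q * p.krp
            - As * A * p.kfa - As * PP * p.kfp,
            A * As * p.kfa - C * (p.kcata + p.kra),
            PP * As * p.kfp - Q * (p.krp + p.kcatp),
        ])

    return rhs


def _classify(params: OneSiteParams, Atot: float, Ptot: float,
              state: HomogeneousState) -> Stability:
    rhs = _reduced_rhs(params, Atot, Ptot)
    v0 = np.array([state.Astar, state.AAstar, state.AstarPPase])
    eps = 1e-9 * max(Atot, 1.0)
    J = np.empty((3, 3))
    for j in range(3):
        dv = np.zeros(3)
        dv[j] = eps
        J[:, j] = (rhs(v0 + dv) - rhs(v0 - dv)) / (2 * eps)
    lam = np.linalg.eigvals(J)
    return "stable" if np.all(lam.real < 0) else "unstable"


def find_steady_states(
    params: OneSiteParams, Atot: float, PPase_total: float
) -> list[tuple[HomogeneousState, Stability]]:
    """All steady states on the physical manifold, with stability labels.

    Roots of Ptot(A*) = ``PPase_total`` are bracketed on a dense A* grid and
    polished with Brent's method; the count is 1 or 3 for this system
    (saddle-node tangencies resolve as 1, the conservative choice).
    """
    if Atot < 0 or PPase_total < 0:
        raise ValueError("concentrations must be non-negative")
    if Atot == 0:
        return []
    if PPase_total == 0.0:
        # no deactivation pathway: everything ends up active
        state = _reconstruct_state(params, Atot, 0.0,
                                   _solve_no_ppase_astar(params, Atot))
        return [(state, "stable")]
    grid = np.linspace(Atot * 1e-9, Atot * (1 - 1e-9), _ASTAR_GRID_N)
    f = ppase_total_at_steady_state(params, Atot, grid) - PPase_total
    roots: list[float] = []
    sign = np.sign(f)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        try:
            r = brentq(
                lambda a: ppase_total_at_steady_state(params, Atot, a)
                - PPase_total,
                grid[i], grid[i + 1], xtol=1e-14, rtol=1e-14,
            )
        except (ValueError, RuntimeError) as exc:  # pragma: no cover
            raise SteadyStateError(
                f"unresolved bracket [{grid[i]:.6g}, {grid[i + 1]:.6g}]"
            ) from exc
        roots.append(float(r))
    out = []
    for r in roots:
        state = _reconstruct_state(params, Atot, PPase_total, r)
        out.append((state, _classify(params, Atot, PPase_total, state)))
    return out


def _solve_no_ppase_astar(params: OneSiteParams, Atot: float) -> float:
    # without phosphatase all kinase is eventually active: A = 0, [AA*] = 0
    return Atot


def bistable_ppase_interval(
    params: OneSiteParams, Atot: float
) -> tuple[float, float] | None:
    """Open interval of total phosphatase with three steady states, or None.

    Detected as the fold of Ptot(A*): the interval between the local
    minimum and local maximum of the steady-state relation.
    """
    grid = np.linspace(Atot * 1e-7, Atot * (1 - 1e-7), _ASTAR_GRID_N)
    ptot = ppase_total_at_steady_state(params, Atot, grid)
    ok = np.isfinite(ptot)
    g, p = grid[ok], ptot[ok]
    if g.size < 10:
        return None
    dp = np.diff(p)
    # Ptot(A*) falls from +inf at A*->0 to 0 at A*->Atot; a fold shows up as
    # an interior rising stretch
    rising = dp > 0
    if not np.any(rising):
        return None
    i0 = int(np.argmax(rising))                   # local minimum
    i1 = int(len(dp) - np.argmax(rising[::-1]))   # local maximum
    lo = float(np.min(p[i0:i1 + 1]))
    hi = float(np.max(p[i0:i1 + 1]))
    if hi <= lo:
        return None
    return (lo, hi)


def bistability_region(
    params: OneSiteParams,
    Atot_grid: Sequence[float],
    PPase_grid: Sequence[float],
) -> np.ndarray:
    """Boolean map (len(Atot_grid) x len(PPase_grid)): True where bistable."""
    Atot_grid = np.asarray(Atot_grid, dtype=float)
    PPase_grid = np.asarray(PPase_grid, dtype=float)
    if np.any(Atot_grid <= 0) or np.any(PPase_grid <= 0):
        raise ValueError("grids must be positive")
    if (np.any(np.diff(Atot_grid) <= 0) or np.any(np.diff(PPase_grid) <= 0)):
        raise ValueError("grids must be increasing")
    out = np.zeros((Atot_grid.size, PPase_grid.size), dtype=bool)
    for i, Atot in enumerate(Atot_grid):
        iv = bistable_ppase_interval(params, Atot)
        if iv is not None:
            out[i] = (PPase_grid > iv[0]) & (PPase_grid < iv[1])
    return out


def bistability_threshold(
    params: OneSiteParams,
    resolution: float = 0.02,
    Atot_lo: float = 0.5,
    Atot_hi: float = 20.0,
) -> float:
    """Minimal total kinase admitting three steady states for some PPase.

    Bisection of the fold predicate on total kinase down to ``resolution``
    (µM).  Raises if the bracket does not actually bracket the onset.
    """
    if resolution > 0.1:
        raise ValueError("resolution must be <= 0.1 µM")

    def bistable(Atot: float) -> bool:
        return bistable_ppase_interval(params, Atot) is not None

    lo, hi = Atot_lo, Atot_hi
    if bistable(lo) or not bistable(hi):
        raise SteadyStateError(
            f"bracket [{lo}, {hi}] µM does not bracket the bistability onset"
        )
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if bistable(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def active_fraction(state: HomogeneousState, Atot: float) -> float:
    """Fraction of total kinase that is active (free + complex-engaged A*)."""
    return state.active_kinase / Atot


@dataclass
class PulseResult:
    trajectory: Trajectory
    label: Literal["high", "low"]
    threshold_astar: float | None


def simulate_with_pulses(
    params: OneSiteParams,
    Atot: float,
    PPase_total: float,
    pulses: Sequence[tuple[float, float]],
    t_end: float,
    sample_dt: float = 10.0,
) -> PulseResult:
    """Perturbation protocol: relax from all-partially-active, then add
    active kinase instantaneously at the given times.

    Each pulse increments both A* and the total kinase (active enzyme is
    added to the mix).  The final label compares the final active
    concentration with the unstable steady state of the final composition.
    """
    times = [t for t, _ in pulses]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("pulses must be time-ordered")
    if times and (times[0] <= 0 or times[-1] >= t_end):
        raise ValueError("pulse times must lie inside (0, t_end)")

    rhs = build_coupled_rhs(params)
    y = HomogeneousState(A=Atot, PPase=PPase_total).to_array()
    seg_edges = [0.0] + list(times) + [t_end]
    all_t: list[np.ndarray] = []
    all_y: list[np.ndarray] = []
    added = 0.0
    for k, (t0, t1) in enumerate(zip(seg_edges[:-1], seg_edges[1:])):
        traj = integrate_adaptive(rhs, y, t1 - t0, sample_dt=sample_dt,
                                  conservation_tol=1e-5)
        sl = slice(1, None) if k else slice(None)
        all_t.append(traj.times[sl] + t0)
        all_y.append(traj.states[sl])
        y = traj.states[-1].copy()
        if k < len(pulses):
            y[1] += pulses[k][1]  # instantaneous addition of active kinase
            added += pulses[k][1]
    full = Trajectory(np.concatenate(all_t), np.vstack(all_y))
    full.totals = {}

    Atot_final = Atot + added
    states = find_steady_states(params, Atot_final, PPase_total)
    unstable = [s for s, lab in states if lab == "unstable"]
    final_active = HomogeneousState.from_array(full.states[-1]).active_kinase
    if unstable:
        thr = unstable[0].active_kinase
        label = "high" if final_active > thr else "low"
    else:
        thr = None
        label = "high" if final_active > 0.5 * Atot_final else "low"
    return PulseResult(trajectory=full, label=label, threshold_astar=thr)


def hysteresis_loop(
    params: OneSiteParams,
    Atot: float,
    ppase_max: float = 1.0,
    n_steps: int = 50,
    cycle_time: float = 7.2e3,
) -> dict[str, np.ndarray]:
    """Quasi-static phosphatase ramp up and back down.

    The phosphatase total is raised stepwise from 0 to ``ppase_max`` and
    back, integrating the coupled system for ``cycle_time/(2 n_steps)`` at
    each level while carrying the kinase state across steps.  The reference
    protocol equilibrates each step for hours (100 h per full cycle); the
    default here is a faster mode whose quasi-steadiness is validated by
    halving the ramp rate in the tests.

    Returns ``{"ppase", "up", "down"}``: active fraction on the rising and
    falling branches at each phosphatase level.
    """
    rhs = build_coupled_rhs(params)
    step_time = cycle_time / (2 * n_steps)
    levels = np.linspace(ppase_max / n_steps, ppase_max, n_steps)

    def run_branch(levels_ordered: np.ndarray, y: np.ndarray) -> np.ndarray:
        fracs = np.empty(levels_ordered.size)
        for i, ptot in enumerate(levels_ordered):
            y = y.copy()
            y[7] = max(ptot - y[4], 0.0)  # adjust free PPase to new total
            traj = integrate_adaptive(rhs, y, step_time, sample_dt=step_time,
                                      conservation_tol=1e-5)
            y = traj.states[-1]
            st = HomogeneousState.from_array(y)
            fracs[i] = st.active_kinase / Atot
        run_branch.last_state = y  # type: ignore[attr-defined]
        return fracs

    y0 = HomogeneousState(A=0.0, Astar=Atot).to_array()
    up = run_branch(levels, y0)
    down = run_branch(levels[::-1], run_branch.last_state)[::-1]
    return {"ppase": levels, "up": up, "down": down}


def steady_state_scan(
    params: OneSiteParams,
    Atot: float,
    ppase_list: Sequence[float],
    init: Literal["initially_high", "initially_low"],
    t_end: float = 5400.0,
    sample_dt: float = 60.0,
) -> np.ndarray:
    """Active fraction after ``t_end`` for each phosphatase concentration.

    'initially_high' starts from fully active kinase; 'initially_low' from
    fully dephosphorylated kinase with the full phosphatase present (the
    ATP-free preincubation read as a completed dephosphorylation).
    """
    if t_end < 3600.0:
        raise ValueError("t_end must be at least 3600 s")
    if init not in ("initially_high", "initially_low"):
        raise ValueError(f"unknown init {init!r}")
    rhs = build_coupled_rhs(params)
    fracs = np.empty(len(ppase_list))
    for i, ptot in enumerate(ppase_list):
        if init == "initially_high":
            y0 = HomogeneousState(Astar=Atot, PPase=ptot)
        else:
            y0 = HomogeneousState(A=Atot, PPase=ptot)
        traj = integrate_adaptive(rhs, y0, t_end, sample_dt=sample_dt,
                                  conservation_tol=1e-5)
        fracs[i] = traj.final_state.active_kinase / Atot
    return fracs
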