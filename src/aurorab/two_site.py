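"""Sequential two-phosphosite autoactivation model and its one-site limit.

The kinase carries two activation sites phosphorylated in order:
A (unphosphorylated, partially active) -> A# (one site, intermediate
activity) -> A## (both sites, fully active).  A converts to A# only in cis;
A# and A## phosphorylate A and A# in trans through Michaelis complexes;
both phosphorylated forms phosphorylate the chemosensor.  The optional
phosphatase branch dephosphorylates in reverse order (A## -> A# -> A).

With the A# -> A## conversion made fast the intermediate becomes a trace
species and the model collapses onto the one-site description; the
limiting-case constant set realizes that regime.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .kinetics import IntegrationError, Trajectory
from .params import OneSiteParams, TwoSiteParams
from scipy.integrate import solve_ivp

TWO_SITE_SPECIES: tuple[str, ...] = (
    "A", "Ah", "Ahh",
    "AAh", "AhAh", "AAhh", "AhAhh",   # kinase-kinase complexes
    "SAh", "SAhh",                    # sensor complexes
    "S", "P",
    "PPase", "AhPPase", "AhhPPase",
)
_I = {n: i for i, n in enumerate(TWO_SITE_SPECIES)}


def conserved_totals_two_site(y: np.ndarray) -> dict[str, float]:
    y = np.asarray(y, dtype=float)
    g = lambda n: y[_I[n]]
    kinase = (g("A") + g("Ah") + g("Ahh")
              + 2 * (g("AAh") + g("AhAh") + g("AAhh") + g("AhAhh"))
              + g("SAh") + g("SAhh") + g("AhPPase") + g("AhhPPase"))
    sensor = g("S") + g("P") + g("SAh") + g("SAhh")
    ppase = g("PPase") + g("AhPPase") + g("AhhPPase")
    return {"kinase": float(kinase), "sensor": float(sensor),
            "phosphatase": float(ppase)}


def build_two_site_rhs(params: TwoSiteParams):
    """Mass-action derivatives of the two-phosphosite system.

    Species order is :data:`TWO_SITE_SPECIES`.  Phosphatase reactions are included
    only when the parameter set carries phosphatase triples.
    """
    p = params
    with_pp = p.AhP is not None and p.AhhP is not None

    def rhs(y: np.ndarray) -> np.ndarray:
        if not np.all(np.isfinite(y)):
            raise IntegrationError(f"non-finite state encountered: {y}")
        (A, Ah, Ahh, C_AAh, C_AhAh, C_AAhh, C_AhAhh,
         C_SAh, C_SAhh, S, _P, PP, C_AhP, C_AhhP) = y
        d = np.zeros(14)

        def complex_step(i_sub, i_enz, i_cpx, tr, sub_conc, enz_conc, cpx):
            """Generic X + Y <-> [XY] -> product + Y bookkeeping (no product)."""
            v_on = sub_conc * enz_conc * tr.lf
            d[i_sub] += -v_on + cpx * tr.lr
            d[i_enz] += -v_on + cpx * (tr.lr + tr.lcat)
            d[i_cpx] += v_on - cpx * (tr.lr + tr.lcat)

        # cis: A -> A#
        d[_I["A"]] -= A * p.lcis
        d[_I["Ah"]] += A * p.lcis
        # A + A# -> 2 A#
        complex_step(_I["A"], _I["Ah"], _I["AAh"], p.AAh, A, Ah, C_AAh)
        d[_I["Ah"]] += C_AAh * p.AAh.lcat
        # A# + A# -> A## + A#
        complex_step(_I["Ah"], _I["Ah"], _I["AhAh"], p.AhAh, Ah, Ah, C_AhAh)
        d[_I["Ahh"]] += C_AhAh * p.AhAh.lcat
        # A + A## -> A# + A##
        complex_step(_I["A"], _I["Ahh"], _I["AAhh"], p.AAhh, A, Ahh, C_AAhh)
        d[_I["Ah"]] += C_AAhh * p.AAhh.lcat
        # A# + A## -> A## + A##
        complex_step(_I["Ah"], _I["Ahh"], _I["AhAhh"], p.AhAhh, Ah, Ahh, C_AhAhh)
        d[_I["Ahh"]] += C_AhAhh * p.AhAhh.lcat
        # S + A# -> P + A#; S + A## -> P + A##
        complex_step(_I["S"], _I["Ah"], _I["SAh"], p.SAh, S, Ah, C_SAh)
        d[_I["P"]] += C_SAh * p.SAh.lcat
        complex_step(_I["S"], _I["Ahh"], _I["SAhh"], p.SAhh, S, Ahh, C_SAhh)
        d[_I["P"]] += C_SAhh * p.SAhh.lcat
        if with_pp:
            # A# + PPase -> A + PPase (reverse-order dephosphorylation)
            complex_step(_I["Ah"], _I["PPase"], _I["AhPPase"], p.AhP,
                         Ah, PP, C_AhP)
            d[_I["A"]] += C_AhP * p.AhP.lcat
            # A## + PPase -> A# + PPase
            complex_step(_I["Ahh"], _I["PPase"], _I["AhhPPase"], p.AhhP,
                         Ahh, PP, C_AhhP)
            d[_I["Ah"]] += C_AhhP * p.AhhP.lcat
        return d

    return rhs


def simulate_two_site(
    params: TwoSiteParams,
    A0: float,
    S0: float,
    t_end: float,
    PPase_total: float = 0.0,
    active_frac0: float = 0.0,
    sample_dt: float = 1.0,
    rtol: float = 1e-8,
) -> Trajectory:
    """Integrate the two-site model from partially active kinase.

    ``active_frac0`` of the kinase starts in the fully phosphorylated A##
    form.  Returns a :class:`Trajectory` over :data:`TWO_SITE_SPECIES`.
    """
    y0 = np.zeros(14)
    y0[_I["A"]] = A0 * (1 - active_frac0)
    y0[_I["Ahh"]] = A0 * active_frac0
    y0[_I["S"]] = S0
    y0[_I["PPase"]] = PPase_total
    rhs = build_two_site_rhs(params)
    t_eval = np.arange(0.0, t_end + 0.5 * sample_dt, sample_dt)
    sol = solve_ivp(lambda _t, y: rhs(np.maximum(y, 0.0)), (0.0, t_end), y0,
                    method="LSODA", t_eval=t_eval, rtol=rtol, atol=1e-12)
    if not sol.success:
        raise IntegrationError(sol.message)
    states = sol.y.T.copy()
    states[(states < 0) & (states > -1e-8)] = 0.0
    traj = Trajectory(sol.t, states, TWO_SITE_SPECIES)
    traj.totals = conserved_totals_two_site(y0)
    traj.params = params
    return traj


def active_two_site(traj: Trajectory) -> np.ndarray:
    """Phosphorylated kinase (one or both sites), free plus complex-engaged."""
    return (traj["Ah"] + traj["Ahh"]
            + traj["AAh"] + traj["AAhh"]
            + 2 * (traj["AhAh"] + traj["AhAhh"])
            + traj["SAh"] + traj["SAhh"]
            + traj["AhPPase"] + traj["AhhPPase"])


def limiting_case_comparison(
    two_site: TwoSiteParams,
    one_site: OneSiteParams,
    scenarios: Iterable[dict] | None = None,
) -> list[dict]:
    """Compare two-site and one-site observables across scenarios.

    Each scenario is ``{"A0": µM, "S0": µM, "t_end": s}``; with S0 > 0 the
    observable is the product curve P(t), otherwise the active-kinase
    curve.  Defaults cover the three progress-curve concentrations and the
    4 µM substrate-free protocol.  Returns, per scenario, the maximum
    absolute discrepancy (µM) and the peak intermediate (A#) fraction.
    """
    from .autoactivation import (  # local import to avoid cycle
        simulate_progress_curve, simulate_uncoupled_activation)

    if scenarios is None:
        scenarios = [
            {"A0": 0.16, "S0": 20.0, "t_end": 3600.0},
            {"A0": 0.5, "S0": 20.0, "t_end": 3600.0},
            {"A0": 1.5, "S0": 20.0, "t_end": 3600.0},
            {"A0": 4.0, "S0": 0.0, "t_end": 6000.0},
        ]
    out = []
    for sc in scenarios:
        A0, S0, t_end = sc["A0"], sc["S0"], sc["t_end"]
        tr2 = simulate_two_site(two_site, A0, max(S0, 0.0), t_end)
        if S0 > 0:
            tr1 = simulate_progress_curve(one_site, A0, S0, t_end)
            obs2, obs1 = tr2["P"], tr1["P"]
        else:
            tr1 = simulate_uncoupled_activation(one_site, A0, 0.0, t_end)
            obs2, obs1 = active_two_site(tr2), tr1.active_kinase()
        n = min(obs1.size, obs2.size)
        # free A# plus every complex-engagement of A#
        inter = (tr2["Ah"] + tr2["AAh"] + 2 * tr2["AhAh"] + tr2["AhAhh"]
                 + tr2["SAh"] + tr2["AhPPase"])
        out.append({
            "A0": A0, "S0": S0, "t_end": t_end,
            "max_abs_discrepancy": float(np.max(np.abs(obs1[:n] - obs2[:n]))),
            "peak_intermediate_fraction": float(np.max(inter) / A0),
        })
    return out
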