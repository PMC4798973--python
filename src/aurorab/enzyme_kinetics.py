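"""Michaelis-Menten characterization utilities for the chemosensor assay.

Fluorescence traces (counts per second) are converted to product
concentration through linear standard curves for substrate and product;
initial rates are read from the sub-10%-conversion window; and (KM, Vmax)
are estimated by a direct nonlinear fit, with Lineweaver-Burk and
Hanes-Woolf linearizations reported as diagnostics only (they weight noise
pathologically and are never authoritative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress


@dataclass(frozen=True)
class StandardCurve:
    """Linear fluorescence-vs-concentration calibration.

    ``slope_substrate`` and ``slope_product`` are in cps/µM; phosphorylation
    increases the chemosensor fluorescence so the product slope must exceed
    the substrate slope.  Default slopes are the reference fluorimeter
    calibration (6520 and 15000 cps/µM); background defaults to 0.
    """

    slope_substrate: float = 6520.0
    slope_product: float = 15000.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.slope_substrate <= 0 or self.slope_product <= 0:
            raise ValueError("standard-curve slopes must be positive")
        if self.slope_product <= self.slope_substrate:
            raise ValueError(
                "product slope must exceed substrate slope "
                "(phosphorylation increases fluorescence)"
            )

    def to_fluorescence(self, P: np.ndarray | float, S_total: float) -> np.ndarray:
        """Total cps of a substrate/product mixture with product level P."""
        P = np.asarray(P, dtype=float)
        return (self.slope_substrate * (S_total - P)
                + self.slope_product * P + self.background)


def fluorescence_to_product(
    cps: Sequence[float], curve: StandardCurve, S_total: float
) -> np.ndarray:
    """Invert the two-component mixture F = s_S (S_tot - P) + s_P P for P.

    The result is clamped to [0, S_total] (round-off at the rails).
    """
    if S_total <= 0:
        raise ValueError("S_total must be positive")
    dslope = curve.slope_product - curve.slope_substrate
    cps = np.asarray(cps, dtype=float)
    P = (cps - curve.background - curve.slope_substrate * S_total) / dslope
    return np.clip(P, 0.0, S_total)


def initial_rate(
    times: Sequence[float],
    P: Sequence[float],
    S_total: float,
    max_conversion: float = 0.10,
) -> float:
    """Least-squares slope (µM/s) of P(t) below the conversion cap.

    The window is the initial-rate convention: samples with
    P < ``max_conversion``*S_total (default < 10% phosphorylation).
    """
    times = np.asarray(times, dtype=float)
    P = np.asarray(P, dtype=float)
    mask = P < max_conversion * S_total
    if mask.sum() < 5:
        raise ValueError(
            f"only {int(mask.sum())} points below the conversion cap (< 5)"
        )
    return float(linregress(times[mask], P[mask]).slope)


@dataclass(frozen=True)
class MMFit:
    """Michaelis-Menten fit with linearization diagnostics.

    ``diagnostics`` holds slope/intercept/R² of the Lineweaver-Burk
    (1/v vs 1/S) and Hanes-Woolf (S/v vs S) lines, plus the (KM, Vmax)
    each implies.
    """

    Vmax: float
    KM: float
    kcat: float
    enzyme: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def catalytic_efficiency(self) -> float:
        """kcat/KM in s^-1 µM^-1."""
        return self.kcat / self.KM


def fit_michaelis_menten(
    concs: Sequence[float], rates: Sequence[float], E: float
) -> MMFit:
    """Fit v = Vmax S / (KM + S) to initial rates at substrate levels S.

    ``E`` is the enzyme concentration (µM); kcat = Vmax/E.  Requires at
    least 4 substrate concentrations.  The direct nonlinear fit is
    authoritative; both linearizations are returned under ``diagnostics``.
    """
    concs = np.asarray(concs, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if concs.size < 4:
        raise ValueError("need at least 4 substrate concentrations")
    if np.any(rates <= 0) or np.any(concs <= 0):
        raise ValueError("rates and concentrations must be positive")

    def mm(S, Vmax, KM):
        return Vmax * S / (KM + S)

    p0 = (rates.max() * 2, np.median(concs))
    popt, _ = curve_fit(mm, concs, rates, p0=p0, maxfev=20000)
    Vmax, KM = map(float, popt)

    lb = linregress(1.0 / concs, 1.0 / rates)
    hw = linregress(concs, concs / rates)
    diagnostics = {
        "lineweaver_burk": {
            "slope": float(lb.slope), "intercept": float(lb.intercept),
            "r_squared": float(lb.rvalue ** 2),
            "Vmax": 1.0 / lb.intercept if lb.intercept != 0 else np.inf,
            "KM": lb.slope / lb.intercept if lb.intercept != 0 else np.inf,
        },
        "hanes_woolf": {
            "slope": float(hw.slope), "intercept": float(hw.intercept),
            "r_squared": float(hw.rvalue ** 2),
            "Vmax": 1.0 / hw.slope if hw.slope != 0 else np.inf,
            "KM": hw.intercept / hw.slope if hw.slope != 0 else np.inf,
        },
    }
    return MMFit(Vmax=Vmax, KM=KM, kcat=Vmax / E, enzyme=E,
                 diagnostics=diagnostics)
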