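"""Rate-constant containers for the Aurora B kinase-phosphatase models.

Units are fixed package-wide: concentrations in µM, time in s, space in µm.
Dissociation rates of Michaelis-Menten complexes are never stored
independently; they are recomputed from the (k_f, K_M, k_cat) triple via
k_r = k_f*K_M - k_cat, which keeps each triple internally consistent.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import yaml

#: relative tolerance allowed between an explicitly supplied dissociation
#: rate and the one implied by its (k_f, K_M, k_cat) triple
_DERIVED_RTOL = 1e-3


def _derived_kr(kf: float, KM: float, kcat: float, name: str) -> float:
    kr = kf * KM - kcat
    if kr < 0:
        raise ValueError(
            f"inconsistent Michaelis triple for {name}: "
            f"kf*KM - kcat = {kr:.3g} < 0"
        )
    return kr


def _check_explicit(explicit: Optional[float], derived: float, name: str) -> None:
    if explicit is None:
        return
    scale = max(abs(derived), 1e-300)
    if abs(explicit - derived) / scale > _DERIVED_RTOL:
        raise ValueError(
            f"explicit {name}={explicit!r} disagrees with derived value "
            f"{derived:.6g} beyond 1 part in 10^3"
        )


@dataclass(frozen=True)
class OneSiteParams:
    """Kinetic constants of the single-phosphosite Aurora B model.

    Parameters
    ----------
    kcat : float
        Catalytic rate of active kinase toward the chemosensor (s^-1).
    KM : float
        Michaelis constant toward the chemosensor (µM).
    kf : float
        Kinase-chemosensor association rate (µM^-1 s^-1).
    kfa : float
        Association rate of active with partially active kinase (µM^-1 s^-1).
    KMa : float
        Michaelis constant of active toward partially active kinase (µM).
    kcata : float
        Catalytic rate of the trans-activation reaction (s^-1).
    kcis : float
        First-order cis (intramolecular) activation rate (s^-1).
    kfp : float
        Phosphatase-kinase association rate (µM^-1 s^-1).
    KMp : float
        Phosphatase Michaelis constant toward active kinase (µM).
    kcatp : float
        Phosphatase catalytic rate (s^-1).

    The dissociation rates ``kr``, ``kra`` and ``krp`` are derived
    attributes.  They may be passed explicitly for round-trip serialization,
    in which case they must agree with the derived values to 0.1%.
    """

    kcat: float = 19.0
    KM: float = 320.0
    kf: float = 50.0
    kfa: float = 0.1
    KMa: float = 51.0
    kcata: float = 2.7e-2
    kcis: float = 7.29e-6
    kfp: float = 0.6
    KMp: float = 1.95
    kcatp: float = 2.4e-2
    kr: float = field(default=None, compare=False)  # type: ignore[assignment]
    kra: float = field(default=None, compare=False)  # type: ignore[assignment]
    krp: float = field(default=None, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None and v < 0:
                raise ValueError(f"{f.name} must be non-negative, got {v!r}")
        kr = _derived_kr(self.kf, self.KM, self.kcat, "chemosensor complex")
        kra = _derived_kr(self.kfa, self.KMa, self.kcata, "trans complex")
        krp = _derived_kr(self.kfp, self.KMp, self.kcatp, "phosphatase complex")
        _check_explicit(self.kr, kr, "kr")
        _check_explicit(self.kra, kra, "kra")
        _check_explicit(self.krp, krp, "krp")
        object.__setattr__(self, "kr", kr)
        object.__setattr__(self, "kra", kra)
        object.__setattr__(self, "krp", krp)

    # -- construction -----------------------------------------------------

    @classmethod
    def defaults(cls, sensor: str = "commercial") -> "OneSiteParams":
        """Reference constant set for the one-site model.

        ``sensor`` selects the chemosensor characterization: the commercial
        peptide (KM = 320 µM) or the custom-synthesized one (KM = 55 µM);
        kcat = 19 s^-1 for both.
        """
        if sensor == "commercial":
            return cls()
        if sensor == "custom":
            return cls(KM=55.0)
        raise ValueError(f"unknown sensor {sensor!r}")

    def replace(self, **changes) -> "OneSiteParams":
        """Return a copy with the given rate constants replaced."""
        for k in ("kr", "kra", "krp"):
            changes.setdefault(k, None)  # rederive
        return replace(self, **changes)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "OneSiteParams":
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "OneSiteParams":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "OneSiteParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class RateTriple:
    """(association, dissociation, catalytic) rates of one enzymatic step."""

    lf: float  # µM^-1 s^-1
    lr: float  # s^-1
    lcat: float  # s^-1

    def __post_init__(self) -> None:
        if min(self.lf, self.lr, self.lcat) < 0:
            raise ValueError("rate constants must be non-negative")

    @property
    def KM(self) -> float:
        return (self.lr + self.lcat) / self.lf


@dataclass(frozen=True)
class TwoSiteParams:
    """Constants of the sequential two-phosphosite autoactivation model.

    Species: A (unphosphorylated), A# (one site phosphorylated, intermediate
    activity) and A## (both sites, fully active).  Each enzyme-substrate pair
    carries a :class:`RateTriple`; complex names follow substrate-then-enzyme
    order (``AA#`` = substrate A, enzyme A#).
    """

    lcis: float
    AAh: RateTriple       # A + A#   -> A# + A#
    AhAh: RateTriple      # A# + A#  -> A## + A#
    AAhh: RateTriple      # A + A##  -> A# + A##
    AhAhh: RateTriple     # A# + A## -> A## + A##
    SAh: RateTriple       # S + A#   -> P + A#
    SAhh: RateTriple      # S + A##  -> P + A##
    AhP: Optional[RateTriple] = None   # A#  + PPase -> A  + PPase
    AhhP: Optional[RateTriple] = None  # A## + PPase -> A# + PPase

    def __post_init__(self) -> None:
        if self.lcis < 0:
            raise ValueError("lcis must be non-negative")

    @classmethod
    def fitted(cls, with_phosphatase: bool = False) -> "TwoSiteParams":
        """Unconstrained best-fit constant set (Table-3 'fitted' column)."""
        pp = RateTriple(0.6, 5.9, 0.12) if with_phosphatase else None
        return cls(
            lcis=6.0e-5,
            AAh=RateTriple(0.1, 10.0, 1.1e-2),
            AhAh=RateTriple(0.1, 10.0, 1.1e-2),
            AAhh=RateTriple(0.1, 9.8, 8.0e-2),
            AhAhh=RateTriple(0.1, 9.8, 8.0e-2),
            SAh=RateTriple(50.0, 1.6e4, 4.7),
            SAhh=RateTriple(50.0, 1.6e4, 19.0),
            AhP=pp,
            AhhP=pp,
        )

    @classmethod
    def limiting_case(cls, with_phosphatase: bool = False) -> "TwoSiteParams":
        """Rapid A#->A## conversion limit, matching the one-site constants."""
        pp = RateTriple(0.6, 5.9, 0.12) if with_phosphatase else None
        return cls(
            lcis=7.29e-6,
            AAh=RateTriple(0.1, 5.1, 3.9e-3),
            AhAh=RateTriple(50.0, 5.1, 1.95),
            AAhh=RateTriple(0.1, 5.1, 2.7e-2),
            AhAhh=RateTriple(0.1, 5.1, 2.7e-2),
            SAh=RateTriple(50.0, 1.6e4, 4.7),
            SAhh=RateTriple(50.0, 1.6e4, 19.0),
            AhP=pp,
            AhhP=pp,
        )

    def catalytic_ratio(self) -> float:
        """lcat(A·A##)/lcat(A·A#): ~7 for the fitted set (sequential model)."""
        return self.AAhh.lcat / self.AAh.lcat
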