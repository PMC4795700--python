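"""Kinetic parameter sets for the reversible GEF exchange cycle.

The exchange mechanism is a four-state enzyme cycle::

    E + G_GDP  <-k1/k2->  E.G_GDP  <-k3/k4[GDP]->  E.G
    E + G_GTP  <-k5/k6->  E.G_GTP  <-k7/k8[GTP]->  E.G

Forward (activating) traversal is E + G_GDP -> E.G_GDP -> E.G -> E.G_GTP
-> E + G_GTP, i.e. rates (k1, k3, k8*GTP, k6); the reverse traversal uses
(k5, k7, k4*GDP, k2).  Units are uM and seconds throughout: bimolecular
rates in 1/(uM*s), unimolecular rates in 1/s.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "KineticParameters",
    "NucleotidePools",
    "SystemTotals",
    "GTPaseSpec",
    "ValidationError",
    "validate",
    "kappa",
    "sample_params",
    "default_fixture",
    "bundle_to_dict",
    "bundle_from_dict",
]

RATE_FIELDS = ("k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8")


class ValidationError(ValueError):
    """Raised when a parameter bundle violates an invariant; names the field."""


@dataclass(frozen=True)
class KineticParameters:
    """The eight rate constants of the reversible exchange mechanism.

    k1: E + G_GDP association (1/(uM*s))
    k2: E.G_GDP dissociation (1/s)
    k3: GDP release from E.G_GDP (1/s)
    k4: GDP rebinding to E.G (1/(uM*s))
    k5: E + G_GTP association (1/(uM*s))
    k6: E.G_GTP dissociation (1/s)
    k7: GTP release from E.G_GTP (1/s)
    k8: GTP binding to E.G (1/(uM*s))
    """

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    k8: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in RATE_FIELDS], dtype=float)

    def replace(self, **kwargs) -> "KineticParameters":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class NucleotidePools:
    """Buffered free nucleotide concentrations (uM), constant in time."""

    gdp: float
    gtp: float


@dataclass(frozen=True)
class SystemTotals:
    """Conserved totals: e0 total GEF, g0 total G protein (uM)."""

    e0: float
    g0: float


@dataclass(frozen=True)
class GTPaseSpec:
    """Which hydrolysis flux applies to free GTP-bound G protein.

    mode="none"      -> flux 0
    mode="intrinsic" -> flux kase*[G_GTP]          (first order)
    mode="gap"       -> flux kase*[G_GTP]*f0/(km+[G_GTP])  (Michaelis-Menten)
    """

    mode: Literal["none", "intrinsic", "gap"] = "none"
    kase: float = 0.0
    km: float = 0.0
    f0: float = 0.0

    def __post_init__(self):
        if self.mode not in ("none", "intrinsic", "gap"):
            raise ValidationError(f"gtpase.mode: unknown mode {self.mode!r}")
        for name in ("kase", "km", "f0"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"gtpase.{name}: must be finite and >= 0, got {v}")
        if self.mode == "gap" and self.km <= 0:
            raise ValidationError("gtpase.km: must be > 0 in gap mode")


def validate(
    params: KineticParameters,
    pools: NucleotidePools,
    totals: SystemTotals,
) -> tuple[KineticParameters, NucleotidePools, SystemTotals]:
    """Check all invariants; return the bundle unchanged or raise ValidationError."""
    for name in RATE_FIELDS:
        v = getattr(params, name)
        if not np.isfinite(v) or v < 0:
            raise ValidationError(f"{name}: rate must be finite and >= 0, got {v}")
    for name in ("gdp", "gtp"):
        v = getattr(pools, name)
        if not np.isfinite(v) or v <= 0:
            raise ValidationError(f"{name}: pool must be finite and > 0, got {v}")
    for name in ("e0", "g0"):
        v = getattr(totals, name)
        if not np.isfinite(v) or v < 0:
            raise ValidationError(f"{name}: total must be finite and >= 0, got {v}")
    return params, pools, totals


def kappa(params: KineticParameters, pools: NucleotidePools) -> float:
    """Equilibrium ratio [G_GDP]/[G_GTP] imposed by the GEF alone.

    kappa = (k2*k4*k5*k7)/(k1*k3*k6*k8) * GDP/GTP — the product of the
    backward-path rates over the forward-path rates, times the nucleotide
    ratio.  Undefined (raises) when any forward rate is zero.
    """
    fwd = params.k1 * params.k3 * params.k6 * params.k8
    if fwd == 0:
        raise ZeroDivisionError(
            "kappa undefined: a forward rate (k1, k3, k6, k8) is zero"
        )
    bwd = params.k2 * params.k4 * params.k5 * params.k7
    return (bwd / fwd) * (pools.gdp / pools.gtp)


def sample_params(
    seed: int,
    log_range: tuple[float, float] = (1e-2, 1e2),
    pool_range: tuple[float, float] = (1.0, 1e3),
    e0: float = 0.1,
    g0_ratio: float = 100.0,
) -> tuple[KineticParameters, NucleotidePools, SystemTotals]:
    """Seeded log-uniform draw of a thermodynamically valid parameter bundle.

    Rates are drawn log-uniformly over ``log_range``, pools over
    ``pool_range``; totals default to basal e0 = 0.1 with g0 = g0_ratio*e0
    so that the enzyme is scarce relative to substrate (e0 << g0).
    """
    lo, hi = log_range
    if not (0 < lo < hi):
        raise ValidationError(f"log_range: need 0 < lo < hi, got {log_range}")
    rng = np.random.default_rng(seed)
    rates = np.exp(rng.uniform(np.log(lo), np.log(hi), size=8))
    pools_arr = np.exp(rng.uniform(np.log(pool_range[0]), np.log(pool_range[1]), size=2))
    params = KineticParameters(*rates)
    pools = NucleotidePools(gdp=float(pools_arr[0]), gtp=float(pools_arr[1]))
    totals = SystemTotals(e0=e0, g0=g0_ratio * e0)
    validate(params, pools, totals)
    return params, pools, totals


def default_fixture() -> tuple[KineticParameters, NucleotidePools, SystemTotals, GTPaseSpec]:
    """A documented stand-in parameter bundle in a Ran-like regime.

    The published rate constants for the Ran:RCC1:RanGAP1 system are not
    available here, so this fixture is an order-of-magnitude stand-in
    chosen to satisfy: enzyme scarce relative to substrate (e0 = 0.1 uM,
    g0 = 10 uM), an excess of GTP over GDP (10:1), fast catalysed GDP
    release, and a hydrolysis rate that visibly suppresses activation at
    basal GEF levels so the canonical stimulation protocol shows the
    expected responses.  Override from a config file for real systems.
    """
    params = KineticParameters(
        k1=1.0,   # 1/(uM*s) association of E with G_GDP
        k2=5.0,   # 1/s
        k3=20.0,  # 1/s catalysed GDP release
        k4=1.0,   # 1/(uM*s) GDP rebinding
        k5=1.0,   # 1/(uM*s) association of E with G_GTP
        k6=5.0,   # 1/s
        k7=10.0,  # 1/s catalysed GTP release
        k8=1.0,   # 1/(uM*s) GTP binding
    )
    pools = NucleotidePools(gdp=25.0, gtp=250.0)
    totals = SystemTotals(e0=0.1, g0=10.0)
    spec = GTPaseSpec(mode="intrinsic", kase=0.2)
    validate(params, pools, totals)
    return params, pools, totals, spec


def bundle_to_dict(
    params: KineticParameters,
    pools: NucleotidePools,
    totals: SystemTotals,
    spec: GTPaseSpec | None = None,
) -> dict:
    d = {f: getattr(params, f) for f in RATE_FIELDS}
    d.update(gdp=pools.gdp, gtp=pools.gtp, e0=totals.e0, g0=totals.g0)
    if spec is not None:
        d["gtpase.mode"] = spec.mode
        d["gtpase.kase"] = spec.kase
        d["gtpase.km"] = spec.km
        d["gtpase.f0"] = spec.f0
    return d


def bundle_from_dict(
    d: dict,
) -> tuple[KineticParameters, NucleotidePools, SystemTotals, GTPaseSpec]:
    missing = [f for f in RATE_FIELDS if f not in d]
    if missing:
        raise ValidationError(f"{missing[0]}: required rate missing")
    params = KineticParameters(**{f: float(d[f]) for f in RATE_FIELDS})
    pools = NucleotidePools(gdp=float(d.get("gdp", 25.0)), gtp=float(d.get("gtp", 250.0)))
    totals = SystemTotals(e0=float(d.get("e0", 0.1)), g0=float(d.get("g0", 10.0)))
    mode = d.get("gtpase.mode", "none")
    if mode == "gap" and "gtpase.km" not in d:
        raise ValidationError("gtpase.km: required in gap mode")
    spec = GTPaseSpec(
        mode=mode,
        kase=float(d.get("gtpase.kase", 0.0)),
        km=float(d.get("gtpase.km", 0.0)),
        f0=float(d.get("gtpase.f0", 0.0)),
    )
    validate(params, pools, totals)
    return params, pools, totals, spec


def save_bundle(path, params, pools, totals, spec=None) -> None:
    with open(path, "w") as fh:
        json.dump(bundle_to_dict(params, pools, totals, spec), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_bundle(path):
    with open(path) as fh:
        return bundle_from_dict(json.load(fh))
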