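"""Deterministic mass-action model of the reversible GEF exchange cycle.

Six species: free GEF ``e``, the three enzyme complexes ``e_gdp``,
``e_gtp``, ``e_g``, and the free G protein pools ``g_gdp``, ``g_gtp``.
Free nucleotide pools are buffered parameters, not species.  Hydrolysis
acts only on free GTP-bound G protein and returns mass to the GDP-bound
pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import GTPaseSpec, KineticParameters, NucleotidePools

__all__ = [
    "SystemState",
    "STATE_FIELDS",
    "gtpase_flux",
    "rhs",
    "rhs_clamped_substrates",
    "make_irreversible",
    "conserved_totals",
    "simulate",
]

STATE_FIELDS = ("e", "e_gdp", "e_gtp", "e_g", "g_gdp", "g_gtp")


@dataclass(frozen=True)
class SystemState:
    """Concentrations (uM) of the six dynamic species."""

    e: float
    e_gdp: float
    e_gtp: float
    e_g: float
    g_gdp: float
    g_gtp: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.e, self.e_gdp, self.e_gtp, self.e_g, self.g_gdp, self.g_gtp],
            dtype=float,
        )

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SystemState":
        return cls(*(float(v) for v in y))


def gtpase_flux(g_gtp: float, spec: GTPaseSpec) -> float:
    """Hydrolysis flux (uM/s) on free GTP-bound G protein."""
    if spec.mode == "none":
        return 0.0
    if spec.mode == "intrinsic":
        return spec.kase * g_gtp
    # gap: Michaelis-Menten in the substrate g_gtp, enzyme total f0
    denom = spec.km + g_gtp
    if denom == 0:
        raise ZeroDivisionError("gap flux degenerate: km + g_gtp = 0")
    return spec.kase * g_gtp * spec.f0 / denom


def rhs(
    y: np.ndarray,
    params: KineticParameters,
    pools: NucleotidePools,
    spec: GTPaseSpec,
) -> np.ndarray:
    """Time derivative of the six-species state vector.

    Both conserved totals (enzyme and G protein mass) have identically
    zero derivative by construction.
    """
    e, e_gdp, e_gtp, e_g, g_gdp, g_gtp = y
    k = params
    f = gtpase_flux(g_gtp, spec)
    de = -e * (k.k1 * g_gdp + k.k5 * g_gtp) + k.k2 * e_gdp + k.k6 * e_gtp
    de_gdp = -(k.k2 + k.k3) * e_gdp + k.k1 * g_gdp * e + k.k4 * e_g * pools.gdp
    de_gtp = -(k.k6 + k.k7) * e_gtp + k.k5 * g_gtp * e + k.k8 * e_g * pools.gtp
    de_g = -(k.k4 * pools.gdp + k.k8 * pools.gtp) * e_g + k.k3 * e_gdp + k.k7 * e_gtp
    dg_gdp = -k.k1 * e * g_gdp + k.k2 * e_gdp + f
    dg_gtp = -k.k5 * e * g_gtp + k.k6 * e_gtp - f
    return np.array([de, de_gdp, de_gtp, de_g, dg_gdp, dg_gtp])


def rhs_clamped_substrates(
    y4: np.ndarray,
    g_gdp: float,
    g_gtp: float,
    params: KineticParameters,
    pools: NucleotidePools,
) -> np.ndarray:
    """Derivative of the four enzyme species with free G protein clamped.

    Oracle for the quasi-steady-state occupancies: holding g_gdp and
    g_gtp fixed, the enzyme subsystem relaxes to the spanning-tree
    occupancy distribution.
    """
    e, e_gdp, e_gtp, e_g = y4
    full = np.array([e, e_gdp, e_gtp, e_g, g_gdp, g_gtp])
    return rhs(full, params, pools, GTPaseSpec(mode="none"))[:4]


def make_irreversible(params: KineticParameters) -> KineticParameters:
    """The artificial irreversible variant: GTP release from E.G_GTP disabled."""
    return params.replace(k7=0.0)


def conserved_totals(y: np.ndarray) -> tuple[float, float]:
    """(total enzyme, total G protein) linear invariants of the flow."""
    e, e_gdp, e_gtp, e_g, g_gdp, g_gtp = y
    return (
        float(e + e_gdp + e_gtp + e_g),
        float(g_gdp + g_gtp + e_gdp + e_gtp + e_g),
    )


def simulate(
    params: KineticParameters,
    pools: NucleotidePools,
    spec: GTPaseSpec,
    y0: np.ndarray,
    t_span: tuple[float, float],
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    method: str = "LSODA",
):
    """Integrate the full six-species model; returns the scipy solution object."""
    sol = solve_ivp(
        lambda t, y: rhs(y, params, pools, spec),
        t_span,
        np.asarray(y0, dtype=float),
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        method=method,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return sol
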