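"""Closed-form steady states of the reduced model, and a numeric oracle.

Without hydrolysis the steady-state free active G protein x = [G_GTP]
solves (kappa+1)*x^2 + 2*b*x - Ks*g0 = 0 with
b = (e0 - g0 + (kappa+1)*Ks)/2; with intrinsic hydrolysis it solves
(K2-K1)*x^2 + 2*bhat*x - kappa_hat*g0*e0 = 0 with
bhat = (K0 + K1*g0 + (kappa+1)*kappa_hat*e0)/2.  Both assume e0 << g0.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import root

from .mass_action import rhs, simulate
from .parameters import GTPaseSpec, KineticParameters, NucleotidePools, SystemTotals
from .qss import SummaryParameters

__all__ = [
    "max_active_fraction",
    "active_fraction_no_gtpase",
    "dgtp_db_sign",
    "active_fraction_intrinsic_gtpase",
    "numeric_steady_state",
]


def max_active_fraction(kappa: float) -> float:
    """Theoretical ceiling on the active proportion: 1/(kappa+1)."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    return 1.0 / (kappa + 1.0)


def _positive_quadratic_root(a: float, b_half: float, c_neg: float) -> float:
    """Positive root of a*x^2 + 2*b_half*x - c_neg = 0 (a, c_neg >= 0).

    Uses the cancellation-free branch: with disc = b^2 + a*c >= b^2 the
    product form c/(b + sqrt(disc)) is stable for b >= 0 and the sum form
    (-b + sqrt(disc))/a for b < 0.  Handles the degenerate linear case
    a = 0 as the limit c/(2b).
    """
    disc = b_half * b_half + a * c_neg
    if disc < 0:
        raise ValueError("negative discriminant: unphysical parameters")
    s = math.sqrt(disc)
    if b_half >= 0:
        denom = b_half + s
        if denom == 0:
            return 0.0
        return c_neg / denom
    if a == 0:
        raise ValueError("no positive root: a = 0 with b < 0")
    return (-b_half + s) / a


def active_fraction_no_gtpase(
    e0: float, g0: float, summary: SummaryParameters
) -> float:
    """Steady-state free [G_GTP]/g0 with no hydrolysis flux.

    Monotone decreasing in e0; tends to 1/(kappa+1) as e0 -> 0.
    """
    kap, Ks = summary.kappa, summary.Ks
    b = 0.5 * (e0 - g0 + (kap + 1.0) * Ks)
    x = _positive_quadratic_root(kap + 1.0, b, Ks * g0)
    return x / g0


def dgtp_db_sign(g0: float, summary: SummaryParameters, b: float) -> float:
    """d[G_GTP]/db along the no-hydrolysis steady-state branch; always < 0."""
    kap, Ks = summary.kappa, summary.Ks
    disc = b * b + (kap + 1.0) * Ks * g0
    return (b / math.sqrt(disc) - 1.0) / (kap + 1.0)


def active_fraction_intrinsic_gtpase(
    e0: float, g0: float, summary: SummaryParameters
) -> float:
    """Steady-state free [G_GTP]/g0 with first-order hydrolysis.

    The admissible root of the quadratic lies in [0, g0]; the K2 = K1
    degenerate case reduces to a linear equation and is handled by the
    same stable root form.  Requires kappa_hat (kfwd/kase) on ``summary``.
    """
    if summary.kappa_hat is None:
        raise ValueError("summary.kappa_hat undefined: need intrinsic hydrolysis spec")
    K0, K1, K2 = summary.K0, summary.K1, summary.K2
    kap, khat = summary.kappa, summary.kappa_hat
    bhat = 0.5 * (K0 + K1 * g0 + (kap + 1.0) * khat * e0)
    x = _positive_quadratic_root(K2 - K1, bhat, khat * g0 * e0)
    return min(max(x / g0, 0.0), 1.0)


def numeric_steady_state(
    params: KineticParameters,
    pools: NucleotidePools,
    totals: SystemTotals,
    spec: GTPaseSpec,
    y0: np.ndarray | None = None,
    horizon: float = 1e4,
    max_doublings: int = 12,
    tol_scale: float = 1e-10,
) -> np.ndarray:
    """Steady state of the full model by long integration plus root refinement.

    Integrates until the derivative is small, doubling the horizon as
    needed, then polishes with a Newton solve on the four-variable
    reduced system (conservation eliminates e and g_gdp, so the totals
    are preserved exactly).  Raises RuntimeError on non-convergence.
    """
    e0, g0 = totals.e0, totals.g0
    scale = max(e0, g0, 1e-30)
    if y0 is None:
        y0 = np.array([e0, 0.0, 0.0, 0.0, g0, 0.0])

    if e0 == 0:
        y = np.array(y0, dtype=float)
        if np.max(np.abs(rhs(y, params, pools, spec))) <= tol_scale * scale:
            return y
        # only hydrolysis can act; it drains g_gtp into g_gdp
        y_end = np.array([0.0, 0.0, 0.0, 0.0, g0, 0.0])
        return y_end

    def reduced(z: np.ndarray) -> np.ndarray:
        e_gdp, e_gtp, e_g, g_gtp = z
        e = e0 - e_gdp - e_gtp - e_g
        g_gdp = g0 - g_gtp - e_gdp - e_gtp - e_g
        y = np.array([e, e_gdp, e_gtp, e_g, g_gdp, g_gtp])
        d = rhs(y, params, pools, spec)
        return d[[1, 2, 3, 5]]

    t = horizon
    y = np.asarray(y0, dtype=float)
    last_residual = np.inf
    for _ in range(max_doublings):
        sol = simulate(params, pools, spec, y, (0.0, t))
        y = sol.y[:, -1]
        z = root(reduced, y[[1, 2, 3, 5]], method="hybr", tol=1e-13)
        if z.success:
            e_gdp, e_gtp, e_g, g_gtp = z.x
            cand = np.array([
                e0 - e_gdp - e_gtp - e_g,
                e_gdp, e_gtp, e_g,
                g0 - g_gtp - e_gdp - e_gtp - e_g,
                g_gtp,
            ])
            resid = np.max(np.abs(rhs(cand, params, pools, spec)))
            if resid <= tol_scale * scale and np.all(cand >= -1e-12 * scale):
                return np.clip(cand, 0.0, None)
            last_residual = resid
        t *= 2.0
    raise RuntimeError(
        f"steady state not converged: residual {last_residual:.3e} "
        f"after horizon {t:.3e}"
    )
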