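"""Scripted stimulation protocols and dose-response sweeps.

The canonical experiment: start at the basal steady state (e0 = 0.1),
step total GEF tenfold at t = 10, then at t = 20 remove free GEF until
the total returns to basal, observing to t = 30.  During simulation free
GEF is not integrated but computed algebraically from the enzyme
conservation law; removal is modelled as e = max(0, target - bound), so
the effective total declines continuously as complexes dissociate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import steady_state as ss
from .mass_action import STATE_FIELDS, gtpase_flux
from .parameters import GTPaseSpec, KineticParameters, NucleotidePools, SystemTotals

__all__ = [
    "StimulationProtocol",
    "TimeSeries",
    "canonical_protocol",
    "run_protocol",
    "fig2_suite",
    "fig3_sweep",
]


@dataclass(frozen=True)
class StimulationProtocol:
    """Piecewise-constant total-GEF schedule.

    segments: ordered (start_time, e0_level) pairs; the first start must
    be 0 and times strictly increase.  removal_phase: whether a downward
    step is realised by removing free GEF (clamp e to zero until bound
    mass decays to the target) rather than rejected as inconsistent.
    """

    segments: tuple = ((0.0, 0.1), (10.0, 1.0), (20.0, 0.1))
    removal_phase: bool = True
    t_end: float = 30.0
    n_points: int = 600

    def __post_init__(self):
        times = [s[0] for s in self.segments]
        if times[0] != 0.0 or any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("segment start times must begin at 0 and strictly increase")
        if any(s[1] < 0 for s in self.segments):
            raise ValueError("e0 levels must be >= 0")
        if self.t_end <= times[-1]:
            raise ValueError("t_end must exceed the last segment start")

    def grid(self) -> np.ndarray:
        return np.linspace(0.0, self.t_end, self.n_points)

    def level_at(self, t: float) -> float:
        lvl = self.segments[0][1]
        for start, e0 in self.segments:
            if t >= start:
                lvl = e0
        return lvl


@dataclass
class TimeSeries:
    """A simulated trajectory with provenance."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 6), columns per STATE_FIELDS
    protocol: StimulationProtocol | None = None
    meta: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_FIELDS))
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            for key, val in sorted(self.meta.items()):
                fh.write(f"# {key} = {val}\n")
            self.to_dataframe().to_csv(fh, index=False)

    def column(self, name: str) -> np.ndarray:
        return self.states[:, STATE_FIELDS.index(name)]


def canonical_protocol(
    basal: float = 0.1, stimulated: float = 1.0, t_end: float = 30.0, n_points: int = 600
) -> StimulationProtocol:
    return StimulationProtocol(
        segments=((0.0, basal), (10.0, stimulated), (20.0, basal)),
        removal_phase=True,
        t_end=t_end,
        n_points=n_points,
    )


def _rhs5(
    y5: np.ndarray,
    e0_level: float,
    params: KineticParameters,
    pools: NucleotidePools,
    spec: GTPaseSpec,
) -> np.ndarray:
    """Five-species derivative with free GEF computed from conservation."""
    e_gdp, e_gtp, e_g, g_gdp, g_gtp = y5
    e = max(0.0, e0_level - (e_gdp + e_gtp + e_g))
    k = params
    f = gtpase_flux(g_gtp, spec)
    de_gdp = -(k.k2 + k.k3) * e_gdp + k.k1 * g_gdp * e + k.k4 * e_g * pools.gdp
    de_gtp = -(k.k6 + k.k7) * e_gtp + k.k5 * g_gtp * e + k.k8 * e_g * pools.gtp
    de_g = -(k.k4 * pools.gdp + k.k8 * pools.gtp) * e_g + k.k3 * e_gdp + k.k7 * e_gtp
    dg_gdp = -k.k1 * e * g_gdp + k.k2 * e_gdp + f
    dg_gtp = -k.k5 * e * g_gtp + k.k6 * e_gtp - f
    return np.array([de_gdp, de_gtp, de_g, dg_gdp, dg_gtp])


def run_protocol(
    params: KineticParameters,
    pools: NucleotidePools,
    spec: GTPaseSpec,
    protocol: StimulationProtocol,
    g0: float | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> TimeSeries:
    """Integrate the protocol from the steady state of its first segment.

    The integrator restarts at every segment boundary so level switches
    are handled exactly.  Output lands on the protocol's uniform grid.
    """
    if g0 is None:
        g0 = 10.0 * max(s[1] for s in protocol.segments)
    e0_first = protocol.segments[0][1]
    y_ss = ss.numeric_steady_state(
        params, pools, SystemTotals(e0=e0_first, g0=g0), spec
    )
    y5 = y_ss[[1, 2, 3, 4, 5]]

    grid = protocol.grid()
    boundaries = [s[0] for s in protocol.segments[1:]] + [protocol.t_end]
    levels = [s[1] for s in protocol.segments]
    times_out, states_out = [], []
    t0 = 0.0
    for level, t1 in zip(levels, boundaries):
        bound = float(y5[0] + y5[1] + y5[2])
        if level < bound - 1e-12 and not protocol.removal_phase:
            raise ValueError(
                f"segment level e0={level} below bound complex mass {bound:.4g} "
                "and removal_phase is disabled"
            )
        mask = (grid >= t0) & (grid <= t1)
        t_eval = np.unique(np.concatenate([[t0], grid[mask], [t1]]))
        sol = solve_ivp(
            lambda t, y: _rhs5(y, level, params, pools, spec),
            (t0, t1),
            y5,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
            method="LSODA",
        )
        if not sol.success:
            raise RuntimeError(f"integration failed in segment at t={t0}: {sol.message}")
        for i, t in enumerate(sol.t):
            if t in grid[mask] and (not times_out or t > times_out[-1]):
                y = sol.y[:, i]
                e = max(0.0, level - (y[0] + y[1] + y[2]))
                times_out.append(t)
                states_out.append([e, *y])
        y5 = sol.y[:, -1]
        t0 = t1

    return TimeSeries(
        times=np.array(times_out),
        states=np.array(states_out),
        protocol=protocol,
        meta={"g0": g0, "gtpase_mode": spec.mode},
    )


def _classify(series: TimeSeries, protocol: StimulationProtocol, g0: float) -> str:
    """Direction of free active G protein change over the stimulated window."""
    t_on, t_off = protocol.segments[1][0], protocol.segments[2][0]
    g_gtp = series.column("g_gtp")
    on = np.searchsorted(series.times, t_on)
    off = np.searchsorted(series.times, t_off) - 1
    delta = g_gtp[off] - g_gtp[on]
    thresh = 1e-6 * g0
    if delta > thresh:
        return "activated"
    if delta < -thresh:
        return "inhibited"
    return "unchanged"


def fig2_suite(
    params: KineticParameters,
    pools: NucleotidePools,
    gtpase_intrinsic: GTPaseSpec,
    gtpase_gap: GTPaseSpec,
    g0: float = 10.0,
    protocol: StimulationProtocol | None = None,
) -> dict:
    """The six canonical stimulation runs: {reversible, irreversible} x
    {none, intrinsic, gap} hydrolysis.  Returns per-panel TimeSeries and a
    qualitative classification of the stimulated-window response.
    """
    from .mass_action import make_irreversible

    if protocol is None:
        protocol = canonical_protocol()
    variants = {
        "irreversible": make_irreversible(params),
        "reversible": params,
    }
    specs = {
        "none": GTPaseSpec(mode="none"),
        "intrinsic": gtpase_intrinsic,
        "gap": gtpase_gap,
    }
    out = {}
    for vname, vparams in variants.items():
        for sname, spec in specs.items():
            series = run_protocol(vparams, pools, spec, protocol, g0=g0)
            out[(vname, sname)] = {
                "series": series,
                "classification": _classify(series, protocol, g0),
            }
    return out


def fig3_sweep(
    params: KineticParameters,
    pools: NucleotidePools,
    mode: str,
    grid: np.ndarray,
    g0: float = 10.0,
    kase: float = 0.2,
    numeric: bool = True,
) -> pd.DataFrame:
    """Steady-state active fraction versus total GEF concentration.

    mode="no_gtpase": analytic fraction from the no-hydrolysis quadratic;
    mode="intrinsic": from the hydrolysis quadratic, with the abscissa
    also reported as kappa_hat*e0.  Numeric columns recompute each point
    from the full mass-action model.
    """
    from .qss import summary_params

    if mode not in ("no_gtpase", "intrinsic"):
        raise ValueError(f"unknown sweep mode {mode!r}")
    spec = (
        GTPaseSpec(mode="none")
        if mode == "no_gtpase"
        else GTPaseSpec(mode="intrinsic", kase=kase)
    )
    summary = summary_params(params, pools, spec)
    rows = []
    for e0 in np.asarray(grid, dtype=float):
        if mode == "no_gtpase":
            frac = ss.active_fraction_no_gtpase(e0, g0, summary)
        else:
            frac = ss.active_fraction_intrinsic_gtpase(e0, g0, summary)
        row = {"e0": e0, "analytic_fraction": frac}
        if summary.kappa_hat is not None:
            row["kappa_hat_e0"] = summary.kappa_hat * e0
        if numeric:
            y = ss.numeric_steady_state(
                params, pools, SystemTotals(e0=e0, g0=g0), spec
            )
            row["numeric_fraction"] = y[5] / g0
            row["complex_total"] = y[1] + y[2] + y[3]
        rows.append(row)
    return pd.DataFrame(rows)
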