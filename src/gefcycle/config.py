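"""Flat-key JSON run configuration and the invariant-check runner."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import parameters as pm
from .mass_action import conserved_totals, rhs, simulate
from .parameters import (
    GTPaseSpec,
    KineticParameters,
    NucleotidePools,
    SystemTotals,
    ValidationError,
)

__all__ = ["RunConfig", "load_config", "save_config", "check"]

_KNOWN_KEYS = set(pm.RATE_FIELDS) | {
    "gdp", "gtp", "e0", "g0",
    "gtpase.mode", "gtpase.kase", "gtpase.km", "gtpase.f0",
    "rtol", "atol", "seed",
    "protocol.basal", "protocol.stimulated", "protocol.t_end", "protocol.n_points",
}

_DEFAULTS = {
    "gdp": 25.0, "gtp": 250.0, "e0": 0.1, "g0": 10.0,
    "gtpase.mode": "none", "gtpase.kase": 0.0, "gtpase.km": 0.0, "gtpase.f0": 0.0,
    "rtol": 1e-9, "atol": 1e-12, "seed": 0,
    "protocol.basal": 0.1, "protocol.stimulated": 1.0,
    "protocol.t_end": 30.0, "protocol.n_points": 600,
}


@dataclass(frozen=True)
class RunConfig:
    params: KineticParameters
    pools: NucleotidePools
    totals: SystemTotals
    gtpase: GTPaseSpec
    rtol: float = 1e-9
    atol: float = 1e-12
    seed: int = 0
    protocol_basal: float = 0.1
    protocol_stimulated: float = 1.0
    protocol_t_end: float = 30.0
    protocol_n_points: int = 600
    raw: dict = field(default_factory=dict, compare=False)

    def to_dict(self) -> dict:
        d = pm.bundle_to_dict(self.params, self.pools, self.totals, self.gtpase)
        d.update(
            rtol=self.rtol, atol=self.atol, seed=self.seed,
            **{
                "protocol.basal": self.protocol_basal,
                "protocol.stimulated": self.protocol_stimulated,
                "protocol.t_end": self.protocol_t_end,
                "protocol.n_points": self.protocol_n_points,
            },
        )
        return d


def _from_dict(d: dict) -> RunConfig:
    unknown = sorted(set(d) - _KNOWN_KEYS)
    if unknown:
        raise ValidationError(f"{unknown[0]}: unknown config key")
    merged = {**_DEFAULTS, **d}
    params, pools, totals, spec = pm.bundle_from_dict(merged)
    return RunConfig(
        params=params, pools=pools, totals=totals, gtpase=spec,
        rtol=float(merged["rtol"]), atol=float(merged["atol"]),
        seed=int(merged["seed"]),
        protocol_basal=float(merged["protocol.basal"]),
        protocol_stimulated=float(merged["protocol.stimulated"]),
        protocol_t_end=float(merged["protocol.t_end"]),
        protocol_n_points=int(merged["protocol.n_points"]),
        raw=dict(d),
    )


def load_config(path) -> RunConfig:
    """Load and fully validate a flat-key JSON config, filling defaults."""
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"config not parseable as JSON: {exc}") from exc
    if not isinstance(d, dict):
        raise ValidationError("config must be a JSON object")
    return _from_dict(d)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def check(cfg: RunConfig, rhs_fn=None) -> dict:
    """Run the cross-module invariant suite; returns a machine-readable report.

    rhs_fn is a test-only hook replacing the mass-action derivative (used
    as a negative control for the conservation probe).
    """
    from .qss import summary_params, qss_rhs
    from .steady_state import numeric_steady_state

    if rhs_fn is None:
        rhs_fn = rhs
    report = {}
    params, pools, totals, spec = cfg.params, cfg.pools, cfg.totals, cfg.gtpase
    e0, g0 = totals.e0, totals.g0

    # conservation along a trajectory from a lopsided start
    y0 = np.array([e0, 0.0, 0.0, 0.0, 0.3 * g0, 0.7 * g0])
    sol = simulate(params, pools, spec, y0, (0.0, 30.0),
                   t_eval=np.linspace(0, 30, 61), rtol=cfg.rtol, atol=cfg.atol)
    drift = 0.0
    for i in range(sol.y.shape[1]):
        te, tg = conserved_totals(sol.y[:, i])
        drift = max(drift, abs(te - e0) / max(e0, 1e-30), abs(tg - g0) / g0)
    report["conservation_drift"] = {"value": drift, "pass": bool(drift <= 1e-8)}

    # rhs annihilates the conservation gradients (symbolic cancellation probe)
    rng = np.random.default_rng(cfg.seed)
    worst = 0.0
    for _ in range(20):
        y = rng.uniform(0, 1, size=6)
        d = rhs_fn(y, params, pools, spec)
        worst = max(worst, abs(d[0] + d[1] + d[2] + d[3]),
                    abs(d[4] + d[5] + d[1] + d[2] + d[3]))
    report["rhs_conservation"] = {"value": worst, "pass": bool(worst <= 1e-12)}

    # detailed balance: exchange equilibrium hits the kappa ratio
    fwd = params.k1 * params.k3 * params.k6 * params.k8
    bwd = params.k2 * params.k4 * params.k5 * params.k7
    if fwd == 0 or bwd == 0:
        report["detailed_balance"] = {
            "value": None, "pass": None,
            "note": "not applicable: kappa undefined or zero (an exchange rate is 0)"}
    else:
        kap = pm.kappa(params, pools)
        y_eq = numeric_steady_state(params, pools, totals, GTPaseSpec(mode="none"))
        rel = abs(y_eq[4] / y_eq[5] - kap) / kap
        report["detailed_balance"] = {"value": rel, "pass": bool(rel <= 1e-6)}

        # reduced model steady state consistent with the full model
        summary = summary_params(params, pools, spec)
        resid = qss_rhs(y_eq[4], y_eq[5], e0, summary, GTPaseSpec(mode="none"))
        scale = summary.kfwd * g0 * e0 / summary.K0
        report["qss_consistency"] = {
            "value": abs(resid) / scale, "pass": bool(abs(resid) / scale <= 1e-6)}

    report["all_pass"] = all(
        v["pass"] for v in report.values()
        if isinstance(v, dict) and v["pass"] is not None
    )
    return report
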