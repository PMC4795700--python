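# gefcycle

Deterministic kinetics of the reversible GEF-catalysed guanine-nucleotide
exchange cycle on G proteins, with pluggable GTPase (hydrolysis) activity:

- **`gefcycle.parameters`** — kinetic parameter bundles (eight exchange
  rates, buffered GDP/GTP pools, conserved totals), validation, JSON
  serialisation, a seeded synthetic generator, and the equilibrium
  constant κ = (k2·k4·k5·k7)/(k1·k3·k6·k8) · [GDP]/[GTP].
- **`gefcycle.mass_action`** — the full six-species mass-action ODE model
  (free GEF, three GEF·G complexes, free GDP-/GTP-bound G protein), with
  hydrolysis acting on free GTP-bound G protein as none / first-order /
  Michaelis–Menten (GAP) flux, and an artificial irreversible variant
  (k7 = 0).
- **`gefcycle.qss`** — a directed-spanning-tree (King–Altman) engine that
  derives the enzyme-complex occupancies symbolically and reduces the
  system to a single ODE, d[G_GTP]/dt = kfwd([G_GDP] − κ[G_GTP])e0 /
  (K0 + K1[G_GDP] + K2[G_GTP]) − f_hydrolysis.
- **`gefcycle.steady_state`** — closed-form steady states: the maximum
  active fraction 1/(κ+1), the no-hydrolysis quadratic (active fraction
  monotone *decreasing* in total GEF), the intrinsic-hydrolysis quadratic
  (fraction monotone increasing in κ̂·e0, κ̂ = kfwd/kase), and a numeric
  steady-state solver (long integration + root refinement).
- **`gefcycle.protocol`** — scripted stimulation experiments (basal →
  10× GEF step → free-GEF removal back to basal) and dose–response
  sweeps, with CSV export.
- **`gefcycle.config` / `gefcycle.cli`** — flat-key JSON configs and the
  `gefcycle` command line.

Units are µM and seconds throughout. The bundled default parameter set is
an explicitly documented stand-in in a Ran-like regime (enzyme scarce,
GTP in excess), not literature values.

## CLI

All subcommands take a flat JSON config (`k1`…`k8`, `gdp`, `gtp`, `e0`,
`g0`, `gtpase.mode|kase|km|f0`, `rtol`, `atol`, `seed`, `protocol.*`;
only the rates are required — everything else defaults).

```sh
gefcycle params --generate 42 --out params.json   # seeded synthetic bundle
gefcycle params --validate config.json
gefcycle reduce --config config.json              # summary constants as JSON
gefcycle simulate --config config.json --variant reversible --gtpase intrinsic --out run.csv
gefcycle fig2 --config config.json --outdir panels/   # all six protocol variants
gefcycle sweep --config config.json --mode no_gtpase --grid 1e-3:10:20 --out sweep.csv
gefcycle check --config config.json               # invariant report, exit 0/1
```

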