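"""Run the five model scenarios and summarize their population dynamics.

The full model couples size-dependent fecundity (favouring large flies)
with density-dependent non-breeding survival (favouring small flies at
high density) plus delayed density dependence.  Each variant removes one
ingredient; the summary shows which ingredients are needed for sustained
multigenerational cycles.
"""

import ecocycles as ec


def cycling(series, burn_in=3):
    acf = ec.autocorrelation(ec.detrend_series(series, burn_in=burn_in))
    return ec.classify_cycling(acf)


scenarios = [
    ec.Scenario("full", n_generations=40),
    ec.Scenario("low_h2", n_generations=40),
    ec.Scenario("no_delay", n_generations=40),
    ec.Scenario("no_viability", n_generations=40),
    ec.Scenario("stop_selection", n_generations=60, switch_generation=40),
]

print(f"{'scenario':<22}{'crash gen':>10}{'cycling':>9}{'period':>8}{'final N':>9}")
for sc in scenarios:
    traj = ec.run_scenario(sc)
    series = traj.X0 if sc.name != "stop_selection" else traj.X0[40:]
    if traj.crashed:
        crash, cyc, period = traj.crash_generation, "-", "-"
    else:
        res = cycling(series)
        crash, cyc = "-", str(res.cycling)
        period = res.period_estimate if res.cycling else "-"
    final = "-" if traj.crashed else f"{traj.X0[-1]:.0f}"
    label = sc.name + (" (tail)" if sc.name == "stop_selection" else "")
    print(f"{label:<22}{str(crash):>10}{cyc:>9}{str(period):>8}{final:>9}")

print(
    "\nCycling requires both viability selection and delayed density"
    "\ndependence; removing only viability selection destabilizes the"
    "\npopulation until it crashes, and near-zero heritability does not"
    "\nprevent cycles (selection reshapes the size distribution within"
    "\neach generation)."
)
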