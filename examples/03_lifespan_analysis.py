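"""Kaplan-Meier lifespan analysis of the TDP-43 proteinopathy cohorts.

Generates synthetic alternate-day-scored survival data calibrated to the
published group means (DMSO vehicle 11.51 d, 0.05 mM MPS 14.37 d, ...),
summarises each cohort over uncensored deaths, and compares MPS to vehicle
with the log-rank test.  The daf-16 null scenario shows the effect collapse.
"""
from wormlead import lifespan as ls
from wormlead import synthgen as sg

for label, scenario in (
    ("TDP-43", sg.LifespanScenario()),
    ("TDP-43; daf-16 null", sg.daf16_lifespan_scenario()),
):
    records = sg.gen_lifespans(scenario, seed=17)
    print(f"--- {label} ---")
    for group in scenario.groups:
        grp = [r for r in records if r.group == group]
        s = ls.mean_lifespan(grp)
        print(f"{group:>13s}: {s.mean_days:5.2f} +- {s.sem:.2f} d "
              f"(n = {s.n_deaths} deaths, {s.n_censored} censored)")
    dmso = [r for r in records if r.group == "DMSO"]
    mps = [r for r in records if r.group == "MPS"]
    chi2, p = ls.logrank(dmso, mps)
    pct = ls.percent_change(
        ls.mean_lifespan(dmso).mean_days, ls.mean_lifespan(mps).mean_days
    )
    print(f"  MPS vs DMSO: {pct:+.1f}% mean lifespan, log-rank chi2 = {chi2:.1f}, p = {p:.2g}")
    print()
# In the TDP-43 background MPS extends mean lifespan by about 25% (p < .05);
# with daf-16 deleted the change is a few percent and not significant.
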