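"""Fit seizure concentration-response curves and compare potencies.

Simulates the PTZ head-bobbing assay for ethosuximide (truth EC50 9.7 mM)
and MPS (truth about half that), summarises per-concentration seizure rates,
fits the variable-slope 4PL to mean head-bob counts, and runs the
extra-sum-of-squares test on the two log EC50 values.
"""
import numpy as np

from wormlead import seizure as sz
from wormlead import synthgen as sg

data = sg.gen_seizure(sg.SeizureScenario(), seed=17)
summary = sz.summarise(data)
print(summary[summary.compound_id.isin(["vehicle", "cpd1"])].round(2).to_string(index=False))

vehicle = summary[summary.conc_molar == 0]
fits = {}
for cid in ("cpd1", "cpd9"):
    drug = summary[summary.compound_id == cid]
    fit = sz.fit_4pl(
        np.concatenate([vehicle.conc_molar, drug.conc_molar]),
        np.concatenate([vehicle.mean_bobs, drug.mean_bobs]),
    )
    fits[cid] = fit
    lo, hi = fit.ci_log_ec50
    print(f"{cid}: EC50 = {fit.ec50 * 1e3:.2f} mM (95% CI {10**lo*1e3:.2f}-{10**hi*1e3:.2f}), "
          f"hill = {fit.hill:.2f}")

a = data[data.compound_id == "cpd1"]
b = data[data.compound_id == "cpd9"]
fold, F, p = sz.compare_log_ec50(
    (a.conc_molar.to_numpy(), a.head_bobs.to_numpy()),
    (b.conc_molar.to_numpy(), b.head_bobs.to_numpy()),
)
# fold < 1 means the second compound (MPS) is more potent; the generating
# truth is a 2-fold potency advantage.
print(f"MPS vs ethosuximide: fold change {fold:.2f}, F = {F:.1f}, p = {p:.2g}")
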