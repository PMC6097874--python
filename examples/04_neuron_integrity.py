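"""Quantify GABAergic D-type motor neuron damage and drug protection.

The 19 cell bodies (13 VD + 6 DD) along the ventral nerve cord are scored
per worm together with process breaks.  Wild type stays essentially intact
through day 7; the TDP-43 background loses bodies and accrues breaks from
day 1; MPS and ethosuximide reduce both.  Groups are compared per age with
Kruskal-Wallis + Dunn's test against the vehicle control.
"""
from wormlead import synthgen as sg
from wormlead import wormstats as ws

frame = sg.gen_neurons(sg.NeuronScenario(), seed=17)
deltas = ws.integrity_deltas(frame, reference_group="TDP43_DMSO")
print(deltas.round(2).to_string(index=False))
print()
# negative break_excess = fewer breaks than the DMSO vehicle (protection)

day5 = frame[frame.age_day == 5]
groups = {g: grp.breaks.to_numpy() for g, grp in day5.groupby("group")}
H, p = ws.kruskal_wallis(*groups.values())
print(f"day-5 breaks, Kruskal-Wallis: H = {H:.1f}, p = {p:.2g}")
dunn = ws.dunns_pairwise(groups, comparisons="control", control="TDP43_DMSO")
print(dunn.round(4).to_string(index=False))
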