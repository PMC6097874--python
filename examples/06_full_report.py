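"""Run the whole desk-scale pipeline with one seed and print the checks.

Equivalent to `wormlead report --seed 17 --out wormlead_report`; the report
bundles compound ranking, seizure potency fits, phenotype statistics,
lifespan comparisons and NMR quantification, plus a pass/fail check table
for the headline numbers (160-fold potency gap, perfect MPO score of 6,
about +25% lifespan extension, exact NMR round trip, MPS occlusion).
"""
import json

from wormlead.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=17, outdir="wormlead_report"))
print(json.dumps(report["checks"], indent=2, sort_keys=True))
print()
print(f"potency fold: {report['potency']['fold']:.0f}x")
print(f"MPO range over library: {report['prioritisation']['min_mpo']:.2f}"
      f" - {report['prioritisation']['max_mpo']:.2f}")
pct = report["lifespan"]["tdp43"]["mps_vs_dmso"]["percent_change"]
print(f"MPS lifespan extension: {pct:+.1f}%")
print("full report written to wormlead_report/report.json")
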