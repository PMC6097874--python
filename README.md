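# wormlead

A desk-scale Python toolkit for the computational path from an antiepileptic
scaffold to a more potent neuroprotective lead in *Caenorhabditis elegans*:
chemoinformatic prioritisation of succinimide-like compounds, quantitative
analysis of PTZ-seizure, locomotion, lifespan and GABAergic-neuron-integrity
screens, and NMR-based quantification of internal drug concentration.  A
seeded synthetic-data module generates every assay table the analysis
consumes, calibrated to the published summary statistics, so the whole
pipeline is testable without animals or a spectrometer.

It is written for computational biologists and medicinal-chemistry-adjacent
scientists who want the analysis layer of such a screen as an importable,
reproducible library.

## What it computes

**Compound prioritisation.** Compounds are held as canonical SMILES (RDKit).
Candidates are filtered on predicted aqueous solubility (retain LogS ≥ −4.5),
then scored on three objectives and Pareto-sorted maximising all three:

- **CNS MPO** — the six-attribute desirability sum
  T = Σᵢ dᵢ ∈ [0, 6] over cLogP, cLogD₇.₄, MW, TPSA, HBD and pKa of the most
  basic centre, with the published knots (e.g. full desirability for
  cLogP ≤ 3, a TPSA plateau on [40, 90] Å²); scores ≥ 4 are conventionally
  "high".
- **Tc** — Tanimoto similarity |A∩B|/|A∪B| of 1024-bit path fingerprints to
  the ethosuximide reference.
- **Bioaccumulation propensity** — a transparent logistic surrogate over
  (MW, cLogP, TPSA, HBD, rotatable bonds); the coefficients are a versioned
  convention of this package, *not* a trained worm-uptake model.

**Seizure pharmacology.** A worm seizes when it shows ≥ 3 PTZ-induced head
bobs per 30-s window; non-seizing immobile worms count as protected only
with a robust touch response, otherwise toxic.  Per-concentration responses
are fitted with the variable-slope four-parameter logistic
y = bottom + (top − bottom)/(1 + 10^((logEC₅₀ − log c)·h)), with profile
confidence intervals on logEC₅₀ and extra-sum-of-squares F tests between
compounds.

**Phenotype statistics.** Body-bend and neuron-integrity tables (19 D-type
cell bodies = 13 VD + 6 DD, plus process breaks) are summarised per
group × adult age and compared with tie-corrected Kruskal–Wallis tests and
Dunn's pairwise z tests (Bonferroni-style family-wise adjustment).

**Lifespan.** Missing/bagged/damaged worms are censored at their last
observed day; survival uses the Kaplan–Meier product-limit estimator and
Mantel–Cox log-rank test (`lifelines`); headline means are arithmetic means
over uncensored death days.

**NMR quantification.** A compound window is integrated against the TSP
reference (trapezoid over a local linear baseline, proton-normalised),
converted to extract concentration through a standard curve, and scaled by
extract volume, worm count (from total protein) and 4 nL per day-1 adult to
an in-worm molar concentration.  Detectability combines a noise floor
(background median + 3·MAD) with a window-occupancy criterion.

## A worked example

```bash
python examples/01_prioritise_library.py
```

ranks the packaged 18-compound screening library against ethosuximide and
prints (abridged):

```
   id                  name  tc_ref  mpo_total  bioacc   logs  front  order
 cpd4         trimethadione   0.230      6.000   0.447 -0.960      1      1
cpd18 N-methyl-ethosuximide   0.788      5.869   0.460 -1.230      1      2
 cpd1          ethosuximide   1.000      5.833   0.417 -0.930      1      3
...
max CNS MPO = 6.00 (6 is a perfect score; >=4 is 'high')
bioaccumulation ethosuximide 0.417 vs MPS 0.404 (gap 0.014)
```

Every compound passes the solubility filter, the library attains the
perfect CNS MPO score of 6, and ethosuximide and MPS have near-identical
bioaccumulation scores — so MPS's ~160-fold potency advantage (optimal
external 0.05 mM vs 8 mM) is not explained by predicted uptake.  The other
examples cover seizure dose–response fitting (`02`), lifespan analysis with
the daf-16 null scenario (`03`), neuron integrity (`04`), NMR quantification
and occlusion (`05`), and the full seeded pipeline report (`06`).  The same
capabilities are exposed as a thin CLI (`wormlead prioritise | simulate |
seizure-fit | phenotypes | lifespan | nmr-quant | report`).

## Caveats

- The bioaccumulation surrogate (`sam_surrogate_v1`) stands in for a worm
  structure-based accumulation model whose internals are not public; treat
  its absolute values as a ranking convention only.
- Fixture LogS values come from an ESOL-style estimator and are
  configuration, not ground truth; MPO components depend on the descriptor
  engine (RDKit Crippen logP, no ionisable centres among the fixture
  compounds, so cLogD = cLogP).
- The MPS NMR windows are approximate transcriptions; the two printed
  windows (succinimide 2.82–2.74 ppm, ethosuximide 1.30–1.28 ppm) are exact.

See `docs/methods.md` for the full model descriptions, generator
calibration targets and known limitations.
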