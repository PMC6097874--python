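# Methods

This note documents the models, conventions and numerical choices behind
`wormlead`, in the spirit of a statistics package's methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Compound model and descriptors

Structures are canonical RDKit SMILES; parsing rejects multi-fragment and
charged input.  Descriptors: molecular weight, Crippen cLogP, TPSA,
hydrogen-bond donors and rotatable bonds from RDKit.  cLogD at pH 7.4
equals cLogP for molecules with no basic centre; when a basic nitrogen is
present (excluding amide/imide and aromatic ring nitrogens) a single-centre
Henderson–Hasselbalch correction cLogD = cLogP − log₁₀(1 + 10^(pKa − 7.4))
is applied with crude class pKas (aliphatic amine 10.0, aniline 4.6).  The
acidic imide N–H is deliberately ignored for `pka_basic`: the MPO attribute
is the most *basic* pKa.  None of the 18 fixture compounds has a basic
centre, so for the packaged library cLogD = cLogP throughout.

Predicted aqueous log-solubility (LogS, log₁₀ mol/L) is per-compound
configuration in the fixture; values were frozen from the package's
ESOL-style linear estimator (0.16 − 0.63·cLogP − 0.0062·MW + 0.066·RB −
0.74·aromatic fraction), which also serves as the fallback for user
compounds without a configured value.  The solubility filter retains
LogS ≥ −4.5 inclusive.

## CNS MPO

Six desirabilities in [0, 1], summed to [0, 6].  Monotone ("smaller is
better") attributes use a linear ramp between a full-desirability and a
zero-desirability knot; TPSA uses a trapezoid.  Knots (shipped in
`data/mpo_knots.yaml`, not hard-coded): cLogP 3/5, cLogD 2/4, MW 360/500,
TPSA (20, 40, 90, 120), HBD 0.5/3.5, pKa 8/10; a molecule with no basic
centre scores full pKa desirability.  Under these knots and RDKit
descriptors the fixture library spans 5.29–6.00; the published low end of
4.3 for the same compound set was produced by a different (unnamed,
logD-capable) descriptor engine, which is why the package treats the
library *minimum* as engine-dependent and only the attainment of the
perfect score of 6 as a hard expectation.

## Bioaccumulation surrogate

`sam_surrogate_v1` is a logistic transform of a linear combination of
(cLogP, MW/100, TPSA/100, HBD, rotatable bonds) with versioned coefficients
in `data/sam_surrogate.yaml`.  It is a transparent stand-in scoring
convention — the cited worm accumulation model's internals are unavailable —
scaled so the succinimide-class screening compounds land in a narrow band
(ethosuximide vs MPS gap < 0.05, which the tests treat as a calibration
check on the defaults, not a law of nature).

## Pareto ranking

Point p dominates q iff p is at least as good on every objective
(direction-adjusted) and strictly better on one; fronts peel iteratively
(front 1 = non-dominated).  Within a front, rows order by descending MPO
total then id — the source analysis tool does not define a within-front
order, so determinism is the only requirement.  Tc to the reference is
maximised directly; a band-desirability treatment of the 70–90% similarity
window was considered and not adopted (the retrieval step, not the ranking,
enforces the similarity band).  The decoy-exclusion step drops compounds
whose Tc to succinimide exceeds their Tc to ethosuximide — the minimal
deterministic rule consistent with "tagged and removed".

## Seizure assay and 4PL fitting

Scoring: seizing ⇔ head bobs ≥ 3 per 30-s window; a failed touch response
always scores toxic (a seizing count without touch response is
contradictory and resolves to toxic, logged); protected requires a robust
touch response.  Toxic worms leave the %-seizing denominator by default
(the source convention is unstated; both modes are supported).

The variable-slope 4PL is fitted by least squares on log₁₀ concentration
with multi-start initialisation (six Hill-slope starts × three midpoint
starts) and box bounds; vehicle (zero-concentration) points are excluded
from the logarithmic fit and only seed the top asymptote.  Confidence
intervals on logEC₅₀ come from the profile likelihood: the interval where
RSS(θ) ≤ RSS_min·(1 + F₁,ₙ₋₄(0.95)/(n − 4)).  Potency comparisons use the
extra-sum-of-squares F test between a model with separate logEC₅₀ per
dataset (separate bottoms/tops/slopes in both models) and one sharing a
single logEC₅₀.  Concentrations are molar internally; mg/mL inputs must be
converted by molecular weight upstream.

## Rank statistics

Kruskal–Wallis is the tie-corrected H with a χ²(k−1) p-value (scipy);
all-identical data returns (0, 1) by definition rather than erroring.
Dunn's pairwise z uses pooled mean ranks with the Σ(t³−t)/(12(N−1)) tie
correction; family-wise adjustment multiplies the raw two-sided normal p by
the number of comparisons, capped at 1 (Bonferroni-style, matching the
behaviour of the mainstream GUI analysis suites; Šidák is available).  The
TDP-43 strain's bends are scored on the unparalysed posterior half in the
wet assay; the data model treats this as a group-level note only, since no
formula depends on it.

## Lifespan

Records carry the last scored day and a status; missing/bagged/damaged
worms are censored at that day (death day = day first scored dead; the
assay's alternate-day resolution is not interval-censored further).  The
headline mean is the arithmetic mean ± SEM over uncensored deaths — the
convention consistent with reported cohort ns — with the KM restricted mean
available separately.  SEMs are per-worm, not replicate-weighted.  KM
estimation and the Mantel–Cox log-rank test delegate to `lifelines`; the
test suite cross-checks both against longhand product-limit and
observed-vs-expected arithmetic.

## NMR quantification

Integration is trapezoidal over the window above a linear baseline through
the window endpoints (vendor processing in the source workflow is
automated and unspecified; a local linear baseline is transparent and
testable).  Ratios are proton-normalised against TSP (9 protons, window
±0.05 ppm).  Calibration is an OLS line through (extract concentration,
integral ratio) standards with a free intercept; quantification inverts it
and clamps non-positive results to a 0 M below-detection outcome.  Internal
concentration = (ratio − b)/k · V_extract / (n_worms · V_worm), with
V_worm = 4 nL (day-1 adult) as a configurable default and worm count
estimated as total protein / protein-per-worm.

Detectability: a window is detectable iff its maximum exceeds the
background's median + 3·MAD *and* the background contributes less than 50%
of the raw window area (occupancy).  Both thresholds are arguments.

Numerical note: in the forward model the compound peak's Lorentzian tail
contributes a concentration-proportional sliver to the TSP window, so the
ratio is (a·c + b)/(T + d·c) — linear to ≈ 1e−5 relative over the standards
range rather than exactly.  Within the calibration range the noise-free
round trip recovers truth to better than 1e−6 relative (the acceptance
tolerance); the property test documents 1e−5 for extrapolated truths.

## Synthetic-data generators

All generators are pure functions of (scenario, seed) via
`numpy.random.default_rng`; a global seed fans out to stages by hashing the
stage name (CRC32 XOR, kept below 2³¹).  Distribution families are
modelling choices — the source reports only means, percentages and ns — and
each is calibrated against a printed summary statistic:

- **Seizure**: head bobs ~ Poisson with a 4PL mean in concentration
  (top = vehicle rate 12 bobs/30 s, bottom 0, Hill −2); truth EC₅₀ 9.7 mM
  for ethosuximide and half that for the more potent succinimides; toxicity
  probability follows its own logistic near 150 mM.  12 worms per
  concentration at 8 log-spaced concentrations (1–100 mM), within the
  printed 5–15/concentration band.
- **Lifespan**: Gompertz death times, shape 0.35/day for all groups, rate
  solved per group so the *expected recorded death day on the alternate-day
  scoring grid* equals the published group mean (continuous-mean
  calibration uses the closed form ∫S dt = e^x E1(x)/shape, x = rate/shape,
  with an asymptotic branch for x > 600).  Grid-aware calibration matters:
  matching the continuous mean would bias discretised cohort means upward
  by about one scoring interval.  Cohorts start at 60 worms × pooled
  replicates (180, or 120 in the daf-16 scenario) with per-group censor
  fractions chosen so expected deaths match the published analysed ns
  (e.g. DMSO 131 of 180).  Group targets: succinimide 12.45, ethosuximide
  13.08, DMSO 11.51, MPS 14.37 d; daf-16 scenario 11.70/11.30/12.03/11.65 d.
- **Neurons**: 19 cell bodies per worm, each lost independently with a
  per-day hazard; breaks accrue as Poisson(rate × age).  Wild type 0.001
  and 0.02/day (intact through day 7); TDP-43 0.035 and 0.9/day (damage
  from day 1); drug treatment multiplies both hazards by 0.55 (1.0 in the
  daf-16 scenario).  Hazards are calibrated to direction and ordering only
  — per-day loss rates are not printed anywhere — and must not be read as
  estimates.
- **Body bends**: negative binomial (variance = μ + αμ², α = 0.08) around
  an age-declining TDP-43 baseline (8 → 2.5 bends/min over days 1–9) times
  a group multiplier; the MPS dose multiplier interpolates log-linearly
  through an inverted-U anchor set peaking at 0.05 mM (×1.45) and dropping
  below 1 above 1 mM.
- **Spectra**: sums of Lorentzians (HWHM 8×10⁻⁴ ppm) on a 8192-point axis
  from 10 to −0.5 ppm; TSP at 0 ppm; compound peaks centred in their
  integration windows with area = response × extract-concentration ×
  protons; a fixed 28-peak endogenous background dense at 2.6–3.0 and
  7.0–7.6 ppm; optional Gaussian noise (0 by default — the quantification
  chain is exercised in its noise-free limit, with noise available for
  robustness experiments).  Matching standards series are generated through
  the same forward model and integration code.

What the generators do *not* emulate: biological replicate structure and
batch effects, inter-worm frailty correlation, non-Poisson seizure
dynamics, realistic metabolite identities or lineshapes (the background is
a fixed synthetic peak list, labelled as such), TDP-43 molecular biology.
Passing tests therefore demonstrate that the *analysis* recovers what the
generating model put in at realistic sample sizes — not that the wet-lab
effects themselves are reproduced.

## Problem sizes and determinism

Default test-suite problem sizes (100-replicate EC₅₀ recovery, 200-replicate
null-uniformity checks, 100 random Pareto instances of 20 × 3) were chosen
so the whole suite runs in about a minute on one CPU while keeping
power-style checks meaningful.  The pipeline report is byte-identical under
a fixed configuration; re-running with the same seed reproduces every
table.

## Known limitations

- The bioaccumulation score is a surrogate ranking, not a prediction with
  units; only relative statements within one model version are meaningful.
- MPO totals are descriptor-engine-dependent; comparisons against scores
  from other engines need re-anchoring.
- The compound-identity ambiguity for the fixture's "2-pyrrolidine" entry
  (transcribed as 2-pyrrolidinone, flagged in the fixture metadata) means
  scoring claims about that compound should not be over-read.
- Mean-lifespan SEMs ignore replicate clustering (per-worm convention).
- The detectability call is threshold-based and qualitative; it reproduces
  occlusion outcomes, not signal-to-noise physics.
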