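"""Seeded generators for every input the analysis pipeline consumes.

Each generator is a pure function of (scenario, seed) and is calibrated so
its defaults reproduce the printed summary statistics of the screening
study it emulates: vehicle worms all seize with ~12 head bobs per 30-s
window and drug response follows a 4PL with the compound's EC50 (9.7 mM for
ethosuximide, roughly half that for MPS/methsuximide); cohort lifespans are
Gompertz with the per-group rate solved so the mean recorded death day hits
the published group means (e.g. 11.51 d for the DMSO-vehicle TDP-43 cohort,
14.37 d under 0.05 mM MPS; near-equal means in the daf-16 null scenario);
neuron integrity starts from 19 intact D-type cell bodies with per-day loss
and break hazards (wild type essentially intact through day 7, TDP-43
damaged from day 1, drug multipliers < 1 protective); body bends follow a
negative binomial around an age-declining baseline with an inverted-U dose
multiplier peaking at 0.05 mM MPS; and 1D 1H spectra are sums of Lorentzian
peaks over a fixed endogenous-metabolite background dense at 2.6-3.0 and
7.0-7.6 ppm.

Distribution families (Poisson, negative binomial, Gompertz, Lorentzian)
are modelling choices of this package; the study reports only means,
percentages and ns.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .errors import FitError, ValidationError
from .lifespan import LifespanRecord
from .nmrquant import TSP_WINDOW, NmrSpectrum, PeakWindow
from .wormstats import N_DTYPE_NEURONS


def child_seed(seed: int, name: str) -> int:
    """Stable per-module child seed derived from a global seed and a label."""
    return (int(seed) ^ zlib.crc32(name.encode())) % (2**31 - 1)


# ---------------------------------------------------------------------------
# seizure assay


@dataclass(frozen=True)
class SeizureScenario:
    """PTZ assay layout: per-compound truth EC50s (None = inert/flat).

    Head bobs per 30-s window are Poisson with a 4PL mean in concentration
    (top = vehicle rate, bottom 0); toxicity probability follows its own
    logistic rising near ``tox_ec50``.
    """

    ec50_molar: Mapping[str, float | None] = field(
        default_factory=lambda: {"cpd1": 9.7e-3, "cpd9": 4.85e-3, "cpd2": None}
    )
    hill: float = -2.0
    vehicle_bobs: float = 12.0  # mean head bobs / 30 s in untreated seizing worms
    concentrations: tuple[float, ...] = tuple(np.geomspace(1e-3, 1e-1, 8))
    n_per_conc: int = 12
    n_vehicle: int = 12
    tox_ec50: float = 0.15  # molar; toxicity rare below ~100 mM
    tox_hill: float = 4.0


def _4pl_mean(conc: float, top: float, log_ec50: float, hill: float) -> float:
    return top / (1.0 + 10.0 ** ((log_ec50 - np.log10(conc)) * hill))


def gen_seizure(scenario: SeizureScenario = SeizureScenario(), seed: int = 0) -> pd.DataFrame:
    """Simulate per-worm seizure observations for every configured compound.

    Columns: ``worm_id, compound_id, conc_molar, head_bobs, mobile,
    touch_response``.  Vehicle rows carry concentration 0 under compound id
    ``vehicle``.
    """
    rng = np.random.default_rng(seed)
    rows = []

    def emit(cid: str, conc: float, n: int, mean_bobs: float, p_tox: float):
        for i in range(n):
            toxic = rng.random() < p_tox
            bobs = 0 if toxic else int(rng.poisson(mean_bobs))
            rows.append(
                {
                    "worm_id": f"{cid}_c{conc:g}_{i}",
                    "compound_id": cid,
                    "conc_molar": conc,
                    "head_bobs": bobs,
                    "mobile": not toxic,
                    "touch_response": not toxic,
                }
            )

    emit("vehicle", 0.0, scenario.n_vehicle, scenario.vehicle_bobs, 0.0)
    for cid, ec50 in scenario.ec50_molar.items():
        for conc in scenario.concentrations:
            if ec50 is None:
                mean = scenario.vehicle_bobs  # inert compound: flat at vehicle rate
            else:
                mean = _4pl_mean(conc, scenario.vehicle_bobs, np.log10(ec50), scenario.hill)
            p_tox = 1.0 / (
                1.0 + (scenario.tox_ec50 / conc) ** scenario.tox_hill
            ) if conc > 0 else 0.0
            emit(cid, conc, scenario.n_per_conc, mean, p_tox)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# lifespan


@dataclass(frozen=True)
class LifespanGroup:
    target_mean: float  # adult days, the published group mean
    n_start: int
    censor_frac: float


def _tdp43_groups() -> dict[str, LifespanGroup]:
    # 3 pooled replicates of 60 day-1 adults; censor fractions chosen so the
    # expected number of deaths matches the published analysed n.
    return {
        "succinimide": LifespanGroup(12.45, 180, 39 / 180),
        "ethosuximide": LifespanGroup(13.08, 180, 41 / 180),
        "DMSO": LifespanGroup(11.51, 180, 49 / 180),
        "MPS": LifespanGroup(14.37, 180, 42 / 180),
    }


def _daf16_groups() -> dict[str, LifespanGroup]:
    # daf-16 null scenario: the drug effects collapse (2 replicates of 60).
    return {
        "succinimide": LifespanGroup(11.70, 120, 34 / 120),
        "ethosuximide": LifespanGroup(11.30, 120, 33 / 120),
        "DMSO": LifespanGroup(12.03, 120, 43 / 120),
        "MPS": LifespanGroup(11.65, 120, 34 / 120),
    }


@dataclass(frozen=True)
class LifespanScenario:
    groups: Mapping[str, LifespanGroup] = field(default_factory=_tdp43_groups)
    shape: float = 0.35  # Gompertz shape (per day); fixed across groups
    scoring_interval: int = 2  # survival scored every alternate day
    first_scoring_day: int = 1


def daf16_lifespan_scenario() -> LifespanScenario:
    return LifespanScenario(groups=_daf16_groups())


def _gompertz_survival(t: np.ndarray | float, rate: float, shape: float) -> np.ndarray | float:
    with np.errstate(over="ignore"):  # exp overflow at large t decays to S = 0
        return np.exp(-(rate / shape) * (np.exp(shape * np.asarray(t, dtype=float)) - 1.0))


def _scoring_grid(shape: float, rate: float, first: int, interval: int) -> np.ndarray:
    days = [first]
    while _gompertz_survival(days[-1], rate, shape) > 1e-12 and days[-1] < 10000:
        days.append(days[-1] + interval)
    return np.array(days, dtype=float)


def _grid_mean(rate: float, shape: float, first: int, interval: int) -> float:
    """Expected recorded death day when deaths are logged on the scoring grid."""
    days = _scoring_grid(shape, rate, first, interval)
    surv = _gompertz_survival(days, rate, shape)
    prev = np.concatenate([[1.0], surv[:-1]])
    return float(np.sum(days * (prev - surv)) + days[-1] * surv[-1])


def calibrate_gompertz(
    target_mean: float,
    shape: float,
    scoring_grid: tuple[int, int] | None = None,
) -> float:
    """Solve for the Gompertz rate whose mean lifespan equals ``target_mean``.

    With ``scoring_grid=None`` the continuous mean (numerically integrated
    survival) is matched to within 1e-6; passing ``(first_day, interval)``
    matches the expected death day recorded on that discrete scoring grid
    instead, which is what the lifespan generator uses so that
    alternate-day scoring does not bias cohort means above their targets.
    """
    if target_mean <= 0 or shape <= 0:
        raise ValidationError("target_mean and shape must be positive")

    if scoring_grid is None:
        # closed form: integral of S(t) dt = e^x E1(x) / shape with x = rate/shape;
        # asymptotic continued series for large x where e^x overflows
        def mean_at(rate: float) -> float:
            x = rate / shape
            if x < 600.0:
                return float(np.exp(x) * special.exp1(x) / shape)
            inv = 1.0 / x
            series = inv * (1.0 - inv * (1.0 - inv * (2.0 - inv * (6.0 - 24.0 * inv))))
            return float(series / shape)
    else:
        first, interval = scoring_grid

        def mean_at(rate: float) -> float:
            return _grid_mean(rate, shape, first, interval)

    def objective(log_rate: float) -> float:
        return mean_at(10.0**log_rate) - target_mean

    lo, hi = -10.0, 2.0
    if objective(lo) < 0 or objective(hi) > 0:
        raise FitError(
            f"Gompertz calibration bracket failure for mean {target_mean} at shape {shape}"
        )
    log_rate = optimize.brentq(objective, lo, hi, xtol=1e-12)
    rate = 10.0**log_rate
    if scoring_grid is None and abs(mean_at(rate) - target_mean) > 1e-6:
        raise FitError("Gompertz calibration did not reach the 1e-6 mean tolerance")
    return rate


def gen_lifespans(
    scenario: LifespanScenario = LifespanScenario(), seed: int = 0
) -> list[LifespanRecord]:
    """Simulate per-worm lifespan records for every scenario group.

    Death times are Gompertz with the rate solved per group against the
    discrete scoring grid; censored worms (missing/bagged/damaged, drawn at
    the configured fraction) leave at a uniformly chosen scoring day no
    later than their death day.
    """
    rng = np.random.default_rng(seed)
    records: list[LifespanRecord] = []
    first, interval = scenario.first_scoring_day, scenario.scoring_interval
    for group, cfg in scenario.groups.items():
        rate = calibrate_gompertz(cfg.target_mean, scenario.shape, (first, interval))
        for i in range(cfg.n_start):
            u = rng.random()
            t = np.log1p(-scenario.shape * np.log(u) / rate) / scenario.shape
            # first scoring day >= t
            k = max(0, int(np.ceil((t - first) / interval)))
            death_day = first + interval * k
            if rng.random() < cfg.censor_frac:
                censor_day = first + interval * rng.integers(0, k + 1)
                reason = rng.choice(["missing", "bagged", "damaged"])
                records.append(
                    LifespanRecord(
                        worm_id=f"{group}_{i}", group=group,
                        last_day_alive=int(censor_day), status="censored",
                        censor_reason=str(reason),
                    )
                )
            else:
                records.append(
                    LifespanRecord(
                        worm_id=f"{group}_{i}", group=group,
                        last_day_alive=int(death_day), status="died",
                    )
                )
    return records


# ---------------------------------------------------------------------------
# neuron integrity


@dataclass(frozen=True)
class NeuronGroup:
    body_hazard: float  # per cell body per day loss probability
    break_rate: float  # expected new breaks per day
    n_per_age: int


def _neuron_groups(protective_multiplier: float = 0.55) -> dict[str, NeuronGroup]:
    tdp_body, tdp_break = 0.035, 0.9
    m = protective_multiplier
    return {
        "WT": NeuronGroup(0.001, 0.02, 30),
        "TDP43_succinimide": NeuronGroup(tdp_body, tdp_break, 40),
        "TDP43_DMSO": NeuronGroup(tdp_body, tdp_break, 40),
        "TDP43_ethosuximide": NeuronGroup(tdp_body * m, tdp_break * m, 40),
        "TDP43_MPS": NeuronGroup(tdp_body * m, tdp_break * m, 40),
    }


@dataclass(frozen=True)
class NeuronScenario:
    groups: Mapping[str, NeuronGroup] = field(default_factory=_neuron_groups)
    ages: tuple[int, ...] = (1, 3, 5, 7)


def daf16_neuron_scenario() -> NeuronScenario:
    """daf-16 null background: drug protection abolished (multiplier 1)."""
    return NeuronScenario(groups=_neuron_groups(protective_multiplier=1.0))


def gen_neurons(scenario: NeuronScenario = NeuronScenario(), seed: int = 0) -> pd.DataFrame:
    """Simulate D-type neuron integrity records.

    Columns ``worm_id, group, age_day, cell_bodies, breaks``; each worm
    starts with all 19 cell bodies, loses each independently with its
    group's per-day hazard, and accrues Poisson breaks.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, cfg in scenario.groups.items():
        for age in scenario.ages:
            p_lost = 1.0 - (1.0 - cfg.body_hazard) ** age
            for i in range(cfg.n_per_age):
                lost = rng.binomial(N_DTYPE_NEURONS, p_lost)
                breaks = rng.poisson(cfg.break_rate * age)
                rows.append(
                    {
                        "worm_id": f"{group}_d{age}_{i}",
                        "group": group,
                        "age_day": age,
                        "cell_bodies": N_DTYPE_NEURONS - int(lost),
                        "breaks": int(breaks),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# body bends


# (dose molar, locomotion multiplier) anchors; log-linear interpolation.
# Inverted-U: improvement peaks near 0.05 mM, higher doses impair instead.
MPS_DOSE_ANCHORS: tuple[tuple[float, float], ...] = (
    (1e-5, 1.10),
    (2.5e-5, 1.35),
    (5e-5, 1.45),
    (2.5e-4, 1.15),
    (1e-3, 0.90),
    (2e-3, 0.70),
)


def mps_dose_multiplier(dose_molar: float) -> float:
    """Locomotion multiplier for an MPS dose (1.0 at dose 0; inverted-U above)."""
    if dose_molar < 0:
        raise ValidationError("dose must be non-negative")
    if dose_molar == 0:
        return 1.0
    doses = np.log10([d for d, _ in MPS_DOSE_ANCHORS])
    mults = np.array([m for _, m in MPS_DOSE_ANCHORS])
    return float(np.interp(np.log10(dose_molar), doses, mults))


def _tdp43_baseline_bends() -> dict[int, float]:
    return {1: 8.0, 3: 6.0, 5: 4.5, 7: 3.5, 9: 2.5}


@dataclass(frozen=True)
class BendsScenario:
    """Body-bend counts: negative binomial around baseline x group multiplier.

    ``group_multipliers`` scale the age-declining TDP-43 baseline; MPS dose
    groups can be added via :func:`bends_dose_scenario`.  ``dispersion`` is
    the NB alpha (variance = mean + alpha * mean^2); 0 recovers Poisson.
    """

    baseline_by_age: Mapping[int, float] = field(default_factory=_tdp43_baseline_bends)
    group_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {
            "TDP43_succinimide": 1.0,
            "TDP43_ethosuximide": 1.40,
            "TDP43_DMSO": 1.0,
            "TDP43_MPS": 1.45,
        }
    )
    dispersion: float = 0.08
    n_per_group_age: int = 50


def bends_dose_scenario(
    doses: Sequence[float] = (2.5e-5, 5e-5, 2.5e-4, 1e-3, 2e-3),
    n_per_group_age: int = 30,
) -> BendsScenario:
    """Concentration-response layout: DMSO vehicle plus MPS dose groups."""
    groups = {"TDP43_DMSO": 1.0}
    for dose in doses:
        groups[f"TDP43_MPS_{dose:g}"] = mps_dose_multiplier(dose)
    return BendsScenario(group_multipliers=groups, n_per_group_age=n_per_group_age)


def gen_bends(scenario: BendsScenario = BendsScenario(), seed: int = 0) -> pd.DataFrame:
    """Simulate body-bend records (columns ``worm_id, group, age_day, bends_per_min``)."""
    rng = np.random.default_rng(seed)
    rows = []
    alpha = scenario.dispersion
    for group, mult in scenario.group_multipliers.items():
        for age, base in scenario.baseline_by_age.items():
            mu = base * mult
            for i in range(scenario.n_per_group_age):
                if alpha <= 1e-8:
                    count = rng.poisson(mu)
                else:
                    count = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))
                rows.append(
                    {
                        "worm_id": f"{group}_d{age}_{i}",
                        "group": group,
                        "age_day": age,
                        "bends_per_min": float(count),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NMR spectra


@dataclass(frozen=True)
class MetaboliteBackground:
    """Endogenous-metabolite peak list as (centre ppm, half-width, area) triples."""

    peaks: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        if any(a < 0 for _, _, a in self.peaks):
            raise ValidationError("background peak amplitudes must be >= 0")


def default_metabolite_background() -> MetaboliteBackground:
    """A fixed worm-lysate-like background, dense at 2.6-3.0 and 7.0-7.6 ppm."""
    return MetaboliteBackground(
        peaks=(
            (0.92, 0.002, 30.0), (1.04, 0.002, 20.0), (1.20, 0.002, 10.0),
            (1.33, 0.0015, 60.0), (1.47, 0.002, 25.0), (1.70, 0.002, 8.0),
            (2.14, 0.002, 20.0), (2.40, 0.002, 15.0),
            (2.62, 0.0015, 30.0), (2.66, 0.0015, 25.0), (2.71, 0.0015, 20.0),
            (2.86, 0.0015, 30.0), (2.91, 0.0015, 28.0), (2.97, 0.0015, 25.0),
            (3.05, 0.002, 40.0), (3.22, 0.002, 80.0), (3.43, 0.002, 50.0),
            (3.56, 0.002, 45.0), (3.71, 0.002, 40.0), (3.89, 0.002, 30.0),
            (4.12, 0.002, 15.0), (5.40, 0.002, 5.0),
            (7.05, 0.002, 12.0), (7.18, 0.002, 15.0), (7.32, 0.0015, 25.0),
            (7.41, 0.0015, 22.0), (7.55, 0.002, 15.0), (8.46, 0.0015, 10.0),
        )
    )


# Integration windows for the three quantified compounds.  The two printed
# windows (succinimide 2.82-2.74, ethosuximide 1.30-1.28 ppm) are exact; the
# MPS aromatic and -CH2 multiplet windows are approximate transcriptions.
DEFAULT_WINDOWS: dict[str, tuple[PeakWindow, ...]] = {
    "cpd2": (PeakWindow("cpd2", 2.74, 2.82, protons=4),),
    "cpd1": (PeakWindow("cpd1", 1.28, 1.30, protons=3),),
    "cpd9": (
        PeakWindow("cpd9", 7.25, 7.45, protons=5),
        PeakWindow("cpd9", 2.84, 2.98, protons=2),
    ),
}


@dataclass(frozen=True)
class SpectrumScenario:
    """Forward model for a worm-lysate spectrum of one treated cohort."""

    compound_id: str = "cpd1"
    windows: tuple[PeakWindow, ...] = DEFAULT_WINDOWS["cpd1"]
    truth_internal_molar: float = 143.8e-6
    n_worms: float = 3000.0
    volume_per_worm_l: float = 4e-9
    extract_volume_l: float = 200e-6
    response_factor: float = 1e6  # integrated area units per (molar x proton)
    peak_width: float = 0.0008  # Lorentzian half-width at half-maximum, ppm
    tsp_area: float = 100.0  # raw TSP reference area (9 protons)
    noise_sigma: float = 0.0
    standard_concs: tuple[float, ...] = (2e-6, 5e-6, 1e-5, 2e-5, 5e-5)
    ppm_max: float = 10.0
    ppm_min: float = -0.5
    n_points: int = 8192


def _lorentzian(x: np.ndarray, centre: float, gamma: float, area: float) -> np.ndarray:
    return area / np.pi * gamma / ((x - centre) ** 2 + gamma**2)


def _axis(scenario: SpectrumScenario) -> np.ndarray:
    return np.linspace(scenario.ppm_max, scenario.ppm_min, scenario.n_points)


def _compound_signal(
    x: np.ndarray, scenario: SpectrumScenario, conc_extract: float
) -> np.ndarray:
    y = np.zeros_like(x)
    for w in scenario.windows:
        centre = 0.5 * (w.lo_ppm + w.hi_ppm)
        area = scenario.response_factor * conc_extract * w.protons
        y += _lorentzian(x, centre, scenario.peak_width, area)
    return y


def gen_spectrum(
    scenario: SpectrumScenario = SpectrumScenario(),
    background: MetaboliteBackground | None = None,
    seed: int = 0,
) -> tuple[NmrSpectrum, list[list[tuple[float, float]]]]:
    """Forward-simulate a lysate spectrum plus matching calibration standards.

    The compound's extract concentration follows from the truth internal
    concentration, worm count, per-worm volume and extract volume; peaks are
    Lorentzians centred in their windows, TSP sits at 0 ppm, and the
    background (if any) is added on top.  Standards are pure-compound
    spectra at ``standard_concs`` integrated with the same windows,
    returned per window as (extract conc, integral ratio) pairs.
    """
    from .nmrquant import integrate_window  # local import to avoid cycle at module load

    for w in scenario.windows:
        if w.lo_ppm < TSP_WINDOW[1] and w.hi_ppm > TSP_WINDOW[0]:
            raise ValidationError(f"window {w} overlaps the TSP reference window")
    rng = np.random.default_rng(seed)
    x = _axis(scenario)
    tsp = _lorentzian(x, 0.0, scenario.peak_width, scenario.tsp_area)
    conc_extract = (
        scenario.truth_internal_molar
        * scenario.n_worms
        * scenario.volume_per_worm_l
        / scenario.extract_volume_l
    )
    y = tsp + _compound_signal(x, scenario, conc_extract)
    if background is not None:
        for centre, gamma, area in background.peaks:
            y = y + _lorentzian(x, centre, gamma, area)
    if scenario.noise_sigma > 0:
        y = y + rng.normal(0.0, scenario.noise_sigma, size=y.shape)
    sample = NmrSpectrum(x, y, meta={"compound_id": scenario.compound_id})

    standards: list[list[tuple[float, float]]] = [[] for _ in scenario.windows]
    for conc in scenario.standard_concs:
        ys = tsp + _compound_signal(x, scenario, conc)
        std = NmrSpectrum(x, ys, meta={"standard_conc": conc})
        for i, w in enumerate(scenario.windows):
            standards[i].append((conc, integrate_window(std, w)))
    return sample, standards


def background_spectrum(
    scenario: SpectrumScenario = SpectrumScenario(),
    background: MetaboliteBackground | None = None,
) -> NmrSpectrum:
    """The matching untreated-lysate spectrum (TSP + endogenous background only)."""
    bg = background if background is not None else default_metabolite_background()
    blank = replace(scenario, truth_internal_molar=0.0, noise_sigma=0.0)
    spectrum, _ = gen_spectrum(blank, background=bg, seed=0)
    return spectrum
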