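"""PTZ-induced seizure assay scoring and concentration-response analysis.

Worms carrying a GABA_A-receptor null mutation respond to pentylenetetrazole
with repetitive "head-bobbing" convulsions.  A worm is scored as seizing
when it shows at least three head bobs in the 30-s scoring window; toxicity
is called from immobility together with a failed touch response.  Potency is
summarised by fitting the variable-slope four-parameter logistic (4PL) to
per-concentration responses and comparing log10 EC50 values between
compounds with an extra-sum-of-squares F test.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import AggregationError, FitError, ValidationError

log = logging.getLogger(__name__)

SEIZING_THRESHOLD = 3  # head bobs per 30-s window


@dataclass(frozen=True)
class SeizureObservation:
    worm_id: str
    compound_id: str
    concentration: float  # molar; 0 = vehicle
    head_bobs: int
    mobile: bool
    touch_response: bool

    def __post_init__(self):
        if self.head_bobs < 0:
            raise ValidationError(f"{self.worm_id}: negative head-bob count")
        if self.concentration < 0:
            raise ValidationError(f"{self.worm_id}: negative concentration")


@dataclass(frozen=True)
class DoseResponseFit:
    """Variable-slope 4PL fit: bottom + (top-bottom) / (1 + 10^((log_ec50 - log10 c) * hill))."""

    bottom: float
    top: float
    log_ec50: float  # log10 molar
    hill: float
    rss: float
    n: int
    ci_log_ec50: tuple[float, float]

    @property
    def ec50(self) -> float:
        return 10.0 ** self.log_ec50


def classify_seizing(head_bobs: int, threshold: int = SEIZING_THRESHOLD) -> bool:
    """A worm seizes when it shows at least ``threshold`` head bobs in the window."""
    if head_bobs < 0:
        raise ValidationError("negative head-bob count")
    return head_bobs >= threshold


def classify_outcome(obs: SeizureObservation, threshold: int = SEIZING_THRESHOLD) -> str:
    """Classify an observation as ``seizing``, ``protected`` or ``toxic``.

    A failed touch response always means toxic (a non-seizing immobile worm
    is only called protected when it responds robustly to touch).  A seizing
    count paired with no touch response is contradictory and resolved to
    toxic with a log message.
    """
    seizing = classify_seizing(obs.head_bobs, threshold)
    if not obs.touch_response:
        if seizing:
            log.warning(
                "%s: seizing head bobs with failed touch response; scored toxic",
                obs.worm_id,
            )
        return "toxic"
    return "seizing" if seizing else "protected"


def summarise(
    observations: list[SeizureObservation] | pd.DataFrame,
    threshold: int = SEIZING_THRESHOLD,
    exclude_toxic_from_denominator: bool = True,
) -> pd.DataFrame:
    """Per (compound, concentration) summary of the seizure assay.

    Returns percentage seizing, mean head-bob count with SEM, group size and
    percentage toxic.  By default toxic worms leave the seizing denominator;
    set ``exclude_toxic_from_denominator=False`` to keep them in it.
    """
    if isinstance(observations, pd.DataFrame):
        observations = [
            SeizureObservation(
                worm_id=str(r.worm_id), compound_id=str(r.compound_id),
                concentration=float(r.conc_molar), head_bobs=int(r.head_bobs),
                mobile=bool(r.mobile), touch_response=bool(r.touch_response),
            )
            for r in observations.itertuples()
        ]
    if not observations:
        raise AggregationError("no observations to summarise")
    rows = []
    frame = pd.DataFrame(
        {
            "compound_id": [o.compound_id for o in observations],
            "conc_molar": [o.concentration for o in observations],
            "head_bobs": [o.head_bobs for o in observations],
            "outcome": [classify_outcome(o, threshold) for o in observations],
        }
    )
    for (cid, conc), grp in frame.groupby(["compound_id", "conc_molar"], sort=True):
        n = len(grp)
        n_toxic = int((grp.outcome == "toxic").sum())
        denom = n - n_toxic if exclude_toxic_from_denominator else n
        n_seizing = int((grp.outcome == "seizing").sum())
        pct_seizing = 100.0 * n_seizing / denom if denom else np.nan
        nontoxic_bobs = grp.loc[grp.outcome != "toxic", "head_bobs"]
        mean_bobs = float(nontoxic_bobs.mean()) if len(nontoxic_bobs) else np.nan
        sem = (
            float(nontoxic_bobs.std(ddof=1) / np.sqrt(len(nontoxic_bobs)))
            if len(nontoxic_bobs) > 1
            else np.nan
        )
        rows.append(
            {
                "compound_id": cid, "conc_molar": conc, "n": n,
                "pct_seizing": pct_seizing, "mean_bobs": mean_bobs,
                "sem_bobs": sem, "pct_toxic": 100.0 * n_toxic / n,
            }
        )
    return pd.DataFrame(rows)


def _4pl(logc: np.ndarray, bottom: float, top: float, log_ec50: float, hill: float) -> np.ndarray:
    with np.errstate(over="ignore"):  # 10^huge -> inf collapses to the asymptote
        return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - logc) * hill))


def _prepare(concentrations, responses) -> tuple[np.ndarray, np.ndarray, float | None]:
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.shape != resp.shape:
        raise ValidationError("concentration and response arrays differ in length")
    vehicle = resp[conc == 0]
    anchor = float(vehicle.mean()) if len(vehicle) else None
    mask = conc > 0
    return np.log10(conc[mask]), resp[mask], anchor


def _fit_core(
    logc: np.ndarray, resp: np.ndarray, top_anchor: float | None
) -> tuple[np.ndarray, float]:
    span = resp.max() - resp.min()
    if span == 0 or len(np.unique(logc)) < 4:
        raise FitError(
            f"degenerate concentration-response data: {len(np.unique(logc))} distinct "
            f"concentrations, response span {span:g}"
        )
    top0 = top_anchor if top_anchor is not None else float(resp.max())
    bottom0 = float(resp.min())
    mid0 = float(np.median(logc))
    best = None
    lo = np.array([resp.min() - span, resp.min() - span, logc.min() - 3, -10.0])
    hi = np.array([resp.max() + span, resp.max() + span, logc.max() + 3, 10.0])
    for hill0 in (-2.0, -1.0, -0.5, 0.5, 1.0, 2.0):
        for mid in (mid0, logc.min(), logc.max()):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", optimize.OptimizeWarning)
                    popt, _ = optimize.curve_fit(
                        _4pl, logc, resp, p0=[bottom0, top0, mid, hill0],
                        bounds=(lo, hi), maxfev=20000,
                    )
            except (RuntimeError, ValueError):
                continue
            rss = float(np.sum((resp - _4pl(logc, *popt)) ** 2))
            if best is None or rss < best[1] - 1e-12:
                best = (popt, rss)
    if best is None:
        raise FitError("4PL fit failed to converge from any start")
    return best


def _profile_ci(
    logc: np.ndarray, resp: np.ndarray, popt: np.ndarray, rss_min: float, alpha: float = 0.05
) -> tuple[float, float]:
    """Profile-likelihood interval on log_ec50 at level 1 - alpha."""
    n, p = len(resp), 4
    if n <= p or rss_min <= 0:
        return (-np.inf, np.inf)
    fcrit = stats.f.ppf(1 - alpha, 1, n - p)
    thresh = rss_min * (1.0 + fcrit / (n - p))

    def profile_rss(le: float) -> float:
        def model(lc, bottom, top, hill):
            return _4pl(lc, bottom, top, le, hill)

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                q, _ = optimize.curve_fit(
                    model, logc, resp, p0=[popt[0], popt[1], popt[3]], maxfev=10000
                )
        except (RuntimeError, ValueError):
            return np.inf
        return float(np.sum((resp - model(logc, *q)) ** 2))

    def crossing(direction: int) -> float:
        step = 0.05
        x_prev = popt[2]
        for i in range(1, 200):
            x = popt[2] + direction * step * i
            if profile_rss(x) > thresh:
                return optimize.brentq(lambda v: profile_rss(v) - thresh, min(x_prev, x), max(x_prev, x))
            x_prev = x
        return direction * np.inf

    return (crossing(-1), crossing(+1))


def fit_4pl(concentrations, responses, top_anchor_from_vehicle: bool = True) -> DoseResponseFit:
    """Least-squares variable-slope 4PL fit with multi-start initialisation.

    Vehicle (zero-concentration) points are excluded from the logarithmic
    fit; when present their mean seeds the top-asymptote initial value.
    Raises :class:`FitError` on degenerate (flat or under-sampled) data.
    """
    logc, resp, anchor = _prepare(concentrations, responses)
    if not top_anchor_from_vehicle:
        anchor = None
    popt, rss = _fit_core(logc, resp, anchor)
    ci = _profile_ci(logc, resp, popt, rss)
    bottom, top, log_ec50, hill = (float(v) for v in popt)
    if bottom > top:  # normalise so bottom <= top (mirror parameterisation)
        bottom, top, hill = top, bottom, -hill
    return DoseResponseFit(
        bottom=bottom, top=top, log_ec50=log_ec50, hill=hill,
        rss=rss, n=len(resp), ci_log_ec50=ci,
    )


def compare_log_ec50(data_a, data_b) -> tuple[float, float, float]:
    """Extra-sum-of-squares comparison of two concentration-response datasets.

    ``data_a``/``data_b`` are ``(concentrations, responses)`` pairs.  The
    null model shares a single log EC50 between datasets (separate bottoms,
    tops and slopes); the alternative frees it.  Returns
    ``(fold_change, F, p)`` where ``fold_change = 10^(log_ec50_b - log_ec50_a)``.
    """
    logc_a, resp_a, anchor_a = _prepare(*data_a)
    logc_b, resp_b, anchor_b = _prepare(*data_b)
    popt_a, rss_a = _fit_core(logc_a, resp_a, anchor_a)
    popt_b, rss_b = _fit_core(logc_b, resp_b, anchor_b)
    rss_full = rss_a + rss_b
    n = len(resp_a) + len(resp_b)
    df_full = n - 8

    def shared_resid(theta):
        ba, ta, ha, bb, tb, hb, le = theta
        return np.concatenate(
            [resp_a - _4pl(logc_a, ba, ta, le, ha), resp_b - _4pl(logc_b, bb, tb, le, hb)]
        )

    le0 = 0.5 * (popt_a[2] + popt_b[2])
    theta0 = [popt_a[0], popt_a[1], popt_a[3], popt_b[0], popt_b[1], popt_b[3], le0]
    sol = optimize.least_squares(shared_resid, theta0, max_nfev=20000)
    rss_shared = float(2 * sol.cost)
    if rss_shared < rss_full:  # shared model can't beat the free one; numerical guard
        rss_shared = rss_full
    if df_full <= 0:
        raise FitError("too few points for an extra-sum-of-squares comparison")
    F = ((rss_shared - rss_full) / 1.0) / (rss_full / df_full) if rss_full > 0 else 0.0
    p = float(stats.f.sf(F, 1, df_full)) if rss_full > 0 else 1.0
    fold = 10.0 ** (popt_b[2] - popt_a[2])
    return float(fold), float(F), p
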