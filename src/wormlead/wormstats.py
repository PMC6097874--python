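"""Locomotion and neuron-integrity summaries with rank-based group tests.

Body-bend counts and ventral-nerve-cord integrity scores (cell bodies out of
the 19 D-type GABAergic motor neurons, 13 VD + 6 DD, plus process breaks)
are summarised per group x adult age, and groups are compared with the
tie-corrected Kruskal-Wallis test followed by Dunn's pairwise z tests with a
Bonferroni-style family-wise adjustment.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AggregationError, ComparisonError, ValidationError

log = logging.getLogger(__name__)

N_DTYPE_NEURONS = 19  # 13 VD + 6 DD cell bodies


@dataclass(frozen=True)
class BodyBendRecord:
    worm_id: str
    group: str
    age_day: int
    bends_per_min: float

    def __post_init__(self):
        if self.bends_per_min < 0:
            raise ValidationError(f"{self.worm_id}: negative body-bend count")
        if self.age_day < 1:
            raise ValidationError(f"{self.worm_id}: age_day must be >= 1")


@dataclass(frozen=True)
class NeuronIntegrityRecord:
    worm_id: str
    group: str
    age_day: int
    cell_bodies: int
    breaks: int

    def __post_init__(self):
        if not 0 <= self.cell_bodies <= N_DTYPE_NEURONS:
            raise ValidationError(
                f"{self.worm_id}: cell_bodies {self.cell_bodies} outside [0, {N_DTYPE_NEURONS}]"
            )
        if self.breaks < 0:
            raise ValidationError(f"{self.worm_id}: negative break count")


def _to_frame(records, columns) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        frame = records.copy()
    else:
        frame = pd.DataFrame([vars(r) for r in records])
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValidationError(f"missing columns {missing}")
    if "cell_bodies" in frame.columns and (
        (frame.cell_bodies < 0) | (frame.cell_bodies > N_DTYPE_NEURONS)
    ).any():
        raise ValidationError(f"cell_bodies outside [0, {N_DTYPE_NEURONS}]")
    return frame


def summarise_bends(records) -> pd.DataFrame:
    """Mean +- SEM body bends per minute by (group, age_day).

    SEM is reported as NaN for singleton groups.
    """
    frame = _to_frame(records, ["group", "age_day", "bends_per_min"])
    if frame.empty:
        raise AggregationError("no body-bend records")
    out = (
        frame.groupby(["group", "age_day"])["bends_per_min"]
        .agg(mean="mean", n="count", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    out["sem"] = out.sd / np.sqrt(out.n)
    return out.drop(columns="sd")


def kruskal_wallis(*groups: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (k-1 df).

    All-identical data returns (0, 1) rather than an error.
    """
    if len(groups) < 2:
        raise ComparisonError("Kruskal-Wallis needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise AggregationError("empty group in Kruskal-Wallis")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*arrays)
    return float(H), float(p)


def dunns_pairwise(
    groups: Mapping[str, Sequence[float]],
    comparisons: str | Sequence[tuple[str, str]] = "all",
    control: str | None = None,
    adjustment: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's post hoc z tests on pooled ranks with tie correction.

    ``comparisons`` may be ``"all"`` (every pair), ``"control"`` (each group
    against ``control``), or an explicit pair list.  Raw two-sided normal p
    values are family-wise adjusted by multiplying by the number of
    comparisons (capped at 1); ``adjustment="sidak"`` uses the Sidak form.
    Returns a frame with columns ``a, b, z, p_raw, p_adj``.
    """
    names = list(groups)
    if len(names) < 2:
        raise ComparisonError("Dunn's test needs at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    pooled = np.concatenate([arrays[k] for k in names])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_rank: dict[str, float] = {}
    start = 0
    for k in names:
        stop = start + len(arrays[k])
        mean_rank[k] = float(ranks[start:stop].mean())
        start = stop
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    if comparisons == "all":
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    elif comparisons == "control":
        if control is None or control not in arrays:
            raise ComparisonError("control-vs-each comparisons need a valid control group")
        pairs = [(control, b) for b in names if b != control]
    else:
        pairs = list(comparisons)
    m = len(pairs)
    rows = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / len(arrays[a]) + 1.0 / len(arrays[b])))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p_raw = float(2.0 * stats.norm.sf(abs(z)))
        if adjustment == "bonferroni":
            p_adj = min(1.0, p_raw * m)
        elif adjustment == "sidak":
            p_adj = 1.0 - (1.0 - p_raw) ** m
        else:
            raise ComparisonError(f"unknown adjustment {adjustment!r}")
        rows.append({"a": a, "b": b, "z": float(z), "p_raw": p_raw, "p_adj": p_adj})
    return pd.DataFrame(rows)


def integrity_deltas(records, reference_group: str) -> pd.DataFrame:
    """Per-age mean cell-body loss and break excess relative to a reference group.

    ``body_loss`` is (reference mean bodies - group mean bodies) and
    ``break_excess`` is (group mean breaks - reference mean breaks), each
    with a combined SEM.  Ages missing from the reference are dropped with a
    warning (partial output).
    """
    frame = _to_frame(records, ["group", "age_day", "cell_bodies", "breaks"])
    if reference_group not in set(frame.group):
        raise ValidationError(f"reference group {reference_group!r} absent")
    stats_by = (
        frame.groupby(["group", "age_day"])
        .agg(
            bodies_mean=("cell_bodies", "mean"),
            bodies_sem=("cell_bodies", "sem"),
            breaks_mean=("breaks", "mean"),
            breaks_sem=("breaks", "sem"),
            n=("cell_bodies", "count"),
        )
        .reset_index()
    )
    ref = stats_by[stats_by.group == reference_group].set_index("age_day")
    rows = []
    for r in stats_by.itertuples():
        if r.age_day not in ref.index:
            log.warning("no %s reference at age day %s; skipped", reference_group, r.age_day)
            continue
        rr = ref.loc[r.age_day]
        rows.append(
            {
                "group": r.group,
                "age_day": r.age_day,
                "body_loss": rr.bodies_mean - r.bodies_mean,
                "body_loss_sem": float(np.hypot(rr.bodies_sem or 0.0, r.bodies_sem or 0.0)),
                "break_excess": r.breaks_mean - rr.breaks_mean,
                "break_excess_sem": float(np.hypot(rr.breaks_sem or 0.0, r.breaks_sem or 0.0)),
                "n": r.n,
            }
        )
    return pd.DataFrame(rows)
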