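"""Multi-parameter compound prioritisation.

Implements the selection workflow used to pick screening candidates around a
reference scaffold: a decoy-similarity exclusion, an aqueous-solubility
(LogS) filter, the six-attribute CNS multiparameter-optimisation (MPO)
desirability score, a transparent worm-bioaccumulation surrogate, and Pareto
non-dominated sorting over (MPO, Tanimoto-to-reference, bioaccumulation).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import compounds as cmp
from .compounds import Compound, DescriptorSet
from .errors import ComputationError, ConfigError, ValidationError

log = logging.getLogger(__name__)

DEFAULT_LOGS_CUTOFF = -4.5


def _load_yaml(name: str) -> dict:
    with resources.files("wormlead.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def default_mpo_knots() -> dict:
    return _load_yaml("mpo_knots.yaml")


def sam_coefficients(model_version: str = "sam_surrogate_v1") -> dict:
    table = _load_yaml("sam_surrogate.yaml")
    if model_version not in table:
        raise ConfigError(f"unknown bioaccumulation model version {model_version!r}")
    return table[model_version]


@dataclass(frozen=True)
class MPOScore:
    """Per-attribute desirabilities (each in [0, 1]) and their sum (0-6)."""

    d_clogp: float
    d_clogd: float
    d_mw: float
    d_tpsa: float
    d_hbd: float
    d_pka: float

    @property
    def total(self) -> float:
        return self.d_clogp + self.d_clogd + self.d_mw + self.d_tpsa + self.d_hbd + self.d_pka


@dataclass(frozen=True)
class BioaccumulationScore:
    value: float
    model_version: str


def desirability_monotonic(x: float, full: float, zero: float) -> float:
    """Smaller-is-better linear desirability: 1 at/below ``full``, 0 at/above ``zero``."""
    if not full < zero:
        raise ConfigError(f"monotone desirability needs full < zero, got {full} >= {zero}")
    if x <= full:
        return 1.0
    if x >= zero:
        return 0.0
    return (zero - x) / (zero - full)


def desirability_hump(x: float, lo0: float, lo1: float, hi1: float, hi0: float) -> float:
    """Trapezoidal desirability: 0 outside (lo0, hi0), 1 on [lo1, hi1], linear ramps between."""
    if not (lo0 < lo1 <= hi1 < hi0):
        raise ConfigError(f"hump knots must satisfy lo0 < lo1 <= hi1 < hi0, got {(lo0, lo1, hi1, hi0)}")
    if x <= lo0 or x >= hi0:
        return 0.0
    if lo1 <= x <= hi1:
        return 1.0
    if x < lo1:
        return (x - lo0) / (lo1 - lo0)
    return (hi0 - x) / (hi0 - hi1)


def cns_mpo(d: DescriptorSet, knots: Mapping | None = None) -> MPOScore:
    """CNS MPO desirability score of a descriptor set.

    A molecule with no basic centre receives full pKa desirability.  Raises
    :class:`ComputationError` naming the attribute if a required descriptor
    is missing (None).
    """
    knots = dict(knots or default_mpo_knots())
    for attr in ("mw", "clogp", "clogd", "tpsa", "hbd"):
        if getattr(d, attr) is None:
            raise ComputationError(f"missing descriptor {attr!r} for MPO scoring")
    if d.pka_basic is None:
        d_pka = 1.0
    else:
        d_pka = desirability_monotonic(d.pka_basic, *knots["pka_basic"])
    return MPOScore(
        d_clogp=desirability_monotonic(d.clogp, *knots["clogp"]),
        d_clogd=desirability_monotonic(d.clogd, *knots["clogd"]),
        d_mw=desirability_monotonic(d.mw, *knots["mw"]),
        d_tpsa=desirability_hump(d.tpsa, *knots["tpsa"]),
        d_hbd=desirability_monotonic(d.hbd, *knots["hbd"]),
        d_pka=d_pka,
    )


def solubility_filter(
    compound_list: Sequence[Compound],
    cutoff: float = DEFAULT_LOGS_CUTOFF,
) -> tuple[list[Compound], list[tuple[str, float]]]:
    """Retain compounds with LogS >= cutoff (inclusive); log rejections.

    Returns ``(retained, rejections)`` where rejections are ``(id, logs)``
    pairs.  A compound with no configured LogS raises
    :class:`ValidationError` (the caller decides whether to estimate one).
    """
    retained: list[Compound] = []
    rejected: list[tuple[str, float]] = []
    for c in compound_list:
        if c.logs is None:
            raise ValidationError(f"{c.id}: no LogS value for solubility filter")
        if c.logs >= cutoff:
            retained.append(c)
        else:
            rejected.append((c.id, c.logs))
    for cid, logs in rejected:
        log.info("solubility filter rejected %s (LogS %.2f < %.2f)", cid, logs, cutoff)
    return retained, rejected


def bioaccumulation_score(
    d: DescriptorSet, model_version: str = "sam_surrogate_v1",
    coefficients: Mapping | None = None,
) -> BioaccumulationScore:
    """Worm bioaccumulation propensity in [0, 1].

    Logistic transform of a versioned linear combination of MW, cLogP, TPSA,
    hydrogen-bond donors and rotatable bonds; this is a transparent surrogate
    scoring convention of this package, not a trained uptake model.
    """
    w = dict(coefficients if coefficients is not None else sam_coefficients(model_version))
    z = (
        w["intercept"]
        + w["clogp"] * d.clogp
        + w["mw_per_100"] * d.mw / 100.0
        + w["tpsa_per_100"] * d.tpsa / 100.0
        + w["hbd"] * d.hbd
        + w["rotatable_bonds"] * d.rotatable_bonds
    )
    return BioaccumulationScore(value=1.0 / (1.0 + np.exp(-z)), model_version=model_version)


def pareto_fronts(points: np.ndarray, directions: Sequence[str]) -> np.ndarray:
    """Assign non-dominated front indices (1-based) by iterative peeling.

    ``points`` is an (n, k) objective matrix and ``directions`` gives
    ``"max"``/``"min"`` per column.  Point p dominates q iff p is at least as
    good on every objective and strictly better on at least one.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if np.isnan(pts).any():
        raise ValidationError("NaN objective value in Pareto sort")
    if pts.shape[1] != len(directions):
        raise ValidationError("directions length must match objective count")
    signed = pts.copy()
    for j, direction in enumerate(directions):
        if direction == "min":
            signed[:, j] = -signed[:, j]
        elif direction != "max":
            raise ConfigError(f"direction must be 'max' or 'min', got {direction!r}")

    n = signed.shape[0]
    fronts = np.zeros(n, dtype=int)
    remaining = list(range(n))
    front = 0
    while remaining:
        front += 1
        nondom = []
        for i in remaining:
            dominated = False
            for j in remaining:
                if j == i:
                    continue
                if np.all(signed[j] >= signed[i]) and np.any(signed[j] > signed[i]):
                    dominated = True
                    break
            if not dominated:
                nondom.append(i)
        for i in nondom:
            fronts[i] = front
        remaining = [i for i in remaining if i not in set(nondom)]
    return fronts


def tag_decoy_similar(
    library: Sequence[Compound],
    decoy: Compound,
    reference: Compound,
    fp_kind: str = cmp.DEFAULT_FP_KIND,
    nbits: int = cmp.DEFAULT_FP_NBITS,
) -> tuple[list[Compound], list[str]]:
    """Drop compounds more similar to a decoy scaffold than to the reference.

    Used to remove candidates closer to the biologically inert parent
    (succinimide) than to the active reference (ethosuximide); dropped ids
    are returned and logged.
    """
    fp_decoy = cmp.fingerprint(decoy, fp_kind, nbits)
    fp_ref = cmp.fingerprint(reference, fp_kind, nbits)
    kept: list[Compound] = []
    dropped: list[str] = []
    for c in library:
        fp = cmp.fingerprint(c, fp_kind, nbits)
        if cmp.tanimoto(fp, fp_decoy) > cmp.tanimoto(fp, fp_ref):
            dropped.append(c.id)
            log.info("excluded %s: closer to decoy %s than reference %s", c.id, decoy.id, reference.id)
        else:
            kept.append(c)
    return kept, dropped


def rank_library(
    library: Sequence[Compound],
    reference: Compound,
    logs_cutoff: float = DEFAULT_LOGS_CUTOFF,
    knots: Mapping | None = None,
    model_version: str = "sam_surrogate_v1",
    fp_kind: str = cmp.DEFAULT_FP_KIND,
    nbits: int = cmp.DEFAULT_FP_NBITS,
) -> pd.DataFrame:
    """Rank a library against a reference compound.

    Applies the solubility filter, computes Tanimoto-to-reference, CNS MPO
    total and bioaccumulation propensity, Pareto-sorts maximising all three,
    and orders rows by (front, descending MPO total, id).  Columns:
    ``id, name, tc_ref, mpo_total, bioacc, logs, front, order``.
    """
    retained, _ = solubility_filter(library, logs_cutoff)
    if not retained:
        log.warning("no compounds passed the solubility filter")
        return pd.DataFrame(
            columns=["id", "name", "tc_ref", "mpo_total", "bioacc", "logs", "front", "order"]
        )
    fp_ref = cmp.fingerprint(reference, fp_kind, nbits)
    rows = []
    for c in retained:
        d = cmp.compute_descriptors(c)
        rows.append(
            {
                "id": c.id,
                "name": c.name,
                "tc_ref": cmp.tanimoto(cmp.fingerprint(c, fp_kind, nbits), fp_ref),
                "mpo_total": cns_mpo(d, knots).total,
                "bioacc": bioaccumulation_score(d, model_version).value,
                "logs": d.logs,
            }
        )
    table = pd.DataFrame(rows)
    objectives = table[["mpo_total", "tc_ref", "bioacc"]].to_numpy()
    table["front"] = pareto_fronts(objectives, ["max", "max", "max"])
    table = table.sort_values(
        ["front", "mpo_total", "id"], ascending=[True, False, True]
    ).reset_index(drop=True)
    table["order"] = table.groupby("front").cumcount() + 1
    return table
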