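"""End-to-end seeded pipeline: prioritise, simulate, analyse, report.

A single global seed fans out to per-stage child seeds by stable hashing of
stage names, so the report is byte-identical across re-runs with the same
configuration and independent of stage ordering.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import compounds as cmp
from . import lifespan as ls
from . import nmrquant as nq
from . import prioritizer as pri
from . import seizure as sz
from . import synthgen as sg
from . import wormstats as ws
from .errors import ConfigError

log = logging.getLogger(__name__)

# optimal external concentrations established by the screens (molar)
OPTIMAL_ETHOSUXIMIDE_M = 8e-3
OPTIMAL_MPS_M = 5e-5


@dataclass(frozen=True)
class RunConfig:
    """Serialisable pipeline configuration; unknown keys are rejected."""

    seed: int = 17
    outdir: str = "wormlead_report"
    logs_cutoff: float = pri.DEFAULT_LOGS_CUTOFF
    reference: str = "cpd1"  # ethosuximide
    bioacc_model: str = "sam_surrogate_v1"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def potency_fold(conc_ref_molar: float = OPTIMAL_ETHOSUXIMIDE_M,
                 conc_test_molar: float = OPTIMAL_MPS_M) -> float:
    """Fold-ratio between two optimal external concentrations (e.g. 8 mM vs 0.05 mM = 160)."""
    if conc_ref_molar <= 0 or conc_test_molar <= 0:
        raise ConfigError("concentrations must be positive")
    return conc_ref_molar / conc_test_molar


def _seizure_stage(seed: int) -> dict:
    data = sg.gen_seizure(sg.SeizureScenario(), seed=seed)
    out = {}
    for cid, truth in (("cpd1", 9.7e-3), ("cpd9", 4.85e-3)):
        sub = data[data.compound_id.isin([cid, "vehicle"])]
        summary = sz.summarise(sub)
        drug = summary[summary.compound_id == cid]
        fit = sz.fit_4pl(
            np.concatenate([[0.0] * int((summary.compound_id == "vehicle").sum()), drug.conc_molar.to_numpy()]),
            np.concatenate(
                [
                    summary.loc[summary.compound_id == "vehicle", "mean_bobs"].to_numpy(),
                    drug.mean_bobs.to_numpy(),
                ]
            ),
        )
        out[cid] = {
            "ec50_mM": fit.ec50 * 1e3,
            "truth_mM": truth * 1e3,
            "hill": fit.hill,
        }
    a = data[data.compound_id == "cpd1"]
    b = data[data.compound_id == "cpd9"]
    fold, F, p = sz.compare_log_ec50(
        (a.conc_molar.to_numpy(), a.head_bobs.to_numpy()),
        (b.conc_molar.to_numpy(), b.head_bobs.to_numpy()),
    )
    out["mps_vs_ethosuximide"] = {"fold_change": fold, "F": F, "p": p}
    return out


def _lifespan_stage(seed: int) -> dict:
    out = {}
    for label, scenario in (
        ("tdp43", sg.LifespanScenario()),
        ("tdp43_daf16", sg.daf16_lifespan_scenario()),
    ):
        records = sg.gen_lifespans(scenario, seed=sg.child_seed(seed, label))
        by_group = {}
        for group in scenario.groups:
            grp = [r for r in records if r.group == group]
            summary = ls.mean_lifespan(grp)
            by_group[group] = {
                "mean_days": summary.mean_days,
                "sem": summary.sem,
                "n_deaths": summary.n_deaths,
                "n_censored": summary.n_censored,
            }
        dmso = [r for r in records if r.group == "DMSO"]
        mps = [r for r in records if r.group == "MPS"]
        chi2, p = ls.logrank(dmso, mps)
        out[label] = {
            "groups": by_group,
            "mps_vs_dmso": {
                "percent_change": ls.percent_change(
                    by_group["DMSO"]["mean_days"], by_group["MPS"]["mean_days"]
                ),
                "logrank_chi2": chi2,
                "logrank_p": p,
            },
        }
    return out


def _phenotype_stage(seed: int) -> dict:
    bends = sg.gen_bends(sg.BendsScenario(), seed=sg.child_seed(seed, "bends"))
    day5 = bends[bends.age_day == 5]
    groups = {g: grp.bends_per_min.to_numpy() for g, grp in day5.groupby("group")}
    H, p_global = ws.kruskal_wallis(*groups.values())
    dunn = ws.dunns_pairwise(groups, comparisons="control", control="TDP43_DMSO")
    neurons = sg.gen_neurons(sg.NeuronScenario(), seed=sg.child_seed(seed, "neurons"))
    deltas = ws.integrity_deltas(neurons, reference_group="TDP43_DMSO")
    day5_mps = deltas[(deltas.group == "TDP43_MPS") & (deltas.age_day == 5)]
    return {
        "bends_day5_kruskal": {"H": H, "p": p_global},
        "bends_day5_dunn": dunn.to_dict("records"),
        "mps_break_excess_day5": float(day5_mps.break_excess.iloc[0]),
    }


def _nmr_stage() -> dict:
    background = sg.default_metabolite_background()
    out = {}
    for cid, truth in (("cpd2", 206.6e-6), ("cpd1", 143.8e-6), ("cpd9", 1.25e-6)):
        scenario = sg.SpectrumScenario(
            compound_id=cid, windows=sg.DEFAULT_WINDOWS[cid], truth_internal_molar=truth
        )
        clean, standards = sg.gen_spectrum(scenario)  # noise-free forward model
        lysate, _ = sg.gen_spectrum(scenario, background=background)
        blank = sg.background_spectrum(scenario, background)
        windows_out = []
        for w, std in zip(scenario.windows, standards):
            cal = nq.fit_calibration(std)
            worms = nq.WormSampleSize(scenario.n_worms)
            conc = nq.internal_concentration(
                nq.integrate_window(clean, w), cal, scenario.extract_volume_l,
                worms, scenario.volume_per_worm_l,
            )
            conc_lysate = nq.internal_concentration(
                nq.integrate_window(lysate, w), cal, scenario.extract_volume_l,
                worms, scenario.volume_per_worm_l,
            )
            detected, diag = nq.detectability(lysate, w, blank)
            windows_out.append(
                {
                    "window_ppm": [w.lo_ppm, w.hi_ppm],
                    "detectable": detected,
                    "occupancy": diag["occupancy"],
                    "recovered_uM": conc.molar * 1e6,
                    "recovered_in_lysate_uM": conc_lysate.molar * 1e6,
                }
            )
        out[cid] = {"truth_uM": truth * 1e6, "windows": windows_out}
    return out


def run_pipeline(config: RunConfig = RunConfig()) -> dict:
    """Execute every stage and return (and write) the JSON-serialisable report."""
    library = cmp.fixture_library()
    reference = cmp.get_compound(library, config.reference)
    ranked = pri.rank_library(
        library, reference, logs_cutoff=config.logs_cutoff, model_version=config.bioacc_model
    )
    d_eth = cmp.compute_descriptors(cmp.get_compound(library, "cpd1"))
    d_mps = cmp.compute_descriptors(cmp.get_compound(library, "cpd9"))
    bio_gap = abs(
        pri.bioaccumulation_score(d_eth, config.bioacc_model).value
        - pri.bioaccumulation_score(d_mps, config.bioacc_model).value
    )
    report = {
        "config": asdict(config),
        "prioritisation": {
            "n_compounds": len(library),
            "n_front1": int((ranked.front == 1).sum()),
            "max_mpo": float(ranked.mpo_total.max()),
            "min_mpo": float(ranked.mpo_total.min()),
            "bioacc_gap_eth_mps": bio_gap,
            "table": ranked.to_dict("records"),
        },
        "potency": {
            "ethosuximide_optimal_mM": OPTIMAL_ETHOSUXIMIDE_M * 1e3,
            "mps_optimal_mM": OPTIMAL_MPS_M * 1e3,
            "fold": potency_fold(),
        },
        "seizure": _seizure_stage(sg.child_seed(config.seed, "seizure")),
        "phenotypes": _phenotype_stage(config.seed),
        "lifespan": _lifespan_stage(config.seed),
        "nmr": _nmr_stage(),
    }
    report["checks"] = {
        "potency_fold_is_160": abs(report["potency"]["fold"] - 160.0) < 1e-9,
        "max_mpo_is_6": abs(report["prioritisation"]["max_mpo"] - 6.0) < 1e-9,
        "lifespan_extension_about_25pct": abs(
            round(report["lifespan"]["tdp43"]["mps_vs_dmso"]["percent_change"]) - 25
        ) <= 3,
        "nmr_ethosuximide_round_trip": abs(
            report["nmr"]["cpd1"]["windows"][0]["recovered_uM"] - 143.8
        ) < 1e-3,
        "mps_windows_occluded": all(
            not w["detectable"] for w in report["nmr"]["cpd9"]["windows"]
        ),
    }
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    ranked.to_csv(outdir / "ranked.csv", index=False)
    return report
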