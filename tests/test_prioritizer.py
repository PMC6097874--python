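"""Desirability scoring, solubility filtering and Pareto ranking."""
import numpy as np
import pytest

from wormlead import compounds as cmp
from wormlead import prioritizer as pri
from wormlead.errors import ConfigError, ValidationError


class TestDesirability:
    @pytest.mark.parametrize(
        "x,expected", [(3.0, 1.0), (5.0, 0.0), (4.0, 0.5), (2.0, 1.0), (6.0, 0.0)]
    )
    def test_monotonic_boundaries_and_midpoint(self, x, expected):
        assert pri.desirability_monotonic(x, 3.0, 5.0) == expected

    def test_monotonic_bad_knots(self):
        with pytest.raises(ConfigError):
            pri.desirability_monotonic(1.0, 5.0, 3.0)

    @pytest.mark.parametrize(
        "x,expected", [(40.0, 1.0), (90.0, 1.0), (65.0, 1.0), (20.0, 0.0), (120.0, 0.0), (30.0, 0.5), (105.0, 0.5)]
    )
    def test_hump_plateau_and_ramps(self, x, expected):
        assert pri.desirability_hump(x, 20, 40, 90, 120) == expected

    def test_hump_bad_knots(self):
        with pytest.raises(ConfigError):
            pri.desirability_hump(1.0, 40, 20, 90, 120)


class TestCnsMpo:
    def test_ethosuximide_hand_value(self, descriptors):
        # all attributes fully desirable except the single N-H donor:
        # d_hbd = (3.5 - 1) / 3 -> total 5 + 5/6
        score = pri.cns_mpo(descriptors["cpd1"])
        assert score.d_hbd == pytest.approx(2.5 / 3.0, abs=1e-12)
        assert score.total == pytest.approx(5.0 + 2.5 / 3.0, abs=1e-9)

    def test_trimethadione_is_perfect(self, descriptors):
        # no donors, TPSA inside the plateau, low MW/logP: every component 1
        assert pri.cns_mpo(descriptors["cpd4"]).total == pytest.approx(6.0, abs=1e-12)

    def test_everything_beyond_zero_cutoffs_scores_zero(self):
        d = cmp.DescriptorSet(
            mw=700.0, clogp=8.0, clogd=8.0, tpsa=200.0, hbd=6, pka_basic=11.0,
            logs=-6.0, rotatable_bonds=12,
        )
        assert pri.cns_mpo(d).total == 0.0

    def test_components_bounded_and_sum(self, descriptors):
        for d in descriptors.values():
            s = pri.cns_mpo(d)
            comps = [s.d_clogp, s.d_clogd, s.d_mw, s.d_tpsa, s.d_hbd, s.d_pka]
            assert all(0.0 <= c <= 1.0 for c in comps)
            assert s.total == pytest.approx(sum(comps), abs=1e-9)


class TestSolubilityFilter:
    def test_boundary_inclusive(self):
        keep = cmp.Compound("a", "a", "C", logs=-4.5)
        drop = cmp.Compound("b", "b", "C", logs=-4.6)
        retained, rejected = pri.solubility_filter([keep, drop])
        assert [c.id for c in retained] == ["a"]
        assert rejected == [("b", -4.6)]

    def test_empty_input(self):
        assert pri.solubility_filter([]) == ([], [])

    def test_idempotent(self, library):
        once, _ = pri.solubility_filter(library)
        twice, _ = pri.solubility_filter(once)
        assert [c.id for c in twice] == [c.id for c in once]

    def test_missing_logs_raises(self):
        with pytest.raises(ValidationError):
            pri.solubility_filter([cmp.Compound("a", "a", "C", logs=None)])


class TestBioaccumulation:
    def test_zero_coefficients_give_half(self, descriptors):
        zero = dict.fromkeys(
            ["intercept", "clogp", "mw_per_100", "tpsa_per_100", "hbd", "rotatable_bonds"], 0.0
        )
        for d in descriptors.values():
            assert pri.bioaccumulation_score(d, coefficients=zero).value == 0.5

    def test_monotone_in_clogp_with_positive_weight(self, descriptors):
        base = descriptors["cpd1"]
        higher = cmp.DescriptorSet(
            mw=base.mw, clogp=base.clogp + 1.0, clogd=base.clogd + 1.0, tpsa=base.tpsa,
            hbd=base.hbd, pka_basic=base.pka_basic, logs=base.logs,
            rotatable_bonds=base.rotatable_bonds,
        )
        assert (
            pri.bioaccumulation_score(higher).value
            >= pri.bioaccumulation_score(base).value
        )

    def test_ethosuximide_and_mps_score_similarly(self, descriptors):
        gap = abs(
            pri.bioaccumulation_score(descriptors["cpd1"]).value
            - pri.bioaccumulation_score(descriptors["cpd9"]).value
        )
        assert gap < 0.05  # calibration check on the default surrogate

    def test_unknown_version_rejected(self, descriptors):
        with pytest.raises(ConfigError):
            pri.bioaccumulation_score(descriptors["cpd1"], model_version="sam_v999")


def brute_force_fronts(points: np.ndarray) -> np.ndarray:
    """Independent O(n^2) dominance oracle (maximisation on all columns)."""
    n = len(points)
    dominates = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if i != j:
                dominates[i, j] = bool(
                    np.all(points[i] >= points[j]) and np.any(points[i] > points[j])
                )
    fronts = np.zeros(n, dtype=int)
    alive = np.ones(n, dtype=bool)
    level = 0
    while alive.any():
        level += 1
        nondominated = alive & ~np.array(
            [np.any(dominates[alive, i]) for i in range(n)]
        )
        fronts[nondominated] = level
        alive &= ~nondominated
    return fronts


class TestParetoFronts:
    def test_single_point(self):
        assert pri.pareto_fronts(np.array([[1.0, 2.0]]), ["max", "max"]).tolist() == [1]

    def test_strict_domination_gives_two_fronts(self):
        fronts = pri.pareto_fronts(np.array([[1.0, 1.0], [2.0, 2.0]]), ["max", "max"])
        assert fronts.tolist() == [2, 1]

    def test_min_direction_flips_dominance(self):
        fronts = pri.pareto_fronts(np.array([[1.0], [2.0]]), ["min"])
        assert fronts.tolist() == [1, 2]

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            pri.pareto_fronts(np.array([[1.0, np.nan]]), ["max", "max"])

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            pts = rng.normal(size=(20, 3))
            got = pri.pareto_fronts(pts, ["max", "max", "max"])
            assert got.tolist() == brute_force_fronts(pts).tolist()

    def test_removing_dominated_point_preserves_front1(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(15, 3))
        fronts = pri.pareto_fronts(pts, ["max"] * 3)
        dominated = np.where(fronts > 1)[0]
        keep = np.delete(np.arange(len(pts)), dominated[0])
        fronts2 = pri.pareto_fronts(pts[keep], ["max"] * 3)
        front1_before = set(keep[i] for i in range(len(keep)) if fronts[keep[i]] == 1)
        front1_after = set(keep[i] for i in range(len(keep)) if fronts2[i] == 1)
        assert front1_before == front1_after


class TestRankLibrary:
    @pytest.fixture(scope="class")
    def ranked(self, library, by_id):
        return pri.rank_library(library, by_id["cpd1"])

    def test_reference_has_unit_similarity(self, ranked):
        assert ranked.loc[ranked.id == "cpd1", "tc_ref"].iloc[0] == 1.0

    def test_fronts_match_pareto_on_same_matrix(self, ranked):
        objective = ranked[["mpo_total", "tc_ref", "bioacc"]].to_numpy()
        assert (
            pri.pareto_fronts(objective, ["max"] * 3).tolist() == ranked.front.tolist()
        )

    def test_max_mpo_is_perfect_score(self, ranked):
        assert ranked.mpo_total.max() == pytest.approx(6.0, abs=1e-9)

    def test_rows_sorted_by_front_then_mpo(self, ranked):
        assert ranked.front.is_monotonic_increasing or (
            ranked.sort_values(["front", "mpo_total", "id"], ascending=[True, False, True])
            .reset_index(drop=True)
            .equals(ranked)
        )

    def test_all_rows_pass_solubility(self, ranked):
        assert (ranked.logs >= pri.DEFAULT_LOGS_CUTOFF).all()

    def test_empty_after_filter_warns_and_returns_empty(self, library, by_id):
        table = pri.rank_library(library, by_id["cpd1"], logs_cutoff=10.0)
        assert table.empty

    def test_mpo_invariant_to_library_composition(self, library, by_id, descriptors):
        small = pri.rank_library(library[:5], by_id["cpd1"])
        full = pri.rank_library(library, by_id["cpd1"])
        for cid in small.id:
            assert small.loc[small.id == cid, "mpo_total"].iloc[0] == pytest.approx(
                full.loc[full.id == cid, "mpo_total"].iloc[0], abs=1e-12
            )


class TestDecoyExclusion:
    def test_succinimide_closer_compounds_dropped(self, library, by_id):
        kept, dropped = pri.tag_decoy_similar(library, by_id["cpd2"], by_id["cpd1"])
        assert "cpd2" in dropped  # the decoy itself is closest to itself
        assert "cpd1" in {c.id for c in kept}
        assert len(kept) + len(dropped) == len(library)
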