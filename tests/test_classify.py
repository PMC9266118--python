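"""Segregation, differentiation scoring, percentages and designation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from limbtraj import (
    ClusterProfile,
    DesignationConfig,
    MarkerPanels,
    conjunctival_diff_score,
    corneal_diff_score,
    designate,
    epithelial_percentages,
    flag_proliferative,
    segregate_epithelial,
    type_non_epithelial,
)
from limbtraj.classify import ClassifyError, LSC_LABELS
from limbtraj.trajectory import BranchAssignment, CellType

from conftest import expected_designations, truth_cluster_mapping


def _profile(cluster_id, condition, n_cells=100, **gene_means):
    genes = sorted(gene_means)
    return ClusterProfile(
        cluster_id=cluster_id,
        condition=condition,
        n_cells=n_cells,
        mean_expr=pd.Series({g: float(gene_means[g]) for g in genes}),
    )


class TestScores:
    @pytest.mark.parametrize(
        "mean, score",
        [(0.0, 1), (0.5, 1), (10.0, 2), (5.5, 2), (20.0, 2), (200.0, 3),
         (1000.0, 3),
         # gap values fall to the nearest range on the geometric scale
         (3.0, 2), (2.0, 1), (50.0, 2), (100.0, 3)],
    )
    def test_corneal_printed_ranges(self, mean, score):
        assert corneal_diff_score(mean) == score

    @pytest.mark.parametrize(
        "mean, score", [(0.1, 1), (0.0, 1), (15.0, 2), (9.5, 2), (2.0, 1),
                        (5.0, 2)]
    )
    def test_conjunctival_printed_ranges(self, mean, score):
        assert conjunctival_diff_score(mean) == score

    @pytest.mark.parametrize("fn", [corneal_diff_score, conjunctival_diff_score])
    def test_invalid_means_rejected(self, fn):
        for bad in (-1.0, np.nan, np.inf):
            with pytest.raises(ClassifyError):
                fn(bad)

    def test_strict_mode_errors_on_gaps(self):
        with pytest.raises(ClassifyError):
            corneal_diff_score(3.0, gap_mode="strict")
        with pytest.raises(ClassifyError):
            conjunctival_diff_score(2.0, gap_mode="strict")
        assert corneal_diff_score(10.0, gap_mode="strict") == 2

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=0, max_value=1e6),
           st.floats(min_value=0, max_value=1e6))
    def test_scoring_total_and_monotone(self, a, b):
        lo, hi = sorted((a, b))
        assert corneal_diff_score(lo) <= corneal_diff_score(hi)
        assert conjunctival_diff_score(lo) <= conjunctival_diff_score(hi)
        assert corneal_diff_score(hi) in (1, 2, 3)
        assert conjunctival_diff_score(hi) in (1, 2)


class TestSegregation:
    def test_high_keratin_is_epithelial(self):
        p = _profile("A", "unwounded", Krt14=50.0, Col1a1=0.0)
        assert segregate_epithelial([p])["A|unwounded"] is True

    def test_stromal_profile_is_not_epithelial(self):
        p = _profile("B", "unwounded", Krt12=0.0, Krt14=0.0, Col1a1=30.0)
        assert segregate_epithelial([p])["B|unwounded"] is False

    def test_default_study_8_plus_8(self, default_run):
        counts = default_run.report.counts
        assert counts["epithelial_clusters_unwounded"] == 8
        assert counts["epithelial_clusters_wounded"] == 8


class TestNonEpithelialTyping:
    def _cohort(self):
        base = dict(Col1a1=0.1, Col1a2=0.1, Dcn=0.1, Cd34=0.1,
                    Trdc=0.1, Cd3g=0.1, Trbc1=0.1,
                    Cxcl2=0.1, Ccl4=0.1, Cd14=0.1)
        t = dict(base, Trdc=30.0, Cd3g=25.0, Trbc1=28.0)
        mac = dict(base, Cxcl2=30.0, Ccl4=25.0, Cd14=28.0)
        stro = dict(base, Col1a1=30.0, Col1a2=25.0, Dcn=20.0, Cd34=15.0)
        ps = [
            _profile("T", "unwounded", **t),
            _profile("M", "unwounded", **mac),
            _profile("S", "unwounded", **stro),
            _profile("flat", "unwounded", **base),
        ]
        for p in ps:
            p.epithelial = False
        return ps

    def test_panel_argmax(self):
        ps = self._cohort()
        assert type_non_epithelial(ps[0], ps) == "t_cell"
        assert type_non_epithelial(ps[1], ps) == "macrophage"
        assert type_non_epithelial(ps[2], ps) == "stromal"

    def test_tie_is_unresolved(self):
        ps = self._cohort()
        assert type_non_epithelial(ps[3], ps) == "unresolved"

    def test_default_study_non_epithelial_types(self, default_run):
        mapping = truth_cluster_mapping(default_run)
        truth = default_run.truth
        for label, lineage in default_run.non_epithelial_types.items():
            assert lineage == truth.cluster_lineage[mapping[label]]


class TestPercentages:
    def test_single_type_is_one(self):
        p = _profile("A", "unwounded", Krt14=10.0)
        p.epithelial = True
        t = CellType("A|unwounded", [("A", "unwounded")], "unwounded_only")
        pct = epithelial_percentages([p], {"A|unwounded": True}, [t])
        assert pct[("A|unwounded", "unwounded")] == 1.0

    def test_hand_fixture_20_80(self):
        a = _profile("A", "unwounded", n_cells=20, Krt14=10.0)
        b = _profile("B", "unwounded", n_cells=80, Krt14=10.0)
        flags = {"A|unwounded": True, "B|unwounded": True}
        types = [
            CellType("A|unwounded", [("A", "unwounded")], "unwounded_only"),
            CellType("B|unwounded", [("B", "unwounded")], "unwounded_only"),
        ]
        pct = epithelial_percentages([a, b], flags, types)
        assert pct[("A|unwounded", "unwounded")] == pytest.approx(0.2)
        assert pct[("B|unwounded", "unwounded")] == pytest.approx(0.8)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(min_value=1, max_value=500), min_size=1,
                    max_size=8))
    def test_sums_to_one_per_condition(self, sizes):
        profiles, types, flags = [], [], {}
        for i, n in enumerate(sizes):
            p = _profile(f"C{i}", "unwounded", n_cells=n, Krt14=5.0)
            p.epithelial = True
            profiles.append(p)
            flags[p.label] = True
            types.append(CellType(p.label, [(f"C{i}", "unwounded")],
                                  "unwounded_only"))
        pct = epithelial_percentages(profiles, flags, types)
        assert sum(pct.values()) == pytest.approx(1.0, abs=1e-9)


class TestProliferation:
    def test_extreme_profile_flagged(self):
        genes = dict(Mki67=1.0, Mcm2=1.0, Mcm3=1.0, Mcm4=1.0, Mcm5=1.0,
                     Mcm6=1.0, Mcm7=1.0)
        quiet = [_profile(f"Q{i}", "unwounded", **genes) for i in range(4)]
        hot = _profile("H", "unwounded", **{g: 10.0 for g in genes})
        flags = flag_proliferative(quiet + [hot])
        assert flags["H|unwounded"] is True
        assert not any(flags[p.label] for p in quiet)

    def test_identical_profiles_never_flagged(self):
        genes = dict(Mki67=3.0, Mcm2=3.0, Mcm3=3.0, Mcm4=3.0, Mcm5=3.0,
                     Mcm6=3.0, Mcm7=3.0)
        ps = [_profile(f"P{i}", "unwounded", **genes) for i in range(5)]
        assert not any(flag_proliferative(ps).values())

    def test_needs_three_profiles(self):
        ps = [_profile("A", "unwounded", Mki67=1.0),
              _profile("B", "unwounded", Mki67=2.0)]
        with pytest.raises(ClassifyError):
            flag_proliferative(ps)

    def test_default_study_planted_proliferative(self, default_run):
        mapping = truth_cluster_mapping(default_run)
        truth = default_run.truth
        flags = flag_proliferative(default_run.profiles)
        for label, flagged in flags.items():
            assert flagged == truth.cluster_proliferative[mapping[label]], label


class TestDesignation:
    def _atlas(self, lsc2_pcts=(0.20, 0.11), lsc1_pcts=(0.18, 0.22)):
        """Minimal synthetic atlas: one trajectory branch with two LSC pairs
        and one LPC, one branch with a differentiated pair, one SPC branch."""
        prolif0 = dict(Mki67=1.0, Mcm2=1.0, Mcm3=1.0, Mcm4=1.0, Mcm5=1.0,
                       Mcm6=1.0, Mcm7=1.0)

        def mk(cid, cond, n, krt12, krt13, prog):
            p = _profile(cid, cond, n_cells=n, Krt12=krt12, Krt13=krt13,
                         Krt14=prog, Krt15=prog, Krt17=30.0, **prolif0)
            p.epithelial = True
            return p

        n_uw, n_wd = 1000, 1000
        profiles = [
            mk("L1u", "unwounded", int(lsc1_pcts[0] * n_uw), 0.3, 0.2, 60),
            mk("L1w", "wounded", int(lsc1_pcts[1] * n_wd), 0.3, 0.2, 60),
            mk("L2u", "unwounded", int(lsc2_pcts[0] * n_uw), 0.3, 0.2, 60),
            mk("L2w", "wounded", int(lsc2_pcts[1] * n_wd), 0.3, 0.2, 60),
            mk("Pu", "unwounded", 150, 12.0, 0.2, 50),
            mk("Pw", "wounded", 150, 12.0, 0.2, 50),
            mk("Du", "unwounded", 150, 250.0, 0.2, 5),
            mk("Dw", "wounded", 150, 250.0, 0.2, 5),
            mk("Su", "unwounded", n_uw - int(lsc1_pcts[0] * n_uw)
               - int(lsc2_pcts[0] * n_uw) - 300, 0.3, 0.2, 20),
            mk("Sw", "wounded", n_wd - int(lsc1_pcts[1] * n_wd)
               - int(lsc2_pcts[1] * n_wd) - 300, 0.3, 0.2, 20),
        ]
        types = [
            CellType("L1u|unwounded+L1w|wounded",
                     [("L1u", "unwounded"), ("L1w", "wounded")], "shared", "B1"),
            CellType("L2u|unwounded+L2w|wounded",
                     [("L2u", "unwounded"), ("L2w", "wounded")], "shared", "B1"),
            CellType("Pu|unwounded+Pw|wounded",
                     [("Pu", "unwounded"), ("Pw", "wounded")], "shared", "B1"),
            CellType("Du|unwounded+Dw|wounded",
                     [("Du", "unwounded"), ("Dw", "wounded")], "shared", "B2"),
            CellType("Su|unwounded+Sw|wounded",
                     [("Su", "unwounded"), ("Sw", "wounded")], "shared", "B3"),
        ]
        branches = BranchAssignment(branches={
            "B1": {"L1u|unwounded", "L1w|wounded", "L2u|unwounded",
                   "L2w|wounded", "Pu|unwounded", "Pw|wounded"},
            "B2": {"Du|unwounded", "Dw|wounded"},
            "B3": {"Su|unwounded", "Sw|wounded"},
        })
        return profiles, types, branches

    def test_reference_percentage_shifts(self):
        """A 20%->11% LSC-eligible type is active; 18%->22% is quiescent."""
        profiles, types, branches = self._atlas()
        labels = {d.cell_type: d.label for d in
                  designate(types, profiles, branches)}
        assert labels["L2u|unwounded+L2w|wounded"] == "putative_active_LSC"
        assert labels["L1u|unwounded+L1w|wounded"] == "putative_quiescent_LSC"
        assert labels["Pu|unwounded+Pw|wounded"] == "putative_LPC"
        assert labels["Du|unwounded+Dw|wounded"] == "putative_differentiating_LPC"
        assert labels["Su|unwounded+Sw|wounded"] == "unknown_origin_SPC"

    def test_no_decrease_is_not_active(self):
        profiles, types, branches = self._atlas(lsc2_pcts=(0.15, 0.15))
        labels = {d.cell_type: d.label for d in
                  designate(types, profiles, branches)}
        assert labels["L2u|unwounded+L2w|wounded"] == "putative_quiescent_LSC"

    def test_ztest_rule_agrees_on_large_shift(self):
        profiles, types, branches = self._atlas()
        cfg = DesignationConfig(decrease_rule="ztest")
        labels = {d.cell_type: d.label for d in
                  designate(types, profiles, branches, config=cfg)}
        assert labels["L2u|unwounded+L2w|wounded"] == "putative_active_LSC"
        assert labels["L1u|unwounded+L1w|wounded"] == "putative_quiescent_LSC"

    def test_labels_are_exclusive(self, default_run):
        seen = {}
        for d in default_run.designations:
            assert d.cell_type not in seen
            seen[d.cell_type] = d.label
            assert sum(d.label == l for l in LSC_LABELS) <= 1

    def test_end_to_end_matches_ground_truth(self, default_run):
        for got, expected in expected_designations(default_run):
            assert len(expected) == 1 and got in expected
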