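"""ΔΔCt arithmetic, calibrator conventions, and reference-gene stability."""

import numpy as np
import pandas as pd
import pytest

from neuroassay import qpcr
from neuroassay.synthetic import CtGroundTruth, generate_ct_table


def make_table(rows):
    return pd.DataFrame(rows, columns=["gene", "group", "dose_mM",
                                       "replicate", "ct"])


@pytest.fixture
def small_table():
    """Two genes, UnDiff at 0 and 7 mM, three replicates, no noise."""
    rows = []
    for dose, target_ct in [(0.0, 25.0), (7.0, 26.0)]:
        for rep in range(1, 4):
            rows.append(("GENE", "UnDiff", dose, rep, target_ct))
            rows.append(("HK", "UnDiff", dose, rep, 20.0))
    return make_table(rows)


class TestDeltaCt:
    def test_pairing_preserves_replicates(self, small_table):
        dct = qpcr.delta_ct(small_table, "HK")
        assert len(dct) == 6
        assert set(dct.loc[dct.dose_mM == 0.0, "delta_ct"]) == {5.0}
        assert set(dct.loc[dct.dose_mM == 7.0, "delta_ct"]) == {6.0}

    def test_hand_values(self):
        t = make_table([("G", "UnDiff", 0.0, 1, 25.0), ("G", "UnDiff", 0.0, 2, 20.0),
                        ("HK", "UnDiff", 0.0, 1, 20.0), ("HK", "UnDiff", 0.0, 2, 20.0)])
        dct = qpcr.delta_ct(t, "HK")
        assert sorted(dct["delta_ct"]) == [0.0, 5.0]

    def test_missing_reference_rows_dropped_with_warning(self, small_table):
        broken = small_table[~((small_table.gene == "HK")
                               & (small_table.replicate == 3))]
        with pytest.warns(UserWarning, match="dropped 2"):
            dct = qpcr.delta_ct(broken, "HK")
        assert len(dct) == 4

    def test_absent_reference_gene_is_error(self, small_table):
        with pytest.raises(ValueError, match="absent"):
            qpcr.delta_ct(small_table, "NOPE")


class TestFoldChange:
    @pytest.mark.parametrize("ddct, fc", [(0.0, 1.0), (1.0, 0.5), (-2.0, 4.0)])
    def test_two_to_minus_ddct(self, ddct, fc):
        dct = pd.DataFrame({
            "gene": "G", "group": "UnDiff",
            "dose_mM": [0.0] * 2 + [7.0] * 2, "replicate": [1, 2, 1, 2],
            "delta_ct": [5.0, 5.0, 5.0 + ddct, 5.0 + ddct]})
        res = qpcr.fold_change(dct)
        got = res.groups.set_index("dose_mM")
        assert got.loc[7.0, "fold_change"] == pytest.approx(fc)

    def test_calibrator_mean_maps_to_unity_both_conventions(self):
        rng = np.random.default_rng(0)
        dct = pd.DataFrame({
            "gene": "G",
            "group": np.repeat(["UnDiff", "Diff"], 6),
            "dose_mM": np.tile(np.repeat([0.0, 35.0], 3), 2),
            "replicate": np.tile([1, 2, 3], 4),
            "delta_ct": rng.normal(5, 1, 12)})
        for convention in ("within-status", "cross-status"):
            cal = qpcr.calibrator_means(dct, convention)
            eff = 2.0
            assert (eff ** -(cal["calibrator_mean_dct"]
                             - cal["calibrator_mean_dct"]) == 1.0).all()
            res = qpcr.fold_change(dct, convention)
            merged = res.replicates.merge(
                cal, on=["gene", "group"] if convention == "within-status"
                else ["gene"])
            at_mean = eff ** -(merged["calibrator_mean_dct"]
                               - merged["calibrator_mean_dct"])
            assert (at_mean == 1.0).all()

    def test_conventions_pick_documented_calibrators(self):
        dct = pd.DataFrame({
            "gene": "G",
            "group": np.repeat(["UnDiff", "Diff"], 4),
            "dose_mM": np.tile([0.0, 0.0, 7.0, 7.0], 2),
            "replicate": np.tile([1, 2], 4),
            "delta_ct": [1.0, 3.0, 9, 9, 5.0, 7.0, 9, 9]})
        within = qpcr.calibrator_means(dct, "within-status")
        got = within.set_index("group")["calibrator_mean_dct"]
        assert got["UnDiff"] == 2.0 and got["Diff"] == 6.0
        cross = qpcr.calibrator_means(dct, "cross-status")
        assert cross["calibrator_mean_dct"].iloc[0] == 2.0

    def test_missing_calibrator_group_names_gene(self):
        dct = pd.DataFrame({"gene": "G", "group": "UnDiff",
                            "dose_mM": [7.0, 7.0], "replicate": [1, 2],
                            "delta_ct": [1.0, 2.0]})
        with pytest.raises(ValueError, match="G"):
            qpcr.calibrator_means(dct, "within-status")

    def test_shift_of_one_gene_leaves_fold_changes_unchanged(self):
        gt = CtGroundTruth({("G1", ("Diff", 35.0)): 0.3},
                           replicate_sd=0.15, seed=4)
        table = generate_ct_table(gt)
        shifted = table.copy()
        shifted.loc[shifted.gene == "G1", "ct"] += 3.7
        a = qpcr.relative_expression(table, reference="B-ACTIN")
        b = qpcr.relative_expression(shifted, reference="B-ACTIN")
        pd.testing.assert_frame_equal(a.groups, b.groups)

    def test_geometric_group_statistic_flag(self):
        dct = pd.DataFrame({"gene": "G", "group": "UnDiff",
                            "dose_mM": [0.0, 0.0, 7.0, 7.0],
                            "replicate": [1, 2, 1, 2],
                            "delta_ct": [5.0, 5.0, 6.0, 8.0]})
        mean_fc = qpcr.fold_change(dct).groups.set_index("dose_mM")
        geo = qpcr.fold_change(dct, group_statistic="geometric"
                               ).groups.set_index("dose_mM")
        assert mean_fc.loc[7.0, "fold_change"] == pytest.approx((0.5 + 0.125) / 2)
        assert geo.loc[7.0, "fold_change"] == pytest.approx(2.0 ** -2.0)

    def test_nonpositive_ct_rejected(self):
        t = make_table([("G", "UnDiff", 0.0, 1, -1.0)])
        with pytest.raises(ValueError):
            qpcr.delta_ct(t, "G")


class TestNormFinder:
    def test_constant_candidate_wins_over_noisy_ones(self):
        gt = CtGroundTruth({}, replicate_sd=0.5,
                           housekeeping_genes=("A", "B", "C"),
                           gene_sd={"A": 0.0}, seed=3)
        res = qpcr.normfinder_stability(generate_ct_table(gt), ("A", "B", "C"))
        assert res.selected_gene == "A"
        assert res.stability["A"] < min(res.stability["B"], res.stability["C"])

    def test_identical_candidates_tie_alphabetically_with_warning(self):
        gt = CtGroundTruth({}, replicate_sd=0.0,
                           housekeeping_genes=("A", "B"), seed=0)
        with pytest.warns(UserWarning, match="tie"):
            res = qpcr.normfinder_stability(generate_ct_table(gt), ("A", "B"))
        assert res.selected_gene == "A"

    def test_zero_variance_input_does_not_divide_by_zero(self):
        gt = CtGroundTruth({}, replicate_sd=0.0,
                           housekeeping_genes=("A", "B", "C"),
                           housekeeping_bias={("B", ("Diff", 35.0)): 1.0},
                           seed=0)
        res = qpcr.normfinder_stability(generate_ct_table(gt), ("A", "B", "C"))
        assert np.isfinite(list(res.stability.values())).all()
        assert res.selected_gene in ("A", "C")

    def test_biased_and_noisy_competitors_rank_behind_stable_gene(self):
        gt = CtGroundTruth({}, replicate_sd=0.1,
                           housekeeping_genes=("A", "B", "C"),
                           gene_sd={"C": 1.0},
                           housekeeping_bias={("B", ("Diff", 35.0)): 1.0},
                           seed=17)
        res = qpcr.normfinder_stability(generate_ct_table(gt), ("A", "B", "C"))
        assert res.selected_gene == "A"
        assert res.stability["A"] < res.stability["B"]
        assert res.stability["A"] < res.stability["C"]

    def test_requires_two_candidates_and_two_groups(self):
        gt = CtGroundTruth({}, seed=0)
        table = generate_ct_table(gt)
        with pytest.raises(ValueError):
            qpcr.normfinder_stability(table, ("B-ACTIN",))
        one_group = table[(table.group == "Diff") & (table.dose_mM == 0.0)]
        with pytest.raises(ValueError):
            qpcr.normfinder_stability(one_group, ("B-ACTIN", "PGK1"))


class TestAutoSelection:
    def test_relative_expression_uses_stable_reference(self):
        gt = CtGroundTruth({("G1", ("UnDiff", 35.0)): 0.25},
                           replicate_sd=0.0,
                           housekeeping_genes=("B-ACTIN", "GAPDH", "PGK1"),
                           gene_sd={"GAPDH": 1.0, "PGK1": 0.6}, seed=8)
        res = qpcr.relative_expression(generate_ct_table(gt), reference="auto")
        got = res.groups.set_index(["gene", "group", "dose_mM"])
        assert got.loc[("G1", "UnDiff", 35.0), "fold_change"] == pytest.approx(
            0.25, abs=1e-12)
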