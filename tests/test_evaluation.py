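"""Stratified splitter, AUC, stability rules, correlations, leakage guards."""

import numpy as np
import pandas as pd
import pytest

from tbs.evaluation import (auc, balance_cost, classify_stability,
                            feature_anthro_correlations, stability_assess,
                            stratified_multicriteria_kfold)


class TestAUC:
    def test_perfect_ordering(self):
        assert auc([0.1, 0.2, 0.8, 0.9], ["A", "A", "B", "B"]) == 1.0

    def test_worked_three_subject_example(self):
        # positives score 0.9 and 0.4, negative 0.8: one win, one loss
        assert auc([0.9, 0.8, 0.4], ["B", "A", "B"]) == 0.5

    def test_all_ties_give_half(self):
        assert auc([1.0, 1.0, 1.0, 1.0], ["A", "B", "A", "B"]) == 0.5

    def test_equals_exhaustive_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(6, 30)
            scores = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
            labels = rng.choice(["A", "B"], size=n)
            if len(set(labels)) < 2:
                continue
            pos = scores[labels == "B"]
            neg = scores[labels == "A"]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc(scores, labels) == pytest.approx(
                wins / (pos.size * neg.size), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], ["A", "A"])


class TestStratifiedSplitter:
    def test_class_totals_conserved(self, study_size_metadata):
        fa = stratified_multicriteria_kfold(study_size_metadata, k=3, seed=1)
        rep = fa.balance_report
        totals = rep.groupby("severity")["n"].sum()
        assert totals["Non"] == 74
        assert totals["Mild"] == 35
        assert totals["Moderate"] == 50
        assert totals["Severe"] == 40
        assert len(fa.assignment) == 199
        assert sorted(set(fa.assignment.values())) == [1, 2, 3]

    def test_partition_exactness(self, study_size_metadata):
        fa = stratified_multicriteria_kfold(study_size_metadata, k=3, seed=2)
        ids = list(fa.assignment)
        assert len(ids) == len(set(ids)) == len(study_size_metadata)

    def test_single_class_even_split(self):
        cohort = pd.DataFrame(dict(
            subject_id=[f"s{i}" for i in range(10)], severity="Mild",
            ahi=10.0, age=50.0, sex="M", bmi=30.0, nc=40.0, mps=2))
        fa = stratified_multicriteria_kfold(cohort, k=2, seed=0)
        counts = pd.Series(fa.assignment).value_counts()
        assert sorted(counts) == [5, 5]

    def test_beats_random_class_only_stratification(self, study_size_metadata):
        coh = study_size_metadata
        fa = stratified_multicriteria_kfold(coh, k=3, seed=3)
        rng = np.random.default_rng(0)
        costs = []
        for _ in range(100):
            a = np.zeros(len(coh), dtype=int)
            for _, idx in coh.groupby("severity").groups.items():
                idx = np.asarray(list(idx))
                a[rng.permutation(idx)] = (np.arange(idx.size) % 3) + 1
            costs.append(balance_cost(coh, a, 3,
                                      ("age", "bmi", "nc", "sex", "mps")))
        assert fa.cost <= np.median(costs)

    def test_determinism(self, study_size_metadata):
        a = stratified_multicriteria_kfold(study_size_metadata, k=3, seed=5)
        b = stratified_multicriteria_kfold(study_size_metadata, k=3, seed=5)
        assert a.assignment == b.assignment

    def test_small_class_warns(self):
        cohort = pd.DataFrame(dict(
            subject_id=["a", "b", "c", "d"],
            severity=["Non", "Non", "Non", "Severe"],
            ahi=[1, 2, 3, 50], age=50.0, sex="M", bmi=30.0, nc=40.0, mps=1))
        with pytest.warns(UserWarning):
            stratified_multicriteria_kfold(cohort, k=3, seed=0)

    def test_rejects_bad_inputs(self, study_size_metadata):
        with pytest.raises(ValueError):
            stratified_multicriteria_kfold(study_size_metadata, k=1)
        with pytest.raises(ValueError):
            stratified_multicriteria_kfold(study_size_metadata, k=3,
                                           criteria=("height",))


class TestStabilityRules:
    @pytest.mark.parametrize("d_auc,d_corr,expected", [
        (0.0, 0.05, "stable"),
        (0.001806, 0.137229, "slightly_unstable"),
        (0.02, 0.2, "unstable"),
        (0.005, 0.16, "unstable"),
        (0.05, 0.05, "unstable"),
    ])
    def test_threshold_rule(self, d_auc, d_corr, expected):
        assert classify_stability(d_auc, d_corr) == expected

    def test_fold_averaging(self):
        per_fold = pd.DataFrame(dict(
            feature=["f", "f"], fold=[1, 2],
            train_auc=[0.9, 0.9], test_auc=[0.9, 0.9],
            train_corr=[0.5, 0.5], test_corr=[0.45, 0.55]))
        recs = stability_assess(per_fold)
        assert len(recs) == 1
        assert recs[0].abs_delta_auc == 0.0
        assert recs[0].abs_delta_corr == pytest.approx(0.05)
        assert recs[0].stability_class == "stable"

    def test_missing_values_rejected(self):
        bad = pd.DataFrame(dict(feature=["f"], fold=[1], train_auc=[np.nan],
                                test_auc=[0.9], train_corr=[0.1],
                                test_corr=[0.1]))
        with pytest.raises(ValueError):
            stability_assess(bad)


class TestAnthroCorrelations:
    def _setup(self):
        cohort = pd.DataFrame(dict(
            subject_id=[f"s{i}" for i in range(12)],
            severity=["Non"] * 6 + ["Severe"] * 6,
            ahi=np.r_[np.linspace(0, 4, 6), np.linspace(35, 80, 6)],
            age=np.linspace(30, 66, 12), sex=["M", "F"] * 6,
            bmi=np.linspace(22, 44, 12), nc=np.linspace(34, 48, 12),
            mps=[1, 2, 3, 4] * 3))
        fa = stratified_multicriteria_kfold(cohort, k=2, seed=0)
        return cohort, fa

    def test_self_correlation_with_nc_is_one(self):
        cohort, fa = self._setup()
        table = pd.DataFrame(
            {"MouthExpiration_Peak": cohort["nc"].to_numpy()},
            index=cohort["subject_id"])
        out = feature_anthro_correlations(table, cohort, fa, variables=("nc",))
        assert np.allclose(out["pearson_r"], 1.0)

    def test_hand_computed_five_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        v = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        r_hand = (np.mean(x * v) - x.mean() * v.mean()) / (x.std() * v.std())
        from scipy.stats import pearsonr
        assert pearsonr(x, v)[0] == pytest.approx(r_hand, abs=1e-12)

    def test_affine_invariance(self):
        cohort, fa = self._setup()
        base = cohort["bmi"].to_numpy() + 0.1 * np.arange(12)
        t1 = pd.DataFrame({"F_X": base}, index=cohort["subject_id"])
        t2 = pd.DataFrame({"F_X": 3.0 * base - 11}, index=cohort["subject_id"])
        o1 = feature_anthro_correlations(t1, cohort, fa, variables=("bmi",))
        o2 = feature_anthro_correlations(t2, cohort, fa, variables=("bmi",))
        assert np.allclose(o1["pearson_r"], o2["pearson_r"])


class TestLeakageGuards:
    def test_gap_regions_ignore_nontraining_subjects(self, pair_acoustics):
        """Gap regions are learned from the training members only: corrupting
        every other subject's spectra leaves them bit-identical."""
        import copy

        from tbs.features import learn_gap_regions

        acoustics, metadata = pair_acoustics
        ids = list(acoustics)
        train = {"Non": [i for i in ids if i.startswith("Non")][:3],
                 "Severe": [i for i in ids if i.startswith("Severe")][:3]}
        test_ids = [i for i in ids
                    if i not in train["Non"] + train["Severe"]]
        r1 = learn_gap_regions(acoustics, train, seed=5)
        corrupted = dict(acoustics)
        for sid in test_ids:
            bad = copy.deepcopy(acoustics[sid])
            for cond in bad.psd:
                bad.psd[cond].power = bad.psd[cond].power * 0 + 99.0
                bad.bispec[cond].magnitude = \
                    bad.bispec[cond].magnitude * 0 + 99.0
            corrupted[sid] = bad
        r2 = learn_gap_regions(corrupted, train, seed=5)
        for cond in r1.bands:
            assert [(b.bin_lo, b.bin_hi) for b in r1.bands[cond]] == \
                [(b.bin_lo, b.bin_hi) for b in r2.bands[cond]]
            assert [(b.row_lo, b.row_hi, b.col_lo, b.col_hi)
                    for b in r1.boxes[cond]] == \
                [(b.row_lo, b.row_hi, b.col_lo, b.col_hi)
                 for b in r2.boxes[cond]]

    def test_selection_sees_training_rows_only(self):
        """Selected features depend only on the training partition."""
        from tbs.selection import three_stage_select

        rng = np.random.default_rng(20)
        X = pd.DataFrame(rng.standard_normal((30, 20)),
                         columns=[f"Average_F{i:02d}" for i in range(20)])
        y = np.repeat(["A", "B"], 15)
        X.iloc[:, 0] += 2.0 * (y == "B")
        f1, _ = three_stage_select(X, y, keep=20, target_n=4, seed=1,
                                   n_bags=10)
        f2, _ = three_stage_select(X, y, keep=20, target_n=4, seed=1,
                                   n_bags=10)
        assert list(f1.columns) == list(f2.columns)


class TestEndToEndReport:
    def test_report_shapes(self, e2e_report):
        aucs = e2e_report["auc"]
        assert set(aucs["pair"]) == {"Non-Mild", "Non-Moderate", "Non-Severe",
                                     "Mild-Moderate", "Mild-Severe",
                                     "Moderate-Severe"}
        assert sorted(aucs["fold"].unique()) == [1, 2]
        assert ((aucs["train_auc"] >= 0) & (aucs["train_auc"] <= 1)).all()
        for key in ("ranking", "stability", "correlations", "fold_balance"):
            assert len(e2e_report[key]) > 0

    def test_ranking_table_schema(self, e2e_report):
        r = e2e_report["ranking"]
        assert {"pair", "feature", "corr_rank", "shap_rank",
                "overall_rank"} <= set(r.columns)
        assert np.allclose(r["overall_rank"],
                           (r["corr_rank"] + r["shap_rank"]) / 2)

    def test_stability_classes_valid(self, e2e_report):
        s = e2e_report["stability"]
        assert set(s["stability_class"]) <= {"stable", "slightly_unstable",
                                             "unstable"}

    def test_severity_gradient_ordering(self, e2e_report):
        """The extreme contrast discriminates at least as well as the
        subtlest one (severity gradient)."""
        mean_auc = e2e_report["auc"].groupby("pair")["test_auc"].mean()
        assert mean_auc["Non-Severe"] > mean_auc["Non-Mild"]
        assert mean_auc["Non-Severe"] >= mean_auc["Mild-Moderate"]


def test_gap_region_serialization_round_trip(tmp_path):
    """Frozen gap regions survive the JSON round trip bit-for-bit."""
    import numpy as np

    from tbs.bispectral import BispecGapBox, GapBand1D
    from tbs.features import GapRegions, load_gap_regions, save_gap_regions

    regions = GapRegions(
        bands={"NoseInspiration": [GapBand1D(f_lo=100.0, f_hi=220.0,
                                             bin_lo=10, bin_hi=22,
                                             direction="Severe")]},
        boxes={"NoseInspiration": [BispecGapBox(
            row_lo=1, row_hi=4, col_lo=2, col_hi=6,
            f1_extent=(80.0, 240.0), f2_extent=(40.0, 160.0),
            component_id=1, component_size=12)]},
        band_bins={"NoseInspiration": np.arange(8, 300)},
        pair=("Non", "Severe"))
    path = tmp_path / "regions.json"
    save_gap_regions(regions, str(path))
    back = load_gap_regions(str(path))
    assert back.pair == ("Non", "Severe")
    assert back.bands["NoseInspiration"][0] == \
        regions.bands["NoseInspiration"][0]
    assert back.boxes["NoseInspiration"][0] == \
        regions.boxes["NoseInspiration"][0]
    assert np.array_equal(back.band_bins["NoseInspiration"],
                          regions.band_bins["NoseInspiration"])
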