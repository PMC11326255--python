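"""Metrics, stratified splitting, CV bookkeeping, and the size analyses."""

import math
import sqlite3

import numpy as np
import pandas as pd
import pytest

from pathpair.dataset import PathwayDefinition
from pathpair.evaluation import (
    COUNT_COLS,
    ConfusionCounts,
    CVResult,
    StratumTooSmallError,
    export_tsv,
    level_overall_mcc,
    mcc,
    mcc_by_metric_threshold,
    metrics,
    pathway_overall_mcc,
    run_cv,
    save_results,
    size_mcc_correlation,
    stratified_split,
    write_figures,
)
from pathpair.model import Hyperparameters

CV_HP = Hyperparameters(hidden_layer_sizes=(32,), max_epochs=12, batch_size=256,
                        learning_rate=2e-3, early_stop_patience=3, seed=0)


def brute_force_mcc(tp, tn, fp, fn):
    """Textbook formula evaluated naively in floats."""
    num = tp * tn - fp * fn
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return 0.0 if den == 0 else num / den


class TestMetrics:
    def test_perfect_classifier(self):
        out = metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert out["mcc"] == 1.0 and out["accuracy"] == 1.0

    def test_direct_formula_example(self):
        out = metrics(ConfusionCounts(tp=2, tn=2, fp=1, fn=1))
        assert out["mcc"] == pytest.approx(3 / 9)

    def test_degenerate_single_class_test_set(self):
        out = metrics(ConfusionCounts(tp=0, tn=10, fp=0, fn=0))
        assert out["mcc"] == 0.0
        assert out["precision"] == 0.0 and out["recall"] == 0.0 and out["f1"] == 0.0

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts())

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 50, size=4))
            if tp + tn + fp + fn == 0:
                continue
            counts = ConfusionCounts(tp, tn, fp, fn)
            assert mcc(counts) == pytest.approx(brute_force_mcc(tp, tn, fp, fn), abs=1e-12)

    def test_counts_are_additive(self):
        a = ConfusionCounts(2, 2, 1, 1)
        b = ConfusionCounts(3, 3, 0, 0)
        assert (a + b) == ConfusionCounts(5, 5, 1, 1)
        assert mcc(a + b) == pytest.approx(brute_force_mcc(5, 5, 1, 1))

    def test_summing_identical_matrices_leaves_mcc_unchanged(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            c = ConfusionCounts(*(int(v) for v in rng.integers(1, 30, size=4)))
            summed = c
            for _ in range(4):
                summed = summed + c
            assert mcc(summed) == pytest.approx(mcc(c))


class TestStratifiedSplit:
    def test_test_fraction_and_disjoint_union(self, tiny_dataset):
        ds = tiny_dataset["dataset"]
        train_rows, test_rows = stratified_split(ds, 0.10, seed=0)
        assert len(test_rows) == round(0.10 * ds.n_entries)
        assert len(np.intersect1d(train_rows, test_rows)) == 0
        assert len(train_rows) + len(test_rows) == ds.n_entries

    def test_per_stratum_share_is_proportional(self, tiny_dataset):
        ds = tiny_dataset["dataset"]
        _, test_rows = stratified_split(ds, 0.10, seed=1)
        strata = [f"{p}|{l}" for p, l in zip(ds.pathway_ids, ds.y)]
        test_set = set(test_rows)
        frame = pd.DataFrame({"stratum": strata, "in_test": [i in test_set for i in range(ds.n_entries)]})
        for _, grp in frame.groupby("stratum"):
            expected = 0.10 * len(grp)
            assert abs(grp["in_test"].sum() - expected) <= 1

    def test_same_seed_same_split(self, tiny_dataset):
        ds = tiny_dataset["dataset"]
        a = stratified_split(ds, 0.10, seed=7)
        b = stratified_split(ds, 0.10, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_small_strata_error_lists_offenders_and_label_key_fallback(self, tiny_dataset):
        ds = tiny_dataset["dataset"].subset(np.arange(8))
        with pytest.raises(StratumTooSmallError):
            stratified_split(ds, 0.25, seed=0, key="pathway_label")


def fake_cv(counts_rows, provenance=None):
    frame = pd.DataFrame(counts_rows, columns=["iteration", "pathway_id", "level", *COUNT_COLS])
    it = []
    for i, grp in frame.groupby("iteration"):
        sums = grp[list(COUNT_COLS)].sum()
        c = ConfusionCounts(*(int(sums[k]) for k in COUNT_COLS))
        it.append({"iteration": i, "seed": i, **metrics(c), **{k: getattr(c, k) for k in COUNT_COLS}})
    return CVResult(pd.DataFrame(it), frame, seeds=list(range(frame["iteration"].nunique())),
                    provenance=provenance or {})


def pdef(pid, level, n_compounds, n_atoms=None):
    return PathwayDefinition(pid, level, frozenset(f"{pid}_m{i}" for i in range(n_compounds)),
                             n_compounds, n_atoms or 5 * n_compounds)


class TestAggregations:
    def test_pathway_overall_mcc_on_summed_matrix(self):
        cv = fake_cv([
            (0, "p1", "L3", 2, 2, 1, 1),
            (1, "p1", "L3", 3, 3, 0, 0),
        ])
        scores = pathway_overall_mcc(cv, [pdef("p1", "L3", 4)])
        assert scores.loc[0, "overall_mcc"] == pytest.approx(brute_force_mcc(5, 5, 1, 1))

    def test_identical_iterations_match_single_iteration(self):
        once = fake_cv([(0, "p1", "L3", 4, 4, 2, 2)])
        twice = fake_cv([(0, "p1", "L3", 4, 4, 2, 2), (1, "p1", "L3", 4, 4, 2, 2)])
        s1 = pathway_overall_mcc(once, [pdef("p1", "L3", 4)])
        s2 = pathway_overall_mcc(twice, [pdef("p1", "L3", 4)])
        assert s1.loc[0, "overall_mcc"] == pytest.approx(s2.loc[0, "overall_mcc"])

    def test_unseen_pathway_warns_and_is_omitted(self):
        cv = fake_cv([(0, "p1", "L3", 1, 1, 0, 0)])
        with pytest.warns(UserWarning, match="absent"):
            scores = pathway_overall_mcc(cv, [pdef("p1", "L3", 2), pdef("p2", "L3", 3)])
        assert list(scores["pathway_id"]) == ["p1"]

    def test_level_mcc_sums_only_that_level(self):
        cv = fake_cv([
            (0, "p1", "L2", 5, 5, 0, 0),
            (0, "p2", "L3", 0, 5, 5, 0),
        ])
        assert level_overall_mcc(cv, "L2") == pytest.approx(1.0)
        assert level_overall_mcc(cv, "L3") == pytest.approx(0.0)
        with pytest.raises(ValueError):
            level_overall_mcc(cv, "L1")

    def test_level_matrices_sum_to_global(self):
        rows = [(i, p, lvl, *np.random.default_rng(i).integers(0, 9, 4))
                for i in range(3) for p, lvl in [("a", "L2"), ("b", "L3"), ("c", "L3")]]
        cv = fake_cv(rows)
        total = cv.pathway_counts[list(COUNT_COLS)].sum()
        by_level = cv.pathway_counts.groupby("level")[list(COUNT_COLS)].sum().sum()
        assert (total == by_level).all()


class TestSizeCorrelation:
    def scores(self, sizes, mccs):
        return pd.DataFrame({
            "pathway_id": [f"p{i}" for i in range(len(sizes))],
            "level": "L3",
            "overall_mcc": mccs,
            "size_compounds": sizes,
            "size_atoms": [5 * s for s in sizes],
        })

    def test_perfectly_comonotone_gives_spearman_one(self):
        out = size_mcc_correlation(self.scores([3, 10, 40, 100, 400], [0.1, 0.2, 0.5, 0.7, 0.9]))
        sp = out[out["method"] == "spearman_regular"]
        assert all(c == pytest.approx(1.0) for c in sp["coefficient"])

    def test_matches_textbook_formulas_on_five_points(self):
        sizes = [3, 7, 12, 30, 80]
        mccs = [0.2, 0.1, 0.5, 0.4, 0.8]
        out = size_mcc_correlation(self.scores(sizes, mccs))
        # rank correlation computed by hand: ranks of sizes are 1..5
        rank_m = pd.Series(mccs).rank()
        rank_s = pd.Series(sizes).rank()
        d2 = ((rank_s - rank_m) ** 2).sum()
        rho_expected = 1 - 6 * d2 / (5 * 24)
        got = out[(out["method"] == "spearman_regular") & (out["size_metric"] == "compounds")]
        assert got["coefficient"].iloc[0] == pytest.approx(rho_expected)
        # product-moment on log10 sizes by the definition formula
        x = np.log10(sizes)
        y = np.array(mccs)
        r_expected = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
            (((x - x.mean()) ** 2).sum()) * (((y - y.mean()) ** 2).sum())
        )
        got_p = out[(out["method"] == "pearson_log10") & (out["size_metric"] == "compounds")]
        assert got_p["coefficient"].iloc[0] == pytest.approx(r_expected)

    def test_independent_mcc_gives_weak_correlation(self):
        rng = np.random.default_rng(0)
        sizes = rng.integers(3, 500, size=100)
        mccs = rng.random(100)
        out = size_mcc_correlation(self.scores(list(sizes), list(mccs)))
        sp = out[out["method"] == "spearman_regular"]
        assert (sp["coefficient"].abs() < 0.3).all()
        assert (sp["p_value"] > 0.01).all()

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            size_mcc_correlation(self.scores([5, 5, 5], [0.5, 0.5, 0.5]))


class TestThresholdCurve:
    def make(self):
        rng = np.random.default_rng(3)
        sizes = {f"p{i}": int(s) for i, s in enumerate(rng.integers(3, 200, size=12))}
        rows = [(it, pid, "L3", *(int(v) for v in rng.integers(0, 20, size=4)))
                for it in range(4) for pid in sizes]
        cv = fake_cv(rows)
        defs = [pdef(p, "L3", s) for p, s in sizes.items()]
        return cv, defs, sizes

    def test_threshold_zero_reproduces_global_mcc(self):
        cv, defs, _ = self.make()
        curve = mcc_by_metric_threshold(cv, defs, [0])
        sums = cv.pathway_counts[list(COUNT_COLS)].sum()
        expected = mcc(ConfusionCounts(*(int(sums[c]) for c in COUNT_COLS)))
        assert curve.loc[0, "overall_mcc"] == pytest.approx(expected)

    def test_retained_count_non_increasing_and_matches_brute_force(self):
        cv, defs, sizes = self.make()
        thresholds = [0, 10, 50, 120]
        curve = mcc_by_metric_threshold(cv, defs, thresholds)
        assert list(curve["n_retained"]) == sorted(curve["n_retained"], reverse=True)
        summed = cv.summed_pathway_counts().set_index("pathway_id")
        for _, row in curve.iterrows():
            kept = [p for p, s in sizes.items() if s >= row["threshold"]]
            assert row["n_retained"] == len(kept)
            sums = summed.loc[kept, list(COUNT_COLS)].sum()
            assert row["overall_mcc"] == pytest.approx(
                mcc(ConfusionCounts(*(int(sums[c]) for c in COUNT_COLS))))

    def test_unsorted_thresholds_rejected(self):
        cv, defs, _ = self.make()
        with pytest.raises(ValueError):
            mcc_by_metric_threshold(cv, defs, [10, 0])

    def test_all_filtered_truncates_with_warning(self):
        cv, defs, _ = self.make()
        with pytest.warns(UserWarning, match="truncated"):
            curve = mcc_by_metric_threshold(cv, defs, [0, 10_000])
        assert list(curve["threshold"]) == [0]


class TestRunCV:
    def test_two_iterations_are_deterministic(self, tiny_dataset):
        ds = tiny_dataset["dataset"]
        a = run_cv(ds, n_iterations=2, hp=CV_HP, base_seed=3)
        b = run_cv(ds, n_iterations=2, hp=CV_HP, base_seed=3)
        pd.testing.assert_frame_equal(a.iteration_metrics, b.iteration_metrics)
        pd.testing.assert_frame_equal(a.pathway_counts, b.pathway_counts)

    def test_per_pathway_counts_sum_to_iteration_totals(self, tiny_dataset):
        ds = tiny_dataset["dataset"]
        cv = run_cv(ds, n_iterations=2, hp=CV_HP, base_seed=4)
        per_it = cv.pathway_counts.groupby("iteration")[list(COUNT_COLS)].sum()
        for _, row in cv.iteration_metrics.iterrows():
            for c in COUNT_COLS:
                assert row[c] == per_it.loc[row["iteration"], c]

    def test_test_set_size_respected(self, tiny_dataset):
        ds = tiny_dataset["dataset"]
        cv = run_cv(ds, n_iterations=1, hp=CV_HP, base_seed=5)
        totals = cv.iteration_metrics.iloc[0][list(COUNT_COLS)].sum()
        assert totals == round(0.10 * ds.n_entries)


def test_results_db_round_trip_and_tsv_export(tmp_path):
    cv = fake_cv([(0, "p1", "L3", 2, 2, 1, 1), (0, "p2", "L2", 3, 3, 0, 0)])
    scores = pathway_overall_mcc(cv, [pdef("p1", "L3", 4), pdef("p2", "L2", 3)])
    db = tmp_path / "results.sqlite"
    save_results(db, cv, scores=scores, provenance={"note": "test"})
    with sqlite3.connect(db) as conn:
        back = pd.read_sql_query("SELECT * FROM pathway_counts", conn)
        pd.testing.assert_frame_equal(back, cv.pathway_counts)
        tables = {r[0] for r in conn.execute("SELECT name FROM sqlite_master WHERE type='table'")}
    assert {"iteration_metrics", "pathway_counts", "pathway_scores", "provenance"} <= tables
    written = export_tsv(db, tmp_path / "tsv")
    assert {p.name for p in written} >= {"iteration_metrics.tsv", "pathway_counts.tsv"}


def test_figures_are_written(tmp_path):
    cv = fake_cv([(i, "p1", "L3", 5, 5, i, 1) for i in range(4)])
    scores = pathway_overall_mcc(cv, [pdef("p1", "L3", 4)])
    curve = mcc_by_metric_threshold(cv, [pdef("p1", "L3", 4)], [0])
    files = write_figures(tmp_path, cv, scores, curve)
    assert all(f.exists() and f.stat().st_size > 0 for f in files)
    assert len(files) == 5
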