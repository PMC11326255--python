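"""Cross-validation, confusion-count bookkeeping, and the pathway-size analyses.

Evaluation follows a Monte-Carlo cross-validation protocol: each iteration
draws a fresh stratified train/test split (stratum = pathway x label, so
every pathway's positive and negative entries appear in each test set in
proportion), fits min/max scaling on the training entries, trains the MLP
and records the overall metrics plus per-pathway confusion counts of the
test entries.  Confusion counts are additive, so per-pathway matrices sum
to per-iteration totals, per-level matrices, and one global matrix; a
pathway's *overall* MCC is the single MCC of its counts summed across all
iterations, which sidesteps per-iteration division-by-zero for small
pathways.
"""

from __future__ import annotations

import logging
import math
import sqlite3
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split

from .dataset import PairedDataset, PathwayDefinition, minmax_scale
from .model import Hyperparameters, train

logger = logging.getLogger(__name__)

COUNT_COLS = ("tp", "tn", "fp", "fn")


@dataclass(frozen=True)
class ConfusionCounts:
    """Integer TP/TN/FP/FN counts; additive across iterations and pathways."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(bool)
        y_pred = np.asarray(y_pred).astype(bool)
        return cls(
            tp=int(np.sum(y_true & y_pred)),
            tn=int(np.sum(~y_true & ~y_pred)),
            fp=int(np.sum(~y_true & y_pred)),
            fn=int(np.sum(y_true & ~y_pred)),
        )


def mcc(counts: ConfusionCounts) -> float:
    """MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)).

    Any zero factor in the denominator makes the coefficient undefined; the
    undefined-as-no-correlation convention returns 0.  Exact integer
    arithmetic in the numerator and radicand avoids overflow for large
    summed matrices.
    """
    tp, tn, fp, fn = int(counts.tp), int(counts.tn), int(counts.fp), int(counts.fn)
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        return 0.0
    return float((tp * tn - fp * fn) / math.sqrt(denom_sq))


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall, F1 and MCC from one confusion matrix.

    Zero-denominator precision/recall/F1 are defined as 0, matching the
    MCC convention.
    """
    if counts.total == 0:
        raise ValueError("metrics undefined for empty confusion counts")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "accuracy": (tp + tn) / counts.total,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "mcc": mcc(counts),
    }


class StratumTooSmallError(ValueError):
    def __init__(self, strata: Sequence[str]):
        self.strata = list(strata)
        super().__init__(
            "strata with fewer than 2 entries (coarsen the key to label-only): "
            + ", ".join(self.strata[:10])
            + ("..." if len(self.strata) > 10 else "")
        )


def stratified_split(
    dataset: PairedDataset,
    test_fraction: float = 0.10,
    seed: int = 0,
    key: str = "pathway_label",
) -> tuple[np.ndarray, np.ndarray]:
    """One stratified train/test row split.

    ``key='pathway_label'`` stratifies on (pathway_id, label); ``'label'``
    coarsens to the label alone for universes whose pathway strata are too
    small.  Returns (train_rows, test_rows); disjoint, union = all rows.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    if key == "pathway_label":
        strata = np.char.add(
            np.char.add(dataset.pathway_ids.astype(str), "|"), dataset.y.astype(str)
        )
    elif key == "label":
        strata = dataset.y.astype(str)
    else:
        raise ValueError(f"unknown stratification key {key!r}")
    values, counts = np.unique(strata, return_counts=True)
    if counts.min() < 2:
        raise StratumTooSmallError(values[counts < 2])
    train_rows, test_rows = train_test_split(
        np.arange(dataset.n_entries),
        test_size=test_fraction,
        random_state=int(seed) % (2**32),
        stratify=strata,
    )
    return np.sort(train_rows), np.sort(test_rows)


@dataclass
class CVResult:
    """Everything recorded across the CV iterations.

    ``iteration_metrics``: one row per iteration (the five overall metrics
    plus the overall confusion counts).  ``pathway_counts``: one row per
    (iteration, pathway) with that pathway's test-entry confusion counts.
    """

    iteration_metrics: pd.DataFrame
    pathway_counts: pd.DataFrame
    seeds: list[int]
    provenance: dict = field(default_factory=dict)

    def summed_pathway_counts(self) -> pd.DataFrame:
        return (
            self.pathway_counts.groupby(["pathway_id", "level"], as_index=False)[list(COUNT_COLS)]
            .sum()
            .sort_values("pathway_id", ignore_index=True)
        )


def run_cv(
    dataset: PairedDataset,
    n_iterations: int = 100,
    hp: Hyperparameters = Hyperparameters(),
    base_seed: int = 0,
    test_fraction: float = 0.10,
    scale: bool = True,
    stratify_key: str = "pathway_label",
) -> CVResult:
    """Monte-Carlo CV: fresh split, fit scaling on train, train, score test.

    Iteration i uses seed ``base_seed + i`` for its split, scaling scope and
    model training, so the whole result is reproducible from one base seed.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    it_rows = []
    pw_rows = []
    seeds = []
    for it in range(n_iterations):
        seed = base_seed + it
        seeds.append(seed)
        try:
            train_rows, test_rows = stratified_split(dataset, test_fraction, seed, stratify_key)
            if scale:
                X_scaled, _ = minmax_scale(dataset.X, train_rows)
                work = replace_X(dataset, X_scaled)
            else:
                work = dataset
            clf = train(work.subset(train_rows), replace(hp, seed=seed))
            _, y_pred = clf.predict(work.subset(test_rows))
        except Exception as exc:
            raise RuntimeError(f"CV iteration {it} failed: {exc}") from exc
        y_true = dataset.y[test_rows]
        overall = ConfusionCounts.from_predictions(y_true, y_pred)
        it_rows.append({"iteration": it, "seed": seed, **metrics(overall),
                        **{c: getattr(overall, c) for c in COUNT_COLS}})
        frame = pd.DataFrame(
            {
                "pathway_id": dataset.pathway_ids[test_rows],
                "level": dataset.levels[test_rows],
                "y": y_true.astype(bool),
                "yhat": y_pred.astype(bool),
            }
        )
        grouped = frame.groupby(["pathway_id", "level"], as_index=False).apply(
            lambda g: pd.Series(
                {
                    "tp": int((g["y"] & g["yhat"]).sum()),
                    "tn": int((~g["y"] & ~g["yhat"]).sum()),
                    "fp": int((~g["y"] & g["yhat"]).sum()),
                    "fn": int((g["y"] & ~g["yhat"]).sum()),
                }
            ),
            include_groups=False,
        )
        grouped.insert(0, "iteration", it)
        pw_rows.append(grouped)
    return CVResult(
        iteration_metrics=pd.DataFrame(it_rows),
        pathway_counts=pd.concat(pw_rows, ignore_index=True),
        seeds=seeds,
        provenance={
            "n_iterations": n_iterations,
            "test_fraction": test_fraction,
            "scaled": scale,
            "stratify_key": stratify_key,
            "base_seed": base_seed,
            "n_entries": dataset.n_entries,
        },
    )


def replace_X(dataset: PairedDataset, X) -> PairedDataset:
    """Dataset copy with a substituted feature matrix (same contract)."""
    return PairedDataset(
        X=X,
        y=dataset.y,
        metabolite_ids=dataset.metabolite_ids,
        pathway_ids=dataset.pathway_ids,
        levels=dataset.levels,
        feature_names=dataset.feature_names,
        provenance=dict(dataset.provenance),
    )


def pathway_overall_mcc(
    cv: CVResult, pathways: Sequence[PathwayDefinition]
) -> pd.DataFrame:
    """One overall MCC per pathway from its summed confusion matrix.

    Columns: pathway_id, level, overall_mcc, size_compounds, size_atoms,
    tp, tn, fp, fn.  Pathways that never appeared in any test split are
    omitted with a warning.
    """
    summed = cv.summed_pathway_counts()
    sizes = {p.pathway_id: p for p in pathways}
    missing = set(sizes) - set(summed["pathway_id"])
    if missing:
        warnings.warn(f"pathways absent from every test split: {sorted(missing)}")
    rows = []
    for rec in summed.itertuples(index=False):
        counts = ConfusionCounts(rec.tp, rec.tn, rec.fp, rec.fn)
        pdef = sizes.get(rec.pathway_id)
        rows.append(
            {
                "pathway_id": rec.pathway_id,
                "level": rec.level,
                "overall_mcc": mcc(counts),
                "size_compounds": pdef.size_compounds if pdef else np.nan,
                "size_atoms": pdef.size_atoms if pdef else np.nan,
                **{c: getattr(counts, c) for c in COUNT_COLS},
            }
        )
    return pd.DataFrame(rows)


def level_overall_mcc(cv: CVResult, level: str) -> float:
    """MCC of the confusion matrix summed over all pathways of one level
    and all CV iterations."""
    sub = cv.pathway_counts[cv.pathway_counts["level"] == level]
    if sub.empty:
        raise ValueError(f"no pathways at hierarchy level {level!r}")
    sums = sub[list(COUNT_COLS)].sum()
    return mcc(ConfusionCounts(*(int(sums[c]) for c in COUNT_COLS)))


def size_mcc_correlation(scores: pd.DataFrame) -> pd.DataFrame:
    """Correlate overall pathway MCC with pathway size, four ways.

    For each size metric (compounds, non-hydrogen atoms): Spearman on the
    regular scale and Pearson on log10(size).  Standard asymptotic
    p-values; no multiple-testing correction.
    """
    if len(scores) < 3:
        raise ValueError("need at least 3 pathway scores to correlate")
    rows = []
    for metric, col in (("compounds", "size_compounds"), ("atoms", "size_atoms")):
        size = scores[col].to_numpy(dtype=float)
        y = scores["overall_mcc"].to_numpy(dtype=float)
        if np.all(size == size[0]) or np.all(y == y[0]):
            raise ValueError("constant input: correlation undefined")
        rho, p_s = stats.spearmanr(size, y)
        r, p_p = stats.pearsonr(np.log10(size), y)
        rows.append({"size_metric": metric, "method": "spearman_regular",
                     "coefficient": float(rho), "p_value": float(p_s)})
        rows.append({"size_metric": metric, "method": "pearson_log10",
                     "coefficient": float(r), "p_value": float(p_p)})
    return pd.DataFrame(rows)


def mcc_by_metric_threshold(
    cv: CVResult,
    pathways: Sequence[PathwayDefinition],
    thresholds: Sequence[int],
    metric: str = "compounds",
) -> pd.DataFrame:
    """Overall MCC of the pathways at or above each size threshold.

    Filtering here only removes pathways from the MCC *calculation* (the
    model was trained on everything).  Threshold 0 reproduces the global
    overall MCC.  If a threshold retains no pathway the curve truncates
    with a warning.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    summed = cv.summed_pathway_counts().set_index("pathway_id")
    sizes = {p.pathway_id: p.size(metric) for p in pathways}
    rows = []
    for t in thresholds:
        kept = [pid for pid in summed.index if sizes.get(pid, 0) >= t]
        if not kept:
            warnings.warn(f"threshold {t} retains no pathways; curve truncated")
            break
        sums = summed.loc[kept, list(COUNT_COLS)].sum()
        rows.append(
            {
                "threshold": int(t),
                "metric": metric,
                "overall_mcc": mcc(ConfusionCounts(*(int(sums[c]) for c in COUNT_COLS))),
                "n_retained": len(kept),
            }
        )
    return pd.DataFrame(rows)


def training_filter_sweep(
    dataset: PairedDataset,
    pathways: Sequence[PathwayDefinition],
    thresholds: Sequence[int],
    eval_ids: Sequence[str],
    n_iterations: int = 10,
    hp: Hyperparameters = Hyperparameters(),
    base_seed: int = 0,
    metric: str = "compounds",
    test_fraction: float = 0.10,
    scale: bool = True,
    stratify_key: str = "pathway_label",
) -> pd.DataFrame:
    """Filter small pathways out of the *training universe* and re-run CV.

    Unlike :func:`mcc_by_metric_threshold`, each threshold retrains the
    model on the filtered cross join.  To make thresholds comparable, the
    reported MCC is always restricted to the fixed ``eval_ids`` pathways,
    which must survive every threshold.
    """
    from .dataset import filter_pathways_by_size

    eval_set = set(eval_ids)
    sizes = {p.pathway_id: p.size(metric) for p in pathways}
    rows = []
    for t in thresholds:
        dropped_eval = [pid for pid in eval_set if sizes.get(pid, 0) < t]
        if dropped_eval:
            raise ValueError(
                f"threshold {t} would filter evaluation pathways: {sorted(dropped_eval)}"
            )
        sub = filter_pathways_by_size(dataset, pathways, t, metric)
        cv = run_cv(sub, n_iterations, hp, base_seed, test_fraction, scale, stratify_key)
        counts = cv.pathway_counts
        counts = counts[counts["pathway_id"].isin(eval_set)]
        sums = counts[list(COUNT_COLS)].sum()
        rows.append(
            {
                "threshold": int(t),
                "metric": metric,
                "n_train_pathways": int(sub.provenance["n_pathways"]),
                "eval_mcc": mcc(ConfusionCounts(*(int(sums[c]) for c in COUNT_COLS))),
            }
        )
    return pd.DataFrame(rows)


# -- persistence and figures --------------------------------------------------

def save_results(
    db_path: str | Path,
    cv: CVResult,
    scores: pd.DataFrame | None = None,
    correlations: pd.DataFrame | None = None,
    threshold_curves: pd.DataFrame | None = None,
    sweep: pd.DataFrame | None = None,
    provenance: Mapping | None = None,
) -> None:
    """Persist all result tables into one SQLite file (replacing it)."""
    db_path = Path(db_path)
    if db_path.exists():
        db_path.unlink()
    with sqlite3.connect(db_path) as conn:
        cv.iteration_metrics.to_sql("iteration_metrics", conn, index=False)
        cv.pathway_counts.to_sql("pathway_counts", conn, index=False)
        if scores is not None:
            scores.to_sql("pathway_scores", conn, index=False)
        if correlations is not None:
            correlations.to_sql("correlations", conn, index=False)
        if threshold_curves is not None:
            threshold_curves.to_sql("threshold_curve", conn, index=False)
        if sweep is not None:
            sweep.to_sql("sweep", conn, index=False)
        prov = {**cv.provenance, **(provenance or {})}
        pd.DataFrame(
            {"key": sorted(prov), "value": [str(prov[k]) for k in sorted(prov)]}
        ).to_sql("provenance", conn, index=False)


def export_tsv(db_path: str | Path, out_dir: str | Path) -> list[Path]:
    """Dump every table of a results database to headered TSV files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    with sqlite3.connect(db_path) as conn:
        tables = [
            r[0]
            for r in conn.execute("SELECT name FROM sqlite_master WHERE type='table' ORDER BY name")
        ]
        for table in tables:
            df = pd.read_sql_query(f"SELECT * FROM {table}", conn)
            path = out_dir / f"{table}.tsv"
            df.to_csv(path, sep="\t", index=False)
            written.append(path)
    return written


def write_figures(
    out_dir: str | Path,
    cv: CVResult | None = None,
    scores: pd.DataFrame | None = None,
    threshold_curves: pd.DataFrame | None = None,
    sweep: pd.DataFrame | None = None,
) -> list[Path]:
    """Write the standard analysis figures as PNGs; skips absent inputs.

    Violin of per-iteration MCC, pathway-size histograms, overall-MCC
    histogram, MCC-vs-size scatterplots (regular and log10), threshold
    curves, and the training-filter sweep bars.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _save(fig, name: str) -> None:
        path = out_dir / name
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    if cv is not None:
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.violinplot(cv.iteration_metrics["mcc"], showmedians=True)
        ax.set_ylabel("MCC per CV iteration")
        ax.set_xticks([])
        _save(fig, "iteration_mcc_violin.png")

    if scores is not None and len(scores):
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
        axes[0].hist(scores["size_compounds"].dropna(), bins=30)
        axes[0].set_xlabel("# member metabolites")
        axes[1].hist(scores["size_atoms"].dropna(), bins=30)
        axes[1].set_xlabel("# non-hydrogen atoms")
        for ax in axes:
            ax.set_ylabel("pathways")
        _save(fig, "pathway_size_histograms.png")

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.hist(scores["overall_mcc"], bins=30)
        ax.set_xlabel("overall pathway MCC")
        ax.set_ylabel("pathways")
        _save(fig, "pathway_mcc_histogram.png")

        fig, axes = plt.subplots(2, 2, figsize=(8, 7))
        for j, (col, label) in enumerate(
            (("size_compounds", "# metabolites"), ("size_atoms", "# non-H atoms"))
        ):
            axes[0, j].scatter(scores[col], scores["overall_mcc"], s=12)
            axes[0, j].set_xlabel(label)
            axes[1, j].scatter(scores[col], scores["overall_mcc"], s=12)
            axes[1, j].set_xscale("log")
            axes[1, j].set_xlabel(f"{label} (log10)")
        for ax in axes.ravel():
            ax.set_ylabel("overall MCC")
        _save(fig, "mcc_vs_size_scatter.png")

    if threshold_curves is not None and len(threshold_curves):
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
        for metric, grp in threshold_curves.groupby("metric"):
            axes[0].plot(grp["threshold"], grp["overall_mcc"], marker="o", label=metric)
            axes[1].plot(grp["threshold"], grp["n_retained"], marker="o", label=metric)
        axes[0].set_ylabel("overall MCC of retained pathways")
        axes[1].set_ylabel("pathways retained")
        for ax in axes:
            ax.set_xlabel("size threshold")
            ax.legend()
        _save(fig, "mcc_by_size_threshold.png")

    if sweep is not None and len(sweep):
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
        axes[0].bar([str(t) for t in sweep["threshold"]], sweep["n_train_pathways"])
        axes[0].set_ylabel("pathways in training set")
        axes[1].bar([str(t) for t in sweep["threshold"]], sweep["eval_mcc"])
        axes[1].set_ylabel("MCC on fixed evaluation pathways")
        for ax in axes:
            ax.set_xlabel("training-set size threshold")
        _save(fig, "training_filter_sweep.png")

    return written
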