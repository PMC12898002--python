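"""Cross-validated evaluation: covariate-balanced stratified k-fold, bagged
1-vs-1 classification, and the feature metric suite.

The splitter stratifies by severity class and additionally balances the joint
distribution of anthropometric criteria (age, BMI, neck circumference, sex,
Mallampati score, optionally AHI) across folds: within each class, subjects
are sorted by a composite z-score of the continuous criteria and snake-dealt
to folds, then local within-class pairwise swaps are accepted while they
reduce a balance cost (squared standardized mean deviations for continuous
criteria plus a chi-square-style divergence for categorical ones).  Swaps
never change per-class fold counts, so the partition and per-class totals are
conserved by construction.

Feature stability follows the train/test delta rule: a feature is stable when
its absolute train-test AUC difference is at most 0.01 and its absolute
train-test label-correlation difference is at most 0.1; it is slightly
unstable when the AUC condition holds and the correlation delta is at most
0.15; otherwise unstable.
"""

from __future__ import annotations

import json
import logging
import os
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata

from .features import (FeatureConfig, base_feature_table,
                       extract_subject_acoustics, gap_region_features,
                       learn_gap_regions)
from .preprocess import apply_normalization, select_normalization
from .selection import (BaggedPairClassifier, aggregate_ranks, rank_min,
                        shap_rank, three_stage_select)

logger = logging.getLogger("tbs")

__all__ = [
    "PAIRS",
    "FoldAssignment",
    "StabilityRecord",
    "stratified_multicriteria_kfold",
    "balance_cost",
    "train_bagged_ovo",
    "auc",
    "stability_assess",
    "feature_anthro_correlations",
    "evaluate_pipeline",
]

#: The six 1-vs-1 severity contrasts.
PAIRS = [("Non", "Mild"), ("Non", "Moderate"), ("Non", "Severe"),
         ("Mild", "Moderate"), ("Mild", "Severe"), ("Moderate", "Severe")]

CONTINUOUS_CRITERIA = ("age", "bmi", "nc", "ahi")
CATEGORICAL_CRITERIA = ("sex", "mps")
DEFAULT_CRITERIA = ("age", "bmi", "nc", "sex", "mps")


@dataclass
class FoldAssignment:
    assignment: dict[str, int]  # subject_id -> fold index (1..k)
    k: int
    balance_report: pd.DataFrame
    cost: float

    def fold_of(self, subject_id: str) -> int:
        return self.assignment[subject_id]

    def subjects_in(self, fold: int) -> list[str]:
        return [s for s, f in self.assignment.items() if f == fold]


def balance_cost(cohort: pd.DataFrame, assignment: np.ndarray, k: int,
                 criteria) -> float:
    """Sum over folds of squared standardized mean deviations (continuous)
    and chi-square-style category divergences (categorical)."""
    cost = 0.0
    for crit in criteria:
        if crit in CONTINUOUS_CRITERIA:
            col = cohort[crit].to_numpy(dtype=float)
            mu, sd = col.mean(), col.std(ddof=0)
            if sd == 0:
                continue
            for f in range(1, k + 1):
                sel = assignment == f
                if sel.any():
                    cost += ((col[sel].mean() - mu) / sd) ** 2
        else:
            col = cohort[crit].astype(str).to_numpy()
            levels, counts = np.unique(col, return_counts=True)
            p_all = counts / counts.sum()
            for f in range(1, k + 1):
                sel = assignment == f
                if not sel.any():
                    continue
                sub = col[sel]
                for lev, p in zip(levels, p_all):
                    p_f = np.mean(sub == lev)
                    cost += (p_f - p) ** 2 / p
    return float(cost)


def stratified_multicriteria_kfold(cohort: pd.DataFrame, k: int = 3,
                                   criteria=DEFAULT_CRITERIA, seed: int = 0,
                                   n_passes: int = 3,
                                   size_tol: float = 0.15) -> FoldAssignment:
    """Severity-stratified k-fold with anthropometric covariate balancing.

    ``cohort`` needs columns subject_id, severity and the criteria columns.
    Deterministic given ``seed``.  Classes smaller than ``k`` are allowed to
    be absent from some folds (with a warning).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    bad = [c for c in criteria if c not in CONTINUOUS_CRITERIA + CATEGORICAL_CRITERIA]
    if bad:
        raise ValueError(f"unknown criteria: {bad}")
    cohort = cohort.reset_index(drop=True)
    n = len(cohort)
    rng = np.random.default_rng(seed)
    assignment = np.zeros(n, dtype=int)

    cont = [c for c in criteria if c in CONTINUOUS_CRITERIA]
    composite = np.zeros(n)
    for c in cont:
        col = cohort[c].to_numpy(dtype=float)
        sd = col.std(ddof=0)
        if sd > 0:
            composite += (col - col.mean()) / sd

    for sev, idx in cohort.groupby("severity").groups.items():
        idx = np.asarray(list(idx))
        if idx.size < k:
            warnings.warn(f"class {sev} has fewer members ({idx.size}) than "
                          f"k={k}; it will be absent from some folds")
        order = idx[np.argsort(composite[idx], kind="stable")]
        # snake deal: 1..k, k..1, 1..k, ...
        fold_seq = []
        f_cycle = list(range(1, k + 1))
        block = 0
        while len(fold_seq) < order.size:
            seq = f_cycle if block % 2 == 0 else f_cycle[::-1]
            fold_seq.extend(seq)
            block += 1
        assignment[order] = fold_seq[:order.size]

    # local within-class pairwise swaps while the balance cost improves
    cost = balance_cost(cohort, assignment, k, criteria)
    for _ in range(n_passes):
        improved = False
        for sev, idx in cohort.groupby("severity").groups.items():
            idx = np.asarray(list(idx))
            perm = rng.permutation(idx.size)
            for a_i in perm:
                a = idx[a_i]
                for b in idx:
                    if assignment[a] == assignment[b] or a >= b:
                        continue
                    assignment[a], assignment[b] = assignment[b], assignment[a]
                    new_cost = balance_cost(cohort, assignment, k, criteria)
                    if new_cost < cost - 1e-12:
                        cost = new_cost
                        improved = True
                    else:
                        assignment[a], assignment[b] = assignment[b], assignment[a]
        if not improved:
            break

    sizes = np.bincount(assignment, minlength=k + 1)[1:]
    target = n / k
    if np.any(np.abs(sizes - target) > max(1.0, size_tol * target)):
        warnings.warn(f"fold sizes {sizes.tolist()} deviate more than "
                      f"{size_tol:.0%} from n/k")

    report = _balance_report(cohort, assignment, k)
    mapping = dict(zip(cohort["subject_id"].astype(str), assignment.tolist()))
    return FoldAssignment(assignment=mapping, k=k, balance_report=report,
                          cost=cost)


def _balance_report(cohort, assignment, k) -> pd.DataFrame:
    rows = []
    for sev in cohort["severity"].unique():
        for f in range(1, k + 1):
            sub = cohort[(cohort["severity"] == sev) & (assignment == f)]
            if len(sub) == 0:
                rows.append(dict(severity=sev, fold=f, n=0))
                continue
            row = dict(severity=sev, fold=f, n=len(sub))
            for c in ("ahi", "age", "bmi", "nc"):
                if c in cohort.columns:
                    row[f"{c}_mean"] = sub[c].mean()
                    row[f"{c}_sd"] = sub[c].std(ddof=1) if len(sub) > 1 else 0.0
            if "sex" in cohort.columns:
                row["n_male"] = int((sub["sex"] == "M").sum())
                row["n_female"] = int((sub["sex"] == "F").sum())
            if "mps" in cohort.columns:
                for m in (1, 2, 3, 4):
                    row[f"mps{m}"] = int((sub["mps"] == m).sum())
            rows.append(row)
    return pd.DataFrame(rows)


def train_bagged_ovo(table: pd.DataFrame, labels, n_bags: int = 100,
                     seed: int = 0) -> BaggedPairClassifier:
    """Fit the bootstrap-aggregated tree ensemble for one class pair."""
    model = BaggedPairClassifier(n_bags=n_bags, seed=seed)
    model.fit(table.to_numpy(dtype=float), np.asarray(labels))
    model.feature_names_ = list(table.columns)
    return model


def auc(scores, labels) -> float:
    """Mann-Whitney rank AUC with ties credited 0.5.  The positive class is
    the lexically larger label."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("binary labels required")
    y = labels == classes[-1]
    n1 = int(y.sum())
    n0 = y.size - n1
    r = rankdata(scores)
    return float((r[y].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


@dataclass
class StabilityRecord:
    feature: str
    abs_delta_auc: float
    abs_delta_corr: float
    stability_class: str


def classify_stability(abs_delta_auc: float, abs_delta_corr: float) -> str:
    if abs_delta_auc <= 0.01 and abs_delta_corr <= 0.1:
        return "stable"
    if abs_delta_auc <= 0.01 and abs_delta_corr <= 0.15:
        return "slightly_unstable"
    return "unstable"


def stability_assess(per_fold: pd.DataFrame) -> list[StabilityRecord]:
    """Classify features by the averaged train/test deltas.

    ``per_fold`` needs columns feature, fold, train_auc, test_auc,
    train_corr, test_corr; deltas are averaged across folds before applying
    the thresholds.
    """
    required = {"feature", "fold", "train_auc", "test_auc",
                "train_corr", "test_corr"}
    if not required.issubset(per_fold.columns):
        raise ValueError(f"missing columns: {required - set(per_fold.columns)}")
    if per_fold[["train_auc", "test_auc"]].isna().any().any():
        raise ValueError("missing fold values")
    out = []
    for feat, grp in per_fold.groupby("feature", sort=True):
        d_auc = float(np.mean(np.abs(grp["train_auc"] - grp["test_auc"])))
        d_corr = float(np.mean(np.abs(grp["train_corr"] - grp["test_corr"])))
        out.append(StabilityRecord(feature=feat, abs_delta_auc=d_auc,
                                   abs_delta_corr=d_corr,
                                   stability_class=classify_stability(d_auc, d_corr)))
    return out


def feature_anthro_correlations(table: pd.DataFrame, cohort: pd.DataFrame,
                                folds: FoldAssignment,
                                variables=("age", "bmi", "nc", "ahi", "sex", "mps"),
                                pair_label: str = "") -> pd.DataFrame:
    """Pearson r between each feature and each anthropometric variable,
    computed independently within each fold's subject subset (reporting only;
    never fed back into training)."""
    meta = cohort.set_index(cohort["subject_id"].astype(str))
    rows = []
    for f in range(1, folds.k + 1):
        ids = [s for s in folds.subjects_in(f) if s in table.index]
        if len(ids) < 3:
            continue
        sub = table.loc[ids]
        for var in variables:
            v = meta.loc[ids, var]
            v = (v == "M").astype(float) if var == "sex" else v.astype(float)
            v = v.to_numpy()
            for feat in table.columns:
                x = sub[feat].to_numpy(dtype=float)
                if np.std(x) == 0 or np.std(v) == 0:
                    r = np.nan  # undefined for zero-variance columns
                else:
                    r = pearsonr(x, v)[0]
                rows.append(dict(feature=feat, variable=var, fold=f,
                                 pair=pair_label, pearson_r=r))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class PipelineConfig:
    k: int = 3
    criteria: tuple = DEFAULT_CRITERIA
    n_bags: int = 100
    keep_univariate: int = 200
    target_n_features: int = 35
    rfe_step: float = 0.1
    features: FeatureConfig = field(default_factory=FeatureConfig)
    pairs: list = field(default_factory=lambda: list(PAIRS))


@dataclass
class PairFoldResult:
    pair: tuple[str, str]
    fold: int
    train_auc: float
    test_auc: float
    selected: list[str]
    normalization: str
    shap_importance: dict[str, float]
    scores: dict[str, float]


def evaluate_pipeline(recordings: dict, metadata: pd.DataFrame,
                      config: PipelineConfig | None = None, seed: int = 0,
                      out_dir: str | None = None, fs: float = 10240.0) -> dict:
    """Run the full pipeline on a cohort: preprocess, learn gap regions on
    fold-train subjects, extract features, select normalization and features
    inside the training fold, train bagged 1-vs-1 ensembles, and assemble the
    ranking / stability / correlation / fold-balance report.

    ``recordings`` maps (subject_id, route) to waveforms sampled at ``fs``.
    """
    cfg = config or PipelineConfig()
    meta = metadata.copy()
    meta["subject_id"] = meta["subject_id"].astype(str)

    t0 = time.perf_counter()
    folds = stratified_multicriteria_kfold(meta, k=cfg.k,
                                           criteria=cfg.criteria, seed=seed)
    logger.info("fold assignment: %.1fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    acoustics = {}
    for sid in meta["subject_id"]:
        acoustics[sid] = extract_subject_acoustics(
            {route: recordings[(sid, route)] for route in ("nose", "mouth")},
            fs, subject_id=sid, cfg=cfg.features)
    base_table = base_feature_table(acoustics)
    logger.info("feature extraction for %d subjects: %.1fs",
                len(acoustics), time.perf_counter() - t0)

    sev = meta.set_index("subject_id")["severity"]
    results: list[PairFoldResult] = []
    stability_rows = []
    ranking_rows = []
    corr_frames = []

    for pair in cfg.pairs:
        pair_ids = [s for s in base_table.index if sev[s] in pair]
        if not pair_ids:
            continue
        per_fold_sel: dict[int, list[str]] = {}
        for f in range(1, cfg.k + 1):
            t_fold = time.perf_counter()
            test_ids = [s for s in pair_ids if folds.fold_of(s) == f]
            train_ids = [s for s in pair_ids if folds.fold_of(s) != f]
            y_train = sev[train_ids].to_numpy()
            y_test = sev[test_ids].to_numpy()
            if np.unique(y_train).size < 2 or np.unique(y_test).size < 2:
                warnings.warn(f"fold {f} lacks both classes for {pair}; skipped")
                continue

            # gap regions from training subjects only
            members = {c: [s for s in train_ids if sev[s] == c] for c in pair}
            regions = learn_gap_regions(acoustics, members, cfg=cfg.features,
                                        seed=seed + 101 * f)
            gap_tbl = pd.DataFrame.from_dict(
                {s: gap_region_features(acoustics[s], regions,
                                        cfg=cfg.features).values
                 for s in train_ids + test_ids}, orient="index")
            tbl = pd.concat([base_table.loc[train_ids + test_ids], gap_tbl],
                            axis=1)
            tbl = _clean(tbl, train_ids)

            choice, train_norm = select_normalization(tbl.loc[train_ids],
                                                      y_train)
            test_norm = apply_normalization(tbl.loc[test_ids], choice)

            selected_tbl, manifest = three_stage_select(
                train_norm, y_train, keep=cfg.keep_univariate,
                target_n=cfg.target_n_features, step=cfg.rfe_step,
                seed=seed + 7 * f, n_bags=cfg.n_bags)
            selected = list(selected_tbl.columns)
            per_fold_sel[f] = selected

            model = train_bagged_ovo(selected_tbl, y_train,
                                     n_bags=cfg.n_bags, seed=seed + 7 * f)
            tr_scores = model.decision_scores(selected_tbl.to_numpy(dtype=float))
            te_scores = model.decision_scores(
                test_norm[selected].to_numpy(dtype=float))
            tr_auc = auc(tr_scores, y_train)
            te_auc = auc(te_scores, y_test)
            importance, _, _ = shap_rank(model, selected_tbl)

            y_tr01 = (y_train == pair[1]).astype(float)
            y_te01 = (y_test == pair[1]).astype(float)
            for feat in selected:
                xtr = train_norm[feat].to_numpy(dtype=float)
                xte = test_norm[feat].to_numpy(dtype=float)
                stability_rows.append(dict(
                    pair="-".join(pair), fold=f, feature=feat,
                    train_auc=auc(xtr, y_train), test_auc=auc(xte, y_test),
                    train_corr=_safe_corr(xtr, y_tr01),
                    test_corr=_safe_corr(xte, y_te01)))
                ranking_rows.append(dict(
                    pair="-".join(pair), fold=f, feature=feat,
                    abs_corr=abs(_safe_corr(xtr, y_tr01)),
                    shap=float(importance[feat])))

            results.append(PairFoldResult(
                pair=pair, fold=f, train_auc=tr_auc, test_auc=te_auc,
                selected=selected, normalization=choice.method,
                shap_importance=importance.to_dict(),
                scores={s: float(v) for s, v in
                        zip(test_ids, te_scores)}))

            corr_frames.append(feature_anthro_correlations(
                pd.concat([train_norm[selected], test_norm[selected]]),
                meta, folds, pair_label="-".join(pair)))
            logger.info("pair %s fold %d: train AUC %.3f test AUC %.3f "
                        "(%.1fs)", "-".join(pair), f, tr_auc, te_auc,
                        time.perf_counter() - t_fold)

    report = _assemble_report(results, stability_rows, ranking_rows,
                              corr_frames, folds)
    if out_dir is not None:
        _write_report(report, out_dir)
    return report


def _safe_corr(x, y):
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(pearsonr(x, y)[0])


def _clean(tbl: pd.DataFrame, train_ids) -> pd.DataFrame:
    """Drop columns unusable on the training fold; impute remaining NaNs
    with the training-fold median (test labels never consulted)."""
    train = tbl.loc[train_ids]
    keep = [c for c in tbl.columns
            if np.isfinite(train[c]).sum() >= max(3, len(train_ids) // 2)]
    tbl = tbl[keep].replace([np.inf, -np.inf], np.nan)
    med = tbl.loc[train_ids].median()
    return tbl.fillna(med).fillna(0.0)


def _assemble_report(results, stability_rows, ranking_rows, corr_frames,
                     folds) -> dict:
    auc_rows = [dict(pair="-".join(r.pair), fold=r.fold,
                     train_auc=r.train_auc, test_auc=r.test_auc,
                     normalization=r.normalization) for r in results]
    auc_df = pd.DataFrame(auc_rows)
    selected = {f"{'-'.join(r.pair)}/fold{r.fold}": r.selected
                for r in results}

    stab_df = pd.DataFrame(stability_rows)
    stability = []
    if len(stab_df):
        for pair, grp in stab_df.groupby("pair"):
            for rec in stability_assess(grp):
                stability.append(dict(pair=pair, feature=rec.feature,
                                      abs_delta_auc=rec.abs_delta_auc,
                                      abs_delta_corr=rec.abs_delta_corr,
                                      stability_class=rec.stability_class))
    stability_df = pd.DataFrame(stability)

    rank_df = pd.DataFrame(ranking_rows)
    ranking = []
    if len(rank_df):
        for pair, grp in rank_df.groupby("pair"):
            per_fold = []
            for f, g in grp.groupby("fold"):
                g = g.set_index("feature")
                per_fold.append(pd.DataFrame({
                    "corr_rank": rank_min(g["abs_corr"]),
                    "shap_rank": rank_min(g["shap"])}))
            merged = pd.concat(per_fold).groupby(level=0).mean()
            for feat, row in merged.iterrows():
                ranking.append(dict(
                    pair=pair, feature=feat,
                    corr_rank=float(row["corr_rank"]),
                    shap_rank=float(row["shap_rank"]),
                    overall_rank=aggregate_ranks(row["corr_rank"],
                                                 row["shap_rank"])))
    ranking_df = pd.DataFrame(ranking)
    if len(ranking_df):
        ranking_df = ranking_df.sort_values(["pair", "overall_rank",
                                             "feature"]).reset_index(drop=True)

    corr_df = pd.concat(corr_frames, ignore_index=True) if corr_frames \
        else pd.DataFrame()
    return dict(auc=auc_df, ranking=ranking_df, stability=stability_df,
                correlations=corr_df, fold_balance=folds.balance_report,
                fold_assignment=folds.assignment, selected=selected)


def _write_report(report: dict, out_dir: str):
    os.makedirs(out_dir, exist_ok=True)
    report["ranking"].to_csv(os.path.join(out_dir, "ranking.csv"), index=False)
    report["stability"].to_csv(os.path.join(out_dir, "stability.csv"),
                               index=False)
    report["correlations"].to_csv(os.path.join(out_dir, "correlations.csv"),
                                  index=False)
    report["fold_balance"].to_csv(os.path.join(out_dir, "fold_balance.csv"),
                                  index=False)
    report["auc"].to_csv(os.path.join(out_dir, "auc.csv"), index=False)
    with open(os.path.join(out_dir, "auc.json"), "w") as fh:
        json.dump(report["auc"].to_dict(orient="records"), fh, indent=2)
    with open(os.path.join(out_dir, "fold_assignment.json"), "w") as fh:
        json.dump(report["fold_assignment"], fh, indent=2)
    with open(os.path.join(out_dir, "selected_features.json"), "w") as fh:
        json.dump(report["selected"], fh, indent=2)
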