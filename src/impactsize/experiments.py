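"""Benchmark experiments comparing Impact with Cohen's d.

Three experiment families:

* :func:`effect_size_table` — Impact (with components) and both Cohen's d
  pooling variants for a collection of two-group samples, plus a Pearson
  correlation helper for regime analyses;
* :func:`robustness_subsampling` — stability of both measures under
  class-proportional Monte-Carlo subsampling at decreasing fractions of
  the data (mean, SD and coefficient of variation across repeated runs);
* :func:`classification_experiment` — the statistics-vs-machine-learning
  contrast: decision tree (Gini) and 500-tree random forest under
  Monte-Carlo cross-validation with 2/3-1/3 splits, optionally with a
  feature-permutation negative control applied to the training split
  only.

All experiments are reproducible given their seed.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier

from .core import (
    ImpactConfig,
    LabeledSample,
    UndefinedEffectSizeError,
    cohens_d,
    compute_impact,
)

__all__ = [
    "effect_size_table",
    "impact_d_correlation",
    "robustness_subsampling",
    "classification_experiment",
]


def _named_samples(samples) -> list[tuple[str, LabeledSample]]:
    if isinstance(samples, Mapping):
        return list(samples.items())
    out = []
    for i, item in enumerate(samples, start=1):
        if isinstance(item, LabeledSample):
            out.append((f"sample_{i}", item))
        elif hasattr(item, "sample") and hasattr(item, "name"):  # SyntheticSubset
            out.append((item.name, item.sample))
        else:
            name, sample = item
            out.append((name, sample))
    if not out:
        raise ValueError("need at least one sample")
    return out


def effect_size_table(samples, config: ImpactConfig | None = None) -> pd.DataFrame:
    """Impact and Cohen's d (both poolings) per sample.

    ``samples`` may be a mapping name -> LabeledSample, a sequence of
    (name, sample) pairs, of SyntheticSubset, or of bare samples.
    Degenerate Cohen's d values are reported as NaN with
    ``cohens_d_defined`` False — never as a fabricated number.
    """
    rows = []
    for name, sample in _named_samples(samples):
        res = compute_impact(sample, config)
        row = {
            "name": name,
            "n1": int(sample.x1.size),
            "n2": int(sample.x2.size),
            "impact": res.impact,
            "ct_diff": res.ct_diff,
            "morph_diff": res.morph_diff,
            "gmd_pooled": res.gmd_pooled,
            "ct_weight": res.ct_weight,
            "gate_pvalue": res.gate_pvalue,
            "gated_zero": res.gated_zero,
        }
        for key, pooling in (("cohens_d_rms", "rms"), ("cohens_d_nweighted", "n_weighted")):
            try:
                row[key] = cohens_d(sample.x1, sample.x2, pooling=pooling)
            except UndefinedEffectSizeError:
                row[key] = np.nan
        row["cohens_d_defined"] = np.isfinite(row["cohens_d_rms"])
        rows.append(row)
    return pd.DataFrame(rows)


def impact_d_correlation(table: pd.DataFrame, names: Sequence[str] | None = None,
                         d_column: str = "cohens_d_rms") -> float:
    """Pearson correlation between Impact and Cohen's d over a row block."""
    sub = table if names is None else table[table["name"].isin(names)]
    sub = sub.dropna(subset=["impact", d_column])
    if len(sub) < 3:
        raise ValueError("need at least 3 defined pairs for a correlation")
    return float(stats.pearsonr(sub["impact"], sub[d_column]).statistic)


def robustness_subsampling(
    sample: LabeledSample,
    fractions: Sequence[float] = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1),
    n_runs: int = 10,
    seed: int = 0,
    config: ImpactConfig | None = None,
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Impact and Cohen's d stability under class-proportional subsampling.

    For each fraction, ``n_runs`` subsamples are drawn without
    replacement, keeping the class proportions of the original sample;
    the table reports mean, SD and coefficient of variation (percent) of
    both measures across runs.  The full fraction (1.0) uses the complete
    sample in every run, so its SD is exactly 0.  Fractions that would
    leave fewer than ``min_per_group`` observations in a group are
    flagged (``ok`` False) rather than silently dropped.
    """
    rng = np.random.default_rng(seed)
    x1, x2 = sample.x1, sample.x2
    rows = []
    for frac in fractions:
        if not 0.0 < frac <= 1.0:
            raise ValueError("fractions must lie in (0, 1]")
        k1 = x1.size if frac == 1.0 else int(round(frac * x1.size))
        k2 = x2.size if frac == 1.0 else int(round(frac * x2.size))
        row = {"fraction": frac, "n1": k1, "n2": k2,
               "ok": k1 >= min_per_group and k2 >= min_per_group}
        if not row["ok"]:
            rows.append(row)
            continue
        imps, ds = [], []
        for _ in range(n_runs):
            s1 = x1 if frac == 1.0 else rng.choice(x1, size=k1, replace=False)
            s2 = x2 if frac == 1.0 else rng.choice(x2, size=k2, replace=False)
            sub = LabeledSample.from_groups(s1, s2)
            imps.append(compute_impact(sub, config).impact)
            try:
                ds.append(cohens_d(s1, s2, pooling="rms"))
            except UndefinedEffectSizeError:
                ds.append(np.nan)
        for label, arr in (("impact", np.asarray(imps)), ("cohens_d", np.asarray(ds))):
            mean = float(np.nanmean(arr))
            sd = float(np.nanstd(arr, ddof=1)) if np.sum(np.isfinite(arr)) > 1 else np.nan
            row[f"{label}_mean"] = mean
            row[f"{label}_sd"] = sd
            row[f"{label}_cv_pct"] = 100.0 * sd / abs(mean) if abs(mean) > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


_METRICS = ["sensitivity", "specificity", "ppv", "npv", "f1", "accuracy", "auc"]


def _binary_metrics(y_true, y_pred, scores, positive) -> dict[str, float]:
    """Standard confusion-matrix metrics in percent (positive = group 2)."""
    pos = np.asarray(y_true) == positive
    pred_pos = np.asarray(y_pred) == positive
    tp = float(np.sum(pos & pred_pos))
    tn = float(np.sum(~pos & ~pred_pos))
    fp = float(np.sum(~pos & pred_pos))
    fn = float(np.sum(pos & ~pred_pos))

    def ratio(num, den):
        return num / den if den > 0 else np.nan

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    f1 = ratio(2 * tp, 2 * tp + fp + fn)
    acc = (tp + tn) / len(pos)
    auc = roc_auc_score(pos, scores)
    return {k: 100.0 * v for k, v in zip(
        _METRICS, (sens, spec, ppv, npv, f1, acc, auc))}


def classification_experiment(
    features: pd.DataFrame,
    labels,
    feature_columns: Sequence[str] | None = None,
    n_cv: int = 100,
    train_frac: float = 2.0 / 3.0,
    permute_control: bool = False,
    seed: int = 0,
    classifiers: Sequence[str] = ("cart", "rf"),
    n_trees: int = 500,
) -> pd.DataFrame:
    """Tree-based group classification under Monte-Carlo cross-validation.

    Each of the ``n_cv`` runs draws a fresh stratified split into
    non-overlapping training (``train_frac`` of the rows) and test data,
    trains a Gini decision tree ("cart") and/or a random forest of
    ``n_trees`` trees with sqrt(d) features per split ("rf"), and scores
    the held-out data.  With ``permute_control`` every feature column of
    the *training split only* is permuted independently, destroying all
    feature-label association while leaving the test data intact — a
    negative control whose accuracy should hover around chance.

    Returns a summary frame (classifier, metric, median, min, max, in
    percent); the per-run values are attached as ``result.attrs["runs"]``.
    """
    y = np.asarray(labels)
    X = features if feature_columns is None else features[list(feature_columns)]
    if len(X) != y.size:
        raise ValueError("features and labels must have the same number of rows")
    levels = np.unique(y)
    if levels.size != 2:
        raise ValueError("labels must have exactly 2 levels")
    positive = levels[1]
    run_seeds = np.random.SeedSequence(seed).generate_state(n_cv) % (2 ** 31)

    records = []
    for run, rs in enumerate(run_seeds):
        rs = int(rs)
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=train_frac, stratify=y, random_state=rs)
        if permute_control:
            rng = np.random.default_rng(rs)
            X_tr = X_tr.copy()
            for col in X_tr.columns:
                X_tr[col] = rng.permutation(X_tr[col].to_numpy())
        for clf_name in classifiers:
            if clf_name == "cart":
                clf = DecisionTreeClassifier(criterion="gini", random_state=rs)
            elif clf_name == "rf":
                clf = RandomForestClassifier(
                    n_estimators=n_trees, max_features="sqrt",
                    random_state=rs, n_jobs=1)
            else:
                raise ValueError(f"unknown classifier {clf_name!r}")
            clf.fit(X_tr, y_tr)
            scores = clf.predict_proba(X_te)[:, list(clf.classes_).index(positive)]
            y_pred = clf.predict(X_te)
            rec = {"run": run, "classifier": clf_name}
            rec.update(_binary_metrics(y_te, y_pred, scores, positive))
            records.append(rec)
    runs = pd.DataFrame(records)

    summary_rows = []
    for clf_name in classifiers:
        block = runs[runs["classifier"] == clf_name]
        for metric in _METRICS:
            vals = block[metric].to_numpy()
            summary_rows.append({
                "classifier": clf_name,
                "metric": metric,
                "median": float(np.nanmedian(vals)),
                "min": float(np.nanmin(vals)),
                "max": float(np.nanmax(vals)),
            })
    summary = pd.DataFrame(summary_rows)
    summary.attrs["runs"] = runs
    summary.attrs["config"] = {
        "n_cv": n_cv, "train_frac": train_frac, "permute_control": permute_control,
        "seed": seed, "classifiers": tuple(classifiers), "n_trees": n_trees,
        "features": list(X.columns),
    }
    return summary
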