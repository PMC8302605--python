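"""Benchmarking of detectors and combination strategies against known truth.

Calls are scored against the simulated DEG flags with the standard confusion
counts and derived metrics — precision (PPV), recall (sensitivity), F-measure
(harmonic mean of precision and recall) — plus a rank-based (Mann–Whitney)
AUC for methods that produce a continuous score.  ``benchmark`` orchestrates
the full sweep over a simulated grid: per dataset it applies the expression
filter, runs the three detectors, evaluates each detector's calls, every
minimum-vote threshold, the combined-FDR call and (optionally) the Naive
Bayes classifier, emitting one record per (dataset, method).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .combine import CombineConfig, NBModel, combine_results, de_calls
from .data_io import CountMatrix, FilterConfig, SampleDesign, filter_low_expression
from .de import run_all_detectors
from .simulate import SimTruth

logger = logging.getLogger(__name__)

METRIC_COLUMNS = [
    "dataset_id", "method", "TP", "FP", "TN", "FN",
    "precision", "recall", "f_measure", "auc",
]


def confusion(calls: pd.Series, truth: SimTruth) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) of boolean calls against the true DEG flags."""
    t = truth.is_deg
    if set(calls.index) != set(t.index):
        raise ValueError("call and truth gene sets differ")
    c = calls.reindex(t.index).astype(bool)
    tp = int((c & t).sum())
    fp = int((c & ~t).sum())
    fn = int((~c & t).sum())
    tn = int((~c & ~t).sum())
    return tp, fp, tn, fn


def metrics(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float, float]:
    """(precision, recall, f_measure); NaN where a denominator is zero."""
    precision = tp / (tp + fp) if tp + fp > 0 else np.nan
    recall = tp / (tp + fn) if tp + fn > 0 else np.nan
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f = np.nan
    else:
        f = 2.0 * precision * recall / (precision + recall)
    return precision, recall, f


def auc(scores, truth) -> float:
    """Rank-based AUC (larger score = more DE); ties get average ranks.

    Equivalent to the trapezoidal area under the ROC curve.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present in the truth")
    ranks = stats.rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _rank_score(fdr: pd.Series, pvalue: pd.Series) -> pd.Series:
    """Continuous DE score ranking by FDR, ties broken by raw p (smaller = more DE)."""
    combined = fdr.to_numpy(dtype=float) + 1e-12 * pvalue.to_numpy(dtype=float)
    return pd.Series(-combined, index=fdr.index)


def _record(dataset_id: str, method: str, calls: pd.Series, truth: SimTruth,
            score: pd.Series | None) -> dict:
    tp, fp, tn, fn = confusion(calls, truth)
    precision, recall, f = metrics(tp, fp, tn, fn)
    a = np.nan
    if score is not None:
        t = truth.is_deg
        if t.any() and not t.all():
            a = auc(score.reindex(t.index).to_numpy(), t.to_numpy())
        else:
            logger.info("dataset %s: single-class truth, AUC skipped", dataset_id)
    return {
        "dataset_id": dataset_id, "method": method,
        "TP": tp, "FP": fp, "TN": tn, "FN": fn,
        "precision": precision, "recall": recall, "f_measure": f, "auc": a,
    }


def evaluate_dataset(
    dataset_id: str,
    m: CountMatrix,
    design: SampleDesign,
    truth: SimTruth,
    filter_cfg: FilterConfig | None = None,
    combine_cfg: CombineConfig | None = None,
    nb_model: NBModel | None = None,
) -> pd.DataFrame:
    """All metric records for one dataset (detectors, thresholds, combined, NB).

    Evaluation covers every simulated gene: genes removed by the expression
    filter are scored as not-called, so filtered-out true DEGs count as
    false negatives.
    """
    combine_cfg = combine_cfg or CombineConfig()
    filtered = filter_low_expression(m, filter_cfg)
    results = run_all_detectors(filtered, design)
    n_methods = len(results)
    all_genes = truth.table.index

    def full(calls_like: pd.Series) -> pd.Series:
        return calls_like.reindex(all_genes, fill_value=False).astype(bool)

    def full_score(score: pd.Series) -> pd.Series:
        # filtered genes rank below every tested gene
        return score.reindex(all_genes, fill_value=float(score.min()) - 1.0)

    records = []
    calls = de_calls(results, combine_cfg)
    for r in results:
        records.append(
            _record(
                dataset_id, r.method_name, full(calls[r.method_name]), truth,
                full_score(_rank_score(r.table["fdr"], r.table["pvalue"])),
            )
        )

    combined = combine_results(results, combine_cfg, nb_model=nb_model)
    votes = combined["votes"]
    for t in range(1, n_methods + 1):
        records.append(
            _record(dataset_id, f"threshold_{t}", full(votes >= t), truth, None)
        )
    records.append(
        _record(
            dataset_id, "combined", full(combined["combined_call"]), truth,
            full_score(-combined["combined_fdr"]),
        )
    )
    if nb_model is not None:
        records.append(
            _record(
                dataset_id, "naive_bayes", full(combined["nb_call"]), truth,
                full_score(combined["nb_posterior"]),
            )
        )
    return pd.DataFrame.from_records(records, columns=METRIC_COLUMNS)


def benchmark(
    datasets: Iterable[tuple[str, object, tuple[CountMatrix, SampleDesign, SimTruth]]],
    filter_cfg: FilterConfig | None = None,
    combine_cfg: CombineConfig | None = None,
    nb_model: NBModel | None = None,
) -> pd.DataFrame:
    """Metric records over a dataset stream as produced by ``run_grid``.

    The stream yields (label, params, (counts, design, truth)); parameters
    with a ``pdeg``/``logfc`` attribute are echoed into the record table so
    summaries can group on them.
    """
    frames = []
    for label, params, (m, design, truth) in datasets:
        try:
            rec = evaluate_dataset(
                label, m, design, truth,
                filter_cfg=filter_cfg, combine_cfg=combine_cfg, nb_model=nb_model,
            )
        except Exception as err:  # attach the dataset id to any stage failure
            raise RuntimeError(f"dataset {label}: {err}") from err
        for attr in ("pdeg", "logfc", "n_genes", "reps_per_group"):
            if hasattr(params, attr):
                rec[attr] = getattr(params, attr)
        frames.append(rec)
    if not frames:
        raise ValueError("need at least one dataset")
    return pd.concat(frames, ignore_index=True)


def summarize(records: pd.DataFrame, group_by: Sequence[str]) -> pd.DataFrame:
    """Grouped five-number summaries plus the mean for every metric column.

    Undefined (NaN) metric values are excluded, with the exclusion count
    reported per group in ``<metric>_n_excluded``.
    """
    if records.empty:
        raise ValueError("empty record table")
    unknown = set(group_by) - set(records.columns)
    if unknown:
        raise ValueError(f"unknown grouping field(s): {sorted(unknown)}")
    value_cols = [c for c in ("precision", "recall", "f_measure", "auc")
                  if c in records.columns]
    rows = []
    for key, grp in records.groupby(list(group_by), sort=True, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(group_by, key))
        for col in value_cols:
            v = grp[col].dropna().to_numpy()
            row[f"{col}_n_excluded"] = int(grp[col].isna().sum())
            if len(v):
                row[f"{col}_mean"] = float(v.mean())
                row[f"{col}_min"] = float(v.min())
                row[f"{col}_q1"] = float(np.percentile(v, 25))
                row[f"{col}_median"] = float(np.median(v))
                row[f"{col}_q3"] = float(np.percentile(v, 75))
                row[f"{col}_max"] = float(v.max())
        rows.append(row)
    return pd.DataFrame(rows)
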