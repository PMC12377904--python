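"""Benchmark statistics for composition recovery.

Estimated and true compositions are compared after normalizing both to
relative abundances: Jensen-Shannon divergence (base 2, bounded [0, 1]) for
overall recovery, coefficient of variation for flatness on uniform designs,
max/min fold-range, Pearson correlation in log10 space with zeros substituted
by (minimum finite log10 - 1), and precision/recall/F1 for presence calls
(present == abundance > 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from scipy.stats import pearsonr

from .quantify import DEFAULT_PERCENTILE, summarize
from .refdb import ReferenceDatabase


def _as_composition(v) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if (arr < 0).any():
        raise ValueError("abundances must be non-negative")
    total = arr.sum()
    return arr / total if total > 0 else arr


def jsd(p, q) -> float:
    """Jensen-Shannon divergence, log base 2: 0 (identical) to 1 (disjoint).

    Inputs are normalized to compositions first; 0*log0 terms contribute
    nothing, so coordinates that are zero in both vectors are inert.
    """
    p = _as_composition(p)
    q = _as_composition(q)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    # scipy returns the JS *distance* (square root of the divergence)
    return float(jensenshannon(p, q, base=2) ** 2)


def coefficient_of_variation(values) -> float:
    """100 * sample standard deviation (n-1) / mean, in percent."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


def log_pearson(truth, estimate) -> float:
    """Pearson correlation of log10 abundances with zero-substitution.

    Zeros (i.e. -inf in log space) in either vector are replaced by the
    minimum finite log10 value across both vectors minus 1.
    """
    t = np.asarray(truth, dtype=float)
    e = np.asarray(estimate, dtype=float)
    if t.shape != e.shape:
        raise ValueError("length mismatch")
    if t.size < 3:
        raise ValueError("need at least three points")
    with np.errstate(divide="ignore"):
        lt = np.log10(t)
        le = np.log10(e)
    finite = np.concatenate([lt[np.isfinite(lt)], le[np.isfinite(le)]])
    if finite.size == 0:
        raise ValueError("no finite abundances")
    floor = finite.min() - 1
    lt[~np.isfinite(lt)] = floor
    le[~np.isfinite(le)] = floor
    if np.allclose(lt, lt[0]) or np.allclose(le, le[0]):
        raise ValueError("correlation undefined for a constant vector")
    return float(pearsonr(lt, le).statistic)


def fold_range(values) -> float:
    """max/min over a vector of positive values (1.0 means perfectly flat)."""
    arr = np.asarray(values, dtype=float)
    if (arr <= 0).any():
        raise ValueError("fold range requires strictly positive values")
    return float(arr.max() / arr.min())


@dataclass(frozen=True)
class PresenceScores:
    precision: float
    recall: float
    f1: float
    undefined: bool = False


def presence_f1(truth_present, called_present) -> PresenceScores:
    """Precision/recall/F1 with 'present' as the positive class."""
    t = np.asarray(truth_present, dtype=bool)
    c = np.asarray(called_present, dtype=bool)
    if t.shape != c.shape:
        raise ValueError("length mismatch")
    tp = int(np.sum(t & c))
    fp = int(np.sum(~t & c))
    fn = int(np.sum(t & ~c))
    if tp + fp == 0:
        return PresenceScores(0.0, 0.0 if tp + fn else 0.0, 0.0, undefined=True)
    precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return PresenceScores(precision, recall, f1)


def benchmark_run(
    db: ReferenceDatabase,
    designs,
    percentile: float = DEFAULT_PERCENTILE,
) -> pd.DataFrame:
    """Simulate, quantify, and score each design with both estimators.

    Each design must use the strain set the database was built from.  For
    every design and for each of the wpFUKM and FPKM estimators, the table
    reports JSD against truth, CV and fold-range (uniform designs), log10
    Pearson over strains present in truth, and presence precision/recall/F1
    (designs with absent strains).
    """
    from .mapping import ExactFragmentMapper, count_fragments
    from .simulate import simulate_reads

    mapper = ExactFragmentMapper(db)
    rows = []
    for i, design in enumerate(designs):
        strain_ids = [s.strain_id for s in design.strains]
        if set(strain_ids) != set(db.strain_ids):
            raise ValueError("design strains do not match the database")
        pairs, truth = simulate_reads(design)
        counts = count_fragments(pairs, mapper)
        report = summarize(db, counts, percentile)
        est = report.strains.set_index("strain_id").loc[strain_ids]
        truth_vec = np.asarray(design.true_abundances, dtype=float)
        has_absent = bool((truth_vec == 0).any())
        for estimator in ("wpfukm", "fpkm"):
            values = est[estimator].to_numpy()
            row = {
                "design": i,
                "distribution": design.distribution_name,
                "estimator": estimator,
                "jsd": jsd(truth_vec, values),
                "cv_pct": np.nan,
                "fold_range": np.nan,
                "log_pearson": np.nan,
                "precision": np.nan,
                "recall": np.nan,
                "f1": np.nan,
            }
            if design.distribution_name == "uniform":
                row["cv_pct"] = coefficient_of_variation(values)
                if (values > 0).all():
                    row["fold_range"] = fold_range(values)
            present = truth_vec > 0
            if present.sum() >= 3:
                try:
                    row["log_pearson"] = log_pearson(
                        truth_vec[present], values[present]
                    )
                except ValueError:
                    pass
            if has_absent:
                scores = presence_f1(present, values > 0)
                row["precision"] = scores.precision
                row["recall"] = scores.recall
                row["f1"] = scores.f1
            rows.append(row)
    return pd.DataFrame(rows)
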