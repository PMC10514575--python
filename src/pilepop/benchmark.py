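"""Benchmark summaries: bias/RMSE of estimators, F1 of SNP calling,
power of the association test at an empirical false-positive rate."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class BenchmarkSummary:
    bias: float
    rmse: float
    f1: float | None = None
    power: float | None = None
    fpr: float | None = None


def bench_freq(estimates, truth) -> BenchmarkSummary:
    """Signed bias and RMSE of frequency estimates against a truth vector.

    ``truth`` is either the per-site population frequency or the realised
    sample frequency, depending on which reference the benchmark targets.
    """
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape:
        raise ValueError("estimates and truth must have equal length")
    err = est - tru
    return BenchmarkSummary(bias=float(err.mean()),
                            rmse=float(np.sqrt(np.mean(err ** 2))))


def bench_snp(calls, truth_is_snp) -> float | None:
    """F1 score (harmonic mean of precision and recall) of SNP calls.

    Returns None when there are neither positive calls nor true positives
    (F1 undefined).
    """
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth_is_snp, dtype=bool)
    tp = int(np.sum(calls & truth))
    fp = int(np.sum(calls & ~truth))
    fn = int(np.sum(~calls & truth))
    if tp + fp + fn == 0:
        return None
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2.0 * precision * recall / (precision + recall)


def bench_assoc(lrts_causal, lrts_null,
                alpha_fpr: float = 0.10) -> tuple[float, float]:
    """Power at an empirical false-positive rate.

    The rejection threshold is the (1 - alpha_fpr) quantile of the
    null-site LRTs; power is the fraction of causal-site LRTs above it.
    """
    causal = np.asarray(lrts_causal, dtype=float)
    null = np.asarray(lrts_null, dtype=float)
    if len(causal) == 0 or len(null) == 0:
        raise ValueError("need nonempty causal and null LRT vectors")
    threshold = float(np.quantile(null, 1.0 - alpha_fpr))
    power = float(np.mean(causal > threshold))
    return power, threshold
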