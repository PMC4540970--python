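"""Independent step-by-step TMM oracle.

A deliberately plain transcription of the trimmed-mean-of-M-values recipe:
explicit per-gene loops, sort-and-slice trimming, no shared code with the
package implementation. Used only as a reference in tests.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_tmm_factors(counts: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05):
    """Return (factors, reference index) for a genes × libraries array."""
    counts = np.asarray(counts, dtype=float)
    n_genes, n_libs = counts.shape
    totals = [sum(counts[g, k] for g in range(n_genes)) for k in range(n_libs)]

    # reference library: 75th percentile of depth-normalized counts closest
    # to the across-library mean of those percentiles
    q75 = [np.quantile([counts[g, k] / totals[k] for g in range(n_genes)], 0.75) for k in range(n_libs)]
    mean_q75 = sum(q75) / n_libs
    ref = min(range(n_libs), key=lambda k: abs(q75[k] - mean_q75))

    log_factors = []
    for k in range(n_libs):
        if k == ref:
            log_factors.append(0.0)
            continue
        M, A, W = [], [], []
        for g in range(n_genes):
            y, r = counts[g, k], counts[g, ref]
            if y > 0 and r > 0:
                p, q = y / totals[k], r / totals[ref]
                M.append(math.log2(p / q))
                A.append(0.5 * math.log2(p * q))
                W.append((totals[k] - y) / (totals[k] * y) + (totals[ref] - r) / (totals[ref] * r))
        n = len(M)
        if n == 0:
            log_factors.append(0.0)
            continue
        lo_m = int(math.floor(n * trim_m))
        lo_a = int(math.floor(n * trim_a))
        order_m = sorted(range(n), key=lambda i: M[i])
        order_a = sorted(range(n), key=lambda i: A[i])
        keep_m = set(order_m[lo_m : n - lo_m])
        keep_a = set(order_a[lo_a : n - lo_a])
        keep = keep_m & keep_a
        num = sum(M[i] / W[i] for i in keep)
        den = sum(1.0 / W[i] for i in keep)
        log_factors.append(num / den if den > 0 else 0.0)

    factors = [2.0**f for f in log_factors]
    geo = math.exp(sum(math.log(f) for f in factors) / n_libs)
    return np.array([f / geo for f in factors]), ref
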