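"""Expressed-gene filtering and TMM normalization.

Genes are kept when every library has at least one mapped read and at least
one library reaches 20 counts. Between-library scaling uses the trimmed mean
of M-values (TMM): per-gene log2 expression ratios against a reference
library are doubly trimmed (by ratio and by abundance) and their
precision-weighted mean gives the library's scaling factor. The product of a
library's total count and its scaling factor is the effective library size,
used downstream as the GLM offset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import CountMatrix

__all__ = [
    "FilterReport",
    "NormalizationResult",
    "filter_expressed",
    "tmm_factors",
    "effective_sizes",
    "TMMNormalizer",
]

MIN_COUNT_EVERY_LIBRARY = 1
MIN_COUNT_ONE_LIBRARY = 20


@dataclass
class FilterReport:
    """Outcome of the expressed-gene filter."""

    n_input: int
    n_retained: int
    n_removed_zero_library: int  # failed: >=1 count in every library
    n_removed_low_max: int  # failed: >=20 counts in at least one library
    # removed genes binned by the number of temperatures at which every
    # replicate library had nonzero counts ("temperature-specific" genes)
    removed_by_n_temperatures: dict[int, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_removed_zero_library": self.n_removed_zero_library,
            "n_removed_low_max": self.n_removed_low_max,
            "removed_by_n_temperatures": {
                str(k): v for k, v in sorted(self.removed_by_n_temperatures.items())
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def filter_expressed(
    matrix: CountMatrix,
    min_count_every: int = MIN_COUNT_EVERY_LIBRARY,
    min_count_one: int = MIN_COUNT_ONE_LIBRARY,
) -> tuple[CountMatrix, FilterReport]:
    """Keep genes expressed in all libraries with ≥20 counts somewhere.

    A gene passes when (a) every library has at least ``min_count_every``
    reads and (b) at least one library has ≥ ``min_count_one``. Both
    thresholds are inclusive. The report bins removed genes by the number of
    temperatures at which all replicate libraries were nonzero, which is how
    temperature-specific expression is summarized.
    """
    counts = matrix.counts.to_numpy()
    rule_every = counts.min(axis=1) >= min_count_every
    rule_max = counts.max(axis=1) >= min_count_one
    keep = rule_every & rule_max
    if not keep.any():
        raise ValueError("no genes pass the expressed-gene filter")

    removed = ~keep
    temps = matrix.temperatures
    by_n_temp: dict[int, int] = {}
    if removed.any():
        sub = counts[removed]
        n_temps = np.zeros(sub.shape[0], dtype=int)
        for t in np.unique(temps):
            cols = temps == t
            n_temps += (sub[:, cols] > 0).all(axis=1).astype(int)
        vals, cnts = np.unique(n_temps, return_counts=True)
        by_n_temp = {int(v): int(c) for v, c in zip(vals, cnts)}

    report = FilterReport(
        n_input=int(counts.shape[0]),
        n_retained=int(keep.sum()),
        n_removed_zero_library=int((~rule_every).sum()),
        n_removed_low_max=int((rule_every & ~rule_max).sum()),
        removed_by_n_temperatures=by_n_temp,
    )
    filtered = CountMatrix(matrix.counts.loc[keep], matrix.samples)
    return filtered, report


@dataclass
class NormalizationResult:
    """TMM scaling factors and effective library sizes."""

    scaling_factors: pd.Series  # geometric mean 1
    effective_library_sizes: pd.Series  # total counts × factor
    reference_library: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scaling_factor": self.scaling_factors,
                "effective_library_size": self.effective_library_sizes,
            }
        ).rename_axis("library_id")

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _choose_reference(counts: np.ndarray, totals: np.ndarray) -> int:
    """Library whose 75th-percentile depth-normalized count is closest to
    the across-library mean of those percentiles (the standard heuristic)."""
    q75 = np.quantile(counts / totals[None, :], 0.75, axis=0)
    return int(np.argmin(np.abs(q75 - q75.mean())))


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Log2 TMM factor of one library against the reference."""
    ok = (obs > 0) & (ref > 0)  # M and A undefined otherwise; no pseudo-counts
    obs, ref = obs[ok].astype(float), ref[ok].astype(float)
    if obs.size == 0:
        return 0.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    M = np.log2(p_obs / p_ref)
    A = 0.5 * np.log2(p_obs * p_ref)
    # precision weight: delta-method binomial variance of M
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    n = M.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(M)
    ra = rankdata(A)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 0.0
    f = (M[keep] / w[keep]).sum() / (1.0 / w[keep]).sum()
    return float(f) if np.isfinite(f) else 0.0


def tmm_factors(
    matrix: CountMatrix,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
    reference_library: str | None = None,
) -> NormalizationResult:
    """Trimmed-mean-of-M-values scaling factors for every library.

    Per library, per-gene log2 depth-normalized ratios (M) against the
    reference and average log2 abundances (A) are computed over genes with
    nonzero counts in both; genes in the upper/lower ``trim_M`` tail of M or
    ``trim_A`` tail of A (rank-based, inclusive) are discarded, and the
    scaling factor is 2 to the inverse-variance-weighted mean of the
    remaining M values. Factors are renormalized to geometric mean 1.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two libraries")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = [matrix.library_ids[i] for i in np.flatnonzero(totals <= 0)]
        raise ValueError(f"libraries with all-zero counts: {bad}")

    if reference_library is None:
        ref_idx = _choose_reference(counts, totals)
    else:
        ref_idx = matrix.library_ids.index(reference_library)
    ref = counts[:, ref_idx]

    log_factors = np.array(
        [
            0.0
            if k == ref_idx
            else _tmm_pair(counts[:, k], ref, totals[k], totals[ref_idx], trim_M, trim_A)
            for k in range(counts.shape[1])
        ]
    )
    factors = 2.0**log_factors
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1

    sf = pd.Series(factors, index=matrix.counts.columns, name="scaling_factor")
    eff = pd.Series(totals * factors, index=matrix.counts.columns, name="effective_library_size")
    return NormalizationResult(sf, eff, matrix.library_ids[ref_idx])


def effective_sizes(matrix: CountMatrix, norm: NormalizationResult) -> np.ndarray:
    """Total counts × scaling factor per library (GLM log-offset input)."""
    totals = matrix.library_totals
    if list(norm.scaling_factors.index) != list(totals.index):
        raise ValueError("normalization result does not match matrix libraries")
    return (totals * norm.scaling_factors).to_numpy(dtype=float)


class TMMNormalizer:
    """Estimator-style wrapper around :func:`tmm_factors`.

    After :meth:`fit`, exposes ``scaling_factors_``,
    ``effective_library_sizes_`` and ``reference_library_``;
    :meth:`transform` returns counts per million of effective library size.
    """

    def __init__(self, trim_M: float = 0.30, trim_A: float = 0.05):
        self.trim_M = trim_M
        self.trim_A = trim_A

    def get_params(self, deep: bool = True) -> dict:
        return {"trim_M": self.trim_M, "trim_A": self.trim_A}

    def set_params(self, **params) -> "TMMNormalizer":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, matrix: CountMatrix) -> "TMMNormalizer":
        result = tmm_factors(matrix, trim_M=self.trim_M, trim_A=self.trim_A)
        self.scaling_factors_ = result.scaling_factors
        self.effective_library_sizes_ = result.effective_library_sizes
        self.reference_library_ = result.reference_library
        self.result_ = result
        return self

    def transform(self, matrix: CountMatrix) -> pd.DataFrame:
        if not hasattr(self, "effective_library_sizes_"):
            raise RuntimeError("TMMNormalizer is not fitted")
        eff = self.effective_library_sizes_.reindex(matrix.counts.columns)
        if eff.isna().any():
            raise ValueError("matrix has libraries unseen at fit time")
        return matrix.counts / eff.to_numpy() * 1e6

    def fit_transform(self, matrix: CountMatrix) -> pd.DataFrame:
        return self.fit(matrix).transform(matrix)
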