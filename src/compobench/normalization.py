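"""The four count-table transformations under comparison.

* relative abundance — counts divided by library size;
* CLR — centered log-ratio, log counts minus their per-sample mean log;
* TMM — weighted trimmed mean of M-values against a reference sample
  (the edgeR scaling-factor algorithm, published defaults: 30% trim on
  M-values, 5% on A-values, precision weights from the binomial delta
  method);
* DESeq-style — median-of-ratios size factors against per-taxon
  geometric means across samples.

All four operate on the taxa x samples count matrix; TMM and DESeq return
per-sample factors which :func:`normalize_counts` applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

RELATIVE = "relative"
CLR = "clr"
TMM = "tmm"
DESEQ = "deseq"
ABSOLUTE = "absolute"

METHODS = (ABSOLUTE, RELATIVE, CLR, TMM, DESEQ)

DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class NormalizedMatrix:
    """A transformed taxa x samples matrix plus the transform's metadata."""

    values: pd.DataFrame
    method: str
    pseudocount: float | None = None
    factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method tag: {self.method!r}")


def as_absolute(matrix: pd.DataFrame) -> NormalizedMatrix:
    """Wrap ground-truth absolute abundances as the un-normalized reference."""
    return NormalizedMatrix(values=matrix, method=ABSOLUTE)


def relative_abundance(counts: pd.DataFrame) -> NormalizedMatrix:
    """Divide each sample by its library size; columns sum to one."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("every sample must have a positive library size")
    return NormalizedMatrix(values=counts / totals, method=RELATIVE)


def clr_transform(
    counts: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> NormalizedMatrix:
    """Centered log-ratio transform, per sample.

    ``clr(x)_i = log(x_i + c) - mean_j log(x_j + c)``; the pseudocount ``c``
    is added only when the matrix contains zeros (sampling zeros do occur
    even though the simulated community has none). Columns sum to zero.
    """
    values = counts.to_numpy(dtype=float)
    has_zero = bool((values == 0).any())
    if np.any(values < 0):
        raise ValueError("counts must be non-negative")
    if has_zero:
        if pseudocount <= 0:
            raise ValueError("zero counts present: a positive pseudocount is required")
        values = values + pseudocount
        used = pseudocount
    else:
        used = 0.0
    logs = np.log(values)
    clr = logs - logs.mean(axis=0, keepdims=True)
    return NormalizedMatrix(
        values=pd.DataFrame(clr, index=counts.index, columns=counts.columns),
        method=CLR,
        pseudocount=used,
    )


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """log2 scaling factor of one sample against the reference (TMM core)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        # binomial delta-method precision weights
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(log_r) & np.isfinite(abs_e)
    if not finite.any():
        raise ValueError("sample shares no positive taxon with the reference")
    log_r, abs_e, v = log_r[finite], abs_e[finite], v[finite]
    if np.max(np.abs(log_r)) < 1e-6:
        return 0.0
    n = log_r.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return 0.0 if not np.isfinite(f) else float(f)


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.3, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, one per sample.

    The reference sample is the one whose 75th-percentile count over
    library size is closest to the mean of that quantity across samples.
    For every sample, per-taxon log2 abundance ratios (M) against the
    reference are trimmed on both M and average abundance (A) and averaged
    with inverse-variance weights. Factors are rescaled to geometric
    mean 1; a pure depth difference between samples yields factors of 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    values = counts.to_numpy(dtype=float)
    lib = values.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample must have a positive library size")
    f75 = np.quantile(values, 0.75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = values[:, ref_idx]
    log_factors = np.array(
        [
            _tmm_pair_factor(values[:, j], ref, lib[j], lib[ref_idx], trim_m, trim_a)
            for j in range(values.shape[1])
        ]
    )
    factors = 2.0 ** log_factors
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def deseq_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one per sample.

    Per taxon, the geometric mean of its counts across samples is the
    pseudo-reference; each sample's size factor is the median over taxa of
    count / pseudo-reference. Only taxa with strictly positive counts in
    every sample enter (the classic definition); if sampling zeros leave
    that set empty, geometric means are taken over positive counts only
    and each sample's median over its own positive taxa.
    """
    values = counts.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("counts must be non-negative")
    all_positive = (values > 0).all(axis=1)
    with np.errstate(divide="ignore"):
        logs = np.where(values > 0, np.log(values), np.nan)
    # median taken on the log scale (exp(median(log ratios))): identical to
    # the median ratio for odd counts, and the canonical average of the two
    # middle ratios' logs for even counts
    if all_positive.any():
        log_geo = logs[all_positive].mean(axis=1)
        sf = np.exp(np.median(logs[all_positive] - log_geo[:, None], axis=0))
    else:
        pos_any = ~np.all(np.isnan(logs), axis=1)
        if not pos_any.any():
            raise ValueError("no taxon with positive counts; size factors undefined")
        log_geo = np.nanmean(logs[pos_any], axis=1)
        sf = np.exp(np.nanmedian(logs[pos_any] - log_geo[:, None], axis=0))
    if np.any(~np.isfinite(sf)) or np.any(sf <= 0):
        raise ValueError("size factors undefined for at least one sample")
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_counts(
    counts: pd.DataFrame, factors: pd.Series, method: str
) -> NormalizedMatrix:
    """Apply per-sample scaling factors to produce normalized abundances.

    TMM factors rescale the *library size* (counts / (library size x
    factor), an effective-library-size normalization); DESeq size factors
    divide the counts directly.
    """
    if (factors <= 0).any():
        raise ValueError("scaling factors must be strictly positive")
    factors = factors.reindex(counts.columns)
    if factors.isna().any():
        raise ValueError("factors must cover every sample")
    if method == TMM:
        denom = counts.sum(axis=0) * factors
    elif method == DESEQ:
        denom = factors
    else:
        raise ValueError(f"normalize_counts applies to 'tmm' or 'deseq', got {method!r}")
    return NormalizedMatrix(values=counts / denom, method=method, factors=factors)


def tmm_normalize(counts: pd.DataFrame, **kwargs) -> NormalizedMatrix:
    return normalize_counts(counts, tmm_factors(counts, **kwargs), TMM)


def deseq_normalize(counts: pd.DataFrame) -> NormalizedMatrix:
    return normalize_counts(counts, deseq_size_factors(counts), DESEQ)
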