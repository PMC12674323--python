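"""Community-level distances and PERMANOVA variance partitioning.

Three sample-by-sample dissimilarities — 1 minus the Pearson correlation
of log-profiles, Bray–Curtis, and Aitchison (Euclidean distance between
CLR-transformed samples) — feed a one-factor PERMANOVA whose R² is the
fraction of the distance matrix's total sum of squares attributable to
the grouping (vegan's ``adonis2`` partition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .normalization import clr_transform

LOG_PEARSON = "log_pearson"
BRAY_CURTIS = "bray_curtis"
AITCHISON = "aitchison"


@dataclass
class PermanovaResult:
    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int


def _as_distance_frame(d: np.ndarray, labels) -> pd.DataFrame:
    d = np.asarray(d, dtype=float)
    if np.any(d < -1e-12):
        raise ValueError("negative distances produced")
    d = np.maximum(d, 0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=labels, columns=labels)


def log_pearson_distance(
    matrix: pd.DataFrame, pseudocount: float = 0.0, already_log: bool = False
) -> pd.DataFrame:
    """1 - Pearson correlation between log-transformed sample profiles.

    ``already_log`` skips the log for matrices on a log-like scale (CLR
    values); otherwise values must be positive after adding the
    pseudocount. Ranges in [0, 2].
    """
    values = matrix.to_numpy(dtype=float)
    if not already_log:
        values = values + pseudocount
        if np.any(values <= 0):
            raise ValueError("values must be positive after pseudocount for the log")
        values = np.log(values)
    if np.any(values.std(axis=0) == 0):
        raise ValueError("a sample profile has zero variance; correlation undefined")
    corr = np.corrcoef(values.T)
    return _as_distance_frame(1.0 - corr, matrix.columns)


def bray_curtis_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Bray–Curtis dissimilarity: sum |x - y| / sum (x + y), per sample pair."""
    values = matrix.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("Bray–Curtis requires non-negative values")
    if np.any(values.sum(axis=0) == 0):
        raise ValueError("Bray–Curtis undefined for an all-zero sample")
    d = squareform(pdist(values.T, metric="braycurtis"))
    return _as_distance_frame(d, matrix.columns)


def aitchison_distance(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Euclidean distance between CLR-transformed samples."""
    clr = clr_transform(counts, pseudocount=pseudocount).values
    return euclidean_distance(clr)


def euclidean_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    d = squareform(pdist(matrix.to_numpy(dtype=float).T, metric="euclidean"))
    return _as_distance_frame(d, matrix.columns)


def _partition(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float, float]:
    """Total / within / between sums of squares from squared distances."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(groups):
        members = np.flatnonzero(groups == g)
        if members.size > 1:
            sub = d2[np.ix_(members, members)]
            ss_within += sub[np.triu_indices(members.size, k=1)].sum() / members.size
    return ss_total, ss_within, ss_total - ss_within


def permanova(
    d: pd.DataFrame,
    groups,
    n_permutations: int = 999,
    rng: np.random.Generator | None = None,
) -> PermanovaResult:
    """One-factor permutational multivariate ANOVA on a distance matrix.

    The total sum of squares ``sum_{i<j} d_ij^2 / n`` is split into within-
    and between-group parts; R² is the between fraction and the pseudo-F
    statistic follows the usual one-way partition. The p-value comes from
    label permutations (R² itself needs none, so ``n_permutations=0`` is
    valid and returns p = NaN).
    """
    groups = np.asarray(groups)
    if groups.size != d.shape[0]:
        raise ValueError("one group label per sample is required")
    levels, counts = np.unique(groups, return_counts=True)
    if levels.size < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if np.any(counts < 1):
        raise ValueError("every group must be non-empty")
    dm = d.to_numpy(dtype=float)
    if not np.allclose(dm, dm.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    d2 = dm**2
    n = dm.shape[0]
    k = levels.size

    ss_total, ss_within, ss_between = _partition(d2, groups)
    if ss_total <= 0:
        raise ValueError("distance matrix has zero total sum of squares")
    r2 = ss_between / ss_total
    pseudo_f = (ss_between / (k - 1)) / (ss_within / (n - k)) if ss_within > 0 else np.inf

    if n_permutations <= 0:
        return PermanovaResult(r2, pseudo_f, np.nan, 0)
    rng = np.random.default_rng(rng)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(groups)
        _, sw, sb = _partition(d2, perm)
        f_perm = (sb / (k - 1)) / (sw / (n - k)) if sw > 0 else np.inf
        if f_perm >= pseudo_f:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return PermanovaResult(r2, pseudo_f, p, n_permutations)
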