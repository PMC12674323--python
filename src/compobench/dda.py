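"""Differential-abundance detection and its scoring against ground truth.

Per taxon, the two arms are compared with a Kruskal–Wallis rank-sum test
on a per-subject response (by default the between-timepoint change), the
p-values are Benjamini–Hochberg adjusted across the taxa of the dataset,
and taxa with adjusted p below the cutoff (default 0.1) are flagged.
Flags are then scored against the known responder set: a flagged
non-responder is a false positive, an unflagged responder a false
negative; each count is scaled by twice its own class size by default
(see :class:`ErrorRates` for the conventions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .community import BASELINE, POST, TREATMENT, CohortDesign, TruthTable
from .normalization import CLR, NormalizedMatrix

DEFAULT_ALPHA = 0.1

#: per-subject response modes
CHANGE = "change"
POST_ONLY = "post_only"

#: scale of the between-timepoint change for non-CLR representations
DIFFERENCE = "difference"
LOG_RATIO = "log_ratio"

#: error-rate denominator conventions
HALF_CLASS = "half_class"   # errors / (2 x class size); "all missed" = 0.5
TOTAL_TAXA = "total_taxa"   # errors / taxon count


@dataclass
class ErrorRates:
    """Confusion counts and rates for one dataset's detections.

    The default ``half_class`` convention scores each error class against
    twice its own reference-class size: FP / (2 x non-responders) and
    FN / (2 x responders), i.e. half the false-alarm and miss rates, so a
    dataset in which every responder is missed (or every non-responder
    flagged) scores exactly 0.500 at any response proportion. The
    ``total_taxa`` alternative divides both counts by the taxon total.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    convention: str = HALF_CLASS

    def __post_init__(self) -> None:
        if self.convention not in (HALF_CLASS, TOTAL_TAXA):
            raise ValueError(f"unknown rate convention: {self.convention!r}")

    @property
    def n_taxa(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def fp_rate(self) -> float:
        if self.convention == TOTAL_TAXA:
            return self.fp / self.n_taxa
        n_null = self.fp + self.tn
        return self.fp / (2 * n_null) if n_null else 0.0

    @property
    def fn_rate(self) -> float:
        if self.convention == TOTAL_TAXA:
            return self.fn / self.n_taxa
        n_resp = self.tp + self.fn
        return self.fn / (2 * n_resp) if n_resp else 0.0


def per_subject_response(
    norm: NormalizedMatrix,
    design: CohortDesign,
    mode: str = CHANGE,
    change_scale: str = LOG_RATIO,
) -> pd.DataFrame:
    """Collapse the two timepoints into one response value per subject.

    ``change`` mode (default) exploits the paired design. On the CLR
    scale the response is always the plain difference post - baseline
    (CLR values are already logs). On the other scales ``change_scale``
    selects the log-ratio ``log(post / baseline)`` (default) or the plain
    difference; for the log-ratio, an offset of half the smallest
    positive value keeps sampling zeros finite. ``post_only`` mode
    returns the post-intervention values as-is.

    Returns a taxa x subjects DataFrame, columns in design order.
    """
    if mode not in (CHANGE, POST_ONLY):
        raise ValueError(f"unknown response mode: {mode!r}")
    if change_scale not in (DIFFERENCE, LOG_RATIO):
        raise ValueError(f"unknown change scale: {change_scale!r}")
    values = norm.values
    base_cols = design.sample_names(BASELINE)
    post_cols = design.sample_names(POST)
    missing = [c for c in (*base_cols, *post_cols) if c not in values.columns]
    if missing:
        raise ValueError(f"matrix is missing samples: {missing}")
    post = values[post_cols].to_numpy(dtype=float)
    if mode == POST_ONLY:
        return pd.DataFrame(post, index=values.index, columns=list(design.subject_ids))
    base = values[base_cols].to_numpy(dtype=float)
    if norm.method == CLR or change_scale == DIFFERENCE:
        resp = post - base
    else:
        eps = 0.0
        both = np.concatenate([base, post], axis=1)
        if (both <= 0).any():
            positives = both[both > 0]
            if positives.size == 0:
                raise ValueError("all values are zero; response undefined")
            eps = 0.5 * positives.min()
        resp = np.log((post + eps) / (base + eps))
    return pd.DataFrame(resp, index=values.index, columns=list(design.subject_ids))


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and its chi-squared p-value.

    A completely tied sample — every observation equal — is defined as no
    evidence: H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    samples = [values[groups == g] for g in levels]
    if len(samples) < 2 or any(s.size < 1 for s in samples):
        raise ValueError("need at least two non-empty groups")
    if np.all(values == values[0]):
        return 0.0, 1.0
    stat, p = stats.kruskal(*samples)
    return float(stat), float(p)


def kruskal_wallis_matrix(
    responses: np.ndarray, in_treatment: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-group Kruskal–Wallis over a taxa x subjects matrix.

    Vectorized equivalent of calling :func:`kruskal_wallis` per row with
    the same tie correction and chi-squared reference (df = 1); rows where
    all subjects tie get H = 0, p = 1.
    """
    X = np.asarray(responses, dtype=float)
    mask = np.asarray(in_treatment, dtype=bool)
    n = X.shape[1]
    n_t = int(mask.sum())
    n_c = n - n_t
    if n_t == 0 or n_c == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(X, axis=1)
    r_t = ranks[:, mask].sum(axis=1)
    r_c = ranks[:, ~mask].sum(axis=1)
    h = 12.0 / (n * (n + 1)) * (r_t**2 / n_t + r_c**2 / n_c) - 3.0 * (n + 1)

    # tie correction: 1 - sum(t^3 - t) / (n^3 - n), run lengths per row
    xs = np.sort(X, axis=1)
    new_run = np.ones_like(xs, dtype=bool)
    new_run[:, 1:] = xs[:, 1:] != xs[:, :-1]
    run_id = np.cumsum(new_run, axis=1)  # 1..k within each row
    offsets = np.arange(X.shape[0])[:, None] * (n + 1)
    flat = (run_id + offsets).ravel()
    cnt = np.bincount(flat, minlength=X.shape[0] * (n + 1) + 1)[1:]
    cnt = cnt.reshape(X.shape[0], n + 1)[:, : n + 1]
    tie_term = ((cnt**3 - cnt).sum(axis=1)).astype(float)
    correction = 1.0 - tie_term / (n**3 - n)

    all_tied = correction <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(all_tied, 0.0, h / np.where(all_tied, 1.0, correction))
    h = np.maximum(h, 0.0)  # guard tiny negative rounding
    p = stats.chi2.sf(h, df=1)
    p = np.where(all_tied, 1.0, p)
    h = np.where(all_tied, 0.0, h)
    return h, p


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def detect_responders(
    norm: NormalizedMatrix,
    design: CohortDesign,
    alpha: float = DEFAULT_ALPHA,
    mode: str = CHANGE,
    change_scale: str = LOG_RATIO,
) -> pd.DataFrame:
    """Per-taxon treatment-vs-control test with BH correction.

    Returns a DataFrame indexed by taxon with columns ``statistic``,
    ``pvalue``, ``padj`` and ``flagged`` (adjusted p < alpha).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    resp = per_subject_response(norm, design, mode=mode, change_scale=change_scale)
    in_treatment = np.array([g == TREATMENT for g in design.group_labels])
    h, p = kruskal_wallis_matrix(resp.to_numpy(), in_treatment)
    padj = bh_adjust(p)
    return pd.DataFrame(
        {
            "statistic": h,
            "pvalue": p,
            "padj": padj,
            "flagged": padj < alpha,
        },
        index=resp.index,
    )


def error_rates(flags, truth: TruthTable, convention: str = HALF_CLASS) -> ErrorRates:
    """Score significance flags against the known responder set.

    See :class:`ErrorRates` for the two rate conventions; the default
    scales each error count by twice its own class size, so that a fully
    misdetected class scores exactly 0.5 regardless of the response
    proportion.
    """
    flags = np.asarray(flags, dtype=bool)
    if flags.size != truth.n_taxa:
        raise ValueError("flags and truth table must cover the same taxa")
    resp = truth.responder
    return ErrorRates(
        tp=int(np.sum(flags & resp)),
        fp=int(np.sum(flags & ~resp)),
        tn=int(np.sum(~flags & ~resp)),
        fn=int(np.sum(~flags & resp)),
        convention=convention,
    )
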