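"""Diagnostic-performance statistics for elastography reads.

AUCs are the Mann-Whitney (rank) statistic with ties counted 1/2, with 95%
confidence intervals from the DeLong structural-components variance
estimator.  Paired AUCs on the same cases are compared with the two-sided
DeLong test.  Also provided: the Tsukuba-score adjustment of BI-RADS
categories (soft lesions downgrade, stiff lesions upgrade one step on the
ordered scale 2 < 3 < 4a < 4b < 4c < 5), the blind-test perceptual score
(fraction of trials in which the observer fails to identify the real
elastogram; 0.5 = indistinguishable), and depth-stratified AUC tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "RocResult",
    "ReaderRecord",
    "BIRADS_SCALE",
    "auc_ci",
    "delong_test",
    "combine_tsukuba_birads",
    "birads_to_score",
    "perceptual_score",
    "depth_stratified_auc",
]

BIRADS_SCALE = ("2", "3", "4a", "4b", "4c", "5")
_BIRADS_INDEX = {c: i for i, c in enumerate(BIRADS_SCALE)}


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class ReaderRecord:
    """One blind-evaluation read of a paired real/virtual elastogram display."""

    case_id: str
    birads: str
    tsukuba_real: int
    tsukuba_virtual: int
    picked_real_correctly: bool
    reader_tier: str  # junior | senior

    def __post_init__(self) -> None:
        if self.birads not in _BIRADS_INDEX:
            raise ValueError(f"invalid BI-RADS category {self.birads!r}")
        for score in (self.tsukuba_real, self.tsukuba_virtual):
            if not 1 <= score <= 5:
                raise ValueError(f"Tsukuba score {score} outside [1, 5]")
        if self.reader_tier not in ("junior", "senior"):
            raise ValueError(f"reader_tier must be junior|senior, got {self.reader_tier!r}")


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong V10/V01 placement components and the Mann-Whitney AUC.

    Midranks handle ties; the AUC equals the brute-force pairwise statistic
    with ties counted 1/2.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_scores = np.concatenate([pos, neg])
    rank_all = rankdata(all_scores)          # midranks over the pooled sample
    rank_pos = rankdata(pos)
    rank_neg = rankdata(neg)
    auc = (rank_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (rank_all[:m] - rank_pos) / n       # one per positive case
    v01 = 1.0 - (rank_all[m:] - rank_neg) / m  # one per negative case
    return auc, v10, v01


def _check_classes(labels: np.ndarray) -> None:
    if not ((labels == 1).any() and (labels == 0).any()):
        raise ValueError("both classes must be present")


def auc_ci(scores: Sequence[float], labels: Sequence[int],
           alpha: float = 0.05) -> RocResult:
    """Mann-Whitney AUC with a DeLong-variance confidence interval."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    _check_classes(labels)
    auc, v10, v01 = _structural_components(scores, labels)
    var = (np.var(v10, ddof=1) / v10.size if v10.size > 1 else 0.0) + \
          (np.var(v01, ddof=1) / v01.size if v01.size > 1 else 0.0)
    z = norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return RocResult(
        auc=float(auc),
        ci_low=float(np.clip(auc - half, 0.0, auc)),
        ci_high=float(np.clip(auc + half, auc, 1.0)),
        n_pos=int((labels == 1).sum()),
        n_neg=int((labels == 0).sum()),
    )


def delong_test(scores_a: Sequence[float], scores_b: Sequence[float],
                labels: Sequence[int]) -> float:
    """Two-sided DeLong p-value for equality of two correlated AUCs."""
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValueError("scores_a, scores_b and labels must have equal length")
    _check_classes(labels)
    auc_a, v10_a, v01_a = _structural_components(a, labels)
    auc_b, v10_b, v01_b = _structural_components(b, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var_diff)
    return float(2 * norm.sf(abs(z)))


def combine_tsukuba_birads(birads: str, tsukuba: int) -> str:
    """Adjust a BI-RADS category by one ordinal step from the Tsukuba score.

    Scores 1-3 (strain present: soft) downgrade; scores 4-5 (no strain:
    stiff) upgrade; clipped at both ends of the 2 < 3 < 4a < 4b < 4c < 5
    scale.
    """
    if birads not in _BIRADS_INDEX:
        raise ValueError(f"invalid BI-RADS category {birads!r}")
    if not 1 <= int(tsukuba) <= 5:
        raise ValueError(f"Tsukuba score must be in [1, 5], got {tsukuba}")
    idx = _BIRADS_INDEX[birads]
    idx += -1 if tsukuba <= 3 else 1
    return BIRADS_SCALE[int(np.clip(idx, 0, len(BIRADS_SCALE) - 1))]


def birads_to_score(birads: str) -> int:
    """Ordinal integer for ROC analysis of categorical reads (2 -> 0 ... 5 -> 5)."""
    return _BIRADS_INDEX[birads]


def perceptual_score(records: Sequence[ReaderRecord]) -> float:
    """Mean blind-test score: 1 when the observer failed to spot the real image.

    A model whose output is indistinguishable from real elastograms scores
    0.5 against a forced-choice observer.
    """
    if len(records) == 0:
        raise ValueError("no reader records")
    return float(np.mean([0.0 if r.picked_real_correctly else 1.0 for r in records]))


def depth_stratified_auc(scores: Sequence[float], labels: Sequence[int],
                         depths_mm: Sequence[float],
                         bin_edges: Sequence[float] = (0.0, 10.0, 15.0, 20.0, np.inf),
                         ) -> pd.DataFrame:
    """Per-depth-bin AUC table; bins missing a class are flagged, not dropped."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    depths = np.asarray(depths_mm, dtype=np.float64)
    edges = np.asarray(bin_edges, dtype=np.float64)
    if not (np.diff(edges) > 0).all():
        raise ValueError("bin edges must be strictly increasing")
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (depths >= lo) & (depths < hi)
        entry = {"depth_lo": lo, "depth_hi": hi, "n": int(mask.sum())}
        sub_labels = labels[mask]
        if mask.sum() and (sub_labels == 1).any() and (sub_labels == 0).any():
            roc = auc_ci(scores[mask], sub_labels)
            entry.update(auc=roc.auc, ci_low=roc.ci_low, ci_high=roc.ci_high,
                         defined=True)
        else:
            entry.update(auc=np.nan, ci_low=np.nan, ci_high=np.nan, defined=False)
        rows.append(entry)
    return pd.DataFrame(rows)
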