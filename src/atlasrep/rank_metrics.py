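"""Rank-based performance metrics.

The central statistic of the package is the area under the empirical ROC
curve (AUROC), computed analytically from midranks rather than by
integrating a thresholded curve.  With ``ranks`` the ascending midranks of
all scores and positives/negatives counted as ``n_pos`` / ``n_neg``::

    AUROC = sum(ranks of positives) / (n_pos * n_neg) - (n_pos + 1) / (2 * n_neg)

which equals the tie-corrected Mann-Whitney estimate of
``P(score_pos > score_neg)`` with ties counted one half.  An AUROC of 0.5
is chance; 1.0 is perfect separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ScoredLabels",
    "auroc",
    "precision_at_full_recall",
    "identity_line_distance",
]


class DegenerateClassError(ValueError):
    """Raised when a metric needs both classes but one is empty."""


@dataclass(frozen=True)
class ScoredLabels:
    """A vector of real-valued scores with binary labels (1 = positive)."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels)
        if scores.shape != labels.shape or scores.ndim != 1:
            raise ValueError("scores and labels must be 1-D and the same length")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels.astype(bool))


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(scores, ScoredLabels):
        return scores.scores, scores.labels
    sl = ScoredLabels(np.asarray(scores, dtype=float), np.asarray(labels))
    return sl.scores, sl.labels


def auroc(scores, labels=None) -> float:
    """Analytic AUROC from midranks (ties count one half).

    Accepts either a :class:`ScoredLabels` or ``(scores, labels)`` arrays.
    Requires at least one positive and one negative sample.
    """
    s, y = _as_arrays(scores, labels)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateClassError(
            f"AUROC needs both classes; got {n_pos} positives, {n_neg} negatives"
        )
    ranks = rankdata(s, method="average")
    return float(ranks[y].sum() / (n_pos * n_neg) - (n_pos + 1) / (2 * n_neg))


def precision_at_full_recall(scores, labels=None) -> float:
    """Precision at the loosest threshold that still captures every positive.

    The threshold is the minimum positive score; everything scoring at or
    above it is called positive, so TP equals the number of positives and
    the return value is ``n_pos / n_called``.
    """
    s, y = _as_arrays(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise DegenerateClassError("precision needs at least one positive")
    threshold = s[y].min()
    called = int((s >= threshold).sum())
    return n_pos / called


def identity_line_distance(points, *, perpendicular: bool = True) -> float:
    """Mean absolute distance of (x, y) points from the identity line y = x.

    By default the perpendicular Euclidean distance ``|x - y| / sqrt(2)``;
    with ``perpendicular=False`` the raw vertical gap ``|x - y|`` (the two
    differ only by the constant sqrt(2)).
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("identity_line_distance needs at least one point")
    pts = pts.reshape(-1, 2)
    gaps = np.abs(pts[:, 0] - pts[:, 1])
    if perpendicular:
        gaps = gaps / np.sqrt(2.0)
    return float(gaps.mean())
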