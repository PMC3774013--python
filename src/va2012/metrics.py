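"""Validity and reliability measures for assigned vs reference causes.

Formulas are the standard ones from the VA-validation literature:
one-vs-rest sensitivity/specificity/PPV/NPV, Cohen's kappa, CSMF
accuracy, per-cause and average chance-corrected concordance, Lin's
concordance correlation coefficient, and a rank-based AUC.  Degenerate
denominators yield ``None`` (undefined flags), never silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .interpret import CSMFVector

__all__ = [
    "ConfusionMatrix",
    "BinaryMetrics",
    "binary_metrics",
    "cohens_kappa",
    "csmf_accuracy",
    "chance_corrected_concordance",
    "csmf_concordance_correlation",
    "rank_auc",
    "collapse_causes",
]


@dataclass
class ConfusionMatrix:
    """Square cross-tabulation; rows = true cause, columns = assigned."""

    causes: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = len(self.causes)
        if self.counts.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(int)

    @classmethod
    def from_pairs(
        cls, true: Sequence[str], assigned: Sequence[str],
        causes: Optional[Sequence[str]] = None,
    ) -> "ConfusionMatrix":
        if len(true) != len(assigned):
            raise ValueError("true/assigned length mismatch")
        if causes is None:
            causes = sorted(set(true) | set(assigned))
        causes = list(causes)
        index = {c: i for i, c in enumerate(causes)}
        counts = np.zeros((len(causes), len(causes)), dtype=int)
        for t, a in zip(true, assigned):
            counts[index[t], index[a]] += 1
        return cls(causes, counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def index(self, cause: str) -> int:
        try:
            return self.causes.index(cause)
        except ValueError:
            raise KeyError(f"cause {cause!r} not in matrix") from None


@dataclass
class BinaryMetrics:
    """One-vs-rest metrics; ``None`` marks an undefined (0/0) ratio."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]


def _ratio(num: float, den: float) -> Optional[float]:
    return None if den == 0 else num / den


def binary_metrics(confusion: ConfusionMatrix, cause: str) -> BinaryMetrics:
    """Collapse to one-vs-rest for ``cause`` and compute the four ratios."""
    j = confusion.index(cause)
    c = confusion.counts
    tp = c[j, j]
    fn = c[j, :].sum() - tp
    fp = c[:, j].sum() - tp
    tn = c.sum() - tp - fn - fp
    return BinaryMetrics(
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
    )


def cohens_kappa(confusion: ConfusionMatrix) -> Optional[float]:
    """(p_o − p_e) / (1 − p_e) with marginal-product expected agreement."""
    total = confusion.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    c = confusion.counts / total
    p_o = np.trace(c)
    p_e = float(c.sum(axis=1) @ c.sum(axis=0))
    if p_e == 1.0:
        return None
    return float((p_o - p_e) / (1.0 - p_e))


def csmf_accuracy(
    true_csmf: CSMFVector, pred_csmf: CSMFVector
) -> Optional[float]:
    """1 − Σ|pred − true| / (2 (1 − min true)).

    The minimum runs over the declared cause list as given, including
    causes with zero true fraction.  Undefined (None) when the true
    distribution is a point mass over a single-cause universe.
    """
    if true_csmf.causes != pred_csmf.causes:
        raise ValueError("cause lists must align")
    t, p = true_csmf.fractions, pred_csmf.fractions
    denom = 2.0 * (1.0 - float(t.min()))
    if denom == 0.0:
        return None
    return float(1.0 - np.abs(p - t).sum() / denom)


@dataclass
class ConcordanceReport:
    causes: list[str]
    per_cause: list[Optional[float]]
    average: Optional[float]


def chance_corrected_concordance(confusion: ConfusionMatrix) -> ConcordanceReport:
    """Per cause j: (P(assigned j | true j) − 1/N) / (1 − 1/N); average over
    causes with at least one true death."""
    n = len(confusion.causes)
    if n < 2:
        raise ValueError("need at least 2 causes")
    per_cause: list[Optional[float]] = []
    for j in range(n):
        row_total = confusion.counts[j, :].sum()
        if row_total == 0:
            per_cause.append(None)
            continue
        frac = confusion.counts[j, j] / row_total
        per_cause.append(float((frac - 1.0 / n) / (1.0 - 1.0 / n)))
    defined = [v for v in per_cause if v is not None]
    average = float(np.mean(defined)) if defined else None
    return ConcordanceReport(list(confusion.causes), per_cause, average)


def csmf_concordance_correlation(
    true_series: Sequence[float], pred_series: Sequence[float]
) -> Optional[float]:
    """Lin's concordance correlation coefficient over paired fractions.

    Undefined (None) when both series have zero variance.
    """
    t = np.asarray(true_series, dtype=float)
    p = np.asarray(pred_series, dtype=float)
    if t.shape != p.shape or t.ndim != 1 or len(t) < 2:
        raise ValueError("need >= 2 aligned paired observations")
    var_t = t.var()
    var_p = p.var()
    denom = var_t + var_p + (t.mean() - p.mean()) ** 2
    if denom == 0.0:
        # identical constant series agree perfectly but carry no signal
        return None if var_t == 0 and var_p == 0 else 0.0
    cov = ((t - t.mean()) * (p - p.mean())).mean()
    return float(2.0 * cov / denom)


def rank_auc(labels: Sequence[int], scores: Sequence[float]) -> Optional[float]:
    """Rank-based (Mann-Whitney) AUC with midrank treatment of score ties."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s), dtype=float)
    sorted_s = s[order]
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0  # midrank, 1-based
        i = j + 1
    rank_sum_pos = ranks[y == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def collapse_causes(
    confusion: ConfusionMatrix, cause_a: str, cause_b: str, merged: str
) -> ConfusionMatrix:
    """Merge two causes into one on both axes (never decreases agreement)."""
    ia, ib = confusion.index(cause_a), confusion.index(cause_b)
    keep = [k for k in range(len(confusion.causes)) if k not in (ia, ib)]
    c = confusion.counts
    merged_row = c[ia, :] + c[ib, :]
    merged_col = c[:, ia] + c[:, ib]
    merged_diag = merged_row[ia] + merged_row[ib]
    new_causes = [confusion.causes[k] for k in keep] + [merged]
    n = len(new_causes)
    out = np.zeros((n, n), dtype=int)
    for r, kr in enumerate(keep):
        for cidx, kc in enumerate(keep):
            out[r, cidx] = c[kr, kc]
        out[r, n - 1] = merged_col[kr]
    for cidx, kc in enumerate(keep):
        out[n - 1, cidx] = merged_row[kc]
    out[n - 1, n - 1] = merged_diag
    return ConfusionMatrix(new_causes, out)
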