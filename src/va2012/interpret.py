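"""Automated cause assignment: Bayesian posterior and Tariff additive scoring.

Both engines are matrix-parameterized; probability or tariff matrices are
user-supplied, fitted from training data, or synthetic — never claimed as
officially endorsed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .questionnaire import VARecord
from .standard import UNKNOWN_CAUSE

__all__ = [
    "ConditionalProbabilityMatrix",
    "TariffMatrix",
    "Assignment",
    "bayes_posterior",
    "fit_tariff",
    "tariff_score",
    "assign",
    "csmf_from_assignments",
    "CSMFVector",
]

PROB_FLOOR = 1e-6  # avoid single-item vetoes from hard zeros


@dataclass
class ConditionalProbabilityMatrix:
    """P(indicator endorsed | cause) with a baseline cause prior."""

    causes: list[str]
    indicators: list[str]
    p: np.ndarray  # shape (n_indicators, n_causes)
    prior: np.ndarray  # shape (n_causes,), sums to 1

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.prior = np.asarray(self.prior, dtype=float)
        if self.p.shape != (len(self.indicators), len(self.causes)):
            raise ValueError(
                f"matrix shape {self.p.shape} inconsistent with "
                f"{len(self.indicators)} indicators x {len(self.causes)} causes"
            )
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise ValueError("conditional probabilities must lie in [0, 1]")
        if self.prior.shape != (len(self.causes),):
            raise ValueError("prior length inconsistent with cause list")
        if np.any(self.prior < 0) or not np.isclose(self.prior.sum(), 1.0):
            raise ValueError("prior must be a normalized probability vector")
        self._row = {iid: k for k, iid in enumerate(self.indicators)}

    @classmethod
    def uniform_prior(
        cls, causes: Sequence[str], indicators: Sequence[str], p: np.ndarray
    ) -> "ConditionalProbabilityMatrix":
        n = len(causes)
        return cls(list(causes), list(indicators), p, np.full(n, 1.0 / n))

    def row_index(self, indicator_id: str) -> int:
        return self._row[indicator_id]

    def to_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.p, index=self.indicators, columns=self.causes)
        frame.index.name = "indicator_id"
        frame.to_csv(path)

    @classmethod
    def from_csv(
        cls, path: str | Path, prior_path: str | Path | None = None
    ) -> "ConditionalProbabilityMatrix":
        frame = pd.read_csv(path, index_col=0)
        causes = [str(c) for c in frame.columns]
        if prior_path is None:
            prior = np.full(len(causes), 1.0 / len(causes))
        else:
            pf = pd.read_csv(prior_path, index_col=0)
            prior = pf.iloc[:, 0].reindex(causes).to_numpy(dtype=float)
        return cls(causes, [str(i) for i in frame.index], frame.to_numpy(float), prior)

    def prior_to_csv(self, path: str | Path) -> None:
        pd.Series(self.prior, index=self.causes, name="prior").rename_axis(
            "va_code"
        ).to_csv(path)


@dataclass
class TariffMatrix:
    """Robust-scaled endorsement deviations for additive scoring."""

    causes: list[str]
    indicators: list[str]
    tariff: np.ndarray  # shape (n_indicators, n_causes)

    def __post_init__(self) -> None:
        self.tariff = np.asarray(self.tariff, dtype=float)
        if self.tariff.shape != (len(self.indicators), len(self.causes)):
            raise ValueError("tariff shape inconsistent with axes")
        if not np.all(np.isfinite(self.tariff)):
            raise ValueError("tariff entries must be finite")
        self._row = {iid: k for k, iid in enumerate(self.indicators)}

    def row_index(self, indicator_id: str) -> int:
        return self._row[indicator_id]

    def to_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.tariff, index=self.indicators, columns=self.causes)
        frame.index.name = "indicator_id"
        frame.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TariffMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls([str(c) for c in frame.columns],
                   [str(i) for i in frame.index],
                   frame.to_numpy(float))


@dataclass
class Assignment:
    """Per-record engine output: full vector over causes plus the top cause."""

    record_id: str
    causes: list[str]
    values: np.ndarray
    top_cause: str
    top_value: float
    engine: str
    tied: bool = False
    degenerate: bool = False


def bayes_posterior(
    record: VARecord,
    matrix: ConditionalProbabilityMatrix,
    mode: str = "positive_only",
) -> tuple[np.ndarray, bool]:
    """Posterior over causes for one record, computed in log space.

    ``positive_only``: posterior_j ∝ prior_j × Π_{i endorsed} P(i|j).
    ``full_bernoulli`` additionally multiplies (1 − P(i|j)) over explicit
    "no" answers.  dont_know / not_applicable contribute nothing.
    Entries are floored at ``PROB_FLOOR`` on both sides.  Returns
    (posterior, degenerate); a degenerate result (no usable likelihood
    mass) falls back to the prior.
    """
    if mode not in ("positive_only", "full_bernoulli"):
        raise ValueError(f"unknown mode: {mode!r}")
    unknown = [i for i in record.responses if i not in matrix._row]
    if unknown:
        raise KeyError(f"record {record.record_id}: indicators not in matrix: "
                       f"{sorted(unknown)[:5]}")
    with np.errstate(divide="ignore"):
        log_post = np.log(matrix.prior.astype(float))
        p = np.clip(matrix.p, PROB_FLOOR, 1.0)
        for iid in sorted(record.endorsed()):
            log_post += np.log(p[matrix.row_index(iid)])
        if mode == "full_bernoulli":
            q = np.clip(1.0 - matrix.p, PROB_FLOOR, 1.0)
            for iid in sorted(record.denied()):
                log_post += np.log(q[matrix.row_index(iid)])
    if np.all(np.isneginf(log_post)):
        return matrix.prior.copy(), True
    log_post -= np.max(log_post[np.isfinite(log_post)])
    post = np.exp(log_post)
    total = post.sum()
    if total <= 0 or not np.isfinite(total):
        return matrix.prior.copy(), True
    return post / total, False


def fit_tariff(
    training_records: Sequence[VARecord],
    training_causes: dict[str, str],
    causes: Sequence[str],
    indicators: Sequence[str],
) -> TariffMatrix:
    """Fit tariffs from endorsement rates.

    tariff(i, j) = (x(i,j) − median_j x(i,·)) / IQR_j x(i,·) with linear-
    interpolation (inclusive) quantiles; IQR = 0 falls back to
    1.4826 × MAD, and to all-zero tariffs for the row if that is zero too.
    """
    causes = list(causes)
    indicators = list(indicators)
    counts = np.zeros((len(indicators), len(causes)))
    totals = np.zeros(len(causes))
    cause_index = {c: j for j, c in enumerate(causes)}
    ind_index = {i: k for k, i in enumerate(indicators)}
    for rec in training_records:
        cause = training_causes.get(rec.record_id)
        if cause is None:
            raise KeyError(f"no training cause for record {rec.record_id}")
        j = cause_index[cause]
        totals[j] += 1
        for iid in rec.endorsed():
            k = ind_index.get(iid)
            if k is not None:
                counts[k, j] += 1
    missing = [c for c, n in zip(causes, totals) if n == 0]
    if missing:
        raise ValueError(f"causes absent from training data: {missing}")
    x = counts / totals  # endorsement rate per (indicator, cause)
    med = np.median(x, axis=1, keepdims=True)
    q75 = np.quantile(x, 0.75, axis=1, keepdims=True)
    q25 = np.quantile(x, 0.25, axis=1, keepdims=True)
    iqr = q75 - q25
    mad_scale = 1.4826 * np.median(np.abs(x - med), axis=1, keepdims=True)
    scale = np.where(iqr > 0, iqr, mad_scale)
    tariff = np.where(scale > 0, (x - med) / np.where(scale > 0, scale, 1.0), 0.0)
    return TariffMatrix(causes, indicators, tariff)


def tariff_score(record: VARecord, tariff_matrix: TariffMatrix) -> np.ndarray:
    """score_j = Σ over endorsed indicators of tariff(i, j); only "yes" counts."""
    scores = np.zeros(len(tariff_matrix.causes))
    for iid in record.endorsed():
        if iid in tariff_matrix._row:
            scores += tariff_matrix.tariff[tariff_matrix.row_index(iid)]
    return scores


def assign(
    record: VARecord,
    engine: str,
    matrix: ConditionalProbabilityMatrix | TariffMatrix,
    mode: str = "positive_only",
    tau: float = 0.0,
) -> Assignment:
    """Assign a top cause; Bayes posteriors below ``tau`` yield VA-99."""
    if engine == "bayes":
        if not isinstance(matrix, ConditionalProbabilityMatrix):
            raise TypeError("bayes engine needs a ConditionalProbabilityMatrix")
        if not 0.0 <= tau <= 1.0:
            raise ValueError("tau must lie in [0, 1]")
        values, degenerate = bayes_posterior(record, matrix, mode)
    elif engine == "tariff":
        if not isinstance(matrix, TariffMatrix):
            raise TypeError("tariff engine needs a TariffMatrix")
        values, degenerate = tariff_score(record, matrix), False
    else:
        raise ValueError(f"unknown engine: {engine!r}")
    top_idx = int(np.argmax(values))  # argmax takes the first maximum
    tied = int(np.sum(values == values[top_idx])) > 1
    top_cause = matrix.causes[top_idx]
    top_value = float(values[top_idx])
    if engine == "bayes" and top_value < tau:
        top_cause = UNKNOWN_CAUSE
    return Assignment(
        record_id=record.record_id,
        causes=list(matrix.causes),
        values=values,
        top_cause=top_cause,
        top_value=top_value,
        engine=engine,
        tied=tied,
        degenerate=degenerate,
    )


@dataclass
class CSMFVector:
    """Cause-specific mortality fractions over an ordered cause list."""

    causes: list[str]
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (len(self.causes),):
            raise ValueError("fractions length inconsistent with cause list")
        if np.any(self.fractions < 0):
            raise ValueError("fractions must be nonnegative")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1 within 1e-9")

    def as_dict(self) -> dict[str, float]:
        return {c: float(f) for c, f in zip(self.causes, self.fractions)}


def csmf_from_assignments(
    assignments: Sequence[Assignment], method: str = "top_cause"
) -> CSMFVector:
    """Estimate CSMFs from assignments by top-cause tally or posterior average."""
    if not assignments:
        raise ValueError("no assignments provided")
    if method not in ("top_cause", "posterior_average"):
        raise ValueError(f"unknown method: {method!r}")
    causes = list(assignments[0].causes)
    for a in assignments:
        if a.causes != causes:
            raise ValueError("assignments disagree on cause order")
    if method == "top_cause":
        order = list(causes)
        if any(a.top_cause == UNKNOWN_CAUSE for a in assignments) and (
            UNKNOWN_CAUSE not in order
        ):
            order.append(UNKNOWN_CAUSE)
        counts = np.zeros(len(order))
        index = {c: j for j, c in enumerate(order)}
        for a in assignments:
            counts[index[a.top_cause]] += 1
        return CSMFVector(order, counts / counts.sum())
    if any(a.engine != "bayes" for a in assignments):
        raise ValueError("posterior_average requires Bayesian assignments")
    stacked = np.vstack([a.values / a.values.sum() for a in assignments])
    return CSMFVector(causes, stacked.mean(axis=0))
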