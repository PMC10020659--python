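"""TOPSIS comprehensive benefit evaluation.

TOPSIS (Technique for Order Preference by Similarity to Ideal Solution)
ranks a set of alternatives (here: intercropping treatments) against a set
of evaluation indicators by their Euclidean distance to a positive ideal
solution (the best attainable value of every indicator) and a negative
ideal solution (the worst).  The closeness coefficient

    C_i = D_i^- / (D_i^+ + D_i^-)

lies in [0, 1]; C_i = 1 means the alternative sits exactly at the positive
ideal.  Indicators may be *benefit* (larger is better), *cost* (smaller is
better) or *interval* (best inside an optimum range — soil pH with optimum
7–8 is the canonical case here; interval columns are mapped onto [0, 1]
with :func:`transform_interval` before normalization and then treated as
benefit indicators).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TopsisError",
    "Indicator",
    "DecisionMatrix",
    "IntervalTransformParams",
    "TopsisResult",
    "transform_interval",
    "normalize_matrix",
    "ideal_solutions",
    "distances",
    "closeness",
    "rank_by_closeness",
    "entropy_weights",
    "run_topsis",
]

Direction = Literal["benefit", "cost", "interval"]


class TopsisError(ValueError):
    """Raised when a TOPSIS stage receives invalid or degenerate input."""


@dataclass(frozen=True)
class Indicator:
    """A single evaluation criterion.

    Parameters
    ----------
    name:
        Column label in the decision matrix.
    direction:
        ``"benefit"`` (larger is better), ``"cost"`` (smaller is better) or
        ``"interval"`` (best inside ``[interval_low, interval_high]``).
    weight:
        Non-negative relative importance.  Weights are renormalized to sum
        to one before they are applied, so only ratios matter.
    interval_low, interval_high:
        Optimum range bounds; required iff ``direction == "interval"``.
    """

    name: str
    direction: Direction = "benefit"
    weight: float = 1.0
    interval_low: float | None = None
    interval_high: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("benefit", "cost", "interval"):
            raise TopsisError(f"indicator {self.name!r}: unknown direction {self.direction!r}")
        if not np.isfinite(self.weight) or self.weight < 0:
            raise TopsisError(f"indicator {self.name!r}: weight must be finite and >= 0")
        if self.direction == "interval":
            if self.interval_low is None or self.interval_high is None:
                raise TopsisError(f"indicator {self.name!r}: interval direction requires bounds")
            if self.interval_low > self.interval_high:
                raise TopsisError(f"indicator {self.name!r}: interval_low > interval_high")


@dataclass
class DecisionMatrix:
    """Treatments × indicators value grid, the TOPSIS input.

    ``values`` is a DataFrame whose index holds the treatment labels and
    whose columns match ``[i.name for i in indicators]`` in order.
    """

    values: pd.DataFrame
    indicators: list[Indicator]

    def __post_init__(self) -> None:
        names = [ind.name for ind in self.indicators]
        if list(self.values.columns) != names:
            raise TopsisError("decision matrix columns must match indicator names in order")
        if len(names) != len(set(names)):
            raise TopsisError("indicator names must be unique")
        if self.values.index.duplicated().any():
            raise TopsisError("treatment labels must be unique")
        if self.values.shape[0] < 2:
            raise TopsisError("a decision matrix needs at least 2 treatments")
        if self.values.shape[1] < 1:
            raise TopsisError("a decision matrix needs at least 1 indicator")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise TopsisError("decision matrix contains missing or non-finite entries")

    @property
    def treatments(self) -> list[str]:
        return [str(t) for t in self.values.index]

    @property
    def directions(self) -> list[str]:
        return [ind.direction for ind in self.indicators]

    @property
    def weights(self) -> np.ndarray:
        return np.array([ind.weight for ind in self.indicators], dtype=float)

    def replace(self, *, values: pd.DataFrame | None = None,
                indicators: list[Indicator] | None = None) -> "DecisionMatrix":
        return DecisionMatrix(
            values=self.values.copy() if values is None else values,
            indicators=list(self.indicators) if indicators is None else indicators,
        )


@dataclass(frozen=True)
class IntervalTransformParams:
    """Bookkeeping for an interval-criterion transform.

    ``scale`` is the divisor M = max(lower − min(x), max(x) − upper); it is
    NaN when every observation already lies inside the optimum interval
    (no division is performed in that case).
    """

    lower_bound: float
    upper_bound: float
    observed_min: float
    observed_max: float
    scale: float


@dataclass
class TopsisResult:
    """Per-treatment distances, closeness index and rank (1 = best)."""

    treatments: list[str]
    d_plus: np.ndarray
    d_minus: np.ndarray
    closeness: np.ndarray
    rank: np.ndarray

    def to_frame(self, ndigits: int | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "treatment": self.treatments,
                "d_plus": self.d_plus,
                "d_minus": self.d_minus,
                "closeness": self.closeness,
                "rank": self.rank,
            }
        )
        if ndigits is not None:
            for col in ("d_plus", "d_minus", "closeness"):
                df[col] = df[col].round(ndigits)
        return df


def transform_interval(
    values: Sequence[float], lower_bound: float, upper_bound: float
) -> tuple[np.ndarray, IntervalTransformParams]:
    """Map an interval criterion onto [0, 1] (1 = inside the optimum range).

    Values inside ``[lower_bound, upper_bound]`` map to 1.  A value ``v``
    below the range maps to ``1 − (lower_bound − v)/M`` and one above to
    ``1 − (v − upper_bound)/M`` with
    ``M = max(lower_bound − min(values), max(values) − upper_bound)``.
    When every observation lies below the lower bound this reduces to the
    familiar soil-pH form ``(v − min)/(lower_bound − min)``.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise TopsisError("transform_interval: empty input")
    if not np.isfinite(v).all():
        raise TopsisError("transform_interval: non-finite input")
    if lower_bound > upper_bound:
        raise TopsisError("transform_interval: lower_bound > upper_bound")

    vmin = float(v.min())
    vmax = float(v.max())
    below = v < lower_bound
    above = v > upper_bound
    out = np.ones_like(v)
    if not below.any() and not above.any():
        params = IntervalTransformParams(lower_bound, upper_bound, vmin, vmax, float("nan"))
        return out, params

    scale = max(lower_bound - vmin, vmax - upper_bound)
    out[below] = 1.0 - (lower_bound - v[below]) / scale
    out[above] = 1.0 - (v[above] - upper_bound) / scale
    params = IntervalTransformParams(lower_bound, upper_bound, vmin, vmax, scale)
    return out, params


def normalize_matrix(matrix: DecisionMatrix, method: str = "vector") -> DecisionMatrix:
    """Normalize columns to a dimensionless scale.

    ``vector``: r_ij = x_ij / sqrt(Σ_i x_ij²); directions are untouched
    (cost columns are handled at the ideal-solution step).  ``minmax``:
    (x−min)/(max−min) for benefit/interval columns, (max−x)/(max−min) for
    cost columns, after which every column is a benefit column.
    """
    X = matrix.values.to_numpy(dtype=float)
    if method == "vector":
        norms = np.sqrt((X**2).sum(axis=0))
        zero = norms == 0
        if zero.any():
            bad = matrix.values.columns[zero][0]
            raise TopsisError(f"vector normalization: column {bad!r} is all zeros")
        R = X / norms
        return matrix.replace(values=pd.DataFrame(R, index=matrix.values.index,
                                                  columns=matrix.values.columns))
    if method == "minmax":
        lo = X.min(axis=0)
        hi = X.max(axis=0)
        rng = hi - lo
        if (rng == 0).any():
            bad = matrix.values.columns[rng == 0][0]
            raise TopsisError(f"minmax normalization: column {bad!r} is constant")
        R = np.empty_like(X)
        new_inds = []
        for j, ind in enumerate(matrix.indicators):
            if ind.direction == "cost":
                R[:, j] = (hi[j] - X[:, j]) / rng[j]
            else:
                R[:, j] = (X[:, j] - lo[j]) / rng[j]
            new_inds.append(dataclasses.replace(ind, direction="benefit",
                                                interval_low=None, interval_high=None))
        return DecisionMatrix(
            values=pd.DataFrame(R, index=matrix.values.index, columns=matrix.values.columns),
            indicators=new_inds,
        )
    raise TopsisError(f"unknown normalization method {method!r}")


def ideal_solutions(weighted: DecisionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Positive and negative ideal solutions of a weighted matrix.

    The positive ideal takes the column maximum for benefit (and
    already-transformed interval) columns and the column minimum for cost
    columns; the negative ideal is the opposite.
    """
    X = weighted.values.to_numpy(dtype=float)
    pos = np.empty(X.shape[1])
    neg = np.empty(X.shape[1])
    for j, ind in enumerate(weighted.indicators):
        if ind.direction == "cost":
            pos[j] = X[:, j].min()
            neg[j] = X[:, j].max()
        else:
            pos[j] = X[:, j].max()
            neg[j] = X[:, j].min()
    return pos, neg


def distances(
    weighted: DecisionMatrix, positive_ideal: np.ndarray, negative_ideal: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean distance of every row to each ideal solution."""
    X = weighted.values.to_numpy(dtype=float)
    pos = np.asarray(positive_ideal, dtype=float)
    neg = np.asarray(negative_ideal, dtype=float)
    if pos.shape != (X.shape[1],) or neg.shape != (X.shape[1],):
        raise TopsisError("ideal solution dimension does not match the matrix")
    d_plus = np.sqrt(((X - pos) ** 2).sum(axis=1))
    d_minus = np.sqrt(((X - neg) ** 2).sum(axis=1))
    return d_plus, d_minus


def closeness(d_plus: float, d_minus: float) -> float:
    """Closeness coefficient C = D⁻ / (D⁺ + D⁻).

    Undefined (raises) when both distances are zero, which can only happen
    when every alternative is identical.
    """
    if d_plus < 0 or d_minus < 0:
        raise TopsisError("closeness: distances must be non-negative")
    denom = d_plus + d_minus
    if denom == 0:
        raise TopsisError("closeness undefined: both ideal distances are zero")
    return d_minus / denom


def rank_by_closeness(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..n, 1 = largest closeness; ties keep stable input order."""
    c = np.asarray(values, dtype=float)
    if not np.isfinite(c).all():
        raise TopsisError("rank_by_closeness: non-finite closeness values")
    order = np.argsort(-c, kind="stable")
    ranks = np.empty(c.size, dtype=int)
    ranks[order] = np.arange(1, c.size + 1)
    return ranks


def entropy_weights(matrix: DecisionMatrix) -> np.ndarray:
    """Objective weights from Shannon entropy of the scaled columns.

    Columns are min-max scaled (direction-aware) internally; a constant
    column is treated as maximally even (entropy e_j = 1) and therefore
    gets weight 0 rather than raising.  With p_ij = r_ij / Σ_i r_ij and
    e_j = −(1/ln n) Σ_i p_ij ln p_ij (0·ln 0 := 0), the weight is
    w_j = (1 − e_j) / Σ_k (1 − e_k).  Raises when every column is constant.
    """
    X = matrix.values.to_numpy(dtype=float)
    n, m = X.shape
    e = np.ones(m)
    for j, ind in enumerate(matrix.indicators):
        col = X[:, j]
        lo, hi = col.min(), col.max()
        if hi == lo:
            continue  # constant column: e_j stays 1, weight 0
        if ind.direction == "cost":
            r = (hi - col) / (hi - lo)
        else:
            r = (col - lo) / (hi - lo)
        total = r.sum()
        if total == 0:
            continue
        p = r / total
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        e[j] = -plogp.sum() / np.log(n)
    d = 1.0 - e
    if d.sum() <= 0:
        raise TopsisError("entropy weights undefined: every column is constant")
    return d / d.sum()


def _normalized_weights(
    matrix: DecisionMatrix, weights: np.ndarray | Sequence[float] | Mapping[str, float] | str | None
) -> np.ndarray:
    if isinstance(weights, str):
        if weights != "entropy":
            raise TopsisError(f"unknown weighting mode {weights!r}")
        w = entropy_weights(matrix)
    elif weights is None:
        w = matrix.weights
    elif isinstance(weights, Mapping):
        try:
            w = np.array([float(weights[ind.name]) for ind in matrix.indicators])
        except KeyError as exc:
            raise TopsisError(f"no weight supplied for indicator {exc.args[0]!r}") from None
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(matrix.indicators),):
            raise TopsisError("weight vector length does not match indicator count")
    if (w < 0).any() or not np.isfinite(w).all():
        raise TopsisError("weights must be finite and non-negative")
    total = w.sum()
    if total <= 0:
        raise TopsisError("weights sum to zero")
    return w / total


def run_topsis(
    matrix: DecisionMatrix,
    *,
    normalization: str = "vector",
    weights: np.ndarray | Sequence[float] | Mapping[str, float] | str | None = None,
) -> TopsisResult:
    """Full TOPSIS pipeline: interval transform → normalize → weight →
    ideal solutions → distances → closeness → rank.

    ``weights`` may be None (use the indicators' own weights), a vector, a
    name → weight mapping, or ``"entropy"`` for data-driven entropy
    weights.  Errors from any stage are re-raised with the stage named.
    """
    def stage(name: str):
        class _Stage:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and isinstance(exc, TopsisError) and not str(exc).startswith(name):
                    raise TopsisError(f"{name}: {exc}") from exc
                return False

        return _Stage()

    work = matrix.replace()
    with stage("interval transform"):
        cols = work.values.copy()
        new_inds = []
        for ind in work.indicators:
            if ind.direction == "interval":
                transformed, _ = transform_interval(
                    cols[ind.name].to_numpy(), ind.interval_low, ind.interval_high
                )
                cols[ind.name] = transformed
                new_inds.append(
                    dataclasses.replace(ind, direction="benefit",
                                        interval_low=None, interval_high=None)
                )
            else:
                new_inds.append(ind)
        work = DecisionMatrix(values=cols, indicators=new_inds)

    with stage("weighting"):
        w = _normalized_weights(work, weights)

    with stage("normalization"):
        normed = normalize_matrix(work, method=normalization)

    weighted = normed.replace(values=normed.values * w)

    with stage("ideal solutions"):
        pos, neg = ideal_solutions(weighted)
    with stage("distances"):
        d_plus, d_minus = distances(weighted, pos, neg)
    with stage("closeness"):
        c = np.array([closeness(dp, dm) for dp, dm in zip(d_plus, d_minus)])
    with stage("ranking"):
        ranks = rank_by_closeness(c)

    return TopsisResult(
        treatments=weighted.treatments,
        d_plus=d_plus,
        d_minus=d_minus,
        closeness=c,
        rank=ranks,
    )
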