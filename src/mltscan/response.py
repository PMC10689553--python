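"""Censoring-aware encoding of metabolite measurements.

Metabolomics abundance columns are rarely clean continuous vectors: values at
or below a limit of quantification (LOQ) are only known to lie below that
limit, and limited instrument precision produces ties (many samples sharing
the identical recorded value).  This module encodes one metabolite column as a
mixture of three observation kinds:

* ``exact``     -- an ordinary continuous measurement,
* ``left``      -- left-censored at the LOQ (true value <= bound),
* ``interval``  -- a tie, treated as a rounding of the truth to within the
  half-gaps toward the adjacent distinct observed values.

Missing values are kept as explicit markers and never silently dropped; the
model layer excludes them per fit.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import DegenerateResponseError


class Kind(str, Enum):
    EXACT = "exact"
    LEFT = "left"
    INTERVAL = "interval"


@dataclass(frozen=True)
class CensoredValue:
    """A single observation: exactly one of the three kinds.

    ``value`` is set for exact observations, ``bound`` for left-censored ones
    (the censoring point, i.e. the LOQ), ``lower``/``upper`` for interval
    observations (the true value lies in ``(lower, upper]``).
    """

    kind: Kind
    value: Optional[float] = None
    bound: Optional[float] = None
    lower: Optional[float] = None
    upper: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind == Kind.EXACT:
            if self.value is None or not np.isfinite(self.value):
                raise ValueError("exact observation requires a finite value")
            if self.bound is not None or self.lower is not None or self.upper is not None:
                raise ValueError("exact observation must not carry bounds")
        elif self.kind == Kind.LEFT:
            if self.bound is None or not np.isfinite(self.bound):
                raise ValueError("left-censored observation requires a finite bound")
            if self.value is not None or self.lower is not None or self.upper is not None:
                raise ValueError("left-censored observation carries only its bound")
        elif self.kind == Kind.INTERVAL:
            if self.lower is None or self.upper is None:
                raise ValueError("interval observation requires lower and upper")
            if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
                raise ValueError("interval endpoints must be finite")
            if not self.lower < self.upper:
                raise ValueError("interval requires lower < upper")
            if self.value is not None or self.bound is not None:
                raise ValueError("interval observation carries only its endpoints")
        else:  # pragma: no cover - enum exhausts kinds
            raise ValueError(f"unknown kind {self.kind!r}")

    @classmethod
    def exact(cls, value: float) -> "CensoredValue":
        return cls(Kind.EXACT, value=float(value))

    @classmethod
    def left(cls, bound: float) -> "CensoredValue":
        return cls(Kind.LEFT, bound=float(bound))

    @classmethod
    def interval(cls, lower: float, upper: float) -> "CensoredValue":
        return cls(Kind.INTERVAL, lower=float(lower), upper=float(upper))

    @property
    def anchors(self) -> Tuple[float, ...]:
        """The finite points this observation pins to the response scale."""
        if self.kind == Kind.EXACT:
            return (self.value,)
        if self.kind == Kind.LEFT:
            return (self.bound,)
        return (self.lower, self.upper)


@dataclass
class ResponseVector:
    """One metabolite's observations, aligned to the study's sample index.

    ``values`` has one entry per sample; ``None`` marks a missing measurement.
    ``support`` is the bounded interval on which the monotone transformation
    is parameterized and contains every anchor point.
    """

    name: str
    values: Tuple[Optional[CensoredValue], ...]
    support: Tuple[float, float]
    loq: Optional[float] = None
    loq_units: Optional[str] = None

    def __post_init__(self) -> None:
        a, b = self.support
        if not (np.isfinite(a) and np.isfinite(b) and a < b):
            raise ValueError("support must be a finite interval (a, b) with a < b")
        for v in self.values:
            if v is None:
                continue
            for pt in v.anchors:
                if not (a <= pt <= b):
                    raise ValueError(
                        f"{self.name}: anchor {pt} outside support ({a}, {b})"
                    )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.array([v is None for v in self.values], dtype=bool)

    def _count(self, kind: Kind) -> int:
        return sum(1 for v in self.values if v is not None and v.kind == kind)

    @property
    def n_exact(self) -> int:
        return self._count(Kind.EXACT)

    @property
    def n_left(self) -> int:
        return self._count(Kind.LEFT)

    @property
    def n_interval(self) -> int:
        return self._count(Kind.INTERVAL)

    @property
    def n_missing(self) -> int:
        return sum(1 for v in self.values if v is None)

    @property
    def counts(self) -> dict:
        return {
            "exact": self.n_exact,
            "left": self.n_left,
            "interval": self.n_interval,
            "missing": self.n_missing,
        }


def default_support(values: Sequence[float], margin: float = 0.1) -> Tuple[float, float]:
    """Bounded support from observed anchor points.

    Takes the observed min/max and extends both ends symmetrically by
    ``margin`` times the observed range.  At least two distinct finite anchors
    are required; a zero range is an error.
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0 or np.unique(arr).size < 2:
        raise ValueError("support requires at least 2 distinct finite anchor points")
    lo, hi = float(arr.min()), float(arr.max())
    rng = hi - lo
    return (lo - margin * rng, hi + margin * rng)


def _tie_intervals(uniques: np.ndarray) -> dict:
    """Map each unique value to the half-gap interval around it.

    ``uniques`` is sorted and has length >= 2.  Interior values span the
    midpoints toward their neighbours; the outermost values extend outward by
    half the nearest inter-value gap, so intervals of distinct values never
    overlap.
    """
    m = len(uniques)
    out = {}
    for j, u in enumerate(uniques):
        lower = (uniques[j - 1] + u) / 2.0 if j > 0 else u - (uniques[1] - u) / 2.0
        upper = (u + uniques[j + 1]) / 2.0 if j < m - 1 else u + (u - uniques[m - 2]) / 2.0
        out[float(u)] = (float(lower), float(upper))
    return out


def encode_response(
    raw: Sequence[float],
    loq: Optional[float] = None,
    tie_policy: str = "interval",
    name: str = "y",
    support: Optional[Tuple[float, float]] = None,
    support_margin: float = 0.1,
    loq_units: Optional[str] = None,
) -> ResponseVector:
    """Encode a raw abundance column as exact / left-censored / interval data.

    Every non-missing value ``v <= loq`` becomes left-censored at the LOQ.
    Under ``tie_policy="interval"`` every value occurring more than once among
    the non-censored values becomes an interval observation spanning the
    midpoints to the adjacent distinct observed values (the outermost tied
    values extend by half the nearest gap); all other values stay exact.

    Raises :class:`DegenerateResponseError` when the column cannot support a
    model: fewer than 3 non-missing values, all values censored, a single
    distinct value, or an LOQ above the maximum observation.
    """
    if tie_policy not in ("interval", "none"):
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    arr = np.asarray(raw, dtype=float).ravel()
    finite = np.isfinite(arr)
    obs = arr[finite]
    if obs.size < 3:
        raise DegenerateResponseError(name, f"only {obs.size} non-missing values (need >= 3)")
    if np.unique(obs).size < 2:
        raise DegenerateResponseError(name, "a single distinct value")
    if loq is not None:
        loq = float(loq)
        if not np.isfinite(loq):
            raise ValueError("loq must be finite")
        if loq > obs.max():
            raise DegenerateResponseError(name, f"LOQ {loq} above the maximum observed value")
        censored = obs <= loq
    else:
        censored = np.zeros(obs.size, dtype=bool)
    noncens = obs[~censored]
    if noncens.size == 0:
        raise DegenerateResponseError(name, "all values censored at the LOQ")

    intervals: dict = {}
    if tie_policy == "interval":
        uniques, cnt = np.unique(noncens, return_counts=True)
        tied = set(uniques[cnt > 1].tolist())
        if tied:
            if uniques.size < 2:
                raise DegenerateResponseError(
                    name, "ties cannot be bracketed: fewer than 2 distinct uncensored values"
                )
            halfgaps = _tie_intervals(uniques)
            intervals = {u: halfgaps[u] for u in tied}

    values: list = []
    for v, ok in zip(arr, finite):
        if not ok:
            values.append(None)
        elif loq is not None and v <= loq:
            values.append(CensoredValue.left(loq))
        elif float(v) in intervals:
            lo, hi = intervals[float(v)]
            values.append(CensoredValue.interval(lo, hi))
        else:
            values.append(CensoredValue.exact(v))

    anchors = [pt for cv in values if cv is not None for pt in cv.anchors]
    if support is None:
        support = default_support(anchors, margin=support_margin)
    return ResponseVector(
        name=name,
        values=tuple(values),
        support=support,
        loq=loq,
        loq_units=loq_units,
    )
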