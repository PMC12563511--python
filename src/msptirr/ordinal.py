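"""Ordinal-pattern statistics: amplitude permutations, permutation entropy
and permutation time irreversibility (PTIRR).

A length-``m`` window of a series is summarised by its *amplitude
permutation*: the tuple ``(j1, ..., jm)`` where ``ji`` is the position that
the i-th window element occupies after a stable ascending sort, with every
group of exactly-equal elements collapsed to the group's minimum position.
This is identical to "min" ranking: ``ji = 1 + #{k : x_k < x_i}``.

Permutation entropy is the Shannon entropy of the empirical forward-pattern
distribution.  PTIRR contrasts each forward pattern's probability with that
of its time-reversed (backward) pattern:

    PTIRR = sum over patterns pi of  p(pi) * |p(pi) - p(~pi)| / (p(pi) + p(~pi))

where ``~pi`` is the tuple reversal of ``pi``.  PTIRR is 0 for a series whose
pattern distribution is symmetric under time reversal (e.g. stationary linear
Gaussian processes, in the large-sample limit) and 1 for a strictly monotone
series.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping

import numpy as np

from ._exceptions import InsufficientDataError, InvalidInputError, ParameterError

__all__ = [
    "amplitude_permutation",
    "backward_permutation",
    "pattern_distribution",
    "permutation_entropy",
    "permutation_time_irreversibility",
    "PatternDistribution",
]

Pattern = tuple[int, ...]


def _as_1d_finite(x, name: str = "series") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InvalidInputError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size and not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return arr


def amplitude_permutation(vector: Iterable[float], tie_tol: float = 0.0) -> Pattern:
    """Amplitude permutation of one embedding vector.

    Parameters
    ----------
    vector
        Sequence of ``m >= 2`` finite reals.
    tie_tol
        Absolute tolerance within which two values count as tied.  The
        default 0 uses exact floating-point equality, which is appropriate
        for quantized acquisition data.

    Returns
    -------
    tuple of int
        Ranks ``(j1, ..., jm)``; tied elements share their tie group's
        minimum rank, so a tie-free vector yields a permutation of
        ``1..m`` and a constant vector yields ``(1, ..., 1)``.
    """
    v = _as_1d_finite(vector, "vector")
    if v.size < 2:
        raise ParameterError("vector must have at least 2 elements")
    if tie_tol < 0:
        raise ParameterError("tie_tol must be >= 0")
    ranks = 1 + np.sum(v[None, :] < v[:, None] - tie_tol, axis=1)
    return tuple(int(r) for r in ranks)


def backward_permutation(forward: Pattern) -> Pattern:
    """Pattern of the time-reversed vector: the tuple reversal of `forward`.

    Under the min-rank tie rule, each element's rank depends only on the
    multiset of window values, so reversing the window reverses the rank
    tuple exactly; no re-sorting is needed.
    """
    fwd = tuple(int(r) for r in forward)
    m = len(fwd)
    if m < 2 or any(not (1 <= r <= m) for r in fwd):
        raise ParameterError(f"not a valid amplitude permutation: {forward!r}")
    return fwd[::-1]


@dataclass(frozen=True)
class PatternDistribution:
    """Empirical forward-pattern distribution of one series at one scale.

    Attributes
    ----------
    counts
        Map pattern tuple -> number of embedding windows showing it.
    m
        Embedding dimension.
    n_vectors
        Total number of embedding windows (sum of counts).
    """

    counts: Mapping[Pattern, int]
    m: int
    n_vectors: int

    def __post_init__(self):
        if self.n_vectors < 1:
            raise ParameterError("n_vectors must be positive")
        if sum(self.counts.values()) != self.n_vectors:
            raise InvalidInputError("counts do not sum to n_vectors")

    @cached_property
    def forward_prob(self) -> dict[Pattern, float]:
        """Probability of each observed forward pattern."""
        n = self.n_vectors
        return {p: c / n for p, c in self.counts.items()}

    def probability(self, pattern: Pattern) -> float:
        """Forward probability of `pattern` (0 if never observed)."""
        return self.forward_prob.get(tuple(pattern), 0.0)

    def backward_probability(self, pattern: Pattern) -> float:
        """Probability of the backward image of `pattern`."""
        return self.probability(backward_permutation(pattern))

    @cached_property
    def U(self) -> int:
        """Number of distinct observed forward patterns."""
        return len(self.counts)

    @cached_property
    def pattern_set(self) -> frozenset[Pattern]:
        """Forward patterns plus the backward images of forward patterns."""
        fwd = set(self.counts)
        return frozenset(fwd | {p[::-1] for p in fwd})

    @cached_property
    def V(self) -> int:
        """Size of :attr:`pattern_set` (``U <= V <= 2U``)."""
        return len(self.pattern_set)

    def to_json(self) -> str:
        """Serialize counts for debugging; keys are comma-joined ranks."""
        payload = {
            "m": self.m,
            "n_vectors": self.n_vectors,
            "counts": {",".join(map(str, p)): c for p, c in sorted(self.counts.items())},
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "PatternDistribution":
        payload = json.loads(text)
        counts = {
            tuple(int(t) for t in key.split(",")): int(c)
            for key, c in payload["counts"].items()
        }
        return cls(counts=counts, m=int(payload["m"]), n_vectors=int(payload["n_vectors"]))


def pattern_distribution(
    series: Iterable[float],
    m: int = 3,
    tau: int = 2,
    tie_tol: float = 0.0,
) -> PatternDistribution:
    """Count the amplitude permutations of all delay-embedding windows.

    The series is embedded as ``X(t) = (x[t], x[t+tau], ..., x[t+(m-1)tau])``
    for ``t = 0 .. l - (m-1)*tau - 1`` and each window mapped to its
    amplitude permutation.

    Raises
    ------
    InsufficientDataError
        If the series is shorter than ``(m-1)*tau + 1`` (no window fits).
    """
    if m < 2:
        raise ParameterError(f"embedding dimension m must be >= 2, got {m}")
    if tau < 1:
        raise ParameterError(f"embedding delay tau must be >= 1, got {tau}")
    if tie_tol < 0:
        raise ParameterError("tie_tol must be >= 0")
    x = _as_1d_finite(series)
    min_len = (m - 1) * tau + 1
    n_vec = x.size - (m - 1) * tau
    if n_vec < 1:
        raise InsufficientDataError(
            f"series of length {x.size} admits no (m={m}, tau={tau}) embedding "
            f"window; at least {min_len} samples are required"
        )
    idx = np.arange(n_vec)[:, None] + np.arange(m)[None, :] * tau
    windows = x[idx]
    # ranks[t, i] = 1 + #{j : x_j < x_i - tol} within window t  (min-rank tie rule)
    ranks = 1 + np.sum(windows[:, None, :] < windows[:, :, None] - tie_tol, axis=2)
    codes = (ranks - 1) @ (m ** np.arange(m, dtype=np.int64))
    uniq, counts = np.unique(codes, return_counts=True)
    powers = m ** np.arange(m, dtype=np.int64)
    patterns: dict[Pattern, int] = {}
    for code, count in zip(uniq.tolist(), counts.tolist()):
        digits = tuple(int(code // p % m) + 1 for p in powers)
        patterns[digits] = count
    return PatternDistribution(counts=patterns, m=m, n_vectors=int(n_vec))


def permutation_entropy(
    dist: PatternDistribution,
    base: float | None = None,
    normalized: bool = False,
) -> float:
    """Shannon entropy of the forward-pattern distribution.

    ``base=None`` (default) uses the natural logarithm; pass 2 for bits.
    ``normalized=True`` divides by ``log(m!)`` so the result lies in [0, 1].
    ``0 * log 0`` is taken as 0.
    """
    log = math.log if base is None else (lambda v: math.log(v, base))
    h = -sum(p * log(p) for p in dist.forward_prob.values() if p > 0)
    h = max(h, 0.0)  # clip -0.0 from rounding
    if normalized:
        h /= log(math.factorial(dist.m))
    return h


def permutation_time_irreversibility(dist: PatternDistribution) -> float:
    """PTIRR: probability-weighted normalized forward/backward divergence.

    Sums ``p_f * |p_f - p_b| / (p_f + p_b)`` over the ``V`` patterns that
    occur forward or as backward images of forward patterns (a pattern in
    that set always has ``p_f + p_b > 0``).  Equals the sum over unordered
    ``{pi, ~pi}`` pairs of ``|p(pi) - p(~pi)|``; lies in [0, 1].
    """
    total = 0.0
    for pattern in dist.pattern_set:
        pf = dist.probability(pattern)
        pb = dist.probability(pattern[::-1])
        if pf > 0:
            total += pf * abs(pf - pb) / (pf + pb)
    return total
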