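"""Embedding-parameter selection: false nearest neighbors (dimension) and
the C-C correlation-integral method (delay), with mode aggregation across
channels.

These selectors are advisory.  The analysis pipeline defaults to m=3, tau=2
without running them; they exist so the choice can be re-derived from data.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from ._exceptions import InsufficientDataError, InvalidInputError, ParameterError

__all__ = ["fnn_dimension", "cc_delay", "aggregate_by_mode", "FNNResult", "CCResult"]


@dataclass(frozen=True)
class FNNResult:
    """False-nearest-neighbor fractions per trial dimension and the choice."""

    fractions: dict[int, float]
    chosen_m: int
    threshold: float
    converged: bool  # False if no dimension fell below the threshold


@dataclass(frozen=True)
class CCResult:
    """C-C statistics per candidate delay and the first-local-minimum choice."""

    taus: tuple[int, ...]
    delta_s: tuple[float, ...]  # mean ΔS(t) over embedding dimensions
    s_mean: tuple[float, ...]   # mean S(t) over dimensions and radii
    chosen_tau: int
    found_minimum: bool  # False -> flat curve, chosen_tau = max_tau fallback


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n_vec = x.size - (m - 1) * tau
    if n_vec < 1:
        raise InsufficientDataError(
            f"series of length {x.size} too short for (m={m}, tau={tau}) embedding"
        )
    idx = np.arange(n_vec)[:, None] + np.arange(m)[None, :] * tau
    return x[idx]


def fnn_dimension(
    series: Iterable[float],
    tau: int = 1,
    max_m: int = 10,
    r_tol: float = 10.0,
    a_tol: float = 2.0,
    threshold: float = 0.01,
) -> FNNResult:
    """Kennel false-nearest-neighbors estimate of the embedding dimension.

    For each trial dimension ``m`` the nearest neighbor of every delay
    vector is found; the pair is a *false* neighbor if adding the (m+1)-th
    coordinate separates it by more than ``r_tol`` times its m-dimensional
    distance, or moves the pair further apart than ``a_tol`` times the
    series standard deviation.  The chosen dimension is the smallest ``m``
    whose false fraction drops below `threshold`.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise InvalidInputError("series must be 1-D")
    if tau < 1 or max_m < 2:
        raise ParameterError("require tau >= 1 and max_m >= 2")
    sd = x.std()
    if sd == 0:
        raise InvalidInputError("constant series: nearest neighbors are undefined")
    if x.size < max_m * tau + 1:
        raise InsufficientDataError(
            f"series of length {x.size} too short for max_m={max_m}, tau={tau}; "
            f"need at least {max_m * tau + 1} samples"
        )

    fractions: dict[int, float] = {}
    chosen = None
    for m in range(1, max_m + 1):
        # restrict to points whose (m+1)-th coordinate x[t + m*tau] exists
        n_pts = x.size - m * tau
        vecs = _embed(x, m, tau)[:n_pts]
        nxt = x[m * tau : m * tau + n_pts]
        tree = cKDTree(vecs)
        dist, nbr = tree.query(vecs, k=2)
        d = dist[:, 1]
        j = nbr[:, 1]
        delta = np.abs(nxt - nxt[j])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, delta / d, np.where(delta > 0, np.inf, 0.0))
        expanded = np.sqrt(d**2 + delta**2) / sd
        false = (ratio > r_tol) | (expanded > a_tol)
        # pairs coincident to machine precision are true neighbors: the ratio
        # test is meaningless when both distances sit at roundoff level
        false &= expanded > 1e-8
        frac = float(false.mean())
        fractions[m] = frac
        if chosen is None and frac < threshold:
            chosen = m
    converged = chosen is not None
    return FNNResult(
        fractions=fractions,
        chosen_m=chosen if converged else max_m,
        threshold=threshold,
        converged=converged,
    )


def _corr_sum(pairdists: np.ndarray, radii: np.ndarray) -> np.ndarray:
    if pairdists.size == 0:
        return np.zeros_like(radii)
    return np.array([(pairdists <= r).mean() for r in radii])


def cc_delay(
    series: Iterable[float],
    max_tau: int = 20,
    dims: Sequence[int] = (2, 3, 4, 5),
    radius_factors: Sequence[float] = (0.5, 1.0, 1.5, 2.0),
    min_range: float = 0.02,
) -> CCResult:
    """C-C estimate of the embedding delay (first local minimum of mean ΔS).

    For every candidate delay ``t`` the series is split into ``t`` disjoint
    sub-series; on each, ``S(m, r, t) = C_m(r) - C_1(r)^m`` is computed from
    correlation sums with the sup-norm, averaged over sub-series.
    ``ΔS(m, t)`` is the spread of S over the radius set (standard radii
    0.5/1/1.5/2 times the series SD), and the chosen delay is the first
    local minimum of ``ΔS(t)`` averaged over dimensions.

    For a dependence-free series (i.i.d. noise) the ΔS curve is flat at
    the sampling-noise level and any numerical "minimum" is meaningless,
    so a local minimum is only accepted when the curve's overall range
    exceeds `min_range`; otherwise ``chosen_tau = max_tau`` is returned
    with ``found_minimum=False``.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise InvalidInputError("series must be 1-D")
    if max_tau < 2:
        raise ParameterError("max_tau must be >= 2")
    if x.size < max(200, max_tau * (max(dims) + 1)):
        raise InsufficientDataError(
            f"series of length {x.size} is too short for a stable C-C estimate"
        )
    sd = x.std()
    if sd == 0:
        raise InvalidInputError("constant series: correlation sums are degenerate")
    radii = np.asarray(radius_factors, dtype=float) * sd

    taus = tuple(range(1, max_tau + 1))
    delta_s: list[float] = []
    s_mean: list[float] = []
    for t in taus:
        subs = [x[j::t] for j in range(t)]
        per_dim_spread = []
        all_s = []
        for m in dims:
            s_vals = np.zeros(len(radii))
            n_used = 0
            for sub in subs:
                if sub.size < (m - 1) + 2:
                    continue
                vecs = _embed(sub, m, 1)
                if vecs.shape[0] < 2:
                    continue
                c_m = _corr_sum(pdist(vecs, metric="chebyshev"), radii)
                c_1 = _corr_sum(pdist(sub[:, None], metric="chebyshev"), radii)
                s_vals += c_m - c_1**m
                n_used += 1
            if n_used == 0:
                continue
            s_vals /= n_used
            per_dim_spread.append(s_vals.max() - s_vals.min())
            all_s.extend(s_vals.tolist())
        delta_s.append(float(np.mean(per_dim_spread)) if per_dim_spread else np.nan)
        s_mean.append(float(np.mean(all_s)) if all_s else np.nan)

    ds = np.asarray(delta_s)
    chosen = None
    finite = ds[np.isfinite(ds)]
    flat = finite.size == 0 or (finite.max() - finite.min()) < min_range
    if not flat:
        for i in range(1, len(ds) - 1):
            if np.isfinite(ds[i - 1 : i + 2]).all() and ds[i] < ds[i - 1] and ds[i] <= ds[i + 1]:
                chosen = taus[i]
                break
    found = chosen is not None
    return CCResult(
        taus=taus,
        delta_s=tuple(delta_s),
        s_mean=tuple(s_mean),
        chosen_tau=chosen if found else max_tau,
        found_minimum=found,
    )


def aggregate_by_mode(per_channel_choices: Sequence[int]) -> int:
    """Most frequent value; ties broken toward the smaller (more conservative)
    embedding parameter."""
    if not per_channel_choices:
        raise ParameterError("cannot aggregate an empty list of choices")
    counts = Counter(int(c) for c in per_channel_choices)
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]
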