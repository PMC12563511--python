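"""Coarse-graining and multiscale profiles (MsPE / MsPTIRR curves).

The multiscale step replaces the series by non-overlapping window means:

    y_s[N] = mean(x[s*(N-1) .. s*N - 1]),   N = 1 .. floor(l / s)

and recomputes the single-scale index (permutation entropy or PTIRR) on the
coarse series at every scale factor ``s``.  Trailing samples beyond
``s * floor(l/s)`` are discarded.  The embedding delay is applied on the
coarse-grained series itself, with no additional scale-dependent stride.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import InsufficientDataError, InvalidInputError, ParameterError
from .ordinal import (
    pattern_distribution,
    permutation_entropy,
    permutation_time_irreversibility,
)

__all__ = [
    "coarse_grain",
    "index_at_scale",
    "profile",
    "subject_profile",
    "ScaleProfile",
    "SubjectProfile",
    "DEFAULT_SCALES",
]

#: Scale factors used throughout: 1..100 in steps of 1.
DEFAULT_SCALES: tuple[int, ...] = tuple(range(1, 101))

_KINDS = ("pe", "ptirr")


def _check_kind(kind: str) -> str:
    k = kind.lower()
    if k not in _KINDS:
        raise ParameterError(f"kind must be one of {_KINDS}, got {kind!r}")
    return k


def coarse_grain(series: Iterable[float], scale: int) -> np.ndarray:
    """Non-overlapping window means of `series` at the given scale factor.

    ``scale=1`` returns the series unchanged; the mean of the retained
    samples is conserved exactly (up to rounding).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise InvalidInputError(f"series must be 1-D, got shape {x.shape}")
    if scale < 1 or int(scale) != scale:
        raise ParameterError(f"scale must be a positive integer, got {scale!r}")
    scale = int(scale)
    n_win = x.size // scale
    if n_win < 1:
        raise InsufficientDataError(
            f"scale {scale} exceeds series length {x.size}: no window fits"
        )
    if scale == 1:
        return x.copy()
    return x[: n_win * scale].reshape(n_win, scale).mean(axis=1)


def index_at_scale(
    series: Iterable[float],
    scale: int,
    m: int = 3,
    tau: int = 2,
    kind: str = "ptirr",
    tie_tol: float = 0.0,
) -> float:
    """Coarse-grain, embed and compute one index value at one scale."""
    kind = _check_kind(kind)
    coarse = coarse_grain(series, scale)
    min_len = (m - 1) * tau + 1
    if coarse.size < min_len:
        raise InsufficientDataError(
            f"coarse series at scale {scale} has {coarse.size} samples; "
            f"at least {min_len} are needed for (m={m}, tau={tau})"
        )
    dist = pattern_distribution(coarse, m=m, tau=tau, tie_tol=tie_tol)
    if kind == "pe":
        return permutation_entropy(dist)
    return permutation_time_irreversibility(dist)


@dataclass(frozen=True)
class ScaleProfile:
    """An MsPE or MsPTIRR curve: one index value per scale factor."""

    scales: tuple[int, ...]
    values: tuple[float, ...]
    kind: str

    def __post_init__(self):
        if len(self.scales) != len(self.values):
            raise InvalidInputError("scales and values must have equal length")
        if any(b <= a for a, b in zip(self.scales, self.scales[1:])):
            raise InvalidInputError("scales must be strictly increasing")
        object.__setattr__(self, "kind", _check_kind(self.kind))

    def __len__(self) -> int:
        return len(self.scales)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def to_frame(self, **labels: str) -> pd.DataFrame:
        """Tidy table with columns scale, index_kind, value (+ any labels)."""
        df = pd.DataFrame(
            {"scale": self.scales, "index_kind": self.kind, "value": self.values}
        )
        for key, val in labels.items():
            df.insert(0, key, val)
        return df


def max_feasible_scale(n_samples: int, m: int = 3, tau: int = 2) -> int:
    """Largest scale whose coarse series still admits one embedding window."""
    return n_samples // ((m - 1) * tau + 1)


def profile(
    series: Iterable[float],
    scales: Sequence[int] = DEFAULT_SCALES,
    m: int = 3,
    tau: int = 2,
    kind: str = "ptirr",
    tie_tol: float = 0.0,
) -> ScaleProfile:
    """Multiscale profile: the requested index at every scale factor.

    All scales are validated up front; an infeasible scale aborts with the
    largest feasible scale for this series length in the message.
    """
    kind = _check_kind(kind)
    x = np.asarray(series, dtype=float)
    scales = tuple(int(s) for s in scales)
    if not scales:
        raise ParameterError("scales must be non-empty")
    feasible = max_feasible_scale(x.size, m=m, tau=tau)
    bad = [s for s in scales if s < 1 or s > feasible]
    if bad:
        raise InsufficientDataError(
            f"scales {bad} are infeasible for a series of length {x.size} "
            f"(m={m}, tau={tau}); the largest feasible scale is {feasible}"
        )
    values = tuple(
        index_at_scale(x, s, m=m, tau=tau, kind=kind, tie_tol=tie_tol) for s in scales
    )
    return ScaleProfile(scales=scales, values=values, kind=kind)


@dataclass(frozen=True)
class SubjectProfile:
    """Per-channel profiles of one recording plus their cross-channel mean."""

    subject_id: str
    group: str
    per_channel: Mapping[str, ScaleProfile]
    mean_profile: ScaleProfile

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: subject_id, group, channel|MEAN, scale, index_kind, value."""
        frames = [
            prof.to_frame(channel=ch, group=self.group, subject_id=self.subject_id)
            for ch, prof in self.per_channel.items()
        ]
        frames.append(
            self.mean_profile.to_frame(
                channel="MEAN", group=self.group, subject_id=self.subject_id
            )
        )
        return pd.concat(frames, ignore_index=True)


def subject_profile(
    recording: np.ndarray,
    scales: Sequence[int] = DEFAULT_SCALES,
    m: int = 3,
    tau: int = 2,
    kind: str = "ptirr",
    channel_labels: Sequence[str] | None = None,
    channels: Sequence[str] | None = None,
    subject_id: str = "",
    group: str = "",
    tie_tol: float = 0.0,
) -> SubjectProfile:
    """Per-channel multiscale profiles and their unweighted channel mean.

    Parameters
    ----------
    recording
        2-D array, channels x samples; all channels the same length.
    channels
        Optional subset of channel labels to analyse (e.g. one brain
        region); defaults to all channels.
    """
    try:
        data = np.asarray(recording, dtype=float)
    except (ValueError, TypeError) as exc:
        raise InvalidInputError(
            "recording must be a rectangular channels x samples matrix "
            "(channel-length mismatch?)"
        ) from exc
    if data.ndim != 2:
        raise InvalidInputError(
            "recording must be a rectangular channels x samples matrix "
            "(channel-length mismatch?)"
        )
    n_ch = data.shape[0]
    if channel_labels is None:
        channel_labels = [f"ch{i:03d}" for i in range(n_ch)]
    if len(channel_labels) != n_ch:
        raise InvalidInputError(
            f"{len(channel_labels)} labels for {n_ch} channels"
        )
    if channels is not None:
        missing = [c for c in channels if c not in set(channel_labels)]
        if missing:
            raise InvalidInputError(f"unknown channel labels: {missing}")
        keep = [i for i, lab in enumerate(channel_labels) if lab in set(channels)]
    else:
        keep = list(range(n_ch))
    if not keep:
        raise InvalidInputError("no channels selected")

    per_channel = {
        channel_labels[i]: profile(
            data[i], scales=scales, m=m, tau=tau, kind=kind, tie_tol=tie_tol
        )
        for i in keep
    }
    stacked = np.vstack([p.as_array() for p in per_channel.values()])
    mean_prof = ScaleProfile(
        scales=tuple(int(s) for s in scales),
        values=tuple(stacked.mean(axis=0).tolist()),
        kind=_check_kind(kind),
    )
    return SubjectProfile(
        subject_id=subject_id,
        group=group,
        per_channel=per_channel,
        mean_profile=mean_prof,
    )
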