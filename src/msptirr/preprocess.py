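"""Filtering and sensor-region grouping for whole-head MEG-style recordings.

All filters are 4th-order Butterworth applied forward-backward
(zero phase).  Zero-phase filtering matters here: a causal filter would
impose its own temporal asymmetry on the signal and contaminate any
time-irreversibility statistic computed downstream.

Sensor grouping follows the CTF naming convention (``MLC11``, ``MRF25``,
``MZO01``, ...): the second character gives the hemisphere (L/R, Z for
midline) and the third the region — Central, Frontal, Occipital, Parietal
or Temporal.  Midline channels take part in whole-head analyses but are
excluded from left/right hemispheric contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal

from ._exceptions import InvalidInputError, ParameterError

__all__ = [
    "BandSpec",
    "DEFAULT_BANDS",
    "RegionMap",
    "lowpass",
    "notch",
    "band_decompose",
    "map_regions",
    "REGIONS",
    "HEMISPHERES",
]

REGIONS = ("C", "F", "O", "P", "T")
HEMISPHERES = ("L", "R")
_REGION_NAMES = {
    "C": "central",
    "F": "frontal",
    "O": "occipital",
    "P": "parietal",
    "T": "temporal",
}


@dataclass(frozen=True)
class BandSpec:
    """One frequency band: name and passband edges in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self):
        if not (0 < self.low_hz < self.high_hz):
            raise ParameterError(
                f"band {self.name!r}: need 0 < low < high, got "
                f"({self.low_hz}, {self.high_hz})"
            )


#: The five canonical bands: delta 1-4, theta 5-8, alpha 9-12, beta 13-29,
#: gamma 30-65 Hz.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 1.0, 4.0),
    BandSpec("theta", 5.0, 8.0),
    BandSpec("alpha", 9.0, 12.0),
    BandSpec("beta", 13.0, 29.0),
    BandSpec("gamma", 30.0, 65.0),
)


def _as_2d(recording) -> np.ndarray:
    data = np.atleast_2d(np.asarray(recording, dtype=float))
    if data.ndim != 2:
        raise InvalidInputError(f"recording must be 1-D or 2-D, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise InvalidInputError("recording contains non-finite values")
    return data


def lowpass(
    recording,
    sample_rate_hz: float,
    cutoff_hz: float = 65.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass, applied channel-wise."""
    data = _as_2d(recording)
    nyq = sample_rate_hz / 2.0
    if not (0 < cutoff_hz < nyq):
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyq}) Hz"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=sample_rate_hz, output="sos")
    out = signal.sosfiltfilt(sos, data, axis=-1)
    return out if np.asarray(recording).ndim == 2 else out[0]


def notch(
    recording,
    sample_rate_hz: float,
    line_hz: float = 50.0,
    width_hz: float = 2.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-stop around the power-line frequency."""
    data = _as_2d(recording)
    nyq = sample_rate_hz / 2.0
    lo, hi = line_hz - width_hz / 2.0, line_hz + width_hz / 2.0
    if not (0 < lo < hi < nyq):
        raise ParameterError(
            f"stop band ({lo}, {hi}) Hz must lie inside (0, Nyquist={nyq}) Hz"
        )
    sos = signal.butter(order, (lo, hi), btype="bandstop", fs=sample_rate_hz, output="sos")
    out = signal.sosfiltfilt(sos, data, axis=-1)
    return out if np.asarray(recording).ndim == 2 else out[0]


def bandpass(
    recording,
    sample_rate_hz: float,
    low_hz: float,
    high_hz: float,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass, applied channel-wise."""
    data = _as_2d(recording)
    nyq = sample_rate_hz / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ParameterError(
            f"pass band ({low_hz}, {high_hz}) Hz must lie inside (0, Nyquist={nyq}) Hz"
        )
    sos = signal.butter(order, (low_hz, high_hz), btype="bandpass", fs=sample_rate_hz, output="sos")
    out = signal.sosfiltfilt(sos, data, axis=-1)
    return out if np.asarray(recording).ndim == 2 else out[0]


def band_decompose(
    recording,
    sample_rate_hz: float,
    bands: Sequence[BandSpec] = DEFAULT_BANDS,
    order: int = 4,
) -> dict[str, np.ndarray]:
    """One zero-phase band-passed copy of the recording per band.

    Bands must be valid (edges inside the Nyquist range) and mutually
    non-overlapping.
    """
    if not bands:
        raise ParameterError("at least one band is required")
    names = [b.name for b in bands]
    if len(set(names)) != len(names):
        raise ParameterError(f"duplicate band names in {names}")
    by_low = sorted(bands, key=lambda b: b.low_hz)
    for a, b in zip(by_low, by_low[1:]):
        if b.low_hz < a.high_hz:
            raise ParameterError(
                f"bands {a.name!r} and {b.name!r} overlap "
                f"({a.low_hz}-{a.high_hz} vs {b.low_hz}-{b.high_hz} Hz)"
            )
    return {
        band.name: bandpass(
            recording, sample_rate_hz, band.low_hz, band.high_hz, order=order
        )
        for band in bands
    }


@dataclass(frozen=True)
class RegionMap:
    """Assignment of channel labels to (hemisphere, region) cells.

    ``hemisphere`` is "L", "R" or "midline"; ``region`` one of C/F/O/P/T.
    Unparsable labels are kept in :attr:`unassigned`, never dropped
    silently.
    """

    assignment: Mapping[str, tuple[str, str]]
    unassigned: tuple[str, ...] = ()

    def channels_in(self, hemisphere: str, region: str) -> list[str]:
        """Labels in one (hemisphere, region) cell, in input order."""
        return [
            ch
            for ch, (h, r) in self.assignment.items()
            if h == hemisphere and r == region
        ]

    def hemispheric_cells(self) -> dict[tuple[str, str], list[str]]:
        """All non-empty L/R x region cells (midline excluded)."""
        cells: dict[tuple[str, str], list[str]] = {}
        for ch, (h, r) in self.assignment.items():
            if h in HEMISPHERES:
                cells.setdefault((h, r), []).append(ch)
        return cells


def map_regions(channel_labels: Iterable[str]) -> RegionMap:
    """Parse CTF-style labels into hemisphere x region cells.

    A label is parsable when it starts with ``M``, its second character is
    L, R or Z (midline) and its third is one of C/F/O/P/T.  Anything else
    lands in the ``unassigned`` bucket.
    """
    assignment: dict[str, tuple[str, str]] = {}
    unassigned: list[str] = []
    for label in channel_labels:
        lab = str(label).strip()
        if (
            len(lab) >= 3
            and lab[0].upper() == "M"
            and lab[1].upper() in ("L", "R", "Z")
            and lab[2].upper() in REGIONS
        ):
            hemi = lab[1].upper()
            assignment[lab] = ("midline" if hemi == "Z" else hemi, lab[2].upper())
        else:
            unassigned.append(lab)
    return RegionMap(assignment=assignment, unassigned=tuple(unassigned))
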