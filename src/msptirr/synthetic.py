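"""Synthetic signals with known time-reversal properties, and two-group
MEG-like cohorts for end-to-end pipeline testing.

Reversible references
    Stationary linear Gaussian processes (i.i.d. noise, Gaussian AR) are
    statistically time-symmetric, so their PTIRR converges to 0; phase-
    randomized surrogates impose the same property on any series while
    preserving its amplitude spectrum.

Irreversible references
    The fully chaotic logistic map (r=4) is the canonical strongly
    time-asymmetric series and serves as the positive control.

Cohorts
    Each synthetic subject is a channels x samples recording: a weighted
    sum of band-limited oscillations (Butterworth-filtered noise per
    frequency band), 1/f background noise, and an additive logistic-map-
    driven irreversible component whose weight (``irreversibility_mix``)
    is the only difference between the two groups.  Channel labels follow
    the CTF convention so region mapping works unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _signal

from ._exceptions import InsufficientDataError, InvalidInputError, ParameterError
from .preprocess import DEFAULT_BANDS, REGIONS, BandSpec, bandpass
from .io import Recording

__all__ = [
    "gen_gaussian_ar",
    "gen_logistic_map",
    "phase_randomized_surrogate",
    "one_over_f_noise",
    "irreversible_component",
    "CohortSpec",
    "Subject",
    "Cohort",
    "gen_cohort",
    "ctf_like_labels",
]


def gen_gaussian_ar(
    n: int,
    coeffs: Sequence[float] = (),
    seed: int | np.random.Generator | None = None,
    scale: float = 1.0,
    burn_in: int = 1000,
) -> np.ndarray:
    """Stationary Gaussian AR(p) realization (time-reversible null).

    ``x[t] = sum_i coeffs[i] * x[t-1-i] + scale * e[t]`` with standard
    normal innovations.  Empty `coeffs` gives i.i.d. Gaussian noise.

    Raises
    ------
    ParameterError
        If the AR polynomial is non-stationary (a characteristic root on
        or outside the unit circle).
    """
    if n < 1:
        raise ParameterError("n must be positive")
    a = np.asarray(coeffs, dtype=float)
    if a.size:
        roots = np.roots(np.concatenate(([1.0], -a)))
        if np.any(np.abs(roots) >= 1.0 - 1e-12):
            raise ParameterError(
                f"AR coefficients {list(a)} are non-stationary "
                f"(characteristic root magnitude {np.abs(roots).max():.4f} >= 1)"
            )
    rng = np.random.default_rng(seed)
    e = scale * rng.standard_normal(n + burn_in)
    if not a.size:
        return e[burn_in:]
    x = _signal.lfilter([1.0], np.concatenate(([1.0], -a)), e)
    return x[burn_in:]


def gen_logistic_map(
    n: int,
    r: float = 4.0,
    x0: float = 0.2,
    transient: int = 1000,
) -> np.ndarray:
    """Logistic-map orbit ``x[t+1] = r x[t] (1 - x[t])`` (irreversible
    positive control); a 1000-step transient is discarded before recording."""
    if not (0.0 < x0 < 1.0):
        raise ParameterError(f"x0 must lie strictly inside (0, 1), got {x0}")
    if not (0.0 < r <= 4.0):
        raise ParameterError(f"r must lie in (0, 4], got {r}")
    if n < 1:
        raise ParameterError("n must be positive")
    x = x0
    for _ in range(transient):
        x = r * x * (1.0 - x)
    out = np.empty(n)
    for t in range(n):
        out[t] = x
        x = r * x * (1.0 - x)
    return out


def phase_randomized_surrogate(
    series, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Phase-randomized surrogate: same amplitude spectrum, random phases.

    Phases of the positive-frequency bins are drawn uniformly with
    Hermitian symmetry enforced (DC, and Nyquist for even length, stay
    real), so the output is a real series with the linear (spectral)
    properties of the input but none of its nonlinear temporal asymmetry.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise InvalidInputError("series must be 1-D")
    if x.size < 64:
        raise InsufficientDataError(
            f"surrogate needs at least 64 samples, got {x.size}"
        )
    rng = np.random.default_rng(seed)
    spec = np.fft.rfft(x)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.size)
    phases[0] = 0.0
    if x.size % 2 == 0:
        phases[-1] = 0.0
    return np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=x.size)


def one_over_f_noise(
    n: int,
    exponent: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Gaussian noise spectrally shaped to ``S(f) ~ 1/f**exponent``,
    standardized to zero mean and unit variance."""
    if n < 2:
        raise ParameterError("n must be >= 2")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=n)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def irreversible_component(
    n: int,
    seed: int | np.random.Generator | None = None,
    upsample: int = 32,
) -> np.ndarray:
    """Standardized logistic-map-driven series: a fully chaotic orbit
    linearly interpolated by `upsample` in time.

    The interpolation stretches the map's temporal asymmetry over
    `upsample` samples, so coarse-graining at moderate scale factors still
    sees a strongly irreversible signal.
    """
    if upsample < 1:
        raise ParameterError("upsample must be >= 1")
    rng = np.random.default_rng(seed)
    n_steps = n // upsample + 2
    orbit = gen_logistic_map(n_steps, r=4.0, x0=float(rng.uniform(0.05, 0.95)))
    coarse_t = np.arange(n_steps) * upsample
    y = np.interp(np.arange(n), coarse_t, orbit)
    y -= y.mean()
    sd = y.std()
    return y / sd if sd > 0 else y


#: SD of the irreversible component relative to the unit-SD oscillatory
#: background at full mix.  Ordinal-pattern asymmetry of an additive mixture
#: is strongly (roughly cubically) diluted by a reversible background, so the
#: component needs headroom above the background for the mix weight to span
#: fully reversible (0) to clearly irreversible (1) channels.
IRREVERSIBLE_GAIN: float = 3.0

#: Relative band powers of a plausible eyes-open resting recording
#: (alpha-dominant, weak gamma).
DEFAULT_BAND_POWERS: dict[str, float] = {
    "delta": 1.0,
    "theta": 0.7,
    "alpha": 1.5,
    "beta": 0.6,
    "gamma": 0.3,
}


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a two-group synthetic cohort.

    Defaults mirror the study geometry: 19 + 15 subjects, 275 channels,
    two minutes at 1200 Hz.  The groups differ only through
    ``irreversibility_mix`` — the weight of the additive irreversible
    component, lower in the patient-like group.
    """

    n_per_group: tuple[int, int] = (19, 15)
    group_labels: tuple[str, str] = ("SZ", "HC")
    irreversibility_mix: tuple[float, float] = (0.1, 0.3)
    n_channels: int = 275
    n_samples: int = 144_000
    sample_rate_hz: float = 1200.0
    band_powers: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_POWERS)
    )
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if any(c < 1 for c in self.n_per_group):
            raise ParameterError("n_per_group entries must be positive")
        if self.n_channels < 1 or self.n_samples < 2:
            raise ParameterError("n_channels and n_samples must be positive")
        if any(not (0.0 <= mx <= 1.0) for mx in self.irreversibility_mix):
            raise ParameterError("irreversibility_mix values must lie in [0, 1]")
        if any(p < 0 for p in self.band_powers.values()):
            raise ParameterError("band powers must be nonnegative")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")
        known = {b.name for b in DEFAULT_BANDS}
        unknown = set(self.band_powers) - known
        if unknown:
            raise ParameterError(f"unknown band names: {sorted(unknown)}")
        nyq = self.sample_rate_hz / 2.0
        for b in DEFAULT_BANDS:
            if self.band_powers.get(b.name, 0.0) > 0 and b.high_hz >= nyq:
                raise ParameterError(
                    f"band {b.name!r} ({b.low_hz}-{b.high_hz} Hz) exceeds the "
                    f"Nyquist frequency {nyq} Hz; lower its power to 0 or raise "
                    "sample_rate_hz"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band_powers"] = dict(self.band_powers)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        d = dict(d)
        for key in ("n_per_group", "group_labels", "irreversibility_mix"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class Subject:
    subject_id: str
    group: str
    recording: Recording


@dataclass(frozen=True)
class Cohort:
    spec: CohortSpec
    subjects: tuple[Subject, ...]

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self):
        return len(self.subjects)


def ctf_like_labels(n_channels: int) -> list[str]:
    """CTF-style labels cycling hemispheres (L, R) and regions (C, F, O,
    P, T) so every region is populated and :func:`map_regions` parses."""
    labels = []
    for i in range(n_channels):
        hemi = "LR"[i % 2]
        region = REGIONS[(i // 2) % len(REGIONS)]
        labels.append(f"M{hemi}{region}{i // (2 * len(REGIONS)) + 1:02d}")
    return labels


def _synth_channel(
    spec: CohortSpec, mix: float, rng: np.random.Generator
) -> np.ndarray:
    n, fs = spec.n_samples, spec.sample_rate_hz
    osc = np.zeros(n)
    for band in DEFAULT_BANDS:
        power = spec.band_powers.get(band.name, 0.0)
        if power <= 0:
            continue
        comp = bandpass(rng.standard_normal(n), fs, band.low_hz, band.high_hz)
        sd = comp.std()
        if sd > 0:
            osc += np.sqrt(power) * comp / sd
    sd = osc.std()
    if sd > 0:
        osc /= sd
    background = spec.noise_sd * one_over_f_noise(n, exponent=1.0, seed=rng)
    irr = IRREVERSIBLE_GAIN * mix * irreversible_component(n, seed=rng)
    return osc + background + irr


def gen_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full two-group cohort described by `spec`.

    Bit-reproducible for a fixed ``spec.seed``: every subject and channel
    draws from its own child of one seed sequence.
    """
    root = np.random.SeedSequence(spec.seed)
    labels = ctf_like_labels(spec.n_channels)
    subjects: list[Subject] = []
    group_iter = [
        (label, count, mix)
        for label, count, mix in zip(
            spec.group_labels, spec.n_per_group, spec.irreversibility_mix
        )
    ]
    subject_seeds = root.spawn(sum(spec.n_per_group))
    k = 0
    for label, count, mix in group_iter:
        for i in range(count):
            rng = np.random.default_rng(subject_seeds[k])
            k += 1
            data = np.vstack(
                [_synth_channel(spec, mix, rng) for _ in range(spec.n_channels)]
            )
            rec = Recording(
                data=data,
                channel_labels=tuple(labels),
                sample_rate_hz=spec.sample_rate_hz,
            )
            subjects.append(
                Subject(subject_id=f"{label}{i + 1:02d}", group=label, recording=rec)
            )
    return Cohort(spec=spec, subjects=tuple(subjects))
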