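"""Recording and result-table input/output.

Recordings travel as delimited text (one column per channel, a header row
of channel labels, and a ``# sample_rate_hz: ...`` comment line) or as an
HDF5 container (dataset ``data`` channels x samples, dataset ``channels``,
attribute ``sample_rate_hz``).  Result tables are tidy long-format TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import InvalidInputError

__all__ = [
    "Recording",
    "read_recording",
    "write_recording",
    "read_manifest",
    "write_manifest",
    "write_table",
    "read_table",
    "write_run_metadata",
]

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class Recording:
    """A multichannel recording: channels x samples with a sampling rate."""

    data: np.ndarray
    channel_labels: tuple[str, ...]
    sample_rate_hz: float | None = None

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise InvalidInputError(
                f"recording data must be 2-D channels x samples, got shape {data.shape}"
            )
        if len(self.channel_labels) != data.shape[0]:
            raise InvalidInputError(
                f"{len(self.channel_labels)} labels for {data.shape[0]} channels"
            )
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_labels", tuple(str(c) for c in self.channel_labels))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def write_recording(path, recording: Recording) -> None:
    """Write a recording as TSV (``.h5``/``.hdf5`` suffix -> HDF5)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        _write_h5(path, recording)
        return
    with open(path, "w") as fh:
        if recording.sample_rate_hz is not None:
            fh.write(f"# sample_rate_hz: {recording.sample_rate_hz:.10g}\n")
        fh.write("\t".join(recording.channel_labels) + "\n")
        np.savetxt(fh, recording.data.T, fmt=_FLOAT_FMT, delimiter="\t")


def read_recording(path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _read_h5(path)
    sample_rate = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "sample_rate_hz" in first:
                sample_rate = float(first.split(":", 1)[1])
            header = fh.readline()
        else:
            header = first
        labels = header.rstrip("\n").split("\t")
        if not labels or labels == [""]:
            raise InvalidInputError(f"{path}: malformed header row (no channel labels)")
        try:
            body = np.loadtxt(fh, delimiter="\t", ndmin=2)
        except ValueError as exc:
            raise InvalidInputError(f"{path}: malformed data rows ({exc})") from exc
    if body.shape[1] != len(labels):
        raise InvalidInputError(
            f"{path}: {len(labels)} channel labels but {body.shape[1]} data columns"
        )
    return Recording(data=body.T, channel_labels=tuple(labels), sample_rate_hz=sample_rate)


def _write_h5(path: Path, recording: Recording) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        dset = h5.create_dataset("data", data=recording.data)
        h5.create_dataset(
            "channels", data=np.array(recording.channel_labels, dtype="S")
        )
        if recording.sample_rate_hz is not None:
            dset.attrs["sample_rate_hz"] = recording.sample_rate_hz


def _read_h5(path: Path) -> Recording:
    import h5py

    with h5py.File(path, "r") as h5:
        data = np.asarray(h5["data"])
        labels = tuple(c.decode() for c in h5["channels"][()])
        rate = h5["data"].attrs.get("sample_rate_hz")
    return Recording(
        data=data,
        channel_labels=labels,
        sample_rate_hz=float(rate) if rate is not None else None,
    )


def write_manifest(path, rows: Sequence[Mapping]) -> None:
    """Write a cohort manifest (subject_id, group, file, seed) as CSV."""
    pd.DataFrame(rows, columns=["subject_id", "group", "file", "seed"]).to_csv(
        path, index=False
    )


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str, "file": str})
    required = {"subject_id", "group", "file"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: manifest lacks columns {sorted(missing)}")
    return df


def write_table(path, frame: pd.DataFrame) -> None:
    """Tidy result table as TSV with a stable float format."""
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_run_metadata(path, config: Mapping) -> None:
    """Sidecar JSON recording the configuration of a run (provenance)."""
    from . import __version__

    payload = {"msptirr_version": __version__, **config}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
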