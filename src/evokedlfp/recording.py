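"""Continuous LFP recording container and its on-disk form.

A recording is stored as two files sharing a stem: ``<name>.csv`` holding a
single column of voltage samples (header ``uV``, full-precision decimal) and a
``<name>.json`` sidecar with the sampling rate, stimulus times and metadata.
The pairing is lossless: ``write_recording`` followed by ``read_recording``
returns an identical object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["Recording", "RecordingSchemaError", "read_recording", "write_recording"]

_SIDECAR_REQUIRED = ("sampling_rate_hz", "stim_times_s")


class RecordingSchemaError(ValueError):
    """Raised when a recording sidecar is missing required fields."""


@dataclass
class Recording:
    """A continuous single-channel voltage trace with stimulus event times.

    Parameters
    ----------
    samples : array of float
        Voltage samples in microvolts.
    sampling_rate : float
        Samples per second (Hz).
    stim_times : sequence of float
        Stimulus onset times in seconds, strictly increasing, inside the
        recording extent.
    subject_id, age_group, condition : str
        Metadata carried through the analysis into tidy output tables.
    """

    samples: np.ndarray
    sampling_rate: float
    stim_times: tuple = ()
    subject_id: str = "rec"
    age_group: str = "NA"
    condition: str = "NA"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D array")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples contain non-finite values")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        self.stim_times = tuple(float(t) for t in self.stim_times)
        if any(b <= a for a, b in zip(self.stim_times, self.stim_times[1:])):
            raise ValueError("stim_times must be strictly increasing")
        dur = self.duration
        if any(t < 0 or t >= dur for t in self.stim_times):
            raise ValueError("stim_times must lie within the recording extent")

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return len(self.samples) / self.sampling_rate

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def _paths(path) -> tuple[Path, Path]:
    p = Path(path)
    if p.suffix in (".csv", ".json"):
        p = p.with_suffix("")
    return p.with_suffix(".csv"), p.with_suffix(".json")


def write_recording(rec: Recording, path) -> tuple[Path, Path]:
    """Write ``rec`` to ``<path>.csv`` + ``<path>.json``; returns both paths.

    Samples are written with 17 significant digits so float64 values
    round-trip exactly.
    """
    csv_path, json_path = _paths(path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(csv_path, rec.samples, fmt="%.17g", header="uV", comments="")
    sidecar = {
        "sampling_rate_hz": rec.sampling_rate,
        "stim_times_s": list(rec.stim_times),
        "subject_id": rec.subject_id,
        "age_group": rec.age_group,
        "condition": rec.condition,
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return csv_path, json_path


def read_recording(path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    ``path`` may point at the CSV, the JSON sidecar, or the common stem.
    """
    csv_path, json_path = _paths(path)
    if not json_path.exists():
        raise RecordingSchemaError(f"missing sidecar {json_path}")
    meta = json.loads(json_path.read_text())
    missing = [k for k in _SIDECAR_REQUIRED if k not in meta]
    if missing:
        raise RecordingSchemaError(
            f"sidecar {json_path} is missing required field(s): {', '.join(missing)}"
        )
    with open(csv_path) as fh:
        header = fh.readline().strip()
        if header != "uV":
            raise RecordingSchemaError(f"{csv_path}: expected header 'uV', got {header!r}")
        samples = np.loadtxt(fh, dtype=np.float64, ndmin=1)
    return Recording(
        samples=samples,
        sampling_rate=float(meta["sampling_rate_hz"]),
        stim_times=tuple(meta["stim_times_s"]),
        subject_id=str(meta.get("subject_id", "rec")),
        age_group=str(meta.get("age_group", "NA")),
        condition=str(meta.get("condition", "NA")),
    )
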