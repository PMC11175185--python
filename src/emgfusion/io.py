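"""Dataset loading (MAT acquisition files), HDF5 persistence, bookkeeping."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import h5py
import numpy as np
from scipy.io import loadmat

from .preprocessing import EmgRecording

logger = logging.getLogger(__name__)

__all__ = [
    "DatasetSpec",
    "SchemaError",
    "dataset_summary",
    "load_ninapro_mat",
    "save_recording",
    "load_recording",
    "log_run",
]


class SchemaError(ValueError):
    """Input file does not match the expected variable layout."""


@dataclass(frozen=True)
class DatasetSpec:
    """Dataset bookkeeping: subjects x gestures x repetitions."""

    n_subjects: int
    n_gestures: int
    n_repetitions: int

    def __post_init__(self):
        if min(self.n_subjects, self.n_gestures, self.n_repetitions) < 1:
            raise ValueError("all counts must be positive")

    @property
    def n_patterns(self) -> int:
        return self.n_subjects * self.n_gestures * self.n_repetitions


def dataset_summary(spec: DatasetSpec, include_rest: bool = False) -> dict:
    """Total pattern count and per-subject trial count.

    Rest (label 0) is excluded from the gesture count by default; the flag
    adds one extra class for variants that classify rest explicitly.
    """
    gestures = spec.n_gestures + (1 if include_rest else 0)
    per_subject = gestures * spec.n_repetitions
    return {
        "n_subjects": spec.n_subjects,
        "n_gestures": gestures,
        "n_repetitions": spec.n_repetitions,
        "n_patterns": spec.n_subjects * per_subject,
        "patterns_per_subject": per_subject,
    }


_DB_LAYOUTS = {
    "db1": {"fs": 100.0, "channels": 10},
    "db2": {"fs": 2000.0, "channels": 12},
}


def load_ninapro_mat(path, database: str = "db1",
                     use_restimulus: bool = False) -> EmgRecording:
    """Load one per-subject acquisition MAT file.

    Expects `emg` (samples x channels), `stimulus` (or `restimulus` with
    the flag) and `repetition` variables; validates the channel count and
    sets the sampling rate for the selected database.
    """
    if database not in _DB_LAYOUTS:
        raise ValueError(f"unknown database {database!r}; expected one of "
                         f"{sorted(_DB_LAYOUTS)}")
    layout = _DB_LAYOUTS[database]
    mat = loadmat(str(path))
    label_key = "restimulus" if use_restimulus else "stimulus"
    for key in ("emg", label_key, "repetition"):
        if key not in mat:
            raise SchemaError(f"MAT file {path} is missing variable {key!r}")
    emg = np.asarray(mat["emg"], dtype=np.float64)
    if emg.ndim != 2 or emg.shape[1] != layout["channels"]:
        raise SchemaError(
            f"expected {layout['channels']} channels for {database}, "
            f"got shape {emg.shape}"
        )
    subject = int(np.asarray(mat.get("subject", 0)).ravel()[0]) if "subject" in mat else 0
    return EmgRecording(emg=emg, stimulus=np.asarray(mat[label_key]).ravel(),
                        repetition=np.asarray(mat["repetition"]).ravel(),
                        fs=layout["fs"], subject=subject)


def save_recording(path, recording: EmgRecording) -> None:
    with h5py.File(path, "w") as handle:
        handle.create_dataset("emg", data=recording.emg)
        handle.create_dataset("stimulus", data=recording.stimulus)
        handle.create_dataset("repetition", data=recording.repetition)
        handle.attrs["fs"] = recording.fs
        handle.attrs["subject"] = recording.subject


def load_recording(path) -> EmgRecording:
    with h5py.File(path, "r") as handle:
        return EmgRecording(emg=handle["emg"][...],
                            stimulus=handle["stimulus"][...],
                            repetition=handle["repetition"][...],
                            fs=float(handle.attrs["fs"]),
                            subject=int(handle.attrs["subject"]))


def log_run(command: str, config: dict, seed: int | None = None) -> dict:
    """Log the reproducibility context of a run and return it."""
    import subprocess

    import numpy
    import scipy

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    record = {
        "command": command,
        "seed": seed,
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
    }
    try:
        record["git_revision"] = subprocess.run(
            ["git", "rev-parse", "--short", "HEAD"], capture_output=True,
            text=True, timeout=5, check=False).stdout.strip() or None
    except OSError:
        record["git_revision"] = None
    logger.info("run context: %s", record)
    return record
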