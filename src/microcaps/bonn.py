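"""Reading and cataloguing Bonn-format single-channel EEG.

The Bonn corpus ships five sets (A-E) of 100 plain-text files each; every
file holds one 23.6 s single-channel recording as 4096 ASCII amplitude
values, one per line, sampled at 173.61 Hz. Amplitudes are kept in raw ADC
units — the recordings were band-passed at acquisition and no further
filtering is applied on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "BONN_FS",
    "BONN_FILE_LEN",
    "Recording",
    "DatasetCase",
    "STANDARD_CASES",
    "read_bonn_file",
    "write_bonn_file",
    "load_set",
    "build_case",
]

logger = logging.getLogger(__name__)

BONN_FS = 173.61
BONN_FILE_LEN = 4096


class BonnFormatError(ValueError):
    """Raised for unparsable or wrongly sized Bonn ASCII files."""


@dataclass
class Recording:
    """One single-channel EEG time series."""

    samples: np.ndarray
    fs: float = BONN_FS
    set_label: str = ""
    source_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class DatasetCase:
    """An experiment-level grouping of sets into classes, e.g. AB vs E."""

    name: str
    class_map: dict[str, int]
    n_classes: int = 0

    def __post_init__(self):
        indices = sorted(set(self.class_map.values()))
        if not self.n_classes:
            self.n_classes = len(indices)
        if indices != list(range(self.n_classes)):
            raise ValueError(
                f"class indices {indices} must be exactly 0..{self.n_classes - 1}"
            )


#: The dataset cases evaluated in the study: binary normal/interictal vs
#: ictal pairings and one ternary case. Class 1 (binary) / class 2 (ternary)
#: is always the ictal set E.
STANDARD_CASES: dict[str, DatasetCase] = {
    "AB_vs_E": DatasetCase("AB_vs_E", {"A": 0, "B": 0, "E": 1}),
    "C_vs_E": DatasetCase("C_vs_E", {"C": 0, "E": 1}),
    "D_vs_E": DatasetCase("D_vs_E", {"D": 0, "E": 1}),
    "A_vs_C_vs_E": DatasetCase("A_vs_C_vs_E", {"A": 0, "C": 1, "E": 2}),
}


def read_bonn_file(
    path, expected_len: int = BONN_FILE_LEN, set_label: str = "", fs: float = BONN_FS
) -> Recording:
    """Parse one Bonn ASCII file (one numeric amplitude per line).

    Some distributed copies carry one extra trailing line; a file of
    ``expected_len + 1`` values is truncated to ``expected_len`` with a
    logged warning. Larger deviations raise ``BonnFormatError``.
    """
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            try:
                values.append(float(stripped))
            except ValueError:
                raise BonnFormatError(
                    f"{path}: non-numeric value {stripped!r} at line {lineno}"
                ) from None
    if abs(len(values) - expected_len) > 1:
        raise BonnFormatError(
            f"{path}: {len(values)} samples, expected {expected_len} (±1)"
        )
    if len(values) == expected_len + 1:
        logger.warning("%s: %d lines, truncating to %d", path, len(values), expected_len)
        values = values[:expected_len]
    if len(values) == expected_len - 1:
        raise BonnFormatError(
            f"{path}: {len(values)} samples, one short of {expected_len}"
        )
    return Recording(np.array(values), fs=fs, set_label=set_label, source_id=path.name)


def write_bonn_file(path, samples) -> None:
    """Write amplitudes one per line (round-trips with read_bonn_file)."""
    samples = np.asarray(samples)
    with open(path, "w") as fh:
        for v in samples:
            fh.write(f"{int(v)}\n" if float(v).is_integer() else f"{v}\n")


def load_set(
    directory, set_label: str, expected_len: int = BONN_FILE_LEN, fs: float = BONN_FS
) -> list[Recording]:
    """Read every file of one set, ordered by filename."""
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    files = [p for p in files if not p.name.startswith(".") and p.suffix != ".json"]
    if not files:
        raise FileNotFoundError(f"no data files in {directory}")
    recordings = []
    for p in files:
        try:
            recordings.append(
                read_bonn_file(p, expected_len=expected_len, set_label=set_label, fs=fs)
            )
        except BonnFormatError as exc:
            raise BonnFormatError(f"while reading set {set_label}: {exc}") from exc
    logger.info("set %s: %d recordings from %s", set_label, len(recordings), directory)
    return recordings


def build_case(
    recordings_by_set: dict[str, list[Recording]], case: DatasetCase
) -> list[tuple[Recording, int]]:
    """Pair every recording of the case's sets with its class index.

    Order is deterministic: sets in class_map order, recordings in the
    (filename-sorted) order load_set produced.
    """
    labeled: list[tuple[Recording, int]] = []
    for set_label, class_idx in case.class_map.items():
        if set_label not in recordings_by_set:
            raise KeyError(f"case {case.name!r} needs set {set_label!r}, not provided")
        for rec in recordings_by_set[set_label]:
            labeled.append((rec, class_idx))
    return labeled
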