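"""Reading and writing of sEMG recordings, manifests, feature tables and reports.

A recording is a plain delimited-text file (comma- or tab-separated, optional
single header line) with one column per sEMG channel plus one knee-angle
column.  A cohort is described by a YAML manifest that lists, per recording,
the file path and the subject/group/motion metadata.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ParseError

GROUPS = ("CG", "SG")
MOTIONS = ("STD", "ST", "Gait")
DEFAULT_CHANNELS = ("RF", "FB", "VM", "SEM")


@dataclass
class Recording:
    """One multi-channel sEMG recording with its knee-angle trace.

    Attributes
    ----------
    semg : ndarray, shape (m, T)
        Raw sEMG, one row per muscle channel (mV scale, unprocessed).
    angle : ndarray, shape (T,)
        Knee goniometer trace in degrees, time-aligned with ``semg``.
    fs : float
        Sampling rate in Hz.
    subject_id : str
    group : str
        ``"CG"`` (control) or ``"SG"`` (knee pathology).
    motion : str
        ``"STD"`` (leg flexion, standing), ``"ST"`` (leg extension,
        sitting) or ``"Gait"`` (level walking).
    channel_names : list of str
        Muscle labels, one per sEMG row.
    """

    semg: np.ndarray
    angle: np.ndarray
    fs: float
    subject_id: str
    group: str
    motion: str
    channel_names: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))

    def __post_init__(self) -> None:
        self.semg = np.asarray(self.semg, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if self.semg.ndim != 2:
            raise ConfigurationError("semg must be a 2-D (channels x samples) array")
        if self.angle.ndim != 1 or self.angle.shape[0] != self.semg.shape[1]:
            raise ConfigurationError(
                "angle must be 1-D with the same sample count as semg "
                f"(got {self.angle.shape} vs {self.semg.shape})"
            )
        if self.fs <= 0:
            raise ConfigurationError(f"fs must be positive, got {self.fs}")
        if len(self.channel_names) != self.semg.shape[0]:
            raise ConfigurationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.semg.shape[0]} channels"
            )
        if self.group not in GROUPS:
            raise ConfigurationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.motion not in MOTIONS:
            raise ConfigurationError(
                f"motion must be one of {MOTIONS}, got {self.motion!r}"
            )

    @property
    def n_channels(self) -> int:
        return self.semg.shape[0]

    @property
    def n_samples(self) -> int:
        return self.semg.shape[1]


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return "\t" if "\t" in sample else ","


def _is_numeric_row(cells: Sequence[str]) -> bool:
    for c in cells:
        try:
            float(c)
        except ValueError:
            return False
    return True


def read_recording(
    path: str | Path,
    layout: Mapping[str, int],
    *,
    fs: float = 1000.0,
    subject_id: str = "",
    group: str = "CG",
    motion: str = "STD",
) -> Recording:
    """Read a delimited-text recording into a :class:`Recording`.

    Parameters
    ----------
    path : path
        CSV/TSV file, one column per channel. Delimiter and an optional
        single header line are auto-detected.
    layout : mapping
        Column map, e.g. ``{"RF": 0, "FB": 1, "VM": 2, "SEM": 3, "angle": 4}``.
        Must contain an ``"angle"`` key; every other key names an sEMG channel.

    Raises
    ------
    ConfigurationError
        If the layout lacks an angle column or references a column the file
        does not have.
    ParseError
        If a cell cannot be parsed as a number (message carries the 1-based
        line number).
    """
    path = Path(path)
    if "angle" not in layout:
        raise ConfigurationError("layout must name an 'angle' column")
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    delim = _sniff_delimiter(lines[0])
    first_cells = lines[0].split(delim)
    has_header = not _is_numeric_row(first_cells)
    data_start = 1 if has_header else 0

    n_cols = len(first_cells)
    for name, col in layout.items():
        if not 0 <= int(col) < n_cols:
            raise ConfigurationError(
                f"{path}: column {col} for {name!r} out of range (file has {n_cols})"
            )

    rows = []
    for lineno, ln in enumerate(lines[data_start:], start=data_start + 1):
        cells = ln.split(delim)
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
    data = np.asarray(rows, dtype=float)

    channel_names = [k for k in layout if k != "angle"]
    semg = data[:, [int(layout[k]) for k in channel_names]].T
    angle = data[:, int(layout["angle"])]
    return Recording(
        semg=semg,
        angle=angle,
        fs=fs,
        subject_id=subject_id,
        group=group,
        motion=motion,
        channel_names=channel_names,
    )


def write_recording(rec: Recording, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a recording as delimited text with a header (channels then angle)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = delimiter.join([*rec.channel_names, "angle"])
    data = np.column_stack([rec.semg.T, rec.angle])
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for row in data:
            fh.write(delimiter.join(repr(float(v)) for v in row) + "\n")


@dataclass
class ManifestEntry:
    path: str
    subject_id: str
    group: str
    motion: str


@dataclass
class Manifest:
    """Cohort description: layout, sampling rate and per-recording metadata."""

    entries: list[ManifestEntry]
    layout: dict[str, int]
    fs: float = 1000.0
    root: Path = Path(".")

    def load_recordings(self) -> list[Recording]:
        return [
            read_recording(
                self.root / e.path,
                self.layout,
                fs=self.fs,
                subject_id=e.subject_id,
                group=e.group,
                motion=e.motion,
            )
            for e in self.entries
        ]


def read_manifest(path: str | Path) -> Manifest:
    """Read a YAML manifest; recording paths resolve relative to its directory."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    for key in ("layout", "recordings"):
        if key not in doc:
            raise ConfigurationError(f"{path}: manifest missing {key!r}")
    entries = [
        ManifestEntry(
            path=r["path"],
            subject_id=str(r["subject_id"]),
            group=r["group"],
            motion=r["motion"],
        )
        for r in doc["recordings"]
    ]
    return Manifest(
        entries=entries,
        layout={k: int(v) for k, v in doc["layout"].items()},
        fs=float(doc.get("fs", 1000.0)),
        root=path.parent,
    )


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "fs": manifest.fs,
        "layout": manifest.layout,
        "recordings": [
            {
                "path": e.path,
                "subject_id": e.subject_id,
                "group": e.group,
                "motion": e.motion,
            }
            for e in manifest.entries
        ],
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as CSV at full float precision (round-trip safe)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_report(report: dict, path: str | Path) -> None:
    """Write a JSON report (nested dicts/lists of numbers and strings)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(report, indent=2, default=_default))


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
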