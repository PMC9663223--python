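"""Recording/event/montage I/O.

The contract of record is a human-inspectable wide CSV for optical-density
recordings (columns ``time_s``, ``ch01_wl780`` .. ``ch15_wl780``,
``ch01_wl850`` .. ``ch15_wl850``), a sidecar TSV for events
(onset/duration/condition) and a YAML file for the montage.  A minimal SNIRF
(HDF5) writer/reader is provided as an optional exchange format; the CSV
dialect remains authoritative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

WAVELENGTHS_NM = (780.0, 850.0)
CONDITIONS = ("Task1", "Task2")

ROI_LABELS = ("DLPFC", "VLPFC_L", "VLPFC_R", "mPFC", "OFC")


class FormatError(ValueError):
    """A file does not conform to the documented schema."""


@dataclass(frozen=True)
class Channel:
    """One source-detector pair on the prefrontal montage."""

    id: int
    source: int
    detector: int
    roi: str

    def __post_init__(self) -> None:
        if self.roi not in ROI_LABELS:
            raise ValueError(f"unknown ROI label {self.roi!r}")


@dataclass(frozen=True)
class ChannelLayout:
    """The 15-channel prefrontal montage (5 sources, 7 detectors, 3 cm pairs)."""

    channels: tuple[Channel, ...]
    separation_cm: float = 3.0

    def __post_init__(self) -> None:
        if self.separation_cm <= 0:
            raise ValueError("source-detector separation must be > 0")
        ids = [c.id for c in self.channels]
        if ids != sorted(set(ids)):
            raise ValueError("channel ids must be unique and sorted")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def rois(self) -> tuple[str, ...]:
        return tuple(c.roi for c in self.channels)

    def roi_channels(self, roi: str) -> list[int]:
        """0-based indices of the channels assigned to *roi*."""
        return [i for i, c in enumerate(self.channels) if c.roi == roi]


#: Default montage: 15 channels from 5 sources and 7 detectors, symmetric about
#: FPz (which sits between channels 7 and 10, inside the mPFC group).  Lateral
#: inferior channels map to left/right VLPFC, superior lateral to DLPFC, the
#: midline row to mPFC and the inferior midline to OFC.
_DEFAULT_CHANNEL_TABLE = (
    (1, 1, 1, "VLPFC_L"),
    (2, 1, 2, "VLPFC_L"),
    (3, 1, 3, "DLPFC"),
    (4, 2, 3, "DLPFC"),
    (5, 2, 4, "OFC"),
    (6, 2, 7, "OFC"),
    (7, 3, 4, "mPFC"),
    (8, 3, 7, "mPFC"),
    (9, 3, 5, "mPFC"),
    (10, 4, 5, "mPFC"),
    (11, 4, 7, "OFC"),
    (12, 4, 6, "DLPFC"),
    (13, 5, 6, "DLPFC"),
    (14, 5, 5, "VLPFC_R"),
    (15, 5, 7, "VLPFC_R"),
)


def default_layout(separation_cm: float = 3.0) -> ChannelLayout:
    """The standard 15-channel prefrontal layout used throughout the package."""
    return ChannelLayout(
        channels=tuple(Channel(*row) for row in _DEFAULT_CHANNEL_TABLE),
        separation_cm=separation_cm,
    )


@dataclass(frozen=True)
class Event:
    """A trial marker: task onset (s), task duration (s), condition label."""

    onset: float
    duration: float
    condition: str

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise FormatError(
                f"unknown condition label {self.condition!r}; expected one of {CONDITIONS}"
            )
        if self.duration < 0:
            raise FormatError("event duration must be >= 0")


@dataclass
class Recording:
    """Dual-wavelength optical-density change time series on one montage.

    ``od`` has shape (n_samples, n_channels, 2) with the last axis ordered as
    :data:`WAVELENGTHS_NM` (780 nm, 850 nm).  OD is the change from each
    channel's temporal mean and is dimensionless; time is seconds from
    recording start.
    """

    time: np.ndarray
    od: np.ndarray
    layout: ChannelLayout
    events: list[Event] = field(default_factory=list)
    filtered: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.od.shape != (self.time.size, self.layout.n_channels, 2):
            raise ValueError(
                f"od shape {self.od.shape} inconsistent with "
                f"{self.time.size} samples x {self.layout.n_channels} channels x 2 wavelengths"
            )
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise FormatError("time axis is not uniformly sampled")
        for ev in self.events:
            if not (self.time[0] <= ev.onset <= self.time[-1]):
                raise FormatError(
                    f"event onset {ev.onset} s outside recording time axis"
                )

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])

    @property
    def n_channels(self) -> int:
        return self.layout.n_channels

    def copy_with(self, **kw) -> "Recording":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# CSV recording format
# ---------------------------------------------------------------------------

def _column_names(n_channels: int) -> list[str]:
    cols = ["time_s"]
    for wl in (780, 850):
        cols += [f"ch{i:02d}_wl{wl}" for i in range(1, n_channels + 1)]
    return cols


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as wide CSV (full float precision)."""
    cols = _column_names(rec.n_channels)
    data = np.column_stack([rec.time, rec.od[:, :, 0], rec.od[:, :, 1]])
    pd.DataFrame(data, columns=cols).to_csv(path, index=False, float_format="%.17g")


def read_recording(
    path: str | Path,
    layout: ChannelLayout | None = None,
    events: list[Event] | None = None,
) -> Recording:
    """Read a wide-CSV recording; raises :class:`FormatError` naming any missing column."""
    layout = layout or default_layout()
    df = pd.read_csv(path, float_precision="round_trip")
    for col in _column_names(layout.n_channels):
        if col not in df.columns:
            raise FormatError(f"recording file {path} is missing column {col!r}")
    n = layout.n_channels
    time = df["time_s"].to_numpy(float)
    od = np.stack(
        [
            df[[f"ch{i:02d}_wl780" for i in range(1, n + 1)]].to_numpy(float),
            df[[f"ch{i:02d}_wl850" for i in range(1, n + 1)]].to_numpy(float),
        ],
        axis=-1,
    )
    return Recording(time=time, od=od, layout=layout, events=list(events or []))


# ---------------------------------------------------------------------------
# Events TSV
# ---------------------------------------------------------------------------

def write_events(events: list[Event], path: str | Path) -> None:
    pd.DataFrame(
        {
            "onset": [e.onset for e in events],
            "duration": [e.duration for e in events],
            "condition": [e.condition for e in events],
        }
    ).to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> list[Event]:
    """Read onset/duration/condition TSV; returns events sorted by onset.

    Overlapping task intervals are logged as a warning but are not fatal —
    out-of-range onsets are only detectable (and rejected) at epoching time.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return []
    for col in ("onset", "duration", "condition"):
        if col not in df.columns:
            raise FormatError(f"events file {path} is missing column {col!r}")
    events = sorted(
        (
            Event(float(r.onset), float(r.duration), str(r.condition))
            for r in df.itertuples()
        ),
        key=lambda e: e.onset,
    )
    for a, b in zip(events, events[1:]):
        if b.onset < a.onset + a.duration:
            logger.warning(
                "task intervals overlap: onset %.3f s (dur %.3f) and onset %.3f s",
                a.onset,
                a.duration,
                b.onset,
            )
    return events


# ---------------------------------------------------------------------------
# Montage YAML
# ---------------------------------------------------------------------------

def write_layout(layout: ChannelLayout, path: str | Path) -> None:
    doc = {
        "separation_cm": layout.separation_cm,
        "channels": [
            {"id": c.id, "source": c.source, "detector": c.detector, "roi": c.roi}
            for c in layout.channels
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_layout(path: str | Path) -> ChannelLayout:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        channels = tuple(
            Channel(int(c["id"]), int(c["source"]), int(c["detector"]), str(c["roi"]))
            for c in doc["channels"]
        )
        return ChannelLayout(channels=channels, separation_cm=float(doc["separation_cm"]))
    except (KeyError, TypeError) as exc:
        raise FormatError(f"montage file {path} is malformed: {exc}") from exc


# ---------------------------------------------------------------------------
# Minimal SNIRF (HDF5) container
# ---------------------------------------------------------------------------

def write_snirf(rec: Recording, path: str | Path) -> None:
    """Write the recording as a minimal SNIRF v1.0 HDF5 container.

    One data block holds all channel x wavelength columns; per-condition stim
    groups carry the trial markers.  Probe positions are schematic (the montage
    is defined logically by source/detector ids, not by digitized coordinates).
    """
    import h5py

    n = rec.n_channels
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("LengthUnit", data="cm")
        meta.create_dataset("TimeUnit", data="s")
        data = nirs.create_group("data1")
        flat = rec.od.reshape(rec.od.shape[0], 2 * n, order="F")  # wl-major like CSV
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=rec.time)
        k = 0
        for wl_index in (1, 2):
            for c in rec.layout.channels:
                k += 1
                ml = data.create_group(f"measurementList{k}")
                ml.create_dataset("sourceIndex", data=c.source)
                ml.create_dataset("detectorIndex", data=c.detector)
                ml.create_dataset("wavelengthIndex", data=wl_index)
                ml.create_dataset("dataType", data=1)  # CW amplitude family
                ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.array(WAVELENGTHS_NM))
        probe.create_dataset(
            "sourcePos2D", data=np.column_stack([np.arange(1, 6) * 3.0, np.zeros(5)])
        )
        probe.create_dataset(
            "detectorPos2D",
            data=np.column_stack([np.arange(1, 8) * 3.0 - 1.5, np.ones(7)]),
        )
        for j, cond in enumerate(CONDITIONS, start=1):
            evs = [e for e in rec.events if e.condition == cond]
            stim = nirs.create_group(f"stim{j}")
            stim.create_dataset("name", data=cond)
            stim.create_dataset(
                "data",
                data=np.array([[e.onset, e.duration, 1.0] for e in evs]).reshape(-1, 3),
            )


def read_snirf(path: str | Path, layout: ChannelLayout | None = None) -> Recording:
    """Read a recording written by :func:`write_snirf`."""
    import h5py

    layout = layout or default_layout()
    n = layout.n_channels
    with h5py.File(path, "r") as f:
        data = f["nirs/data1"]
        time = np.asarray(data["time"])
        flat = np.asarray(data["dataTimeSeries"])
        if flat.shape[1] != 2 * n:
            raise FormatError(
                f"SNIRF data block has {flat.shape[1]} columns, expected {2 * n}"
            )
        od = flat.reshape(flat.shape[0], n, 2, order="F")
        events: list[Event] = []
        j = 1
        while f"nirs/stim{j}" in f:
            stim = f[f"nirs/stim{j}"]
            name = stim["name"][()]
            name = name.decode() if isinstance(name, bytes) else str(name)
            for onset, duration, _amp in np.asarray(stim["data"]).reshape(-1, 3):
                events.append(Event(float(onset), float(duration), name))
            j += 1
    events.sort(key=lambda e: e.onset)
    return Recording(time=time, od=od, layout=layout, events=events)
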