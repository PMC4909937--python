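"""On-disk artifact I/O with exact round-trips.

Frame stacks travel as raw interleaved 24-bit RGB (the rig camera's native
dump format, green channel carrying the GCaMP emission) or multi-page TIFF,
each with a small JSON sidecar for geometry/timebase; event logs as JSONL
or CSV; masks as 8-bit label TIFF; cage configuration as YAML.  Readers
never silently drop frames or events.
"""

from __future__ import annotations

import csv
import hashlib
import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .controller import CageConfig, Event, EventLog, LogConsistencyError

__all__ = [
    "FrameStack",
    "MaskSet",
    "FrameBoundaryError",
    "FixtureCorruptionError",
    "read_raw_rgb",
    "write_raw_rgb",
    "read_tiff_stack",
    "write_tiff_stack",
    "read_event_log",
    "write_event_log",
    "read_masks",
    "write_masks",
    "load_config",
    "save_config",
    "load_table2_fixture",
    "LAB_CAGES",
]

EVENT_SCHEMA = "mesocage-events-1"

#: cage groups trained daily on a laboratory bench (vs. facility-trained GU)
LAB_CAGES = ("AB", "EL", "EP")

# sha256 of the packaged session-table fixture, guarding silent edits
_TABLE2_SHA256 = "acd049d765417c3a681e494c6751eb0e00ea0ad1b419c9dec75885dc4557d398"


class FrameBoundaryError(ValueError):
    """A raw video file does not contain a whole number of frames."""


class FixtureCorruptionError(RuntimeError):
    """A packaged fixture fails its checksum."""


# ---------------------------------------------------------------------------
# in-memory containers
# ---------------------------------------------------------------------------


@dataclass
class FrameStack:
    """A T x H x W fluorescence movie with timebase and provenance.

    ``t0`` is seconds relative to the session clock (``t0_iso`` anchors it
    to wall time when known).  ``channel`` records which RGB plane the data
    came from; GCaMP emission is imaged in green.
    """

    data: np.ndarray
    frame_rate_hz: float = 30.0
    t0: float = 0.0
    t0_iso: str | None = None
    source: str = "synthetic"          # raw_rgb24 | tiff | synthetic
    channel: str = "green"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("FrameStack needs a T x H x W array with T >= 1")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.frame_rate_hz


@dataclass
class MaskSet:
    """Brain-window mask, off-window correction ROI and bregma landmark."""

    window_mask: np.ndarray
    correction_roi: np.ndarray
    bregma_px: tuple[int, int]

    def __post_init__(self) -> None:
        self.window_mask = np.asarray(self.window_mask, dtype=bool)
        self.correction_roi = np.asarray(self.correction_roi, dtype=bool)
        if self.window_mask.shape != self.correction_roi.shape:
            raise ValueError("masks must share a shape")
        if np.any(self.window_mask & self.correction_roi):
            raise ValueError("correction ROI must lie entirely outside the window")
        r, c = self.bregma_px
        h, w = self.window_mask.shape
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError("bregma_px outside the frame")


# ---------------------------------------------------------------------------
# raw RGB24
# ---------------------------------------------------------------------------

_CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


def read_raw_rgb(path, width: int, height: int, channel: str = "green",
                 frame_rate_hz: float = 30.0, t0: float = 0.0) -> FrameStack:
    """Read a raw interleaved RGB24 dump, returning one colour plane.

    The file must hold a whole number of ``3 * width * height``-byte
    frames; a truncated file raises :class:`FrameBoundaryError` with the
    offending byte offset.
    """
    raw = Path(path).read_bytes()
    frame_bytes = 3 * width * height
    n, rem = divmod(len(raw), frame_bytes)
    if rem:
        raise FrameBoundaryError(
            f"{path}: {len(raw)} bytes is not a multiple of {frame_bytes}; "
            f"frame boundary broken at byte offset {n * frame_bytes}")
    if n == 0:
        raise FrameBoundaryError(f"{path}: empty video file")
    arr = np.frombuffer(raw, dtype=np.uint8).reshape(n, height, width, 3)
    plane = arr[..., _CHANNEL_INDEX[channel]].copy()
    return FrameStack(plane, frame_rate_hz=frame_rate_hz, t0=t0,
                      source="raw_rgb24", channel=channel)


def write_raw_rgb(stack: FrameStack, path) -> None:
    """Write a stack as raw interleaved RGB24 plus a JSON sidecar.

    The stack's plane is stored in its recorded channel; the other two
    planes are zero.  Data must be uint8 (RGB24 is 8 bits per channel).
    """
    if stack.data.dtype != np.uint8:
        raise ValueError("raw RGB24 requires uint8 data")
    n, h, w = stack.shape
    rgb = np.zeros((n, h, w, 3), dtype=np.uint8)
    rgb[..., _CHANNEL_INDEX[stack.channel]] = stack.data
    Path(path).write_bytes(rgb.tobytes())
    _write_sidecar(path, stack, width=w, height=h)


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def _write_sidecar(path, stack: FrameStack, **extra) -> None:
    meta = {"fps": stack.frame_rate_hz, "t0": stack.t0, "t0_iso": stack.t0_iso,
            "source": stack.source, "channel": stack.channel}
    meta.update(extra)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_sidecar(path) -> dict:
    p = _sidecar_path(path)
    return json.loads(p.read_text()) if p.exists() else {}


# ---------------------------------------------------------------------------
# TIFF stacks and masks
# ---------------------------------------------------------------------------


def write_tiff_stack(stack: FrameStack, path) -> None:
    """Write a multi-page TIFF (grayscale) with a JSON sidecar."""
    tifffile.imwrite(str(path), stack.data, photometric="minisblack")
    _write_sidecar(path, stack)


def read_tiff_stack(path, frame_rate_hz: float | None = None) -> FrameStack:
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    meta = _read_sidecar(path)
    return FrameStack(
        data,
        frame_rate_hz=frame_rate_hz or meta.get("fps", 30.0),
        t0=meta.get("t0", 0.0), t0_iso=meta.get("t0_iso"),
        source="tiff", channel=meta.get("channel", "green"))


def write_masks(masks: MaskSet, path) -> None:
    """Write masks as one 8-bit label TIFF (window=1, correction ROI=2)."""
    label = np.zeros(masks.window_mask.shape, dtype=np.uint8)
    label[masks.window_mask] = 1
    label[masks.correction_roi] = 2
    tifffile.imwrite(str(path), label)
    _sidecar_path(path).write_text(json.dumps(
        {"bregma_px": list(masks.bregma_px)}))


def read_masks(path) -> MaskSet:
    label = tifffile.imread(str(path))
    meta = _read_sidecar(path)
    bregma = tuple(meta.get("bregma_px", (label.shape[0] // 2,
                                          label.shape[1] // 2)))
    return MaskSet(label == 1, label == 2, bregma)


# ---------------------------------------------------------------------------
# event logs
# ---------------------------------------------------------------------------

_LOG_FIELDS = ("t", "tag", "kind")


def write_event_log(log: EventLog, path) -> None:
    """Write an event log as JSONL (default) or CSV, by extension."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        payload_keys = sorted({k for e in log.events for k in e.payload})
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(list(_LOG_FIELDS) + payload_keys)
            for e in log.events:
                writer.writerow(
                    [repr(e.t), e.tag, e.kind]
                    + [_csv_cell(e.payload.get(k)) for k in payload_keys])
    else:
        with path.open("w") as fh:
            header = {"schema": EVENT_SCHEMA, "t0_iso": log.t0_iso,
                      "t0_hour": log.t0_hour}
            fh.write(json.dumps(header) + "\n")
            for e in log.events:
                rec = {"t": e.t, "tag": e.tag, "kind": e.kind}
                if e.payload:
                    rec["payload"] = e.payload
                fh.write(json.dumps(rec) + "\n")


def _csv_cell(v):
    if v is None:
        return ""
    if isinstance(v, float):
        return repr(v)
    return v


def read_event_log(path, validate: bool = True) -> EventLog:
    """Read a JSONL or CSV event log; format chosen by extension.

    Invariant violations are reported with the offending line number.
    """
    path = Path(path)
    log = EventLog()
    if path.suffix.lower() == ".csv":
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            for i, row in enumerate(reader):
                payload = {}
                for k, v in row.items():
                    if k in _LOG_FIELDS or v in ("", None):
                        continue
                    try:
                        payload[k] = float(v) if "." in v or "e" in v else v
                    except ValueError:
                        payload[k] = v
                try:
                    log.append(Event(float(row["t"]), row["tag"],
                                     row["kind"], payload))
                except (ValueError, LogConsistencyError) as err:
                    raise LogConsistencyError(f"{path} line {i + 2}: {err}")
    else:
        with path.open() as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                rec = json.loads(line)
                if "schema" in rec:
                    log.t0_iso = rec.get("t0_iso")
                    log.t0_hour = rec.get("t0_hour", log.t0_hour)
                    continue
                try:
                    log.append(Event(float(rec["t"]), rec.get("tag", ""),
                                     rec["kind"], rec.get("payload", {})))
                except (ValueError, LogConsistencyError) as err:
                    raise LogConsistencyError(f"{path} line {i + 1}: {err}")
    if validate:
        log.validate()
    return log


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------


def save_config(config: CageConfig, path) -> None:
    d = {k: (list(v) if isinstance(v, tuple) else v)
         for k, v in config.__dict__.items()}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def load_config(path) -> CageConfig:
    d = yaml.safe_load(Path(path).read_text()) or {}
    if d.get("reward_times") is not None:
        d["reward_times"] = tuple(d["reward_times"])
    return CageConfig(**d)


# ---------------------------------------------------------------------------
# packaged session table
# ---------------------------------------------------------------------------


def load_table2_fixture() -> pd.DataFrame:
    """Load the packaged per-mouse head-fixing session table.

    Sixteen mice across four cage groups (AB, EL, EP lab-trained; GU
    facility-trained) with total entries, head-fixes and days tested, plus
    the per-day rates as originally printed (1-decimal) for verification.
    The file is checksummed against silent modification.
    """
    ref = importlib.resources.files("mesocage").joinpath("data/table2.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE2_SHA256:
        raise FixtureCorruptionError(
            f"session-table fixture checksum mismatch ({digest})")
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw))
    df["cage"] = df["animal_id"].str[:2]
    return df
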