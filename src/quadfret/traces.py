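"""Per-molecule two-channel trace records and their plain-text dialect.

Traces are stored as tab-separated text with columns
``molecule_id  frame  donor  acceptor`` (frames 1-based and contiguous), one
file per condition, with a ``key=value`` manifest sidecar holding the
condition labels (construct, protein concentration, salt, ...). The format is
deliberately diffable and language-agnostic; round-trips are bit-exact
because floats are written in shortest round-trip representation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .errors import EmptyDataError, FormatError, IntegrityError, ParameterError

__all__ = [
    "TraceRecord",
    "TraceSet",
    "read_traces",
    "write_traces",
    "detect_bleach",
    "manifest_path",
]

REQUIRED_COLUMNS = ("molecule_id", "frame", "donor", "acceptor")


@dataclass
class TraceRecord:
    """One molecule's donor/acceptor intensity time series.

    ``bleach_frame`` is the 1-based index of the first frame after
    single-step photobleaching (total-intensity collapse), or ``None`` if the
    fluorophores survive the recording. Downstream analysis only uses frames
    before ``bleach_frame``.
    """

    molecule_id: str
    donor: np.ndarray
    acceptor: np.ndarray
    frame_interval: float = 0.1
    bleach_frame: int | None = None
    channel_labels: tuple = ("donor", "acceptor")

    def __post_init__(self):
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.ndim != 1 or self.acceptor.ndim != 1:
            raise ParameterError("donor/acceptor must be 1-D series")
        if self.donor.size != self.acceptor.size:
            raise ParameterError(
                f"channel length mismatch for {self.molecule_id!r}: "
                f"{self.donor.size} vs {self.acceptor.size}"
            )
        if self.donor.size < 1:
            raise ParameterError(f"empty trace {self.molecule_id!r}")
        if self.frame_interval <= 0:
            raise ParameterError("frame_interval must be positive")
        if self.bleach_frame is not None:
            if not 1 <= int(self.bleach_frame) <= self.n_frames:
                raise ParameterError(
                    f"bleach_frame {self.bleach_frame} outside [1, {self.n_frames}]"
                )
            self.bleach_frame = int(self.bleach_frame)

    @property
    def n_frames(self) -> int:
        return self.donor.size

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor

    @property
    def times(self) -> np.ndarray:
        """Frame start times in seconds (frame i covers [i*dt, (i+1)*dt))."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class TraceSet:
    """Ordered collection of traces measured under one condition.

    ``manifest`` carries the condition labels (construct name, protein
    concentration in nM, salt, temperature, seed for synthetic sets) and must
    be non-empty. ``truth`` optionally holds simulator ground truth keyed by
    molecule_id (see :mod:`quadfret.simulate`).
    """

    traces: list
    manifest: dict
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.manifest:
            raise ParameterError("manifest condition labels must be non-empty")
        ids = [t.molecule_id for t in self.traces]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise IntegrityError(f"duplicate molecule_id {dup!r} in TraceSet")

    def __len__(self):
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def __getitem__(self, key):
        if isinstance(key, str):
            for t in self.traces:
                if t.molecule_id == key:
                    return t
            raise KeyError(key)
        return self.traces[key]


def manifest_path(path) -> str:
    return f"{os.fspath(path)}.manifest"


def read_traces(path, manifest: dict | None = None, frame_interval: float = 0.1) -> TraceSet:
    """Read a trace TSV (and its manifest sidecar) into a TraceSet.

    Frames must be contiguous from 1 within each molecule; duplicate
    (molecule_id, frame) rows raise :class:`IntegrityError`. An explicit
    ``manifest`` argument overrides the sidecar.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, sep="\t", dtype={"molecule_id": str}, float_precision="round_trip"
    )
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing column {col!r} in {path}")
    if manifest is None:
        manifest = _read_manifest(manifest_path(path))
    if not manifest:
        manifest = {"source": os.path.basename(path)}
    frame_interval = float(manifest.get("frame_interval", frame_interval))
    traces = []
    # sort=False keeps molecules in file order for exact round-trips
    for mol, grp in df.groupby("molecule_id", sort=False):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        if np.unique(frames).size != frames.size:
            raise IntegrityError(f"duplicate frame rows for molecule {mol!r}")
        if not np.array_equal(frames, np.arange(1, frames.size + 1)):
            raise IntegrityError(
                f"frames not contiguous from 1 for molecule {mol!r}"
            )
        bleach = None
        if "bleach_frame" in grp.columns:
            val = grp["bleach_frame"].iloc[0]
            if pd.notna(val) and str(val) not in ("", "none"):
                bleach = int(val)
        traces.append(
            TraceRecord(
                molecule_id=str(mol),
                donor=grp["donor"].to_numpy(dtype=float),
                acceptor=grp["acceptor"].to_numpy(dtype=float),
                frame_interval=frame_interval,
                bleach_frame=bleach,
            )
        )
    return TraceSet(traces=traces, manifest=dict(manifest))


def write_traces(traceset: TraceSet, path) -> str:
    """Write the TSV dialect ``read_traces`` accepts, plus the manifest sidecar."""
    if len(traceset) == 0:
        raise EmptyDataError("refusing to write an empty TraceSet")
    path = os.fspath(path)
    parts = []
    for t in traceset:
        parts.append(
            pd.DataFrame(
                {
                    "molecule_id": t.molecule_id,
                    "frame": np.arange(1, t.n_frames + 1),
                    "donor": t.donor,
                    "acceptor": t.acceptor,
                }
            )
        )
    # shortest round-trip repr keeps read∘write bit-exact on intensities
    pd.concat(parts, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format=lambda v: repr(float(v))
    )
    _write_manifest(manifest_path(path), traceset.manifest)
    return path


def _read_manifest(path) -> dict:
    if not os.path.exists(path):
        return {}
    manifest = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            manifest[key.strip()] = value.strip()
    return manifest


def _write_manifest(path, manifest: dict):
    with open(path, "w") as fh:
        for key in sorted(manifest):
            fh.write(f"{key}={manifest[key]}\n")


def detect_bleach(trace: TraceRecord, drop_fraction: float = 0.3) -> int | None:
    """Locate single-step photobleaching on the total-intensity channel.

    Returns the 1-based index of the first frame where the median-smoothed
    total intensity falls below ``drop_fraction`` of its initial median and
    stays below until the end of the trace, or ``None`` if no such frame
    exists. Invariant under uniform positive rescaling of both channels.
    """
    if not 0 < drop_fraction < 1:
        raise ParameterError("drop_fraction must lie in (0, 1)")
    if trace.n_frames < 2:
        raise ParameterError("need at least 2 frames to detect bleaching")
    total = trace.total
    smooth_n = min(5, trace.n_frames)
    smoothed = median_filter(total, size=smooth_n, mode="nearest")
    baseline = np.median(smoothed[: min(10, trace.n_frames)])
    if baseline <= 0:
        return None
    below = smoothed < drop_fraction * baseline
    if not below[-1]:
        return None
    # first index from which `below` holds through the end
    not_below = np.nonzero(~below)[0]
    first = 0 if not_below.size == 0 else not_below[-1] + 1
    if first >= trace.n_frames:
        return None
    return int(first) + 1
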