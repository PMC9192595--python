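"""Piecewise-constant state occupancy of a single molecule in time.

A :class:`StatePath` is the common currency between the trajectory simulator
(ground truth) and the hidden-Markov segmenter (inference): an ordered list of
contiguous segments, each holding one conformational state for a strictly
positive duration. Helper functions convert between continuous-time paths and
the camera's frame grid (dominant-occupancy labels, fractional occupancy
weights for camera integration).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError

__all__ = ["Segment", "StatePath", "occupancy_matrix", "path_from_frame_labels"]

_EPS = 1e-9


@dataclass(frozen=True)
class Segment:
    """One constant-state stretch of a trajectory, in seconds."""

    state: str
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class StatePath:
    """Labeled, contiguous segmentation of one molecule's trajectory.

    Parameters
    ----------
    molecule_id : str
        Identifier shared with the source trace.
    segments : list of Segment
        Contiguous, non-overlapping, each with positive duration; adjacent
        segments carry distinct states.
    source : {"simulated", "inferred"}
        Provenance of the segmentation.
    emission_centers : dict, optional
        Mean FRET level associated with each state label, used for transition
        density coordinates and anchor-based state labeling.
    """

    molecule_id: str
    segments: list
    source: str = "simulated"
    emission_centers: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.segments:
            raise ParameterError("StatePath requires at least one segment")
        prev = None
        for seg in self.segments:
            if seg.duration <= 0:
                raise ParameterError(
                    f"segment of non-positive duration in {self.molecule_id!r}"
                )
            if prev is not None:
                if abs(prev.end - seg.start) > _EPS:
                    raise ParameterError(
                        f"segments not contiguous in {self.molecule_id!r}"
                    )
                if prev.state == seg.state:
                    raise ParameterError(
                        f"adjacent segments share state {seg.state!r} "
                        f"in {self.molecule_id!r}"
                    )
            prev = seg

    @property
    def start(self) -> float:
        return self.segments[0].start

    @property
    def end(self) -> float:
        return self.segments[-1].end

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def states(self) -> list:
        """Distinct states in order of first appearance."""
        seen = []
        for seg in self.segments:
            if seg.state not in seen:
                seen.append(seg.state)
        return seen

    @property
    def n_transitions(self) -> int:
        return len(self.segments) - 1

    def transitions(self) -> list:
        """(state_before, state_after) for every segment boundary."""
        return [
            (a.state, b.state)
            for a, b in zip(self.segments[:-1], self.segments[1:])
        ]

    def frame_labels(self, n_frames: int, frame_interval: float, states=None):
        """Dominant-occupancy state label of each camera frame.

        Frame ``i`` (0-based) covers ``[i*dt, (i+1)*dt)``. Ties break toward
        the state listed first in ``states`` (default: order of appearance).
        """
        if states is None:
            states = self.states
        W = occupancy_matrix(self, n_frames, frame_interval, states)
        labels = np.asarray(states, dtype=object)[np.argmax(W, axis=1)]
        return labels

    def relabel(self, mapping: dict) -> "StatePath":
        """Return a copy with states renamed through ``mapping``.

        Segments that become adjacent duplicates after renaming are merged.
        """
        segs = []
        for seg in self.segments:
            new = mapping.get(seg.state, seg.state)
            if segs and segs[-1].state == new:
                segs[-1] = Segment(new, segs[-1].start, seg.end)
            else:
                segs.append(Segment(new, seg.start, seg.end))
        centers = {}
        for state, center in self.emission_centers.items():
            centers.setdefault(mapping.get(state, state), center)
        return replace(self, segments=segs, emission_centers=centers)

    def snap_to_frames(
        self, frame_interval: float, n_frames=None, min_frames: int = 1
    ) -> "StatePath":
        """Quantize segment boundaries onto the camera frame grid.

        Each frame takes its dominant-occupancy state; runs shorter than
        ``min_frames`` are absorbed into the preceding run (or following, for
        the first run). Used to build frame-exact ground truth against which
        frame-level inference can be compared without boundary ambiguity.
        """
        if n_frames is None:
            n_frames = int(round(self.duration / frame_interval))
        labels = self.frame_labels(n_frames, frame_interval)
        labels = _absorb_short_runs(labels, min_frames)
        return path_from_frame_labels(
            self.molecule_id,
            labels,
            frame_interval,
            source=self.source,
            emission_centers=self.emission_centers,
        )


def _absorb_short_runs(labels, min_frames):
    if min_frames <= 1:
        return labels
    labels = np.asarray(labels, dtype=object).copy()
    changed = True
    while changed:
        changed = False
        runs = _runs(labels)
        for i, (state, lo, hi) in enumerate(runs):
            if hi - lo < min_frames and len(runs) > 1:
                repl = runs[i - 1][0] if i > 0 else runs[i + 1][0]
                labels[lo:hi] = repl
                changed = True
                break
    return labels


def _runs(labels):
    runs = []
    lo = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[lo]:
            runs.append((labels[lo], lo, i))
            lo = i
    return runs


def occupancy_matrix(path: StatePath, n_frames: int, frame_interval: float, states):
    """Fractional occupancy of each state within each camera frame.

    Returns an ``(n_frames, len(states))`` array whose rows sum to 1 for
    frames fully covered by the path (and to the covered fraction otherwise).
    This is the camera-integration weight matrix used when rendering
    intensities from a continuous-time path.
    """
    dt = float(frame_interval)
    if dt <= 0:
        raise ParameterError("frame_interval must be positive")
    index = {s: j for j, s in enumerate(states)}
    W = np.zeros((n_frames, len(states)))
    for seg in path.segments:
        j = index[seg.state]
        f0 = max(int(np.floor(seg.start / dt + _EPS)), 0)
        f1 = min(int(np.ceil(seg.end / dt - _EPS)), n_frames)
        if f1 <= f0:
            continue
        fr = np.arange(f0, f1)
        lo = fr * dt
        overlap = np.minimum(lo + dt, seg.end) - np.maximum(lo, seg.start)
        W[fr, j] += overlap / dt
    return W


def path_from_frame_labels(
    molecule_id, labels, frame_interval, source="inferred", emission_centers=None
):
    """Build a StatePath from per-frame state labels (frame i = [i*dt, (i+1)*dt))."""
    labels = np.asarray(labels, dtype=object)
    if labels.size == 0:
        raise ParameterError("no frame labels")
    dt = float(frame_interval)
    segs = [
        Segment(state, lo * dt, hi * dt) for state, lo, hi in _runs(labels)
    ]
    return StatePath(
        molecule_id=molecule_id,
        segments=segs,
        source=source,
        emission_centers=dict(emission_centers or {}),
    )
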