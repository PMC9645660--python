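"""Frame-to-frame single-organoid tracking.

Detections in consecutive frames are matched by solving a minimum-cost
assignment problem: the cost of pairing a tracked organoid with a current
detection is the inverse of the number of pixels their masks share, so pairs
of similar shape and position are cheapest.  The cost matrix is padded with
pseudo-assignment rows/columns (cost ``pad_cost`` each) so that organoids may
disappear and new ones appear; the Hungarian (Munkres) algorithm finds the
optimal matching.  Tracks persist through up to ``max_missing`` unmatched
frames using their last-seen mask, then retire; retired track ids are never
reused.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

#: label value recorded for a frame where a track was not matched
MISSING = 0

#: zero-overlap pairs get this multiple of pad_cost, which makes a
#: disappearance+appearance (2 * pad_cost) strictly cheaper than a forced match
PROHIBITIVE_FACTOR = 10.0


def overlap_counts(prev: np.ndarray, curr: np.ndarray) -> np.ndarray:
    """Shared-pixel counts between labels of two labeled images.

    Entry (i, j) is the number of pixels where ``prev == i+1`` and
    ``curr == j+1``; shape is (prev.max(), curr.max()).
    """
    prev = np.asarray(prev)
    curr = np.asarray(curr)
    if prev.shape != curr.shape:
        raise ValueError("labeled images must have the same shape")
    n, m = int(prev.max()), int(curr.max())
    if n == 0 or m == 0:
        return np.zeros((n, m), dtype=np.int64)
    both = (prev > 0) & (curr > 0)
    joint = prev[both].astype(np.int64) * (m + 1) + curr[both]
    counts = np.bincount(joint, minlength=(n + 1) * (m + 1))
    return counts.reshape(n + 1, m + 1)[1:, 1:]


def build_cost_matrix(overlaps: np.ndarray, pad_cost: float = 1.0) -> np.ndarray:
    """Padded square cost matrix from a shared-pixel count matrix.

    Real entries are 1/overlap (a prohibitive finite constant where the
    overlap is zero).  The matrix is padded to (n+m) x (n+m): pad rows and
    columns carry ``pad_cost`` so every organoid can opt out of matching, and
    the pad-pad corner is free.
    """
    overlaps = np.asarray(overlaps, dtype=np.float64)
    if np.any(overlaps < 0):
        raise ValueError("overlap counts must be non-negative")
    n, m = overlaps.shape
    real = np.where(overlaps > 0, 1.0 / np.maximum(overlaps, 1e-300),
                    PROHIBITIVE_FACTOR * pad_cost)
    cost = np.zeros((n + m, n + m))
    cost[:n, :m] = real
    cost[:n, m:] = pad_cost
    cost[n:, :m] = pad_cost
    return cost


def solve_assignment(cost: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-cost one-to-one assignment (Hungarian/Munkres) of a square
    padded matrix; returns (row_indices, column_indices)."""
    cost = np.asarray(cost, dtype=np.float64)
    if cost.ndim != 2 or cost.shape[0] != cost.shape[1]:
        raise ValueError("cost matrix must be square (pad it first)")
    return linear_sum_assignment(cost)


class TrackTable:
    """Per-track, per-frame record of instance-label assignments.

    ``entries[track_id][frame]`` is the instance label in that frame, or
    ``MISSING`` (0) for frames where the track was present but unmatched.
    """

    def __init__(self):
        self.entries: dict[int, dict[int, int]] = {}
        self.birth: dict[int, int] = {}
        self.last_seen: dict[int, int] = {}
        self._next_id = 1

    def new_track(self, frame: int, label: int) -> int:
        tid = self._next_id
        self._next_id += 1
        self.entries[tid] = {frame: label}
        self.birth[tid] = frame
        self.last_seen[tid] = frame
        return tid

    def record(self, tid: int, frame: int, label: int) -> None:
        self.entries[tid][frame] = label
        if label != MISSING:
            self.last_seen[tid] = frame

    def track_ids(self) -> list[int]:
        return sorted(self.entries)

    def label_of(self, tid: int, frame: int) -> int | None:
        return self.entries[tid].get(frame)

    def labels_at(self, frame: int) -> dict[int, int]:
        """track id → instance label for tracks present (matched) at frame."""
        return {tid: fr[frame] for tid, fr in self.entries.items()
                if fr.get(frame, MISSING) != MISSING}

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"track_id": tid, "frame": f, "label": lab,
             "status": "present" if lab != MISSING else "missing"}
            for tid in sorted(self.entries)
            for f, lab in sorted(self.entries[tid].items())
        ]
        return pd.DataFrame(rows, columns=["track_id", "frame", "label", "status"])


def track_sequence(frames: list[np.ndarray], pad_cost: float = 1.0,
                   max_missing: int = 1) -> TrackTable:
    """Track labeled instances across a time-lapse sequence.

    Frame 0 instances seed tracks.  Each later frame is matched against the
    last-seen pixel masks of active tracks by minimum-cost assignment on
    inverse shared-pixel counts.  Unmatched detections open new tracks;
    unmatched tracks are marked MISSING and retire after ``max_missing``
    consecutive missed frames.
    """
    if len(frames) == 0:
        raise ValueError("empty frame sequence")
    shape = np.asarray(frames[0]).shape
    for f in frames:
        if np.asarray(f).shape != shape:
            raise ValueError("all frames must share one shape")

    table = TrackTable()
    # active: track id -> (last-seen boolean mask, consecutive missed count)
    active: dict[int, tuple[np.ndarray, int]] = {}
    first = np.asarray(frames[0])
    for lab in np.unique(first):
        if lab > 0:
            tid = table.new_track(0, int(lab))
            active[tid] = (first == lab, 0)

    for t in range(1, len(frames)):
        curr = np.asarray(frames[t])
        curr_labels = [int(v) for v in np.unique(curr) if v > 0]
        tids = sorted(active)
        n, m = len(tids), len(curr_labels)
        overlaps = np.zeros((n, m), dtype=np.int64)
        for i, tid in enumerate(tids):
            mask, _ = active[tid]
            counts = np.bincount(curr[mask], minlength=curr.max() + 1)
            for j, lab in enumerate(curr_labels):
                overlaps[i, j] = counts[lab]
        matched_tracks: dict[int, int] = {}
        if n or m:
            cost = build_cost_matrix(overlaps, pad_cost)
            rows, cols = solve_assignment(cost)
            for r, c in zip(rows, cols):
                if r < n and c < m and overlaps[r, c] > 0:
                    matched_tracks[tids[r]] = curr_labels[c]
        taken = set(matched_tracks.values())
        for tid in tids:
            if tid in matched_tracks:
                lab = matched_tracks[tid]
                table.record(tid, t, lab)
                active[tid] = (curr == lab, 0)
            else:
                mask, missed = active[tid]
                missed += 1
                table.record(tid, t, MISSING)
                if missed > max_missing:
                    del active[tid]
                else:
                    active[tid] = (mask, missed)
        for lab in curr_labels:
            if lab not in taken:
                tid = table.new_track(t, lab)
                active[tid] = (curr == lab, 0)
    return table


def relabel_stack(frames: list[np.ndarray], table: TrackTable) -> list[np.ndarray]:
    """Rewrite instance labels as persistent track ids (id-stable stack)."""
    out = []
    for t, frame in enumerate(frames):
        frame = np.asarray(frame)
        new = np.zeros_like(frame, dtype=np.int32)
        for tid, lab in table.labels_at(t).items():
            new[frame == lab] = tid
        out.append(new)
    return out
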