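"""Segmentation and per-channel normalization of recordings.

Recordings are cut into fixed-length non-overlapping windows (default eleven
30-s segments) and each segment channel is normalized to zero mean and unit
standard deviation before spectral decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from envtails.errors import DataError, ValidationError
from envtails.synthetic import Recording


@dataclass
class Segment:
    """A fixed-length window of a recording."""

    data: np.ndarray  # channels x samples
    fs: float
    start_time: float
    normalized: bool = False

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _gap_plan(slack: int, n_gaps: int) -> np.ndarray:
    """Split ``slack`` spare samples into n_gaps integer gaps that are as
    equal as possible (largest-remainder)."""
    if n_gaps == 0:
        return np.zeros(0, dtype=int)
    base, rem = divmod(slack, n_gaps)
    gaps = np.full(n_gaps, base, dtype=int)
    gaps[:rem] += 1
    return gaps


def extract_segments(
    recording: Recording,
    n_segments: int = 11,
    segment_length: float = 30.0,
    offset: float = 10.0,
    tiling: str = "even",
) -> list[Segment]:
    """Cut ``n_segments`` non-overlapping windows of ``segment_length`` seconds.

    Placement skips an initial ``offset`` (shrunk if the recording is only
    just long enough) and then either spreads the windows with equal gaps
    over the remaining span (``tiling="even"``, the default) or tiles them
    back to back (``tiling="contiguous"``).  Segments are returned in
    temporal order and their supports are pairwise disjoint.
    """
    if n_segments < 1:
        raise ValidationError("n_segments must be >= 1")
    if segment_length <= 0:
        raise ValidationError("segment_length must be > 0")
    if tiling not in ("even", "contiguous"):
        raise ValidationError(f"unknown tiling {tiling!r}")
    fs = recording.fs
    seg_samp = int(round(segment_length * fs))
    total = recording.data.shape[1]
    need = n_segments * seg_samp
    if need > total:
        raise DataError(
            f"recording {recording.participant_id} too short: needs "
            f"{need / fs:.1f} s for {n_segments} x {segment_length} s segments, "
            f"has {total / fs:.1f} s"
        )
    # shrink the offset if the recording cannot afford it
    off_samp = min(int(round(offset * fs)), total - need)
    off_samp = max(off_samp, 0)
    slack = total - off_samp - need
    if tiling == "even":
        gaps = _gap_plan(slack, n_segments - 1)
    else:
        gaps = np.zeros(n_segments - 1, dtype=int)
    starts = np.empty(n_segments, dtype=int)
    starts[0] = off_samp
    for i in range(1, n_segments):
        starts[i] = starts[i - 1] + seg_samp + gaps[i - 1]
    return [
        Segment(
            data=recording.data[:, s : s + seg_samp].copy(),
            fs=fs,
            start_time=s / fs,
        )
        for s in starts
    ]


def normalize_segment(segment: Segment) -> Segment:
    """Normalize every channel to mean 0 and (population) SD 1.

    Idempotent; raises :class:`DataError` naming the first constant channel,
    since a zero-variance channel cannot be scaled to unit SD.
    """
    mean = segment.data.mean(axis=1, keepdims=True)
    sd = segment.data.std(axis=1, keepdims=True)  # population SD (1/n)
    bad = np.flatnonzero(sd[:, 0] == 0)
    if bad.size:
        raise DataError(
            f"channel {bad[0]} is constant in segment at t={segment.start_time:.1f} s"
        )
    return replace(segment, data=(segment.data - mean) / sd, normalized=True)
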