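"""Tail statistics of amplitude-envelope time courses.

Every envelope time course is treated directly as an empirical distribution
(one realization per time point) and summarized by sample skewness
g1 = m3 / m2^{3/2} and Fisher excess kurtosis g2 = m4 / m2^2 - 3, with
central moments m_k = (1/n) sum (x - xbar)^k and no small-sample bias
correction by default (segments are tens of thousands of samples long, where
the correction is negligible).  Per-participant features are the median of
the per-segment values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from envtails.errors import DataError, ValidationError

METRICS = ("skewness", "kurtosis")


def _check_sample(x: np.ndarray, min_len: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError("expected a 1-D sample")
    if len(x) < min_len:
        raise ValidationError(f"need at least {min_len} observations, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise DataError("sample contains non-finite values")
    if np.ptp(x) == 0:
        raise DataError("sample has zero variance")
    return x


def sample_skewness(x: np.ndarray, bias: bool = True) -> float:
    """Sample skewness g1 = m3 / m2^(3/2)."""
    x = _check_sample(x, 3)
    return float(stats.skew(x, bias=bias))


def sample_excess_kurtosis(x: np.ndarray, bias: bool = True) -> float:
    """Fisher excess kurtosis g2 = m4 / m2^2 - 3 (0 for a normal sample)."""
    x = _check_sample(x, 4)
    return float(stats.kurtosis(x, fisher=True, bias=bias))


_METRIC_FN = {"skewness": sample_skewness, "kurtosis": sample_excess_kurtosis}


def aggregate_segments(per_segment_values: np.ndarray) -> float:
    """Median across segments (mean of the two central order statistics for
    even counts)."""
    v = np.asarray(per_segment_values, dtype=float)
    if v.size == 0:
        raise ValidationError("no segment values to aggregate")
    if not np.all(np.isfinite(v)):
        raise DataError("segment values contain non-finite entries")
    return float(np.median(v))


@dataclass
class TailFeatures:
    """Participants x channels matrix of one tail metric at one frequency."""

    metric: str
    frequency: float
    values: np.ndarray  # participants x channels
    participant_ids: list[str]

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValidationError(f"unknown metric {self.metric!r}")
        if self.values.ndim != 2:
            raise ValidationError("values must be participants x channels")
        if len(self.participant_ids) != self.values.shape[0]:
            raise ValidationError("one participant id per row is required")


def segment_metrics(envelopes: np.ndarray, metric: str) -> np.ndarray:
    """Apply one tail metric along the time axis of a (segments, channels,
    frequencies, time) envelope tensor -> (segments, channels, frequencies)."""
    if metric not in _METRIC_FN:
        raise ValidationError(f"unknown metric {metric!r}")
    flat = envelopes.reshape(-1, envelopes.shape[-1])
    if metric == "skewness":
        out = stats.skew(flat, axis=-1, bias=True)
    else:
        out = stats.kurtosis(flat, axis=-1, fisher=True, bias=True)
    return out.reshape(envelopes.shape[:-1])


def build_feature_block(
    cohort_envelopes: list[np.ndarray],
    metric: str,
    frequency: float,
    frequencies: tuple[float, ...],
    participant_ids: list[str] | None = None,
) -> TailFeatures:
    """Per-participant feature matrix for one (metric, frequency) analysis.

    ``cohort_envelopes`` holds one (segments, channels, frequencies, time)
    tensor per participant; entry [p, c] of the result is the median over
    segments of the metric applied to participant p's envelope at channel c
    and the requested frequency.
    """
    if metric not in _METRIC_FN:
        raise ValidationError(f"unknown metric {metric!r}")
    freqs = list(frequencies)
    if frequency not in freqs:
        raise ValidationError(f"frequency {frequency} not among analyzed {freqs}")
    fi = freqs.index(frequency)
    shapes = {env.shape[:3] for env in cohort_envelopes}
    if len(shapes) != 1:
        raise ValidationError(f"ragged cohort: envelope shapes {sorted(shapes)}")
    if participant_ids is None:
        participant_ids = [f"P{i:04d}" for i in range(len(cohort_envelopes))]
    rows = []
    for env in cohort_envelopes:
        per_seg = segment_metrics(env[:, :, fi : fi + 1, :], metric)[:, :, 0]
        rows.append(np.median(per_seg, axis=0))
    return TailFeatures(
        metric=metric,
        frequency=frequency,
        values=np.asarray(rows),
        participant_ids=list(participant_ids),
    )


def write_feature_block(
    block: TailFeatures,
    path: str | Path,
    n_segments: int | None = None,
    seed=None,
    config_hash: str | None = None,
) -> None:
    """Write a feature block as TSV (rows = participants) plus JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        block.values,
        index=pd.Index(block.participant_ids, name="participant_id"),
        columns=[f"ch{c:03d}" for c in range(block.values.shape[1])],
    )
    df.to_csv(path, sep="\t")
    sidecar = {
        "metric": block.metric,
        "frequency": block.frequency,
        "n_segments": n_segments,
        "seed": None if seed is None else int(seed),
        "config_hash": config_hash,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_feature_block(path: str | Path) -> TailFeatures:
    """Read a TSV feature block written by :func:`write_feature_block`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="participant_id", float_precision="round_trip")
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return TailFeatures(
        metric=sidecar["metric"],
        frequency=sidecar["frequency"],
        values=df.to_numpy(),
        participant_ids=[str(i) for i in df.index],
    )
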