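"""End-to-end orchestration: cohort -> envelope tail features -> PLS report.

One run performs ``len(frequencies) * len(metrics)`` group analyses (ten with
the defaults: five frequencies times skewness and kurtosis), each consisting
of a mean-centered SVD, a permutation test on the singular values and a
within-group bootstrap for the channel bootstrap ratios.  Only the first
latent variable is surfaced in the report (it explains the largest share of
the between-group variance); the full LV set stays in the per-analysis JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from envtails.errors import DataError, ValidationError
from envtails.preprocess import extract_segments, normalize_segment
from envtails.pls import average_site_scores, bootstrap_test, mean_centered_svd, permutation_test
from envtails.synthetic import AgeGroupDesign, Recording
from envtails.tails import METRICS, TailFeatures, segment_metrics
from envtails.wavelet import WaveletSpec, cwt_envelope

logger = logging.getLogger("envtails")


@dataclass
class AnalysisConfig:
    """Defaults of the full analysis; every field can be overridden."""

    frequencies: tuple[float, ...] = (2.0, 6.0, 10.5, 22.0, 39.0)
    metrics: tuple[str, ...] = ("skewness", "kurtosis")
    n_segments: int = 11
    segment_length: float = 30.0
    segment_offset: float = 10.0
    tiling: str = "even"
    wavelet_order: int = 8
    edge_policy: str = "keep"
    n_perm: int = 10000
    n_boot: int = 10000
    n_groups: int = 5
    seed: int = 0
    outdir: str | None = None

    def validate(self, fs: float | None = None) -> None:
        if self.n_segments < 1 or self.n_perm < 1 or self.n_boot < 2 or self.n_groups < 2:
            raise ValidationError("counts (segments, permutations, bootstraps, groups) too small")
        if self.segment_length <= 0:
            raise ValidationError("segment_length must be > 0")
        if any(m not in METRICS for m in self.metrics):
            raise ValidationError(f"metrics must be among {METRICS}")
        if fs is not None and any(f >= fs / 2 for f in self.frequencies):
            raise ValidationError(f"analysis frequencies must stay below Nyquist {fs / 2} Hz")
        # construct to trigger its own validation
        self.wavelet_spec()

    def wavelet_spec(self) -> WaveletSpec:
        return WaveletSpec(
            order=self.wavelet_order,
            center_frequencies=tuple(self.frequencies),
            edge_policy=self.edge_policy,
        )

    def hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class AnalysisReport:
    """Per-(frequency, metric) LV1 results plus run metadata."""

    analyses: dict  # (frequency, metric) -> result dict
    config_hash: str
    seed: int
    site_ids: np.ndarray
    site_positions: np.ndarray

    @property
    def n_analyses(self) -> int:
        return len(self.analyses)


def participant_features(recording: Recording, config: AnalysisConfig) -> np.ndarray:
    """Tail features of one participant: (metrics, channels, frequencies).

    Segments are extracted, normalized per channel, decomposed into
    frequency-specific amplitude envelopes, summarized per segment by each
    tail metric, and aggregated across segments by the median.
    """
    wspec = config.wavelet_spec()
    segments = extract_segments(
        recording,
        n_segments=config.n_segments,
        segment_length=config.segment_length,
        offset=config.segment_offset,
        tiling=config.tiling,
    )
    per_seg = {m: [] for m in config.metrics}
    for seg in segments:
        env = cwt_envelope(normalize_segment(seg), wspec)  # (C, F, T)
        for m in config.metrics:
            per_seg[m].append(segment_metrics(env[None], m)[0])  # (C, F)
    return np.stack([np.median(np.stack(per_seg[m]), axis=0) for m in config.metrics])


def cohort_feature_blocks(
    recordings: list[Recording], design: AgeGroupDesign, config: AnalysisConfig
) -> dict[tuple[float, str], TailFeatures]:
    """Feature matrices for every (frequency, metric) analysis of a cohort."""
    if not recordings:
        raise DataError("empty cohort")
    n_ch = {r.n_channels for r in recordings}
    if len(n_ch) != 1:
        raise DataError(f"inconsistent channel counts across cohort: {sorted(n_ch)}")
    config.validate(fs=recordings[0].fs)
    feats = []
    for rec in recordings:
        t0 = time.perf_counter()
        feats.append(participant_features(rec, config))
        logger.debug("features %s in %.2f s", rec.participant_id, time.perf_counter() - t0)
    feats = np.stack(feats)  # (P, metrics, channels, freqs)
    blocks: dict[tuple[float, str], TailFeatures] = {}
    for fi, freq in enumerate(config.frequencies):
        for mi, metric in enumerate(config.metrics):
            blocks[(freq, metric)] = TailFeatures(
                metric=metric,
                frequency=freq,
                values=feats[:, mi, :, fi],
                participant_ids=list(design.participant_ids),
            )
    return blocks


def analyze_block(
    block: TailFeatures,
    design: AgeGroupDesign,
    site_id: np.ndarray,
    n_perm: int,
    n_boot: int,
    perm_seed,
    boot_seed,
) -> dict:
    """One mean-centered PLS analysis of a feature block, fully serializable."""
    model = mean_centered_svd(block.values, design)
    perm = permutation_test(block.values, design, n_perm, perm_seed)
    boot = bootstrap_test(block.values, design, n_boot, boot_seed)
    _, site_bsr = average_site_scores(boot.bsr[:, 0], site_id)
    return {
        "frequency": block.frequency,
        "metric": block.metric,
        "contrast_lv1": model.contrasts[:, 0].tolist(),
        "contrasts": model.contrasts.tolist(),
        "singular_values": model.singular_values.tolist(),
        "explained": model.explained.tolist(),
        "p_values": perm.p_values.tolist(),
        "p_lv1": float(perm.p_values[0]),
        "bsr_lv1": boot.bsr[:, 0].tolist(),
        "site_bsr_lv1": site_bsr.tolist(),
        "n_perm": n_perm,
        "n_boot": n_boot,
    }


def run_full_analysis(
    recordings: list[Recording],
    design: AgeGroupDesign,
    config: AnalysisConfig,
) -> AnalysisReport:
    """Run every (frequency, metric) PLS analysis on a cohort.

    Deterministic under a fixed ``config.seed``: independent random streams
    for the permutation and bootstrap stages of each analysis are spawned
    from the master seed in a fixed order.  If ``config.outdir`` is set,
    per-analysis JSON, channel/site bootstrap-ratio TSVs, topography tables
    and a run log are written there.
    """
    t_start = time.perf_counter()
    config.validate(fs=recordings[0].fs if recordings else None)
    outdir = Path(config.outdir) if config.outdir else None
    handler = None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    try:
        return _run_full_analysis(recordings, design, config, outdir, t_start)
    finally:
        if handler is not None:
            logger.removeHandler(handler)
            handler.close()


def _run_full_analysis(
    recordings: list[Recording],
    design: AgeGroupDesign,
    config: AnalysisConfig,
    outdir: Path | None,
    t_start: float,
) -> AnalysisReport:
    cfg_hash = config.hash()
    logger.info("run start: %d recordings, config %s, seed %d", len(recordings), cfg_hash, config.seed)

    blocks = cohort_feature_blocks(recordings, design, config)
    logger.info("features done in %.1f s", time.perf_counter() - t_start)

    site_id = recordings[0].site_id
    positions = recordings[0].positions
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(2 * len(blocks))
    analyses: dict[tuple[float, str], dict] = {}
    for i, ((freq, metric), block) in enumerate(sorted(blocks.items())):
        t0 = time.perf_counter()
        result = analyze_block(
            block,
            design,
            site_id,
            config.n_perm,
            config.n_boot,
            perm_seed=children[2 * i],
            boot_seed=children[2 * i + 1],
        )
        result["config_hash"] = cfg_hash
        result["seed"] = config.seed
        analyses[(freq, metric)] = result
        logger.info(
            "PLS %g Hz %s: p=%.4g (%.1f s)", freq, metric, result["p_lv1"], time.perf_counter() - t0
        )
        if outdir:
            stem = f"pls_{metric}_{freq:g}Hz"
            (outdir / f"{stem}.json").write_text(json.dumps(result, indent=2))
            pd.DataFrame(
                {"channel": np.arange(len(result["bsr_lv1"])), "bsr_lv1": result["bsr_lv1"]}
            ).to_csv(outdir / f"{stem}_channels.tsv", sep="\t", index=False)
            site_vals = np.asarray(result["site_bsr_lv1"])
            export_topography(
                site_vals,
                _site_positions(positions, site_id),
                outdir / f"{stem}_topography.tsv",
                site_ids=np.unique(site_id),
            )

    report = AnalysisReport(
        analyses=analyses,
        config_hash=cfg_hash,
        seed=config.seed,
        site_ids=np.unique(site_id),
        site_positions=_site_positions(positions, site_id),
    )
    if outdir:
        summary = pd.DataFrame(
            [
                {
                    "frequency": f,
                    "metric": m,
                    "p_lv1": r["p_lv1"],
                    "explained_lv1": r["explained"][0],
                    "singular_value_lv1": r["singular_values"][0],
                }
                for (f, m), r in sorted(analyses.items())
            ]
        )
        summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    logger.info("run done in %.1f s (%d analyses)", time.perf_counter() - t_start, len(analyses))
    return report


def _site_positions(positions: np.ndarray, site_id: np.ndarray) -> np.ndarray:
    sites, inverse = np.unique(site_id, return_inverse=True)
    out = np.empty((len(sites), 2))
    for axis in range(2):
        out[:, axis] = np.bincount(inverse, weights=positions[:, axis]) / np.bincount(inverse)
    return out


def export_topography(
    site_values: np.ndarray,
    site_positions: np.ndarray,
    path: str | Path,
    site_ids: np.ndarray | None = None,
) -> None:
    """Write per-site values with 2-D positions as a TSV, sorted by site id."""
    site_values = np.asarray(site_values, dtype=float)
    site_positions = np.asarray(site_positions, dtype=float)
    if site_positions.ndim != 2 or site_positions.shape[0] != len(site_values):
        raise ValidationError("one 2-D position per site value is required")
    if site_ids is None:
        site_ids = np.arange(len(site_values))
    order = np.argsort(site_ids)
    pd.DataFrame(
        {
            "site_id": np.asarray(site_ids)[order],
            "x": site_positions[order, 0],
            "y": site_positions[order, 1],
            "value": site_values[order],
        }
    ).to_csv(path, sep="\t", index=False)


def read_topography(path: str | Path) -> pd.DataFrame:
    # round_trip parsing keeps the TSV <-> memory round trip bit-exact
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
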