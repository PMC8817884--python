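"""Correlation-based comparison of candidate depth indices.

Each candidate index series is compared against a reference depth series
(BIS-like, 0-100) by the Pearson correlation coefficient
COR = cov(x, y) / sqrt(var(x) var(y)); |COR| is banded as high (> 0.8),
moderate (0.5-0.8], low (0.3-0.5], none (<= 0.3), boundary values going to
the lower band.  The cohort-level comparison reports mean +/- SD of |COR|
across subjects per index, sorted descending — the protocol used to pick
the observation index that best tracks the reference monitor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CorrelationResult", "correlation", "classify_band", "index_comparison"]

BAND_THRESHOLDS = (0.8, 0.5, 0.3)  # high > 0.8 >= moderate > 0.5 >= low > 0.3 >= none


@dataclass
class CorrelationResult:
    index_name: str
    cor: float  # mean signed correlation across subjects
    abs_cor: float  # mean |COR| across subjects
    abs_cor_sd: float
    band: str
    per_subject: dict


def correlation(x, y) -> float:
    """Pearson correlation; NaN (undefined) when either input is constant."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.mean((x - np.mean(x)) * (y - np.mean(y))) / (sx * sy))


def classify_band(abs_cor: float) -> str:
    """Band label for |COR|; boundary values fall to the lower band."""
    if not (0 <= abs_cor <= 1):
        raise ValueError(f"|COR| must lie in [0, 1], got {abs_cor}")
    if abs_cor > BAND_THRESHOLDS[0]:
        return "high"
    if abs_cor > BAND_THRESHOLDS[1]:
        return "moderate"
    if abs_cor > BAND_THRESHOLDS[2]:
        return "low"
    return "none"


def index_comparison(
    feature_table: pd.DataFrame,
    reference_depth: dict,
    index_columns=None,
    align_tolerance: float = 2.0,
) -> list[CorrelationResult]:
    """Rank candidate indices by mean |COR| with the reference depth.

    ``feature_table`` holds per-epoch index values with ``subject_id`` and
    ``epoch_time`` columns; ``reference_depth`` maps subject_id to a
    DepthTrajectory.  Features and reference are joined per subject by
    nearest timestamp; a subject whose alignment gap exceeds
    ``align_tolerance`` seconds is skipped with a warning.  Results are
    sorted by mean |COR| descending.
    """
    import warnings

    if index_columns is None:
        index_columns = [
            c for c in feature_table.columns if c not in ("subject_id", "epoch_time")
        ]
    per_index: dict[str, dict] = {name: {} for name in index_columns}
    for sid, sub in feature_table.groupby("subject_id", sort=False):
        traj = reference_depth.get(sid)
        if traj is None:
            warnings.warn(f"subject {sid}: no reference depth, skipped")
            continue
        t = sub["epoch_time"].to_numpy(dtype=float)
        gaps = np.abs(
            t - traj.times[np.clip(np.searchsorted(traj.times, t), 0, len(traj.times) - 1)]
        )
        if gaps.max() > align_tolerance:
            warnings.warn(
                f"subject {sid}: alignment gap {gaps.max():.2f}s exceeds "
                f"tolerance {align_tolerance}s, skipped"
            )
            continue
        ref = traj.depth_at(t)
        for name in index_columns:
            c = correlation(sub[name].to_numpy(dtype=float), ref)
            if not np.isnan(c):
                per_index[name][sid] = c
    results = []
    for name in index_columns:
        vals = per_index[name]
        if not vals:
            continue
        cors = np.array(list(vals.values()))
        abs_mean = float(np.mean(np.abs(cors)))
        results.append(
            CorrelationResult(
                index_name=name,
                cor=float(np.mean(cors)),
                abs_cor=abs_mean,
                abs_cor_sd=float(np.std(np.abs(cors))),
                band=classify_band(min(abs_mean, 1.0)),
                per_subject=vals,
            )
        )
    results.sort(key=lambda r: r.abs_cor, reverse=True)
    return results


def write_comparison_report(results: list[CorrelationResult], path) -> None:
    """Delimited report: index name, mean |COR| +/- SD, band."""
    pd.DataFrame(
        {
            "index": [r.index_name for r in results],
            "abs_cor_mean": [r.abs_cor for r in results],
            "abs_cor_sd": [r.abs_cor_sd for r in results],
            "band": [r.band for r in results],
        }
    ).to_csv(path, index=False, float_format="%.4f")
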