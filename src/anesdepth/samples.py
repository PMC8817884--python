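"""Feature-image sample construction and subject-level cohort splitting.

The regressor consumes 24x24 "feature images": the 48 indicators of 12
consecutive epochs (periods), concatenated oldest-first in schema order
into a 576-vector and reshaped row-major.  The target is the reference
depth at the window's final period — a causal monitoring target.

Features are z-scored per indicator with statistics from the training
split only; the same statistics are applied unchanged to validation and
test so no information leaks across the split.  The split itself is by
subject, never by sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SampleImage",
    "CohortSplit",
    "Standardizer",
    "build_samples",
    "split_cohort",
    "write_samples",
    "read_samples",
]

IMAGE_SIDE = 24
IMAGE_SIZE = IMAGE_SIDE * IMAGE_SIDE  # 576
DEFAULT_PERIODS_PER_SAMPLE = 12


@dataclass
class SampleImage:
    """One 24x24 feature image with its regression target."""

    pixels: np.ndarray  # (24, 24)
    target: float  # depth in [0, 100]
    subject_id: str
    time: float  # seconds, end of the window
    phase: str = "maintenance"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (IMAGE_SIDE, IMAGE_SIDE):
            raise ValueError(f"pixels must be {IMAGE_SIDE}x{IMAGE_SIDE}")
        if not (0 <= self.target <= 100):
            raise ValueError(f"target must lie in [0, 100], got {self.target}")

    def flatten(self) -> np.ndarray:
        """Row-major 576-vector; inverse of the construction reshape."""
        return self.pixels.reshape(IMAGE_SIZE)


@dataclass
class CohortSplit:
    train: list
    validation: list
    test: list

    def __post_init__(self) -> None:
        groups = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("split groups must be disjoint")

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.train), len(self.validation), len(self.test)


@dataclass
class Standardizer:
    """Per-indicator z-scoring frozen on the training split."""

    mean: np.ndarray
    std: np.ndarray
    columns: list = field(default_factory=list)

    @classmethod
    def fit(cls, table: pd.DataFrame, columns) -> "Standardizer":
        x = table[list(columns)].to_numpy(dtype=float)
        std = x.std(axis=0)
        std[std == 0] = 1.0  # constant indicator: centered, not scaled
        return cls(mean=x.mean(axis=0), std=std, columns=list(columns))

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        x = out[self.columns].to_numpy(dtype=float)
        out[self.columns] = (x - self.mean) / self.std
        return out


def build_samples(
    feature_table: pd.DataFrame,
    reference_depth: dict,
    periods_per_sample: int = DEFAULT_PERIODS_PER_SAMPLE,
    stride: int = 1,
    standardizer: Standardizer | None = None,
) -> list[SampleImage]:
    """Slide a window of consecutive periods into 24x24 samples.

    ``feature_table`` must carry ``subject_id`` and ``epoch_time`` plus the
    indicator columns in schema order; indicator count x
    ``periods_per_sample`` must equal 576.  ``reference_depth`` maps
    subject_id to a DepthTrajectory supplying target and phase at each
    window end.  Pass a fitted :class:`Standardizer` to z-score (fit it on
    the training subjects only).
    """
    feature_cols = [
        c for c in feature_table.columns if c not in ("subject_id", "epoch_time")
    ]
    n_ind = len(feature_cols)
    if n_ind * periods_per_sample != IMAGE_SIZE:
        raise ValueError(
            f"indicator count ({n_ind}) x periods_per_sample "
            f"({periods_per_sample}) must equal {IMAGE_SIZE}"
        )
    if standardizer is not None:
        feature_table = standardizer.transform(feature_table)
    samples: list[SampleImage] = []
    for sid, sub in feature_table.groupby("subject_id", sort=False):
        traj = reference_depth[sid]
        values = sub[feature_cols].to_numpy(dtype=float)
        times = sub["epoch_time"].to_numpy(dtype=float)
        n_periods = len(sub)
        for start in range(0, n_periods - periods_per_sample + 1, stride):
            window = values[start : start + periods_per_sample]  # oldest first
            t_end = times[start + periods_per_sample - 1]
            vec = window.reshape(IMAGE_SIZE)  # row-major: period-major order
            samples.append(
                SampleImage(
                    pixels=vec.reshape(IMAGE_SIDE, IMAGE_SIDE),
                    target=float(np.clip(traj.depth_at(t_end), 0, 100)),
                    subject_id=sid,
                    time=float(t_end),
                    phase=str(traj.phase_at(np.array([t_end]))[0]),
                )
            )
    return samples


def split_cohort(subject_ids, sizes=(61, 16, 16), seed: int = 0) -> CohortSplit:
    """Seeded uniform random partition of subjects into train/val/test."""
    subject_ids = list(subject_ids)
    if sum(sizes) != len(subject_ids):
        raise ValueError(
            f"split sizes {sizes} must sum to cohort size {len(subject_ids)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subject_ids))
    shuffled = [subject_ids[i] for i in order]
    n_tr, n_va, _ = sizes
    return CohortSplit(
        train=shuffled[:n_tr],
        validation=shuffled[n_tr : n_tr + n_va],
        test=shuffled[n_tr + n_va :],
    )


def write_samples(samples: list[SampleImage], path) -> None:
    """One row per sample: metadata + the flattened 576-vector."""
    rows = []
    for s in samples:
        row = {"subject_id": s.subject_id, "time": s.time, "phase": s.phase,
               "target": s.target}
        row.update({f"px{i}": v for i, v in enumerate(s.flatten())})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_samples(path) -> list[SampleImage]:
    df = pd.read_csv(path)
    px_cols = [c for c in df.columns if c.startswith("px")]
    if len(px_cols) != IMAGE_SIZE:
        raise ValueError(f"sample store must carry exactly {IMAGE_SIZE} pixel columns")
    px_cols = sorted(px_cols, key=lambda c: int(c[2:]))
    return [
        SampleImage(
            pixels=row[px_cols].to_numpy(dtype=float).reshape(IMAGE_SIDE, IMAGE_SIDE),
            target=float(row["target"]),
            subject_id=str(row["subject_id"]),
            time=float(row["time"]),
            phase=str(row["phase"]),
        )
        for _, row in df.iterrows()
    ]
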