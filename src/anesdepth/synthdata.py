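"""Seeded synthetic anesthesia cohorts.

No public recording of propofol EEG with paired reference depth exists for
this pipeline, so the generator emulates the *structure* such data must
have for the method to be exercised end-to-end:

- a latent depth trajectory on [0, 100] (100 = awake) with three
  contiguous phases: induction (falling), maintenance (low plateau with
  slow wander), recovery (rising);
- single-channel EEG built from three band-limited Gaussian noise
  components (slow 0.5-4 Hz, mid 6-12 Hz, fast 15-42 Hz) whose gains are
  log-linear in the latent depth: fast power rises and slow power falls as
  the subject lightens, so the alpha ratio, SEF95 and the entropies move
  in the direction they are used clinically;
- a regularity component: the deeper the subject, the stronger a smoothing
  AR(1) filter applied to the fast component, lowering sample and
  permutation entropy at depth;
- a reference "BIS-like" series = latent depth + bounded observation noise
  (SD 3), clipped to [0, 100];
- demographics drawn within the published cohort ranges (height 158-180 cm,
  weight 54-93 kg, age 22-83 yr, male fraction ~0.73).

Everything is a pure function of the seed.  The generator makes no claim
of physiological realism beyond these monotone spectral/regularity
contracts; see the methods note for what that implies for test evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from anesdepth.preprocess import RawRecording, DepthTrajectory

__all__ = ["SubjectProfile", "GeneratorSpec", "simulate_subject", "simulate_cohort"]


@dataclass
class SubjectProfile:
    """Demographic covariates for one synthetic subject."""

    height: float  # cm
    weight: float  # kg
    age: float  # years
    sex: int  # 1 = male, 0 = female

    HEIGHT_RANGE = (158.0, 180.0)
    WEIGHT_RANGE = (54.0, 93.0)
    AGE_RANGE = (22.0, 83.0)

    def __post_init__(self) -> None:
        if not self.HEIGHT_RANGE[0] <= self.height <= self.HEIGHT_RANGE[1]:
            raise ValueError(f"height {self.height} outside cohort range")
        if not self.WEIGHT_RANGE[0] <= self.weight <= self.WEIGHT_RANGE[1]:
            raise ValueError(f"weight {self.weight} outside cohort range")
        if not self.AGE_RANGE[0] <= self.age <= self.AGE_RANGE[1]:
            raise ValueError(f"age {self.age} outside cohort range")


@dataclass
class GeneratorSpec:
    """Cohort-level generator settings.

    ``phase_duration`` seconds per phase (induction, maintenance,
    recovery); ``depth_awake``/``depth_deep`` anchor the trajectory;
    ``ratio_span`` is the log10 fast/slow gain swing across the full depth
    range; ``ar_deep`` the AR(1) smoothing coefficient at maximum depth;
    ``obs_noise_sd`` the reference-monitor observation noise.
    """

    n_subjects: int = 93
    fs: float = 125.0
    phase_duration: float = 120.0
    depth_awake: float = 92.0
    depth_deep: float = 32.0
    ratio_span: float = 1.6
    ar_deep: float = 0.85
    noise_sd: float = 1.0
    obs_noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("fs", "phase_duration", "noise_sd", "obs_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.ar_deep < 1:
            raise ValueError("ar_deep must lie in [0, 1)")


def _depth_trajectory(spec: GeneratorSpec, rng: np.random.Generator, times):
    """Piecewise-smooth latent depth with the three clinical phases."""
    T = spec.phase_duration
    awake = spec.depth_awake + rng.normal(0, 2)
    deep = spec.depth_deep + rng.normal(0, 2)
    t = np.asarray(times)
    depth = np.empty_like(t)
    phase = np.empty(t.shape, dtype=object)

    ind = t < T
    mnt = (t >= T) & (t < 2 * T)
    rec = t >= 2 * T
    # induction: smooth sigmoid fall awake -> deep
    u = (t[ind] - T / 2) / (T / 8)
    depth[ind] = deep + (awake - deep) / (1 + np.exp(u))
    phase[ind] = "induction"
    # maintenance: plateau with slow wander
    wander = 3.0 * np.sin(2 * np.pi * (t[mnt] - T) / T * rng.uniform(0.8, 1.4))
    depth[mnt] = deep + wander
    phase[mnt] = "maintenance"
    # recovery: smooth rise deep -> awake
    u = (t[rec] - 2.5 * T) / (T / 8)
    depth[rec] = deep + (awake - deep) / (1 + np.exp(-u))
    phase[rec] = "recovery"
    return np.clip(depth, 0, 100), phase


def _bandlimited_noise(rng, n, fs, lo, hi):
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    s = x.std()
    return x / s if s > 0 else x


def simulate_subject(
    profile: SubjectProfile, spec: GeneratorSpec, seed: int, subject_id: str = "S0"
) -> tuple[RawRecording, DepthTrajectory]:
    """One synthetic recording with its ground-truth depth trajectory.

    The returned trajectory's ``depth`` is the *observed* (BIS-like)
    reference: latent depth plus clipped observation noise.  Spectral gains
    follow the latent depth: log10 gains of the fast and slow components
    are linear in depth with opposite signs, and the fast component is
    AR(1)-smoothed with a coefficient growing as depth falls.
    """
    rng = np.random.default_rng(seed)
    n = int(round(3 * spec.phase_duration * spec.fs))
    t = np.arange(n) / spec.fs
    latent, phase = _depth_trajectory(spec, rng, t)

    # depth normalized to [0, 1]: 1 = awake
    d01 = latent / 100.0
    half_span = spec.ratio_span / 2.0
    gain_fast = 10 ** (half_span * (d01 - 0.6))
    gain_slow = 10 ** (-half_span * (d01 - 0.6))

    slow = _bandlimited_noise(rng, n, spec.fs, 0.5, 4.0)
    mid = _bandlimited_noise(rng, n, spec.fs, 6.0, 12.0)
    fast = _bandlimited_noise(rng, n, spec.fs, 15.0, 42.0)

    # regularity: stronger AR(1) smoothing of the fast component at depth
    a = spec.ar_deep * (1.0 - d01)
    smoothed = np.empty_like(fast)
    prev = 0.0
    coef = np.clip(a, 0.0, 0.99)
    for i in range(n):  # time-varying one-pole filter
        prev = coef[i] * prev + (1.0 - coef[i]) * fast[i]
        smoothed[i] = prev
    fast = smoothed / max(smoothed.std(), 1e-12)

    eeg = (
        gain_slow * slow
        + 0.6 * mid
        + gain_fast * fast
        + spec.noise_sd * 0.2 * rng.standard_normal(n)
    )
    eeg *= 10.0  # microvolt-ish scale

    observed = np.clip(latent + rng.normal(0, spec.obs_noise_sd, size=n), 0, 100)
    rec = RawRecording(eeg, spec.fs, subject_id=subject_id)
    traj = DepthTrajectory(times=t, depth=observed, phase=phase)
    return rec, traj


def simulate_cohort(
    spec: GeneratorSpec | None = None,
) -> list[tuple[RawRecording, DepthTrajectory, SubjectProfile]]:
    """Independent seeded subjects with demographics in cohort ranges."""
    spec = spec or GeneratorSpec()
    rng = np.random.default_rng(spec.seed)
    cohort = []
    for i in range(spec.n_subjects):
        profile = SubjectProfile(
            height=float(rng.uniform(*SubjectProfile.HEIGHT_RANGE)),
            weight=float(rng.uniform(*SubjectProfile.WEIGHT_RANGE)),
            age=float(rng.uniform(*SubjectProfile.AGE_RANGE)),
            sex=int(rng.random() < 0.73),
        )
        sub_seed = int(rng.integers(0, 2**31 - 1))
        rec, traj = simulate_subject(profile, spec, sub_seed, subject_id=f"S{i:03d}")
        cohort.append((rec, traj, profile))
    return cohort
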