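"""Per-epoch EEG indices used as depth-of-anesthesia indicators.

Three entropy families quantify signal regularity (regularity rises, hence
entropy falls, as anesthesia deepens):

- sample entropy, ``-ln(A(m+1,r)/A(m,r))`` with Chebyshev distance and
  self-matches excluded (Richman-Moorman convention); defaults m=2,
  r=0.2 x epoch SD, window N=500;
- permutation ("sort") entropy, the Shannon entropy of ordinal-pattern
  frequencies normalized by log(m!); defaults m=4, tau=1;
- wavelet entropy, the Shannon entropy of relative wavelet energies
  across decomposition scales; default db4, 5 levels (6 scales including
  the final approximation).

Spectral indices compare power in fixed bands: the alpha ratio
log10(E[30-42.5]/E[6-12]), beta ratio log10(E[30-42.5]/E[12-21]) and
(beta-alpha) ratio log10(E[6-12]/E[11-21]); the 11-21 Hz denominator is the
published band and a 12-21 Hz variant is selectable.  MPF and SEF95 are the
50% and 95% spectral quantiles on (0, 47] Hz.

ApEn, SFS and SpEn have no public defining formulas in the monitoring
literature they come from; the versions here are documented surrogates
(standard approximate entropy; a fast/slow log power ratio; the Shannon
entropy of the normalized PSD) and are flagged ``surrogate`` in the schema.

The full indicator schema pads these with sub-band powers, wavelet relative
energies, Hjorth parameters and simple waveform statistics to reach a
configurable indicator count (default 48 including the four demographic
covariates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps
from scipy import stats as spstats

from anesdepth.preprocess import EpochedSignal

__all__ = [
    "EntropyParams",
    "SpectralBands",
    "sample_entropy",
    "permutation_entropy",
    "wavelet_entropy",
    "wavelet_relative_energies",
    "band_power",
    "band_ratio",
    "spectral_summaries",
    "spectral_summaries_from_psd",
    "stft_spectrogram",
    "surrogate_indices",
    "approximate_entropy",
    "feature_schema",
    "extract_features",
    "write_feature_table",
    "read_feature_table",
]

SPECTRUM_F_MAX = 47.0  # upper edge of the analysis band, Hz


@dataclass
class EntropyParams:
    """Embedding and decomposition parameters for the entropy indices."""

    sampen_m: int = 2
    sampen_r: float = 0.2  # fraction of epoch SD
    sampen_N: int = 500
    pe_m: int = 4
    pe_tau: int = 1
    we_wavelet: str = "db4"
    we_levels: int = 5

    def __post_init__(self) -> None:
        if self.sampen_m < 1:
            raise ValueError("sampen_m must be >= 1")
        if self.sampen_r <= 0:
            raise ValueError("sampen_r must be positive")
        if self.pe_m < 2:
            raise ValueError("pe_m must be >= 2")
        if self.pe_tau < 1:
            raise ValueError("pe_tau must be >= 1")
        if self.we_levels < 1:
            raise ValueError("we_levels must be >= 1")


@dataclass
class SpectralBands:
    """Frequency bands (Hz) entering the three log band ratios."""

    alpha_num: tuple = (30.0, 42.5)
    alpha_den: tuple = (6.0, 12.0)
    beta_num: tuple = (30.0, 42.5)
    beta_den: tuple = (12.0, 21.0)
    bma_num: tuple = (6.0, 12.0)
    bma_den: tuple = (11.0, 21.0)  # published band; (12, 21) variant selectable

    def validate(self, fs: float) -> None:
        for name, (lo, hi) in self.__dict__.items():
            if not (0 <= lo < hi <= fs / 2):
                raise ValueError(f"band {name} = ({lo}, {hi}) invalid for fs={fs}")


# ---------------------------------------------------------------------------
# entropies


def _check_vector(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty input vector")
    return x


def sample_entropy(x, m: int = 2, r: float | None = None) -> float:
    """Sample entropy with Chebyshev distance, self-matches excluded.

    ``r`` is in the units of ``x``; pass ``None`` for the 0.2 x SD
    convention.  Returns NaN (undefined) when no template pairs match at
    either length.
    """
    x = _check_vector(x)
    N = x.size
    if N <= m + 1:
        raise ValueError(f"need N > m+1 = {m + 1}, got N = {N}")
    if r is None:
        r = 0.2 * float(np.std(x))
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    # templates of length m and m+1, both over the first N-m start points
    # so the count ratio is a conditional probability
    n_templates = N - m
    idx = np.arange(n_templates)
    tm = x[idx[:, None] + np.arange(m)[None, :]]
    tm1 = x[idx[:, None] + np.arange(m + 1)[None, :]]
    dm = np.max(np.abs(tm[:, None, :] - tm[None, :, :]), axis=-1)
    dm1 = np.max(np.abs(tm1[:, None, :] - tm1[None, :, :]), axis=-1)
    off = ~np.eye(n_templates, dtype=bool)
    B = int(np.count_nonzero((dm <= r) & off))
    A = int(np.count_nonzero((dm1 <= r) & off))
    if A == 0 or B == 0:
        return float("nan")
    return -math.log(A / B)


def approximate_entropy(x, m: int = 2, r: float | None = None) -> float:
    """Approximate entropy (self-matches included): Phi^m - Phi^{m+1}."""
    x = _check_vector(x)
    N = x.size
    if N <= m + 1:
        raise ValueError(f"need N > m+1 = {m + 1}, got N = {N}")
    if r is None:
        r = 0.2 * float(np.std(x))
    if r <= 0:
        raise ValueError("tolerance r must be positive")

    def phi(mm: int) -> float:
        n = N - mm + 1
        tmpl = x[np.arange(n)[:, None] + np.arange(mm)[None, :]]
        d = np.max(np.abs(tmpl[:, None, :] - tmpl[None, :, :]), axis=-1)
        c = np.count_nonzero(d <= r, axis=1) / n
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def permutation_entropy(x, m: int = 4, tau: int = 1) -> float:
    """Normalized permutation entropy in [0, 1].

    Shannon entropy of the ordinal-pattern distribution of length-``m``
    windows at lag ``tau``, normalized by log(m!).  0 for a monotone
    sequence (single pattern), 1 for a uniform pattern distribution.
    """
    x = _check_vector(x)
    if m < 2:
        raise ValueError("order m must be >= 2")
    if m > 8:
        raise ValueError("order m must be <= 8 (m! patterns must be enumerable)")
    if tau < 1:
        raise ValueError("lag tau must be >= 1")
    n_win = x.size - (m - 1) * tau
    if n_win < 2:
        raise ValueError(
            f"need length >= (m-1)*tau + 2 = {(m - 1) * tau + 2}, got {x.size}"
        )
    windows = x[np.arange(n_win)[:, None] + np.arange(m)[None, :] * tau]
    # ordinal pattern = permutation that sorts the window (ties by position)
    patterns = np.argsort(windows, axis=1, kind="stable")
    # encode each pattern as an integer in base m
    codes = (patterns * (m ** np.arange(m))[None, :]).sum(axis=1)
    counts = np.unique(codes, return_counts=True)[1]
    p = counts / counts.sum()
    H = -np.sum(p * np.log(p))
    return float(H / math.log(math.factorial(m)))


def wavelet_relative_energies(
    x, wavelet: str = "db4", levels: int = 5
) -> np.ndarray:
    """Relative wavelet energies P_j over detail scales + final approximation.

    Returned in order [approximation, detail_levels ... detail_1]; sums to 1.
    """
    x = _check_vector(x)
    if wavelet not in pywt.wavelist(kind="discrete"):
        raise ValueError(
            f"unknown wavelet {wavelet!r}; supported discrete bases: "
            f"{', '.join(pywt.wavelist(kind='discrete')[:20])}, ..."
        )
    max_level = pywt.dwt_max_level(x.size, pywt.Wavelet(wavelet).dec_len)
    if levels > max_level:
        raise ValueError(
            f"signal of length {x.size} supports at most {max_level} "
            f"decomposition levels with {wavelet}"
        )
    # periodization keeps the transform orthogonal, so scale energies
    # partition the signal energy exactly
    coeffs = pywt.wavedec(x, wavelet, level=levels, mode="periodization")
    energies = np.array([float(np.sum(c**2)) for c in coeffs])
    total = energies.sum()
    if total == 0:
        raise ValueError("zero-energy signal has no wavelet energy distribution")
    return energies / total


def wavelet_entropy(x, wavelet: str = "db4", levels: int = 5) -> float:
    """Shannon entropy (natural log) of the relative wavelet energies.

    Bounded by [0, log(levels + 1)] since levels detail scales plus the
    approximation give J = levels + 1 scales.
    """
    p = wavelet_relative_energies(x, wavelet, levels)
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


# ---------------------------------------------------------------------------
# spectra


def _welch_psd(x, fs: float) -> tuple[np.ndarray, np.ndarray]:
    x = _check_vector(x)
    nperseg = min(x.size, 256)
    return sps.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)


def _psd_band_power(f, psd, f_lo, f_hi) -> float:
    df = f[1] - f[0]
    mask = (f >= f_lo) & (f < f_hi)
    if not mask.any():
        raise ValueError(
            f"band ({f_lo}, {f_hi}) Hz contains no spectral bins at "
            f"resolution {df:.4g} Hz"
        )
    return float(np.sum(psd[mask]) * df)


def band_power(x, fs: float, f_lo: float, f_hi: float) -> float:
    """Integrated Welch PSD over [f_lo, f_hi) Hz.

    Rectangle integration over PSD bins, so power is exactly additive over
    a partition of (0, fs/2) and the total approximates signal variance.
    """
    if not (0 <= f_lo < f_hi <= fs / 2):
        raise ValueError(f"band ({f_lo}, {f_hi}) must lie within [0, fs/2]")
    f, psd = _welch_psd(x, fs)
    return _psd_band_power(f, psd, f_lo, f_hi)


def band_ratio(x, fs: float, num_band, den_band) -> float:
    """log10 power ratio between two bands; NaN when the denominator is 0."""
    p_num = band_power(x, fs, *num_band)
    p_den = band_power(x, fs, *den_band)
    if p_den == 0 or p_num == 0:
        return float("nan")
    return math.log10(p_num / p_den)


def _psd_quantile(f, psd, q: float, f_max: float = SPECTRUM_F_MAX) -> float:
    mask = (f > 0) & (f <= f_max)
    f, psd = f[mask], psd[mask]
    cum = np.cumsum(psd)
    total = cum[-1]
    if total == 0:
        return float("nan")
    return float(np.interp(q * total, cum, f))


def spectral_summaries_from_psd(f, psd) -> tuple[float, float]:
    """(MPF, SEF95) from an explicit PSD on a frequency grid."""
    f = np.asarray(f, dtype=float)
    psd = np.asarray(psd, dtype=float)
    return _psd_quantile(f, psd, 0.5), _psd_quantile(f, psd, 0.95)


def spectral_summaries(x, fs: float) -> tuple[float, float]:
    """Median power frequency and 95% spectral edge frequency on (0, 47] Hz.

    MPF is the frequency below which half the power lies; SEF95 the 95%
    point; MPF <= SEF95 always.  Returns (NaN, NaN) for an all-zero epoch.
    """
    x = _check_vector(x)
    if not np.any(x):
        return float("nan"), float("nan")
    f, psd = _welch_psd(x, fs)
    return spectral_summaries_from_psd(f, psd)


def stft_spectrogram(
    x, fs: float, win_len: int, hop: int, window: str = "hann"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Squared-magnitude short-time Fourier transform.

    Returns (freqs, times, S) with S of shape (n_freqs, n_cols) and
    ``n_cols = floor((L - win_len)/hop) + 1``; times are window centers.
    Squared magnitudes, no per-window normalization, so
    ``sum(S) * 2 / sum(w^2)`` approximates total signal energy (one-sided
    spectrum, window correction).
    """
    x = _check_vector(x)
    L = x.size
    if not (1 <= hop <= win_len <= L):
        raise ValueError(
            f"need 1 <= hop <= win_len <= L, got hop={hop}, win_len={win_len}, L={L}"
        )
    w = sps.get_window(window, win_len, fftbins=True)
    n_cols = (L - win_len) // hop + 1
    starts = np.arange(n_cols) * hop
    frames = x[starts[:, None] + np.arange(win_len)[None, :]] * w[None, :]
    S = np.abs(np.fft.rfft(frames, axis=1)) ** 2  # (n_cols, n_freqs)
    freqs = np.fft.rfftfreq(win_len, d=1.0 / fs)
    times = (starts + win_len / 2) / fs
    return freqs, times, S.T


def surrogate_indices(x, fs: float) -> tuple[float, float, float]:
    """(ApEn, SFS, SpEn) surrogate sub-parameters.

    ApEn: standard approximate entropy (m=2, r=0.2 x SD).
    SFS ("synch fast slow"): log10 of broadband (0.5-47 Hz) over fast-band
    (40-47 Hz) power — a documented stand-in relating slow and fast
    activity, not the proprietary bispectral sub-parameter.
    SpEn: Shannon entropy (natural log) of the normalized PSD on (0, 47] Hz.
    """
    x = _check_vector(x)
    apen = approximate_entropy(x, m=2)
    f, psd = _welch_psd(x, fs)
    p_broad = _psd_band_power(f, psd, 0.5, min(SPECTRUM_F_MAX, fs / 2))
    p_fast = _psd_band_power(f, psd, 40.0, min(SPECTRUM_F_MAX, fs / 2))
    sfs = math.log10(p_broad / p_fast) if p_fast > 0 and p_broad > 0 else float("nan")
    mask = (f > 0) & (f <= SPECTRUM_F_MAX)
    p = psd[mask]
    tot = p.sum()
    if tot == 0:
        spen = float("nan")
    else:
        p = p[p > 0] / tot
        spen = float(-np.sum(p * np.log(p)))
    return apen, sfs, spen


# ---------------------------------------------------------------------------
# feature schema and extraction

SUB_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta1": (12.0, 21.0),
    "beta2": (21.0, 30.0),
    "gamma": (30.0, 42.5),
}

COVARIATES = ("height", "weight", "age", "sex")


@dataclass
class FeatureSpec:
    name: str
    surrogate: bool = False


def feature_schema(n_indicators: int = 48) -> list[FeatureSpec]:
    """Ordered indicator schema: EEG indices first, covariates last.

    The named indices are augmented with sub-band powers, wavelet relative
    energies, extra entropy orders, Hjorth parameters and waveform
    statistics so that ``n_indicators`` (including the 4 covariates) is
    reached; the order is fixed and shared by feature tables and samples.
    """
    eeg: list[FeatureSpec] = [
        FeatureSpec("SampEn"),
        FeatureSpec("PeEn"),
        FeatureSpec("WE"),
        FeatureSpec("alpha_ratio"),
        FeatureSpec("beta_ratio"),
        FeatureSpec("bma_ratio"),
        FeatureSpec("SFS", surrogate=True),
        FeatureSpec("MPF"),
        FeatureSpec("SEF95"),
        FeatureSpec("ApEn", surrogate=True),
        FeatureSpec("SpEn", surrogate=True),
    ]
    eeg += [FeatureSpec(f"logP_{b}") for b in SUB_BANDS]
    eeg += [FeatureSpec(f"relP_{b}") for b in SUB_BANDS]
    eeg += [FeatureSpec(f"PeEn_m{m}") for m in (3, 5, 6)]
    eeg += [FeatureSpec("SampEn_m3")]
    eeg += [FeatureSpec(f"wavP_{j}") for j in range(6)]
    eeg += [
        FeatureSpec("SEF90"),
        FeatureSpec("peak_freq"),
        FeatureSpec("spec_centroid"),
        FeatureSpec("spec_bandwidth"),
        FeatureSpec("hjorth_activity"),
        FeatureSpec("hjorth_mobility"),
        FeatureSpec("hjorth_complexity"),
        FeatureSpec("zero_cross_rate"),
        FeatureSpec("rms_amplitude"),
        FeatureSpec("line_length"),
        FeatureSpec("kurtosis"),
    ]
    n_eeg = n_indicators - len(COVARIATES)
    if n_eeg < 11:
        raise ValueError("n_indicators must allow at least the 11 named indices")
    if n_eeg > len(eeg):
        raise ValueError(
            f"schema supports at most {len(eeg) + len(COVARIATES)} indicators"
        )
    return eeg[:n_eeg] + [FeatureSpec(c) for c in COVARIATES]


def _epoch_features(
    x: np.ndarray,
    fs: float,
    params: EntropyParams,
    bands: SpectralBands,
    names: list[str],
) -> dict[str, float]:
    f, psd = _welch_psd(x, fs)
    nyq = fs / 2
    f_max = min(SPECTRUM_F_MAX, nyq)
    vals: dict[str, float] = {}

    def bp(lo, hi):
        return _psd_band_power(f, psd, lo, min(hi, nyq))

    def logratio(num, den):
        pn, pdn = bp(*num), bp(*den)
        return math.log10(pn / pdn) if pn > 0 and pdn > 0 else float("nan")

    r_abs = params.sampen_r * float(np.std(x))
    total = bp(0.0, f_max)
    _cache: dict[str, object] = {}

    def surrogates():
        if "surr" not in _cache:
            _cache["surr"] = surrogate_indices(x, fs)
        return _cache["surr"]

    def wav_p():
        if "wavp" not in _cache:
            _cache["wavp"] = wavelet_relative_energies(
                x, params.we_wavelet, params.we_levels
            )
        return _cache["wavp"]
    dx = np.diff(x)
    var_x, var_dx = float(np.var(x)), float(np.var(dx))
    mob = math.sqrt(var_dx / var_x) if var_x > 0 else float("nan")

    for name in names:
        if name in COVARIATES:
            continue
        try:
            vals[name] = _one_feature(
                name, x, fs, f, psd, f_max, params, bands, r_abs, total,
                dx, var_x, var_dx, mob, bp, logratio, surrogates, wav_p,
            )
        except ValueError:  # degenerate epoch: undefined index, imputed later
            vals[name] = float("nan")
    return vals


def _one_feature(
    name, x, fs, f, psd, f_max, params, bands, r_abs, total,
    dx, var_x, var_dx, mob, bp, logratio, surrogates, wav_p,
):
    if name == "SampEn":
        v = sample_entropy(x, params.sampen_m, r_abs) if r_abs > 0 else float("nan")
    elif name == "SampEn_m3":
        v = sample_entropy(x, 3, r_abs) if r_abs > 0 else float("nan")
    elif name == "PeEn":
        v = permutation_entropy(x, params.pe_m, params.pe_tau)
    elif name.startswith("PeEn_m"):
        v = permutation_entropy(x, int(name[6:]), params.pe_tau)
    elif name == "WE":
        v = wavelet_entropy(x, params.we_wavelet, params.we_levels)
    elif name == "alpha_ratio":
        v = logratio(bands.alpha_num, bands.alpha_den)
    elif name == "beta_ratio":
        v = logratio(bands.beta_num, bands.beta_den)
    elif name == "bma_ratio":
        v = logratio(bands.bma_num, bands.bma_den)
    elif name in ("SFS", "ApEn", "SpEn"):
        apen, sfs, spen = surrogates()
        v = {"SFS": sfs, "ApEn": apen, "SpEn": spen}[name]
    elif name == "MPF":
        v = _psd_quantile(f, psd, 0.5, f_max)
    elif name == "SEF95":
        v = _psd_quantile(f, psd, 0.95, f_max)
    elif name == "SEF90":
        v = _psd_quantile(f, psd, 0.90, f_max)
    elif name.startswith("logP_"):
        p = bp(*SUB_BANDS[name[5:]])
        v = math.log10(p) if p > 0 else float("nan")
    elif name.startswith("relP_"):
        v = bp(*SUB_BANDS[name[5:]]) / total if total > 0 else float("nan")
    elif name.startswith("wavP_"):
        v = float(wav_p()[int(name[5:])])
    elif name == "peak_freq":
        mask = (f > 0) & (f <= f_max)
        v = float(f[mask][np.argmax(psd[mask])]) if mask.any() else float("nan")
    elif name == "spec_centroid":
        mask = (f > 0) & (f <= f_max)
        pt = psd[mask].sum()
        v = float(np.sum(f[mask] * psd[mask]) / pt) if pt > 0 else float("nan")
    elif name == "spec_bandwidth":
        mask = (f > 0) & (f <= f_max)
        pt = psd[mask].sum()
        if pt > 0:
            mu = np.sum(f[mask] * psd[mask]) / pt
            v = float(np.sqrt(np.sum((f[mask] - mu) ** 2 * psd[mask]) / pt))
        else:
            v = float("nan")
    elif name == "hjorth_activity":
        v = var_x
    elif name == "hjorth_mobility":
        v = mob
    elif name == "hjorth_complexity":
        var_ddx = float(np.var(np.diff(dx)))
        v = (
            math.sqrt(var_ddx / var_dx) / mob
            if var_dx > 0 and mob and mob > 0
            else float("nan")
        )
    elif name == "zero_cross_rate":
        xc = x - np.mean(x)
        v = float(np.count_nonzero(np.diff(np.signbit(xc)))) / x.size
    elif name == "rms_amplitude":
        v = float(np.sqrt(np.mean(x**2)))
    elif name == "line_length":
        v = float(np.mean(np.abs(dx)))
    elif name == "kurtosis":
        v = float(spstats.kurtosis(x)) if var_x > 0 else float("nan")
    else:
        raise KeyError(f"unknown indicator {name!r}")
    return v


def extract_features(
    ep: EpochedSignal,
    profile=None,
    params: EntropyParams | None = None,
    bands: SpectralBands | None = None,
    n_indicators: int = 48,
) -> pd.DataFrame:
    """Per-epoch feature table in schema order.

    One row per epoch, columns = indicator schema plus ``subject_id`` and
    ``epoch_time``.  Undefined indices (flat epochs, zero band powers) are
    imputed with the per-column median across the subject's valid epochs
    (0 when a column is entirely undefined) so the table carries no NaN.
    ``profile`` supplies the demographic covariates (attributes height,
    weight, age, sex); zeros are used when absent.
    """
    params = params or EntropyParams()
    bands = bands or SpectralBands()
    bands.validate(ep.fs)
    schema = feature_schema(n_indicators)
    names = [s.name for s in schema]
    rows = [
        _epoch_features(ep.epochs[i], ep.fs, params, bands, names)
        for i in range(ep.n_epochs)
    ]
    df = pd.DataFrame(rows)
    for c in COVARIATES:
        if profile is not None:
            raw = getattr(profile, c)
            df[c] = float(raw if c != "sex" else (1.0 if raw in (1, "M", "male") else 0.0))
        else:
            df[c] = 0.0
    df = df[names]
    med = df.median()
    df = df.fillna(med).fillna(0.0)
    df.insert(0, "subject_id", ep.subject_id)
    df.insert(1, "epoch_time", ep.epoch_times)
    return df


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
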