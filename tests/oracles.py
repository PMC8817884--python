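"""Independent brute-force reference implementations.

Deliberately slow and literal — plain Python loops and direct formula
transcriptions — so they share no code path with the package. Used to
freeze expected values and to cross-check the vectorized implementations.
"""

import itertools
import math

import numpy as np


def sampen_bruteforce(x, m, r):
    """Sample entropy by explicit O(N^2) template counting."""
    x = list(map(float, x))
    N = len(x)

    def count(mm):
        n = 0
        for i in range(N - m):  # same template range at both lengths
            for j in range(N - m):
                if i == j:
                    continue
                d = max(abs(x[i + k] - x[j + k]) for k in range(mm))
                if d <= r:
                    n += 1
        return n

    B = count(m)
    A = count(m + 1)
    if A == 0 or B == 0:
        return float("nan")
    return -math.log(A / B)


def apen_bruteforce(x, m, r):
    """Approximate entropy by direct Phi^m - Phi^{m+1} with self-matches."""
    x = list(map(float, x))
    N = len(x)

    def phi(mm):
        n = N - mm + 1
        total = 0.0
        for i in range(n):
            c = 0
            for j in range(n):
                d = max(abs(x[i + k] - x[j + k]) for k in range(mm))
                if d <= r:
                    c += 1
            total += math.log(c / n)
        return total / n

    return phi(m) - phi(m + 1)


def pe_bruteforce(x, m, tau):
    """Permutation entropy via an explicit ordinal-pattern histogram."""
    x = list(map(float, x))
    counts = {p: 0 for p in itertools.permutations(range(m))}
    n_win = len(x) - (m - 1) * tau
    for i in range(n_win):
        window = [x[i + k * tau] for k in range(m)]
        pattern = tuple(sorted(range(m), key=lambda k: (window[k], k)))
        counts[pattern] += 1
    total = sum(counts.values())
    H = 0.0
    for c in counts.values():
        if c:
            p = c / total
            H -= p * math.log(p)
    return H / math.log(math.factorial(m))


def we_bruteforce(x, wavelet, levels):
    """Wavelet entropy by per-coefficient energy summation."""
    import pywt

    coeffs = pywt.wavedec(
        np.asarray(x, dtype=float), wavelet, level=levels, mode="periodization"
    )
    energies = []
    for c in coeffs:
        e = 0.0
        for v in c:
            e += float(v) * float(v)
        energies.append(e)
    total = sum(energies)
    S = 0.0
    for e in energies:
        p = e / total
        if p > 0:
            S -= p * math.log(p)
    return S


def welch_bruteforce(x, fs, nperseg=None, f_lo=None, f_hi=None):
    """Hand-written Welch PSD (Hann, 50% overlap) and optional band power."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    nperseg = min(n, 256) if nperseg is None else nperseg
    step = nperseg // 2
    w = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(nperseg) / nperseg)
    segs = []
    start = 0
    while start + nperseg <= n:
        seg = x[start : start + nperseg]
        seg = (seg - seg.mean()) * w  # constant detrend per segment
        spec = np.abs(np.fft.rfft(seg)) ** 2
        segs.append(spec)
        start += step
    psd = np.mean(segs, axis=0) / (fs * np.sum(w**2))
    psd[1:-1] *= 2  # one-sided
    f = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    if f_lo is None:
        return f, psd
    df = f[1] - f[0]
    return float(np.sum(psd[(f >= f_lo) & (f < f_hi)]) * df)


def correlation_bruteforce(x, y):
    """Pearson correlation by hand-expanded sums."""
    x = list(map(float, x))
    y = list(map(float, y))
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    vx = sum((a - mx) ** 2 for a in x) / n
    vy = sum((b - my) ** 2 for b in y) / n
    return cov / math.sqrt(vx * vy)
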