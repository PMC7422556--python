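"""Independent brute-force reference implementations used as test oracles.

Everything here is written from the direct mathematical definitions — plain
Python loops, O(L^2) discrete Fourier transform — deliberately sharing no
code path with the package implementation.
"""

from __future__ import annotations

import cmath
import math

MAD_SCALE = 1.4826
SPECTRAL_FLOOR = 1e-12


def _median(xs):
    s = sorted(xs)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else 0.5 * (s[mid - 1] + s[mid])


def _quantile(xs, p):
    """Linear-interpolation quantile at fraction p of sorted data."""
    s = sorted(xs)
    h = (len(s) - 1) * p
    lo = math.floor(h)
    hi = math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def _dft_power(xs):
    """Periodogram |X_k|^2 / L for k = 0..L//2 by direct summation."""
    L = len(xs)
    powers = []
    for k in range(L // 2 + 1):
        acc = 0j
        for n, x in enumerate(xs):
            acc += x * cmath.exp(-2j * cmath.pi * k * n / L)
        powers.append(abs(acc) ** 2 / L)
    return powers


def _dominant(powers, fs, L):
    total = sum(powers)
    ac = powers[1:]
    peak = max(ac)
    k = ac.index(peak) + 1
    if peak <= SPECTRAL_FLOOR * max(total, 1e-300):
        return 0.0, 0.0
    return k * fs / L, peak


def oracle_features(window, fs):
    """26-feature vector of an (L, 3) window from direct definitions."""
    L = len(window)
    cols = [[row[a] for row in window] for a in range(3)]
    means = [sum(c) / L for c in cols]
    sds = [math.sqrt(sum((v - m) ** 2 for v in c) / (L - 1)) for c, m in zip(cols, means)]

    def corr(i, j):
        num = sum((cols[i][n] - means[i]) * (cols[j][n] - means[j]) for n in range(L))
        den = math.sqrt(
            sum((v - means[i]) ** 2 for v in cols[i])
            * sum((v - means[j]) ** 2 for v in cols[j])
        )
        return num / den if den > 0 else 0.0

    mag = [math.sqrt(x * x + y * y + z * z) for x, y, z in window]
    mag_mean = sum(mag) / L
    m2 = sum((v - mag_mean) ** 2 for v in mag) / L
    m3 = sum((v - mag_mean) ** 3 for v in mag) / L
    m4 = sum((v - mag_mean) ** 4 for v in mag) / L
    mag_std = math.sqrt(sum((v - mag_mean) ** 2 for v in mag) / (L - 1))
    mag_range = max(mag) - min(mag)
    mag_iqr = _quantile(mag, 0.75) - _quantile(mag, 0.25)
    mag_skew = m3 / m2**1.5 if m2 > 0 else 0.0
    mag_kurt = m4 / m2**2 - 3.0 if m2 > 0 else 0.0
    sma = sum(abs(x) + abs(y) + abs(z) for x, y, z in window) / L

    tilt = 0.0
    for (x, y, z), m in zip(window, mag):
        c = min(1.0, max(-1.0, z / m)) if m > 0 else 1.0
        tilt += math.degrees(math.acos(c))
    tilt /= L

    crossings = 0
    dev = [v - mag_mean for v in mag]
    for a, b in zip(dev, dev[1:]):
        if a * b < 0:
            crossings += 1
    mcr = crossings / (L - 1)

    domfreqs, dompows = [], []
    for c in cols:
        p = _dft_power(c)
        f, pw = _dominant(p, fs, L)
        domfreqs.append(f)
        dompows.append(pw)

    mp = _dft_power(mag)
    mag_domfreq, _ = _dominant(mp, fs, L)
    ac = mp[1:]
    total_ac = sum(ac)
    if max(ac) <= SPECTRAL_FLOOR * max(sum(mp), 1e-300):
        entropy = 0.0
    else:
        entropy = 0.0
        for p in ac:
            q = p / total_ac
            if q > 0:
                entropy -= q * math.log(q)
        entropy /= math.log(len(ac))

    return (
        means
        + sds
        + [corr(0, 1), corr(0, 2), corr(1, 2)]
        + [mag_mean, mag_std, mag_range, mag_iqr, mag_skew, mag_kurt]
        + [sma, tilt, mcr]
        + domfreqs
        + dompows
        + [mag_domfreq, entropy]
    )


def oracle_outlier_rows(rows, threshold=3.0):
    """Row indices flagged by the any-column scaled-MAD rule, brute force."""
    n = len(rows)
    k = len(rows[0])
    flagged = set()
    for j in range(k):
        col = [rows[i][j] for i in range(n)]
        med = _median(col)
        smad = MAD_SCALE * _median([abs(v - med) for v in col])
        for i in range(n):
            dev = abs(rows[i][j] - med)
            if (smad > 0 and dev > threshold * smad) or (smad == 0 and dev > 0):
                flagged.add(i)
    return flagged


def oracle_confusion(observed, predicted, classes):
    """O(n*K^2) tally of the (observed row, predicted column) counts."""
    counts = [[0] * len(classes) for _ in classes]
    for i, ci in enumerate(classes):
        for j, cj in enumerate(classes):
            for o, p in zip(observed, predicted):
                if o == ci and p == cj:
                    counts[i][j] += 1
    return counts
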