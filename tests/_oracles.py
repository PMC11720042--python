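"""Independent brute-force oracles used by the tests.

These reimplement the sway statistics by direct elementwise summation and an
explicit DFT matrix, deliberately avoiding the library code paths they are
used to check.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_sway_features(ap, ml, fs: float) -> dict[str, float]:
    """All 14 sway statistics from first principles (loops and explicit DFT)."""
    ap = [float(v) for v in ap]
    ml = [float(v) for v in ml]
    n = len(ap)
    t = n / fs

    rd = [math.sqrt(a * a + m * m) for a, m in zip(ap, ml)]
    mdist = sum(rd) / n
    mdist_ap = sum(abs(a) for a in ap) / n
    mdist_ml = sum(abs(m) for m in ml) / n
    rdist = max(rd) - min(rd)
    rdist_ap = max(ap) - min(ap)
    rdist_ml = max(ml) - min(ml)
    rms = math.sqrt(sum(v * v for v in rd) / n)
    rms_ap = math.sqrt(sum(v * v for v in ap) / n)
    rms_ml = math.sqrt(sum(v * v for v in ml) / n)
    totex = sum(
        math.sqrt((ap[i + 1] - ap[i]) ** 2 + (ml[i + 1] - ml[i]) ** 2)
        for i in range(n - 1)
    )
    mv = totex / t
    shoelace = sum(ap[i + 1] * ml[i] - ap[i] * ml[i + 1] for i in range(n - 1))
    sa = abs(shoelace) / (2 * t)

    # one-sided periodogram of the mean-removed RD series via explicit DFT
    mean_rd = sum(rd) / n
    x = np.array(rd) - mean_rd
    m_idx = np.arange(n)
    dft = np.exp(-2j * np.pi * np.outer(m_idx, m_idx) / n) @ x
    n_half = n // 2
    g = np.abs(dft[: n_half + 1]) ** 2 / (fs * n)
    g[1:] *= 2.0
    if n % 2 == 0:
        g[n_half] /= 2.0
    freqs = m_idx[: n_half + 1] * fs / n
    g, freqs = g[1:], freqs[1:]  # DC excluded
    mu0 = float(np.sum(g))
    mu1 = float(np.sum(freqs * g))
    mu2 = float(np.sum(freqs**2 * g))
    mf = totex / (2 * math.pi * mdist * t)
    cf = math.sqrt(mu2 / mu0)
    df = math.sqrt(max(1.0 - mu1**2 / (mu0 * mu2), 0.0))

    return {
        "MDIST": mdist,
        "MDIST_AP": mdist_ap,
        "MDIST_ML": mdist_ml,
        "RDIST": rdist,
        "RDIST_AP": rdist_ap,
        "RDIST_ML": rdist_ml,
        "RMS_DIST": rms,
        "RMS_DIST_AP": rms_ap,
        "RMS_DIST_ML": rms_ml,
        "MV": mv,
        "SA": sa,
        "MF": mf,
        "CF": cf,
        "DF": df,
    }


def oracle_aucroc(scores, labels, positive) -> float:
    """Pairwise-counting AUCROC: ties count one half."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))
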