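"""Information-gain ranking of sway features.

Information gain (IG) of a feature with respect to the class label is the
reduction in label entropy once the feature is known,

    IG = H(label) - sum_b p(b) H(label | bin b)     [bits],

computed on an equal-frequency discretisation of the continuous feature
(10 bins by default).  Features are reported both as raw IG and as their
percentage share of the summed IG over all features, sorted descending.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sway_features import FEATURE_NAMES


def discretize_equal_frequency(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile (equal-frequency) bin labels.

    Distinct values split into bins whose counts differ by at most one;
    tied values always share a bin.  A constant series yields a single bin.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = np.asarray(values, dtype=float)
    n = len(values)
    order = np.argsort(values, kind="stable")
    provisional = np.empty(n, dtype=int)
    provisional[order] = (np.arange(n) * n_bins) // n
    # ties must not straddle a bin edge: give every duplicate the bin of its
    # first occurrence in sorted order
    bins = provisional.copy()
    sorted_vals = values[order]
    first_bin_of_value: dict[float, int] = {}
    for pos in range(n):
        v = sorted_vals[pos]
        if v not in first_bin_of_value:
            first_bin_of_value[v] = provisional[order[pos]]
        bins[order[pos]] = first_bin_of_value[v]
    return bins


def _entropy_bits(counts: np.ndarray) -> float:
    counts = counts[counts > 0]
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(feature_bins: np.ndarray, labels: np.ndarray) -> float:
    """IG in bits from a contingency table of bins x labels."""
    feature_bins = np.asarray(feature_bins)
    labels = np.asarray(labels)
    if len(feature_bins) == 0 or len(feature_bins) != len(labels):
        raise ValueError("feature_bins and labels must be equal-length, non-empty")
    n = len(labels)
    _, label_idx = np.unique(labels, return_inverse=True)
    _, bin_idx = np.unique(feature_bins, return_inverse=True)
    h_label = _entropy_bits(np.bincount(label_idx))
    h_cond = 0.0
    for b in range(bin_idx.max() + 1):
        mask = bin_idx == b
        h_cond += mask.sum() / n * _entropy_bits(np.bincount(label_idx[mask]))
    return max(h_label - h_cond, 0.0)


def rank_features(table: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """IG ranking of the sway features in a feature table.

    Returns columns ``feature, ig_bits, share_pct, rank`` sorted by
    descending IG (ties broken alphabetically).  When every feature has zero
    IG the shares are undefined and reported as NaN.
    """
    features = [c for c in FEATURE_NAMES if c in table.columns]
    labels = table["label"].to_numpy()
    igs = {
        f: information_gain(
            discretize_equal_frequency(table[f].to_numpy(), n_bins), labels
        )
        for f in features
    }
    df = pd.DataFrame(
        {"feature": list(igs), "ig_bits": list(igs.values())}
    ).sort_values(["ig_bits", "feature"], ascending=[False, True], kind="stable")
    total = df["ig_bits"].sum()
    df["share_pct"] = df["ig_bits"] / total * 100.0 if total > 0 else float("nan")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def write_importance_csv(report: pd.DataFrame, path) -> None:
    report[["feature", "ig_bits", "share_pct", "rank"]].to_csv(path, index=False)
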