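"""Binarization of continuous densitometry-style time profiles.

Two statistical steps turn a lane-intensity time course into an on/off
profile: background subtraction (the profile minimum is taken as background)
and maximum-entropy (Kapur) thresholding on a histogram of the normalized
intensities.  The threshold is the histogram cut maximizing the summed
Shannon entropies of the below- and above-threshold classes; a sample is ON
when its background-subtracted intensity exceeds the threshold.

Profiles are one-dimensional numeric traces (node, minute, intensity); image
handling is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "IntensityProfile",
    "BinaryProfile",
    "subtract_background",
    "max_entropy_threshold",
    "binarize_profile",
    "read_intensity_profiles",
    "write_intensity_profiles",
    "read_binary_profiles",
    "write_binary_profiles",
]


@dataclass(frozen=True)
class IntensityProfile:
    """A continuous time profile of one node: (minute, intensity >= 0) samples."""

    node: str
    minutes: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        minutes = np.asarray(self.minutes, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        if minutes.shape != values.shape or minutes.ndim != 1:
            raise ValueError("minutes and values must be 1-D and equal length")
        if len(minutes) >= 2 and not np.all(np.diff(minutes) > 0):
            raise ValueError(f"profile {self.node!r}: minutes must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"profile {self.node!r}: intensities must be finite")
        object.__setattr__(self, "minutes", minutes)
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class BinaryProfile:
    """An on/off time profile on the same sampling grid as its source."""

    node: str
    minutes: np.ndarray
    bits: np.ndarray

    def __post_init__(self) -> None:
        minutes = np.asarray(self.minutes, dtype=np.int64)
        bits = np.asarray(self.bits, dtype=np.uint8)
        if minutes.shape != bits.shape or minutes.ndim != 1:
            raise ValueError("minutes and bits must be 1-D and equal length")
        if not np.all((bits == 0) | (bits == 1)):
            raise ValueError("bits must be 0/1")
        object.__setattr__(self, "minutes", minutes)
        object.__setattr__(self, "bits", bits)


def subtract_background(profile: IntensityProfile) -> IntensityProfile:
    """Subtract the profile minimum (the background level), flooring at 0."""
    if len(profile.values) < 2:
        raise ValueError("background subtraction needs >= 2 samples")
    if np.any(profile.values < 0):
        raise ValueError(f"profile {profile.node!r}: negative intensities")
    corrected = np.maximum(profile.values - profile.values.min(), 0.0)
    return IntensityProfile(profile.node, profile.minutes, corrected)


def max_entropy_threshold(values, bins: int = 256) -> float:
    """Kapur maximum-entropy threshold of a 1-D sample.

    The values are min-max normalized onto a ``bins``-bin histogram; for each
    candidate cut the Shannon entropies of the background (bins up to and
    including the cut) and foreground classes are summed, and the cut with
    the maximal sum is returned, mapped back to the original intensity
    scale.  Ties break toward the lower threshold.  ``0 * log 0`` counts
    as 0.  A constant input has no threshold and raises ``ValueError``.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("need a 1-D sample with >= 2 values")
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise ValueError("constant input: no threshold exists")
    norm = (values - lo) / (hi - lo)
    counts, edges = np.histogram(norm, bins=bins, range=(0.0, 1.0))
    p = counts / counts.sum()
    cum = np.cumsum(p)

    def class_entropy(probs: np.ndarray, mass: float) -> float:
        q = probs[probs > 0] / mass
        return float(-(q * np.log(q)).sum())

    best_k, best_score = None, -np.inf
    for k in range(bins - 1):
        p_bg = cum[k]
        p_fg = 1.0 - p_bg
        if p_bg <= 0.0 or p_fg <= 0.0:
            continue
        score = class_entropy(p[: k + 1], p_bg) + class_entropy(p[k + 1 :], p_fg)
        if score > best_score:  # strict: ties keep the lower k
            best_score, best_k = score, k
    if best_k is None:
        raise ValueError("degenerate histogram: no valid threshold")
    return float(lo + edges[best_k + 1] * (hi - lo))


def binarize_profile(profile: IntensityProfile, bins: int = 256) -> BinaryProfile:
    """Background-subtract then threshold: bit = 1 iff value > threshold."""
    corrected = subtract_background(profile)
    threshold = max_entropy_threshold(corrected.values, bins=bins)
    bits = (corrected.values > threshold).astype(np.uint8)
    return BinaryProfile(profile.node, profile.minutes, bits)


# ---------------------------------------------------------------------------
# CSV I/O: long tables with columns node,t,value (continuous) or node,t,bit
# ---------------------------------------------------------------------------

def read_intensity_profiles(path: str | Path) -> list[IntensityProfile]:
    df = pd.read_csv(path)
    out = []
    for node, grp in df.groupby("node", sort=False):
        grp = grp.sort_values("t")
        out.append(IntensityProfile(str(node), grp["t"].to_numpy(), grp["value"].to_numpy()))
    return out


def write_intensity_profiles(profiles, path: str | Path) -> None:
    rows = [
        {"node": p.node, "t": int(t), "value": float(v)}
        for p in profiles
        for t, v in zip(p.minutes, p.values)
    ]
    pd.DataFrame(rows, columns=["node", "t", "value"]).to_csv(path, index=False)


def read_binary_profiles(path: str | Path) -> list[BinaryProfile]:
    df = pd.read_csv(path)
    out = []
    for node, grp in df.groupby("node", sort=False):
        grp = grp.sort_values("t")
        out.append(BinaryProfile(str(node), grp["t"].to_numpy(), grp["bit"].to_numpy()))
    return out


def write_binary_profiles(profiles, path: str | Path) -> None:
    rows = [
        {"node": p.node, "t": int(t), "bit": int(b)}
        for p in profiles
        for t, b in zip(p.minutes, p.bits)
    ]
    pd.DataFrame(rows, columns=["node", "t", "bit"]).to_csv(path, index=False)
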