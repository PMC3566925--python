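"""Alignment of digital and experimental fingerprints by cross-correlation.

Electrophoresis sizes fragments a few bp short of their true sequence
length (a systematic drift of about 4-6 bp).  Binning both fingerprints
to 1-bp vectors and sliding one against the other finds the lag with the
highest cosine-normalized cross-correlation; shifting the digital profile
by that lag aligns the two for peak-by-peak matching and mirror plotting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .seqio import TRFLPProfile, DEFAULT_SIZE_RANGE

logger = logging.getLogger(__name__)

DEFAULT_MAX_LAG = 20


@dataclass
class CrossCorrelationResult:
    """Correlation coefficient per integer lag and the optimum.

    ``optimal_lag`` is the shift to *add* to digital fragment sizes; the
    observed electrophoretic drift therefore appears as a negative lag.
    """

    lags: list[int]
    coefficients: list[float]
    optimal_lag: int
    max_coefficient: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_bp": self.lags, "coefficient": self.coefficients})


@dataclass
class PeakMatch:
    etrf_size: int
    shifted_dtrf_size: int
    distance: int


@dataclass
class MatchResult:
    matches: list[PeakMatch]
    unmatched_etrfs: list[int]
    unmatched_dtrfs: list[int]
    percent_affiliated: float


def profile_to_vector(
    profile: TRFLPProfile,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
) -> np.ndarray:
    """Dense abundance vector, one entry per integer bp (inclusive bounds).

    Peaks outside *size_range* are dropped and the remainder renormalized
    to sum to 100 (fragments below 50 bp are not comparable to the
    electropherogram window).
    """
    lo, hi = size_range
    vec = np.zeros(hi - lo + 1)
    for size, abundance in profile.peaks:
        if lo <= size <= hi:
            vec[size - lo] += abundance
    total = vec.sum()
    if total <= 0:
        raise ValueError("profile has no peaks within the size range")
    return vec * (100.0 / total)


def cross_correlate(
    dvec: np.ndarray,
    evec: np.ndarray,
    max_lag: int = DEFAULT_MAX_LAG,
) -> CrossCorrelationResult:
    """Cosine-normalized cross-correlation over integer lags.

    ``coefficient(l) = Σ_j d[j]·e[j+l] / (‖d‖·‖e‖)`` with out-of-range
    indices contributing zero, for l in [−max_lag, +max_lag]; the global
    norms make coefficients comparable across lags and bounded by 1.
    Ties at the optimum resolve to the smallest |lag|, then the negative
    one.
    """
    dvec = np.asarray(dvec, dtype=float)
    evec = np.asarray(evec, dtype=float)
    if dvec.shape != evec.shape:
        raise ValueError("vectors must have the same length")
    dnorm = float(np.linalg.norm(dvec))
    enorm = float(np.linalg.norm(evec))
    if dnorm == 0 or enorm == 0:
        raise ValueError("zero-norm vector")
    n = len(dvec)
    lags = list(range(-max_lag, max_lag + 1))
    coefficients = []
    for lag in lags:
        if lag >= 0:
            dot = float(np.dot(dvec[: n - lag], evec[lag:])) if lag < n else 0.0
        else:
            dot = float(np.dot(dvec[-lag:], evec[: n + lag])) if -lag < n else 0.0
        coefficients.append(dot / (dnorm * enorm))
    best = max(zip(coefficients, lags), key=lambda cl: (cl[0], -abs(cl[1]), -cl[1]))
    return CrossCorrelationResult(lags, coefficients, best[1], best[0])


def correlate_profiles(
    dprofile: TRFLPProfile,
    eprofile: TRFLPProfile,
    max_lag: int = DEFAULT_MAX_LAG,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
) -> CrossCorrelationResult:
    """Convenience wrapper: bin both profiles and cross-correlate."""
    return cross_correlate(
        profile_to_vector(dprofile, size_range),
        profile_to_vector(eprofile, size_range),
        max_lag,
    )


def apply_shift(profile: TRFLPProfile, lag: int) -> TRFLPProfile:
    """Shift every peak size by *lag* bp (drift correction).

    Peaks leaving the profile's size range are dropped with a warning and
    the remainder renormalized.
    """
    lo, hi = profile.size_range
    shifted: dict[int, float] = {}
    dropped = []
    for size, abundance in profile.peaks:
        new = size + lag
        if lo <= new <= hi:
            shifted[new] = shifted.get(new, 0.0) + abundance
        else:
            dropped.append(size)
    if dropped:
        logger.warning(
            "shift %+d bp: %d peak(s) left the %s bp window and were dropped: %s",
            lag, len(dropped), profile.size_range, dropped,
        )
    return TRFLPProfile.from_abundances(
        profile.sample_id, profile.kind, shifted, profile.size_range
    )


def match_peaks(
    eprofile: TRFLPProfile,
    shifted_dprofile: TRFLPProfile,
    tolerance: int = 1,
) -> MatchResult:
    """Greedy nearest-size matching of experimental to digital peaks.

    Each peak is used at most once; candidate pairs are taken in order of
    size distance (ties toward the smaller digital size).  The affiliation
    percentage is 100·|matches| / (number of experimental peaks).
    """
    e_sizes = eprofile.sizes
    d_sizes = shifted_dprofile.sizes
    candidates = sorted(
        (
            (abs(e - d), d, e)
            for e in e_sizes
            for d in d_sizes
            if abs(e - d) <= tolerance
        ),
    )
    used_e: set[int] = set()
    used_d: set[int] = set()
    matches: list[PeakMatch] = []
    for dist, d, e in candidates:
        if e in used_e or d in used_d:
            continue
        used_e.add(e)
        used_d.add(d)
        matches.append(PeakMatch(e, d, dist))
    matches.sort(key=lambda m: m.etrf_size)
    percent = 100.0 * len(matches) / len(e_sizes) if e_sizes else 0.0
    return MatchResult(
        matches=matches,
        unmatched_etrfs=[e for e in e_sizes if e not in used_e],
        unmatched_dtrfs=[d for d in d_sizes if d not in used_d],
        percent_affiliated=percent,
    )


def mirror_data(
    eprofile: TRFLPProfile,
    shifted_dprofile: TRFLPProfile,
    clip: float = 5.0,
    size_range: tuple[int, int] = DEFAULT_SIZE_RANGE,
) -> pd.DataFrame:
    """Paired table for mirror plotting across the full size window.

    Display columns are clipped at *clip* percent (tall peaks annotated
    with their true abundance beside the truncated bar); the true values
    are carried alongside.
    """
    lo, hi = size_range
    sizes = np.arange(lo, hi + 1)
    e = dict(eprofile.peaks)
    d = dict(shifted_dprofile.peaks)
    e_ab = np.array([e.get(int(s), 0.0) for s in sizes])
    d_ab = np.array([d.get(int(s), 0.0) for s in sizes])
    return pd.DataFrame(
        {
            "size_bp": sizes,
            "etrf_abundance": e_ab,
            "dtrf_abundance": d_ab,
            "etrf_display": np.minimum(e_ab, clip),
            "dtrf_display": np.minimum(d_ab, clip),
        }
    )
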