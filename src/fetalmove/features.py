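"""Time, frequency and wavelet domain (TFWD) features of a denoised epoch.

Each 2.56 s epoch is summarized by 22 named features in a fixed order:

* 11 time-domain statistics and dimensionless shape factors (mean, std,
  median, max, min, IQR, energy, waveform/crest/pulse/margin factor),
* 8 spectral summaries of the one-sided magnitude spectrum (location and
  height of the two dominant peaks, mean, skewness, kurtosis, normalized
  Shannon spectral entropy),
* 3 wavelet-subband aggregates over a db4 decomposition (summed subband
  energy, mean and standard deviation).

Shape-factor conventions follow standard condition-monitoring usage: with
RMS = sqrt(energy/n), peak = max|x|, mean|x| and (mean sqrt|x|)^2,
waveform = RMS/mean|x|, crest = peak/RMS, pulse = peak/mean|x| and
margin = peak/(mean sqrt|x|)^2.  Ratios with zero denominators are defined
as 0 and flagged as degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pywt
from scipy import stats
from scipy.signal import get_window

from .preprocess import Epoch

__all__ = [
    "FEATURE_NAMES",
    "TIME_FEATURE_NAMES",
    "FREQ_FEATURE_NAMES",
    "WAVELET_FEATURE_NAMES",
    "SpectrumConfig",
    "WaveletConfig",
    "FeatureGroup",
    "time_features",
    "freq_features",
    "wavelet_features",
    "extract_tfwd",
    "feature_matrix",
]

TIME_FEATURE_NAMES = [
    "T_Mean", "T_STD", "T_Median", "T_Max", "T_Min", "T_IQR",
    "T_Energy", "T_WF", "T_CF", "T_PF", "T_MF",
]
FREQ_FEATURE_NAMES = [
    "F_FIM", "F_SM", "F_FISM", "F_SSM",
    "F_Mean", "F_Skewness", "F_Kurtosis", "F_Entropy",
]
WAVELET_FEATURE_NAMES = ["W_Energy", "W_Mean", "W_STD"]
FEATURE_NAMES = TIME_FEATURE_NAMES + FREQ_FEATURE_NAMES + WAVELET_FEATURE_NAMES


@dataclass(frozen=True)
class SpectrumConfig:
    """Spectral-estimator settings: taper window and mean removal."""

    window: str = "hann"
    one_sided: bool = True
    detrend_mean: bool = True

    def __post_init__(self):
        if self.window not in ("hann", "rectangular"):
            raise ValueError(f"unsupported window {self.window!r}")


@dataclass(frozen=True)
class WaveletConfig:
    """Discrete wavelet transform settings.

    Periodization padding keeps the orthonormal db4 transform exactly
    energy-preserving, so the summed subband energy equals the time-domain
    energy.
    """

    family: str = "db4"
    level: int = 4
    padding: str = "periodization"

    def __post_init__(self):
        if self.level < 1:
            raise ValueError("level must be >= 1")


class FeatureGroup(dict):
    """A named-feature dict carrying a ``degenerate`` flag."""

    degenerate: bool = False


def time_features(x: np.ndarray) -> FeatureGroup:
    """The 11 time-domain features of a sample vector (length >= 4)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("need a 1-d vector of length >= 4")
    n = x.size
    out = FeatureGroup()
    out["T_Mean"] = float(np.mean(x))
    out["T_STD"] = float(np.std(x))  # population (ddof=0)
    out["T_Median"] = float(np.median(x))
    out["T_Max"] = float(np.max(x))
    out["T_Min"] = float(np.min(x))
    q1, q3 = np.quantile(x, [0.25, 0.75])  # linear-interpolation quantiles
    out["T_IQR"] = float(q3 - q1)
    energy = float(np.sum(x * x))
    out["T_Energy"] = energy
    rms = np.sqrt(energy / n)
    peak = float(np.max(np.abs(x)))
    absmean = float(np.mean(np.abs(x)))
    sqrtabsmean = float(np.mean(np.sqrt(np.abs(x)))) ** 2
    degenerate = False

    def ratio(num, den):
        nonlocal degenerate
        if den == 0.0:
            degenerate = True
            return 0.0
        return num / den

    out["T_WF"] = ratio(rms, absmean)
    out["T_CF"] = ratio(peak, rms)
    out["T_PF"] = ratio(peak, absmean)
    out["T_MF"] = ratio(peak, sqrtabsmean)
    out.degenerate = degenerate
    return out


def _magnitude_spectrum(
    x: np.ndarray, fs: float, cfg: SpectrumConfig
) -> tuple[np.ndarray, np.ndarray]:
    if cfg.detrend_mean:
        x = x - np.mean(x)
    if cfg.window == "hann":
        x = x * get_window("hann", x.size)
    S = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    return freqs, S


def freq_features(
    x: np.ndarray, fs: float, cfg: SpectrumConfig = SpectrumConfig()
) -> FeatureGroup:
    """The 8 frequency-domain features from the one-sided magnitude spectrum.

    The spectrum maximum F_SM and its frequency F_FIM (ties broken toward the
    lowest frequency); the sub-maximum F_SSM is the largest *local* maximum
    outside the global peak's 3-bin neighbourhood (0 if none), with frequency
    F_FISM.  F_Skewness / F_Kurtosis are the standardized 3rd/4th moments of
    the spectral magnitudes (kurtosis non-excess, Gaussian -> 3).  F_Entropy
    is Shannon entropy of the normalized power, divided by log(n_bins), so it
    lies in [0, 1]: near 0 for a pure tone, near 1 for white noise.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 8:
        raise ValueError("need a 1-d vector of length >= 8")
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    freqs, S = _magnitude_spectrum(x, fs, cfg)
    out = FeatureGroup()
    imax = int(np.argmax(S))  # argmax returns the first (lowest-frequency) tie
    out["F_FIM"] = float(freqs[imax])
    out["F_SM"] = float(S[imax])

    # local maxima, excluding the global-max bin and its two neighbours
    excluded = {imax - 1, imax, imax + 1}
    best_i, best_v = -1, 0.0
    for i in range(1, S.size - 1):
        if i in excluded:
            continue
        if S[i] > S[i - 1] and S[i] >= S[i + 1] and S[i] > best_v:
            best_i, best_v = i, float(S[i])
    if best_i >= 0:
        out["F_FISM"] = float(freqs[best_i])
        out["F_SSM"] = best_v
    else:
        out["F_FISM"] = 0.0
        out["F_SSM"] = 0.0

    out["F_Mean"] = float(np.mean(S))
    if np.std(S) == 0.0:
        out["F_Skewness"] = 0.0
        out["F_Kurtosis"] = 0.0
        out.degenerate = True
    else:
        out["F_Skewness"] = float(stats.skew(S))
        out["F_Kurtosis"] = float(stats.kurtosis(S, fisher=False))

    power = S * S
    total = power.sum()
    if total == 0.0:
        out["F_Entropy"] = 0.0
        out.degenerate = True
    else:
        p = power / total
        nz = p[p > 0]
        out["F_Entropy"] = float(-(nz * np.log(nz)).sum() / np.log(S.size))
    return out


def wavelet_features(
    x: np.ndarray, cfg: WaveletConfig = WaveletConfig()
) -> FeatureGroup:
    """Wavelet-subband aggregates over details D1..Dlevel + approximation.

    W_Energy sums the squared coefficients of every subband, W_Mean the
    subband means and W_STD the subband standard deviations (population).
    """
    x = np.asarray(x, dtype=float)
    max_level = pywt.dwt_max_level(x.size, pywt.Wavelet(cfg.family).dec_len)
    if cfg.level > max_level:
        raise ValueError(
            f"level {cfg.level} infeasible for length {x.size}; "
            f"maximum feasible level is {max_level}"
        )
    coeffs = pywt.wavedec(x, cfg.family, mode=cfg.padding, level=cfg.level)
    out = FeatureGroup()
    out["W_Energy"] = float(sum(np.sum(c * c) for c in coeffs))
    out["W_Mean"] = float(sum(np.mean(c) for c in coeffs))
    out["W_STD"] = float(sum(np.std(c) for c in coeffs))
    return out


def extract_tfwd(
    epoch: Epoch,
    scfg: SpectrumConfig = SpectrumConfig(),
    wcfg: WaveletConfig = WaveletConfig(),
) -> pd.Series:
    """All 22 features of one (single-channel) epoch, in the fixed order."""
    x = np.asarray(epoch.samples, dtype=float)
    if x.ndim != 1:
        raise ValueError(
            "extract_tfwd expects a single-channel epoch; run preprocess_epoch first"
        )
    t = time_features(x)
    f = freq_features(x, epoch.fs, scfg)
    w = wavelet_features(x, wcfg)
    values = {**t, **f, **w}
    series = pd.Series([values[name] for name in FEATURE_NAMES], index=FEATURE_NAMES)
    series.attrs["degenerate"] = bool(t.degenerate or f.degenerate or w.degenerate)
    return series


def feature_matrix(
    epochs: Iterable[Epoch],
    scfg: SpectrumConfig = SpectrumConfig(),
    wcfg: WaveletConfig = WaveletConfig(),
    labels: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Feature rows for a sequence of epochs; adds a ``label`` column when known."""
    epochs = list(epochs)
    rows = [extract_tfwd(ep, scfg, wcfg) for ep in epochs]
    df = pd.DataFrame(rows).reset_index(drop=True)
    if labels is not None:
        df["label"] = np.asarray(labels, dtype=int)[: len(df)]
    elif epochs and all(ep.label is not None for ep in epochs):
        df["label"] = [int(ep.label) for ep in epochs]
    return df
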