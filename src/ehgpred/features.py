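"""The 23 temporal, spectral and nonlinear EHG window parameters.

Each 120 s analysis window of the conditioned bipolar EHG is characterized
by: peak-to-peak amplitude; dominant frequencies DF1 (0.2-1 Hz) and DF2
(0.34-1 Hz); the high-to-low band energy ratio H/L (energy in 0.34-1 Hz over
energy in 0.2-0.34 Hz, the Fast Wave High / Fast Wave Low split); the nine
deciles D1-D9 of the in-band power spectrum; the spectral moment ratio SMR;
binary and 6-state Lempel-Ziv complexity; sample, fuzzy and spectral
entropy; time reversibility; and the Poincare descriptors SD1, SD2 and
SD1/SD2.

Features that are undefined on a window (zero variance, empty band, no
template matches) are returned as NaN sentinels and logged; they are never
silently imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from ._kernels import fuzzy_phis, lz76_phrase_count, sampen_counts

logger = logging.getLogger(__name__)

#: Canonical ordering of the 23 window features.
FEATURE_NAMES: tuple[str, ...] = (
    "app",
    "df1",
    "df2",
    "hl_ratio",
    "d1",
    "d2",
    "d3",
    "d4",
    "d5",
    "d6",
    "d7",
    "d8",
    "d9",
    "smr",
    "lz_bin",
    "lz_multi6",
    "sampen",
    "fuzzyen",
    "specen",
    "timerev",
    "sd1",
    "sd2",
    "sd1_sd2",
)


@dataclass(frozen=True)
class FeatureParams:
    """Configuration of the window parameters.

    The EHG literature values are used as defaults: the dominant-frequency /
    decile / SMR band is 0.2-1 Hz (fast-wave physiology, avoids ECG and
    respiration interference), spectral entropy uses the full 0.1-4 Hz EHG
    band, entropies use m = 2 with r = 0.15 x window SD, and the fuzzy
    membership exponent is 2. SMR uses spectral moment orders (-1, 5).
    """

    band_df1: tuple[float, float] = (0.2, 1.0)
    band_df2: tuple[float, float] = (0.34, 1.0)
    band_low: tuple[float, float] = (0.2, 0.34)
    band_high: tuple[float, float] = (0.34, 1.0)
    band_full: tuple[float, float] = (0.1, 4.0)
    smr_orders: tuple[float, float] = (-1.0, 5.0)
    entropy_m: int = 2
    entropy_r_factor: float = 0.15
    fuzzy_grad: float = 2.0
    timerev_lag: int = 1
    poincare_lag: int = 1


@dataclass
class PSD:
    """One-sided power spectral density of a window (density scaling)."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.ndim != 1 or self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must be 1-D arrays of equal length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    def band_mask(self, band: tuple[float, float]) -> np.ndarray:
        return (self.freqs >= band[0]) & (self.freqs <= band[1])


def estimate_psd(window: np.ndarray, fs: float) -> PSD:
    """Hamming-tapered full-window periodogram (resolution 1/win_s Hz).

    The window mean is removed before tapering; with density scaling the
    integrated PSD matches the tapered time-domain power (Parseval within
    numerical accuracy). A constant window yields an all-zero PSD, which is
    flagged and propagates NaN sentinels to the spectral features.
    """
    x = np.asarray(window, dtype=float)
    if x.size < 2:
        raise ValueError("window too short for PSD estimation")
    freqs, power = sps.periodogram(
        x, fs=fs, window="hamming", detrend="constant", scaling="density"
    )
    if not np.any(power > 0):
        logger.warning("constant window: all-zero PSD; spectral features will be NaN")
    return PSD(freqs=freqs, power=power)


def _dominant_frequency(psd: PSD, band: tuple[float, float]) -> float:
    mask = psd.band_mask(band)
    if not mask.any() or psd.power[mask].sum() <= 0:
        return math.nan
    f = psd.freqs[mask]
    p = psd.power[mask]
    return float(f[int(np.argmax(p))])


def spectral_features(psd: PSD, params: FeatureParams = FeatureParams()) -> dict[str, float]:
    """DF1, DF2, H/L ratio, power-spectrum deciles D1-D9 and SMR.

    Deciles: Dk is the smallest grid frequency at which the cumulative power
    over the decile band reaches k/10 of the band total. SMR is the ratio of
    spectral moments M_{n1}/M_{n2} with M_n = sum P(f) f^n over the band.
    """
    out: dict[str, float] = {}
    out["df1"] = _dominant_frequency(psd, params.band_df1)
    out["df2"] = _dominant_frequency(psd, params.band_df2)

    lo = psd.power[psd.band_mask(params.band_low)].sum()
    hi = psd.power[psd.band_mask(params.band_high)].sum()
    if lo > 0:
        out["hl_ratio"] = float(hi / lo)
    else:
        logger.warning("zero power in the low band: H/L ratio undefined")
        out["hl_ratio"] = math.nan

    mask = psd.band_mask(params.band_df1)
    f = psd.freqs[mask]
    p = psd.power[mask]
    total = p.sum()
    if total > 0:
        cum = np.cumsum(p)
        for k in range(1, 10):
            idx = int(np.searchsorted(cum, k / 10.0 * total))
            out[f"d{k}"] = float(f[min(idx, f.size - 1)])
        n1, n2 = params.smr_orders
        m1 = float(np.sum(p * f**n1))
        m2 = float(np.sum(p * f**n2))
        out["smr"] = m1 / m2 if m2 > 0 else math.nan
    else:
        for k in range(1, 10):
            out[f"d{k}"] = math.nan
        out["smr"] = math.nan
    return out


def peak_to_peak(window: np.ndarray) -> float:
    """Peak-to-peak amplitude: max - min of the window."""
    x = np.asarray(window, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    return float(x.max() - x.min())


def _symbolize_binary(x: np.ndarray) -> np.ndarray:
    return (x > np.median(x)).astype(np.int64)


def _symbolize_quantile(x: np.ndarray, n_states: int) -> np.ndarray:
    # Equiprobable (quantile) bins; robust to amplitude nonstationarity.
    edges = np.quantile(x, np.arange(1, n_states) / n_states)
    return np.searchsorted(edges, x, side="left").astype(np.int64)


def lempel_ziv(window: np.ndarray, n_states: int = 2) -> float:
    """Normalized LZ76 complexity c(n) * log_alpha(n) / n with alpha = n_states.

    Binary symbolization is above/below the median; the multistate variant
    uses within-window equiprobable quantile bins. A constant window reduces
    to a single-symbol sequence and returns the minimal normalized value.
    """
    x = np.asarray(window, dtype=float)
    if x.size < 100:
        raise ValueError("window too short for Lempel-Ziv complexity")
    if n_states == 2:
        sym = _symbolize_binary(x)
    else:
        sym = _symbolize_quantile(x, n_states)
    c = lz76_phrase_count(sym)
    n = x.size
    return float(c * math.log(n, n_states) / n)


def sample_entropy(
    window: np.ndarray, m: int = 2, r_factor: float = 0.15
) -> float:
    """Sample entropy -ln(A/B) with Chebyshev tolerance r = r_factor x SD.

    B counts template pairs of length m within r (self-matches excluded),
    A the same for length m + 1; both run over the N - m templates whose
    extension exists. A = 0 (or SD = 0) gives a NaN sentinel.
    """
    x = np.asarray(window, dtype=float)
    if x.size < 200:
        raise ValueError("window too short for sample entropy")
    sd = float(np.std(x))
    if sd == 0:
        logger.warning("zero-SD window: sample entropy undefined")
        return math.nan
    a, b = sampen_counts(x, m, r_factor * sd)
    if a == 0 or b == 0:
        logger.warning("no template matches: sample entropy undefined")
        return math.nan
    return float(-math.log(a / b))


def fuzzy_entropy(
    window: np.ndarray, m: int = 2, r_factor: float = 0.15, grad: float = 2.0
) -> float:
    """Fuzzy entropy -ln(phi_{m+1}/phi_m) with soft membership exp(-(d/r)^grad).

    Templates are mean-centered; the hard match indicator of sample entropy
    is replaced by a graded membership, so the estimate stays finite on
    windows where sample entropy is undefined.
    """
    x = np.asarray(window, dtype=float)
    if x.size < 200:
        raise ValueError("window too short for fuzzy entropy")
    sd = float(np.std(x))
    if sd == 0:
        logger.warning("zero-SD window: fuzzy entropy undefined")
        return math.nan
    phi_m, phi_m1 = fuzzy_phis(x, m, r_factor * sd, grad)
    if phi_m <= 0 or phi_m1 <= 0:
        return math.nan
    return float(-math.log(phi_m1 / phi_m))


def spectral_entropy(psd: PSD, band: tuple[float, float] = (0.1, 4.0)) -> float:
    """Shannon entropy of the normalized in-band spectrum, scaled to [0, 1].

    The in-band PSD is normalized to a probability mass over bins; the
    entropy is divided by log(number of bins), so a delta spectrum gives 0
    and an exactly uniform spectrum gives 1.
    """
    mask = psd.band_mask(band)
    p = psd.power[mask]
    if p.size < 2:
        raise ValueError("need at least 2 PSD bins in band")
    total = p.sum()
    if total <= 0:
        logger.warning("zero total power in band: spectral entropy undefined")
        return math.nan
    q = p / total
    q = q[q > 0]
    h = float(-np.sum(q * np.log(q)))
    return h / math.log(p.size)


def time_reversibility(window: np.ndarray, lag: int = 1) -> float:
    """Third moment of lagged differences: mean of (x_t - x_{t-lag})^3.

    Zero for time-symmetric signals (e.g. linear Gaussian processes or
    sines over whole cycles); exactly negated under time reversal.
    """
    x = np.asarray(window, dtype=float)
    if x.size <= lag:
        raise ValueError("window shorter than lag")
    d = x[lag:] - x[:-lag]
    return float(np.sum(d**3) / (x.size - lag))


def poincare(window: np.ndarray, lag: int = 1) -> tuple[float, float, float]:
    """Poincare plot descriptors (SD1, SD2, SD1/SD2) at the given lag.

    SD1 is the dispersion of (x_{i+lag} - x_i)/sqrt(2) (perpendicular to the
    identity line), SD2 of (x_{i+lag} + x_i)/sqrt(2) (parallel). SD2 = 0
    gives a NaN sentinel for the ratio.
    """
    x = np.asarray(window, dtype=float)
    if x.size <= lag + 1:
        raise ValueError("window too short for Poincare descriptors")
    diff = (x[lag:] - x[:-lag]) / math.sqrt(2.0)
    summ = (x[lag:] + x[:-lag]) / math.sqrt(2.0)
    sd1 = float(np.std(diff))
    sd2 = float(np.std(summ))
    # a numerically-constant cloud has no defined orientation
    if sd2 <= 1e-12 * float(np.abs(summ).max(initial=0.0)):
        sd2 = 0.0
    ratio = sd1 / sd2 if sd2 > 0 else math.nan
    if sd2 == 0:
        logger.warning("degenerate Poincare cloud: SD1/SD2 undefined")
    return sd1, sd2, ratio


def extract_window(
    window: np.ndarray, fs: float, params: FeatureParams = FeatureParams()
) -> dict[str, float]:
    """All 23 features of one window, NaN sentinels for undefined values."""
    x = np.asarray(window, dtype=float)
    out: dict[str, float] = {"app": peak_to_peak(x)}
    psd = estimate_psd(x, fs)
    out.update(spectral_features(psd, params))
    out["lz_bin"] = lempel_ziv(x, 2)
    out["lz_multi6"] = lempel_ziv(x, 6)
    out["sampen"] = sample_entropy(x, params.entropy_m, params.entropy_r_factor)
    out["fuzzyen"] = fuzzy_entropy(
        x, params.entropy_m, params.entropy_r_factor, params.fuzzy_grad
    )
    out["specen"] = spectral_entropy(psd, params.band_full)
    out["timerev"] = time_reversibility(x, params.timerev_lag)
    sd1, sd2, ratio = poincare(x, params.poincare_lag)
    out["sd1"], out["sd2"], out["sd1_sd2"] = sd1, sd2, ratio
    return out


def extract_all(window_set, params: FeatureParams = FeatureParams()):
    """Feature matrix for a WindowSet: one row per window, 23 columns.

    Returns a pandas DataFrame indexed by window position, with a
    ``start_s`` column followed by the 23 features in canonical order.
    """
    import pandas as pd

    if len(window_set.windows) == 0:
        raise ValueError("empty WindowSet")
    rows = []
    for w in window_set.windows:
        rows.append(extract_window(w, window_set.fs, params))
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    df.insert(0, "start_s", np.asarray(window_set.start_times, dtype=float))
    return df
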