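"""Time- and frequency-domain sEMG features and the per-channel feature vector.

Fourteen features commonly used in myoelectric control are computed per
channel per window: RMS, MAV, WL, ZC, DASDV, LOG, SSI, TM3, TM4, TM5, FR,
IEMG, MFMN and MFMD.  The per-channel feature vector is
``f = [1, x1, ..., x14]`` — a leading constant 1 is prepended so that the
outer-product fusion map retains the original feature values in its first
row and column.

Frequency-domain features use the one-sided power spectrum
``P(f) = |FFT(S)|^2`` over ``[0, fs/2]``.  MFMN is the power-weighted mean
frequency; MFMD is the frequency at which cumulative power first reaches
half the total; FR is the ratio of low-band to high-band power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "FEATURE_NAMES",
    "SpectralConfig",
    "PowerSpectrum",
    "FeatureVector",
    "power_spectrum",
    "evaluate_feature",
    "build_feature_vector",
    "feature_table",
]

#: Canonical feature order x1..x14.
FEATURE_NAMES: tuple[str, ...] = (
    "RMS", "MAV", "WL", "ZC", "DASDV", "LOG", "SSI",
    "TM3", "TM4", "TM5", "FR", "IEMG", "MFMN", "MFMD",
)


@dataclass(frozen=True)
class SpectralConfig:
    """Spectral and threshold parameters for feature evaluation.

    ``zc_threshold`` is the amplitude threshold eps for the zero-crossing
    count (0 by default: band-passed signals carry negligible DC offset).
    ``fr_low_band`` / ``fr_high_band`` are the FR numerator and denominator
    bands in Hz; the defaults split the 20-500 Hz device pass-band at its
    midpoint.
    """

    fs: float = 1000.0
    zc_threshold: float = 0.0
    fr_low_band: tuple[float, float] = (20.0, 250.0)
    fr_high_band: tuple[float, float] = (250.0, 500.0)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.zc_threshold < 0:
            raise ValueError("zc_threshold must be >= 0")
        llc, ulc = self.fr_low_band
        lhc, uhc = self.fr_high_band
        if not (0 <= llc < ulc):
            raise ValueError("fr_low_band must satisfy 0 <= LLC < ULC")
        if not (lhc < uhc <= self.fs / 2):
            raise ValueError("fr_high_band must satisfy LHC < UHC <= fs/2")


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided power spectrum: frequency grid and nonnegative power."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have equal length")

    @property
    def total(self) -> float:
        return float(self.power.sum())

    def band_power(self, low: float, high: float) -> float:
        """Sum of power over bins whose center lies in [low, high)."""
        mask = (self.freqs >= low) & (self.freqs < high)
        return float(self.power[mask].sum())


@dataclass(frozen=True)
class FeatureVector:
    """``[1, x1..x14]`` in canonical order; length m + 1 = 15."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.names) + 1,):
            raise ValueError("feature vector must have length m + 1")
        if self.values[0] != 1.0:
            raise ValueError("feature vector must start with the constant 1")

    @property
    def m(self) -> int:
        return len(self.names)


def power_spectrum(channel_signal: np.ndarray, config: SpectralConfig) -> PowerSpectrum:
    """One-sided power spectrum ``|FFT|^2`` of a window over ``[0, fs/2]``."""
    x = np.asarray(channel_signal, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("signal must have at least 2 samples")
    spec = np.fft.rfft(x)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / config.fs)
    return PowerSpectrum(freqs=freqs, power=power)


# -- individual feature formulas --------------------------------------------

def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(x**2)))


def _mav(x: np.ndarray) -> float:
    return float(np.mean(np.abs(x)))


def _wl(x: np.ndarray) -> float:
    return float(np.sum(np.abs(np.diff(x))))


def _zc(x: np.ndarray, eps: float) -> float:
    # Crossing at i requires strict sign opposition S_i * S_{i+1} < 0 and an
    # amplitude step |S_i - S_{i+1}| >= eps.
    prod = x[:-1] * x[1:]
    step = np.abs(np.diff(x))
    return float(np.count_nonzero((prod < 0) & (step >= eps)))


def _dasdv(x: np.ndarray) -> float:
    return float(np.sqrt(np.sum(np.diff(x) ** 2) / (x.size - 1)))


def _log_printed(x: np.ndarray) -> float:
    return float(np.exp(np.mean(x)))


def _log_conventional(x: np.ndarray) -> float:
    # exp(mean(log|S_i|)): the log-detector form common in the myoelectric
    # literature; offered as a variant, not the default.
    with np.errstate(divide="ignore"):
        return float(np.exp(np.mean(np.log(np.abs(x)))))


def _ssi(x: np.ndarray) -> float:
    return float(np.sum(x**2))


def _tm(x: np.ndarray, order: int) -> float:
    return float(np.abs(np.mean(x**order)))


def _iemg(x: np.ndarray) -> float:
    return float(np.sum(np.abs(x)))


def _fr(ps: PowerSpectrum, config: SpectralConfig) -> float:
    low = ps.band_power(*config.fr_low_band)
    high = ps.band_power(*config.fr_high_band)
    if high == 0.0:
        warnings.warn(
            "FR undefined: zero power in the high band; returning NaN",
            RuntimeWarning,
            stacklevel=3,
        )
        return float("nan")
    return low / high


def _mfmn(ps: PowerSpectrum) -> float:
    total = ps.total
    if total == 0.0:
        return 0.0
    return float(np.sum(ps.freqs * ps.power) / total)


def _mfmd(ps: PowerSpectrum) -> float:
    total = ps.total
    if total == 0.0:
        return 0.0
    cum = np.cumsum(ps.power)
    idx = int(np.searchsorted(cum, total / 2.0))
    return float(ps.freqs[idx])


def evaluate_feature(
    name: str,
    channel_signal: np.ndarray,
    config: SpectralConfig = SpectralConfig(),
    log_variant: str = "printed",
) -> float:
    """Evaluate one named feature on a single-channel window.

    ``log_variant`` selects the LOG form: ``"printed"`` is ``exp(mean(S))``;
    ``"conventional"`` is ``exp(mean(log|S|))``.
    """
    x = np.asarray(channel_signal, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("signal must have at least 2 samples")
    key = name.upper()
    if key in ("FR", "MFMN", "MFMD"):
        ps = power_spectrum(x, config)
        if key == "FR":
            return _fr(ps, config)
        return _mfmn(ps) if key == "MFMN" else _mfmd(ps)
    time_domain: dict[str, Callable[[np.ndarray], float]] = {
        "RMS": _rms,
        "MAV": _mav,
        "WL": _wl,
        "ZC": lambda s: _zc(s, config.zc_threshold),
        "DASDV": _dasdv,
        "LOG": _log_printed if log_variant == "printed" else _log_conventional,
        "SSI": _ssi,
        "TM3": lambda s: _tm(s, 3),
        "TM4": lambda s: _tm(s, 4),
        "TM5": lambda s: _tm(s, 5),
        "IEMG": _iemg,
    }
    try:
        return time_domain[key](x)
    except KeyError:
        raise KeyError(f"unknown feature {name!r}; expected one of {FEATURE_NAMES}") from None


def build_feature_vector(
    channel_signal: np.ndarray, config: SpectralConfig = SpectralConfig()
) -> FeatureVector:
    """Assemble ``f = [1, x1..x14]`` for one channel of one window."""
    x = np.asarray(channel_signal, dtype=float).ravel()
    values = np.empty(len(FEATURE_NAMES) + 1)
    values[0] = 1.0
    # Compute the spectrum once and reuse it for the three spectral features.
    ps = power_spectrum(x, config)
    for k, name in enumerate(FEATURE_NAMES, start=1):
        if name == "FR":
            values[k] = _fr(ps, config)
        elif name == "MFMN":
            values[k] = _mfmn(ps)
        elif name == "MFMD":
            values[k] = _mfmd(ps)
        else:
            values[k] = evaluate_feature(name, x, config)
    return FeatureVector(values=values)


def feature_table(
    windows: Sequence, config: SpectralConfig = SpectralConfig()
):
    """Tabulate per-channel features for a sequence of windows.

    Returns a pandas DataFrame with columns ``window, channel, label,
    x1_RMS .. x14_MFMD``, suitable for delimited-text export.
    """
    import pandas as pd

    rows = []
    for wi, win in enumerate(windows):
        for ch in range(win.data.shape[0]):
            fv = build_feature_vector(win.data[ch], config)
            row = {"window": wi, "channel": ch, "label": win.label}
            row.update(
                {f"x{k + 1}_{name}": fv.values[k + 1] for k, name in enumerate(FEATURE_NAMES)}
            )
            rows.append(row)
    return pd.DataFrame(rows)
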