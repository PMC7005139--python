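"""Channel-level fNIRS preprocessing.

The stages, in pipeline order: voltage-to-OD conversion, bad-channel
rejection by coefficient of variation and saturation, Butterworth
band-pass filtering (high-pass order 3 at 0.009 Hz, low-pass order 7 at
0.08 Hz), optional global short-channel scalp regression (used only on
the minimum-norm branch), and motion time-point removal at 3 SD on the
short channels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

log = logging.getLogger(__name__)


@dataclass
class ChannelTimeSeries:
    """Multichannel, multiwavelength channel data.

    ``data`` is (time, channel, wavelength), either raw voltages
    (``units='V'``) or optical density (``units='OD'``); the two are never
    mixed in one container.
    """

    data: np.ndarray
    fs: float = 18.5
    wavelengths: tuple[float, ...] = (780.0, 805.0, 830.0)
    channel_class: np.ndarray | None = None  # "short"/"long" per channel
    channel_array: np.ndarray | None = None
    units: str = "V"
    bad_channels: np.ndarray = field(default=None)  # bool (C,)
    removed_timepoints: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    saturated: np.ndarray = field(default=None)  # bool (C,)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (time, channel, wavelength)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        C = self.data.shape[1]
        if self.bad_channels is None:
            self.bad_channels = np.zeros(C, dtype=bool)
        if self.saturated is None:
            self.saturated = np.zeros(C, dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def short_mask(self) -> np.ndarray:
        if self.channel_class is None:
            raise ValueError("channel classes not set")
        return np.asarray(self.channel_class) == "short"

    def good_mask(self) -> np.ndarray:
        return ~self.bad_channels


@dataclass(frozen=True)
class PreprocessConfig:
    """Thresholds and filter settings for the preprocessing chain."""

    cv_threshold: float = 15.0       # percent
    hp_order: int = 3
    hp_cutoff: float = 0.009         # Hz
    lp_order: int = 7
    lp_cutoff: float = 0.08          # Hz
    spike_sd: float = 3.0
    scalp_regression: bool = True    # MN / MN-WU branch only
    saturation_ceiling: float | None = None  # ADC ceiling in volts
    saturation_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.hp_order < 1 or self.lp_order < 1:
            raise ValueError("filter orders must be >= 1")


def detect_saturation(series: ChannelTimeSeries, ceiling: float,
                      fraction: float = 0.01) -> np.ndarray:
    """Flag channels whose voltage sits at the ADC ceiling too often.

    A channel is saturated when at least ``fraction`` of its samples are at
    or above ``ceiling`` at any wavelength.
    """
    if series.units != "V":
        raise ValueError("saturation is defined on voltage data")
    at_ceiling = (series.data >= ceiling).mean(axis=0)  # (C, W)
    return (at_ceiling >= fraction).any(axis=1)


def to_optical_density(series: ChannelTimeSeries) -> ChannelTimeSeries:
    """Convert voltages to base-10 optical density, -log10(V / mean V).

    The reference intensity is the per-channel, per-wavelength temporal
    mean.  Channels with any non-positive sample cannot be transformed and
    are flagged bad (their OD is set to zero) rather than silently
    producing non-finite values.
    """
    if series.units != "V":
        raise ValueError("input must be voltage data")
    v = series.data
    invalid = (v <= 0).any(axis=(0, 2))
    od = np.zeros_like(v)
    ok = ~invalid
    if ok.any():
        vref = v[:, ok, :].mean(axis=0, keepdims=True)
        od[:, ok, :] = -np.log10(v[:, ok, :] / vref)
    out = replace(series)
    out.data = od
    out.units = "OD"
    out.bad_channels = series.bad_channels | invalid
    out.saturated = series.saturated | invalid
    return out


def channel_cv(series: ChannelTimeSeries) -> np.ndarray:
    """Coefficient of variation, 100 * sigma / mu, percent, per (channel,
    wavelength), computed on the raw voltages (population SD)."""
    if series.units != "V":
        raise ValueError("CV is defined on raw voltage data")
    mu = series.data.mean(axis=0)
    sd = series.data.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * np.abs(sd / mu)
    cv[mu == 0] = np.inf
    return cv


def reject_bad_channels(cv: np.ndarray, saturation_flags: np.ndarray,
                        threshold: float = 15.0) -> np.ndarray:
    """Bad-channel mask: CV strictly above threshold at any wavelength, or
    saturated.  A CV of exactly the threshold is retained."""
    bad = (cv > threshold).any(axis=1) | np.asarray(saturation_flags, dtype=bool)
    if bad.all():
        raise RuntimeError("all channels rejected; check data quality / thresholds")
    return bad


def _design_sos(config: PreprocessConfig, fs: float) -> tuple[np.ndarray, np.ndarray]:
    nyq = fs / 2.0
    if not (0 < config.hp_cutoff < nyq and 0 < config.lp_cutoff < nyq):
        raise ValueError("filter cutoffs must lie below the Nyquist frequency")
    hp = signal.butter(config.hp_order, config.hp_cutoff, "highpass", fs=fs, output="sos")
    lp = signal.butter(config.lp_order, config.lp_cutoff, "lowpass", fs=fs, output="sos")
    return hp, lp


def butterworth_gain(freq: float, config: PreprocessConfig = PreprocessConfig()) -> float:
    """Analytic single-pass magnitude response of the HP+LP cascade,
    |H| = (1 + (fc/f)^(2*n_hp))^-1/2 * (1 + (f/fc)^(2*n_lp))^-1/2."""
    ghp = (1.0 + (config.hp_cutoff / freq) ** (2 * config.hp_order)) ** -0.5
    glp = (1.0 + (freq / config.lp_cutoff) ** (2 * config.lp_order)) ** -0.5
    return ghp * glp


def bandpass(series: ChannelTimeSeries, config: PreprocessConfig = PreprocessConfig(),
             mode: str = "zero_phase") -> ChannelTimeSeries:
    """Cascade high-pass then low-pass Butterworth filtering along time.

    ``zero_phase`` applies each stage forward-backward (no phase
    distortion, squared magnitude response); ``single_pass`` applies a
    causal single pass whose gain follows the analytic Butterworth
    magnitude formula.
    """
    hp, lp = _design_sos(config, series.fs)
    min_len = 3 * max(config.hp_order, config.lp_order) + 1
    if series.n_samples <= min_len:
        raise ValueError(f"series too short to filter stably (need > {min_len})")
    x = series.data
    if mode == "zero_phase":
        y = signal.sosfiltfilt(hp, x, axis=0)
        y = signal.sosfiltfilt(lp, y, axis=0)
    elif mode == "single_pass":
        y = signal.sosfilt(hp, x, axis=0)
        y = signal.sosfilt(lp, y, axis=0)
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    out = replace(series)
    out.data = y
    return out


def regress_scalp_global(series: ChannelTimeSeries,
                         short_mask: np.ndarray | None = None,
                         bad_mask: np.ndarray | None = None) -> ChannelTimeSeries:
    """Regress the global mean of the good short channels out of every channel.

    The global short-channel average (per wavelength) is taken as the scalp
    hemodynamics; each channel's least-squares fit on [1, g] is removed,
    leaving residuals orthogonal to the regressor.  Used only on the
    minimum-norm branch; the hierarchical-Bayes solver sees unregressed
    data because it models the scalp compartment explicitly.
    """
    if short_mask is None:
        short_mask = series.short_mask
    if bad_mask is None:
        bad_mask = series.bad_channels
    good_short = np.asarray(short_mask) & ~np.asarray(bad_mask)
    if not good_short.any():
        raise RuntimeError("no good short channels available for scalp regression")
    x = series.data
    out = replace(series)
    y = x.copy()
    for w in range(x.shape[2]):
        g = x[:, good_short, w].mean(axis=1)
        gd = g - g.mean()
        denom = gd @ gd
        if denom <= 0:
            warnings.warn("zero-variance scalp regressor; data returned unchanged")
            continue
        X = np.column_stack([np.ones_like(g), g])
        coef, *_ = np.linalg.lstsq(X, x[:, :, w], rcond=None)
        y[:, :, w] = x[:, :, w] - X @ coef
    out.data = y
    return out


def remove_bad_timepoints(series: ChannelTimeSeries,
                          short_mask: np.ndarray | None = None,
                          bad_mask: np.ndarray | None = None,
                          k: float = 3.0) -> tuple[ChannelTimeSeries, np.ndarray]:
    """Drop time points that exceed k SD from the mean on any good short channel.

    Statistics are computed per channel on the (filtered) series; channels
    with zero SD never trigger removal.  The same index set is removed
    from every channel.  Returns the reduced series and the retained
    indices; the removed indices are recorded on the result.
    """
    if short_mask is None:
        short_mask = series.short_mask
    if bad_mask is None:
        bad_mask = series.bad_channels
    good_short = np.asarray(short_mask) & ~np.asarray(bad_mask)
    x = series.data[:, good_short, :]
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    with np.errstate(invalid="ignore"):
        over = np.abs(x - mu) > k * sd
    over &= sd > 0
    bad_t = over.any(axis=(1, 2))
    if bad_t.all():
        raise RuntimeError("every time point flagged as motion; aborting")
    if bad_t.mean() > 0.5:
        warnings.warn(f"{bad_t.mean():.0%} of time points removed")
    retained = np.flatnonzero(~bad_t)
    out = replace(series)
    out.data = series.data[retained]
    out.removed_timepoints = np.flatnonzero(bad_t)
    return out, retained


def preprocess_run(voltages: ChannelTimeSeries,
                   config: PreprocessConfig = PreprocessConfig(),
                   filter_mode: str = "zero_phase",
                   ) -> tuple[ChannelTimeSeries, ChannelTimeSeries, dict]:
    """Full chain for one run, returning both solver branches.

    Returns ``(hb_branch, mn_branch, info)``: the hierarchical-Bayes branch
    is band-passed OD without scalp regression; the minimum-norm branch
    additionally has the global short-channel scalp signal regressed out.
    Both share the same bad-channel mask and removed time points (the
    motion criterion is evaluated on the unregressed branch).
    """
    cv = channel_cv(voltages)
    sat = voltages.saturated.copy()
    if config.saturation_ceiling is not None:
        sat |= detect_saturation(voltages, config.saturation_ceiling,
                                 config.saturation_fraction)
    od = to_optical_density(voltages)
    bad = reject_bad_channels(cv, sat | od.bad_channels, config.cv_threshold)
    od.bad_channels = bad
    od.saturated = sat
    filt = bandpass(od, config, mode=filter_mode)
    filt_hb, retained = remove_bad_timepoints(filt, k=config.spike_sd)
    if config.scalp_regression:
        filt_mn = regress_scalp_global(filt_hb)
    else:
        filt_mn = filt_hb
    info = {
        "cv": cv,
        "bad_channels": bad,
        "n_bad_channels": int(bad.sum()),
        "removed_timepoints": filt_hb.removed_timepoints,
        "n_removed": int(filt_hb.removed_timepoints.size),
        "n_retained": int(retained.size),
    }
    log.info("preprocess: %d bad channels, %d time points removed",
             info["n_bad_channels"], info["n_removed"])
    return filt_hb, filt_mn, info
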