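"""Spectral feature extraction for quantitative EEG.

Implements the transformation of a 60-s EEG epoch into the spectral
quantities used throughout the package:

* Welch power spectral density at 1-Hz bins (Hann window, 1-s data blocks,
  half overlap, per-segment mean removal),
* band powers over inclusive integer frequency ranges
  (theta 4-7 Hz, alpha 8-12 Hz, beta 13-25 Hz, delta 0-3 Hz),
* the normalized spectrum (per-bin share of total 0-50 Hz power),
* the theta/beta ratio (TBR), and
* the attention-to-resting alpha power ratio, the biomarker of interest:
  alpha power during a sustained-attention task divided by alpha power
  during eyes-closed rest (lower values = stronger attention-related
  alpha suppression).

Scaling follows the Parseval convention: per-bin power in uV^2 with Hann
window power compensation, so the 0-Nyquist sum approximates the signal
variance. At 1-s windows and 1-Hz bins, per-bin power and spectral density
coincide numerically. Frequencies are always identified by their integer Hz
value, never by array index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .recording import CleanEpoch

#: Inclusive integer band edges in Hz. Delta is used for simulation and
#: per-frequency reporting only.
DEFAULT_BANDS: dict[str, tuple[int, int]] = {
    "delta": (0, 3),
    "theta": (4, 7),
    "alpha": (8, 12),
    "beta": (13, 25),
}

TOTAL_BAND: tuple[int, int] = (0, 50)


@dataclass
class SpectralConfig:
    """Welch estimation and band-definition settings.

    ``aggregate="mean"`` is standard Welch averaging across segments;
    ``"sum"`` multiplies by the segment count for pipelines that accumulate
    rather than average block periodograms. The constant factor cancels in
    every normalized quantity, the TBR and the alpha ratio.
    """

    window_len: float = 1.0          # seconds per data block
    overlap_frac: float = 0.5        # fraction of block overlap
    window_shape: str = "hann"
    freq_resolution: float = 1.0     # Hz
    total_band: tuple[int, int] = TOTAL_BAND
    bands: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    aggregate: str = "mean"          # "mean" | "sum"

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_frac < 1:
            raise ValueError("overlap_frac must lie in [0, 1)")
        if self.window_shape != "hann":
            raise ValueError("only the Hann window is supported")
        if self.aggregate not in ("mean", "sum"):
            raise ValueError("aggregate must be 'mean' or 'sum'")
        for name, (lo, hi) in self.bands.items():
            if hi < lo:
                raise ValueError(f"band {name!r} is empty")


@dataclass
class PowerSpectrum:
    """Per-channel Welch power at integer 1-Hz bins, in uV^2 per bin."""

    channel_labels: tuple[str, ...]
    freqs: np.ndarray                # integer Hz bins, 0..fs/2
    power: np.ndarray                # (n_channels, n_freqs), >= 0
    n_segments: int
    config: SpectralConfig

    def values(self) -> np.ndarray:
        return self.power


@dataclass
class NormalizedSpectrum:
    """Per-bin share of total 0-50 Hz power; each channel sums to 1."""

    channel_labels: tuple[str, ...]
    freqs: np.ndarray                # integer Hz bins, 0..50
    fraction: np.ndarray             # (n_channels, n_freqs), in [0, 1]

    def values(self) -> np.ndarray:
        return self.fraction


def expected_n_segments(n_samples: int, window_samples: int, overlap_frac: float) -> int:
    """Segment count of Welch's method: floor((N-L)/(L*(1-overlap))) + 1."""
    step = int(round(window_samples * (1.0 - overlap_frac)))
    return (n_samples - window_samples) // step + 1


def compute_welch_psd(epoch: CleanEpoch, config: SpectralConfig | None = None) -> PowerSpectrum:
    """Welch PSD of a clean epoch at 1-Hz bins.

    Each data block is mean-subtracted, Hann-windowed and periodogram-scaled
    with window power compensation (one-sided, non-DC/non-Nyquist bins
    doubled) so that the 0-Nyquist per-bin sum approximates the signal
    variance. Blocks are combined according to ``config.aggregate``.
    """
    config = config or SpectralConfig()
    fs = epoch.fs
    nperseg = fs * config.window_len
    if abs(nperseg - round(nperseg)) > 1e-9:
        raise ValueError("fs x window_len must be an integer number of samples")
    nperseg = int(round(nperseg))
    data = epoch.data
    if data.shape[1] < nperseg:
        raise ValueError("epoch too short")
    if not np.all(np.isfinite(data)):
        raise ValueError("invalid signal")

    noverlap = int(round(nperseg * config.overlap_frac))
    freqs, pxx = sps.welch(
        data,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        average="mean",
        axis=-1,
    )
    # density (uV^2/Hz) -> power per bin (uV^2) at bin width 1/window_len Hz
    pxx = pxx * (1.0 / config.window_len)
    n_seg = expected_n_segments(data.shape[1], nperseg, config.overlap_frac)
    if config.aggregate == "sum":
        pxx = pxx * n_seg
    return PowerSpectrum(
        channel_labels=epoch.channel_labels,
        freqs=np.round(freqs).astype(int) if config.freq_resolution == 1.0 else freqs,
        power=pxx,
        n_segments=n_seg,
        config=config,
    )


def band_power(
    spectrum: PowerSpectrum | NormalizedSpectrum,
    band: tuple[int, int] | str,
) -> np.ndarray:
    """Sum of per-bin values over the inclusive range ``lo..hi`` Hz.

    ``band`` may be a named band ("theta", "alpha", "beta", "delta",
    "total") or an explicit ``(lo, hi)`` pair of integer Hz edges.
    Returns one value per channel.
    """
    if isinstance(band, str):
        if band == "total":
            lo, hi = TOTAL_BAND
        else:
            bands = getattr(getattr(spectrum, "config", None), "bands", DEFAULT_BANDS)
            if band not in bands:
                raise KeyError(f"unknown band {band!r}")
            lo, hi = bands[band]
    else:
        lo, hi = band
    freqs = np.asarray(spectrum.freqs)
    if lo < freqs.min() or hi > freqs.max():
        raise ValueError(f"band [{lo}, {hi}] outside spectrum support "
                         f"[{freqs.min()}, {freqs.max()}]")
    mask = (freqs >= lo) & (freqs <= hi)
    return spectrum.values()[:, mask].sum(axis=1)


def normalize_spectrum(spectrum: PowerSpectrum) -> NormalizedSpectrum:
    """Per-bin power divided by the channel's total 0-50 Hz power."""
    lo, hi = getattr(spectrum.config, "total_band", TOTAL_BAND)
    freqs = np.asarray(spectrum.freqs)
    mask = (freqs >= lo) & (freqs <= hi)
    sub = spectrum.power[:, mask]
    totals = sub.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("degenerate spectrum: zero total 0-50 Hz power")
    return NormalizedSpectrum(
        channel_labels=spectrum.channel_labels,
        freqs=freqs[mask],
        fraction=sub / totals[:, None],
    )


def theta_beta_ratio(spectrum: PowerSpectrum | NormalizedSpectrum) -> np.ndarray:
    """Theta-band power divided by beta-band power, per channel.

    Identical whether computed on a raw or a normalized spectrum (the
    normalization constant cancels).
    """
    theta = band_power(spectrum, "theta")
    beta = band_power(spectrum, "beta")
    if np.any(beta <= 0):
        raise ValueError("undefined TBR: zero beta power")
    return theta / beta


def alpha_ratio(
    attention: PowerSpectrum | NormalizedSpectrum,
    resting: PowerSpectrum | NormalizedSpectrum,
) -> np.ndarray:
    """Attention-to-resting alpha power ratio, per channel.

    Alpha-band (8-12 Hz) power during the attention task divided by
    alpha-band power during eyes-closed rest. Both inputs must cover the
    same channels; pass two :class:`NormalizedSpectrum` objects for the
    normalized-mode ratio (the default elsewhere in the package) or two raw
    :class:`PowerSpectrum` objects for the raw-power ratio.
    """
    if tuple(attention.channel_labels) != tuple(resting.channel_labels):
        raise ValueError("channel mismatch between attention and resting spectra")
    a = band_power(attention, "alpha")
    r = band_power(resting, "alpha")
    if np.any(r <= 0):
        raise ValueError("zero resting alpha power")
    return a / r


def per_frequency_spectra(
    spectra_by_group: dict[str, list[NormalizedSpectrum]],
) -> pd.DataFrame:
    """Group-mean normalized spectra with per-bin dispersion.

    Parameters
    ----------
    spectra_by_group : dict
        Maps group label to the list of per-participant normalized spectra
        (same channels and bins for every member).

    Returns
    -------
    DataFrame with columns ``group, channel, freq, mean, sd, n`` — the
    per-group mean and standard deviation of the normalized power at each
    0-50 Hz bin, ready for the per-frequency t-test.
    """
    rows = []
    for group, spectra in spectra_by_group.items():
        if len(spectra) == 0:
            raise ValueError(f"empty group {group!r}")
        ref = spectra[0]
        stack = np.stack([s.fraction for s in spectra])  # (n, ch, f)
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=1) if len(spectra) > 1 else np.zeros_like(mean)
        for ci, ch in enumerate(ref.channel_labels):
            for fi, f in enumerate(np.asarray(ref.freqs)):
                rows.append((group, ch, int(f), mean[ci, fi], sd[ci, fi], len(spectra)))
    return pd.DataFrame(rows, columns=["group", "channel", "freq", "mean", "sd", "n"])


def spectral_features(
    resting: PowerSpectrum,
    attention: PowerSpectrum | None = None,
    ratio_mode: str = "normalized",
) -> pd.DataFrame:
    """Per-channel feature table for one participant.

    Columns: ``channel, theta_power, alpha_power, beta_power,
    total_power_0_50, tbr`` and, when an attention spectrum is supplied,
    ``alpha_ratio`` computed in ``ratio_mode`` ("normalized" or "raw").
    Band powers and TBR are always taken from the resting spectrum.
    """
    if ratio_mode not in ("normalized", "raw"):
        raise ValueError("ratio_mode must be 'normalized' or 'raw'")
    df = pd.DataFrame({
        "channel": list(resting.channel_labels),
        "theta_power": band_power(resting, "theta"),
        "alpha_power": band_power(resting, "alpha"),
        "beta_power": band_power(resting, "beta"),
        "total_power_0_50": band_power(resting, "total"),
        "tbr": theta_beta_ratio(resting),
    })
    if attention is not None:
        if ratio_mode == "normalized":
            ratio = alpha_ratio(normalize_spectrum(attention), normalize_spectrum(resting))
        else:
            ratio = alpha_ratio(attention, resting)
        df["alpha_ratio"] = ratio
    return df
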