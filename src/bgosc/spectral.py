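"""Morlet-wavelet spectral estimation, band summaries, and peak handling.

Spectral power is estimated by convolving the conditioned continuous signal
with L2-normalized complex Morlet wavelets (default 7 cycles at every
frequency) and averaging squared coefficient magnitude over time and epochs.
With the L2 normalization used here, ``2 * E|c(f)|^2`` is an estimate of the
one-sided power spectral density at f, so Morlet band power is directly
comparable to a Welch periodogram of the same signal.

Impedance differences between electrodes rescale the raw voltage; spectra
are therefore normalized by dividing the time-domain signal by its standard
deviation (equivalently dividing power by the signal variance), which makes
the spectrum invariant to any positive rescaling of the input.

Peak detection removes the aperiodic 1/f trend by a linear fit of log-power
on log-frequency (line-noise band excluded) and searches the flattened
spectrum for the most prominent in-band local maximum. The flatten-and-align
display shifts each flattened spectrum so individual peak frequencies
coincide at relative frequency zero before group averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig
from scipy.fft import fft as _fft, ifft as _ifft, next_fast_len

from .preprocess import EpochedChannel

#: Canonical analysis bands (Hz, inclusive).
BANDS: dict[str, tuple[float, float]] = {"low_frequency": (3.0, 12.0), "beta": (13.0, 35.0)}

#: Line-noise band excluded from the aperiodic fit.
NOTCH_EXCLUDE = (48.0, 52.0)


def default_freq_grid(lo: float = 1.0, hi: float = 98.0, step: float = 0.5) -> np.ndarray:
    return np.round(np.arange(lo, hi + step / 2, step), 6)


@dataclass
class TimeFrequencyCoefficients:
    """Complex Morlet coefficients sliced into epochs.

    ``coeffs`` has shape [n_epochs x n_freqs x epoch_samples]. ``valid`` marks
    coefficient samples farther than half a wavelet length from the edges of
    the underlying continuous recording; only valid samples enter averages.
    ``signal_variance`` is the variance of the conditioned input, kept for
    the impedance (standard deviation) normalization of power.
    """

    freqs: np.ndarray
    fs: float
    n_cycles: float
    coeffs: np.ndarray
    valid: np.ndarray
    signal_variance: float
    structure: str | None = None

    @property
    def n_epochs(self) -> int:
        return self.coeffs.shape[0]


@dataclass
class Peak:
    freq_hz: float
    prominence: float


@dataclass
class SpectralResult:
    """Normalized per-channel power spectrum with band summaries."""

    freqs: np.ndarray
    power: np.ndarray
    band_means: dict[str, float]
    structure: str | None = None
    peaks: dict[str, Peak | None] = field(default_factory=dict)
    normalized: bool = True


def morlet_kernel(f: float, fs: float, n_cycles: float = 7.0) -> np.ndarray:
    """L2-normalized complex Morlet wavelet sampled at ``fs``.

    The Gaussian envelope has sigma_t = n_cycles / (2 pi f); support is
    truncated at +-5 sigma_t. Normalization enforces integral |psi|^2 dt = 1.
    """
    sigma_t = n_cycles / (2.0 * np.pi * f)
    half = int(np.ceil(5.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    k = np.exp(2j * np.pi * f * t) * np.exp(-(t**2) / (2.0 * sigma_t**2))
    k /= np.sqrt(np.sum(np.abs(k) ** 2) / fs)
    return k


def morlet_transform(
    epochs: EpochedChannel,
    freqs: np.ndarray | None = None,
    n_cycles: float = 7.0,
) -> TimeFrequencyCoefficients:
    """Morlet transform of an epoched channel.

    The convolution runs on the continuous conditioned series (a 7-cycle
    wavelet at 3 Hz is longer than a 2 s epoch, so per-epoch convolution
    would leave no usable low-frequency samples); the coefficient stream is
    then sliced at the epoch boundaries. Samples within half a wavelet
    length of the recording edges are flagged invalid per frequency.
    """
    freqs = default_freq_grid() if freqs is None else np.asarray(freqs, dtype=float)
    fs = epochs.fs_out
    if freqs.max() >= fs / 2.0:
        raise ValueError(f"max frequency {freqs.max()} Hz is at or above Nyquist ({fs / 2} Hz)")
    if n_cycles < 3:
        raise ValueError("n_cycles must be at least 3 for a usable Morlet wavelet")
    x = epochs.data
    n = len(x)
    kernels = [morlet_kernel(f, fs, n_cycles) for f in freqs]
    halves = np.array([(len(k) - 1) // 2 for k in kernels])
    hmax = int(halves.max())
    width = 2 * hmax + 1
    bank = np.zeros((len(freqs), width), dtype=np.complex128)
    for i, k in enumerate(kernels):
        h = halves[i]
        bank[i, hmax - h : hmax + h + 1] = k
    # c(t) = integral x(tau) psi*(tau - t) dtau  ==  (x conv psi)(t) * dt,
    # batched over the wavelet bank via a single FFT of the signal
    nfft = next_fast_len(n + width - 1)
    X = _fft(x, nfft)
    K = _fft(bank, nfft, axis=1)
    full = _ifft(X[None, :] * K, axis=1)[:, : n + width - 1]
    coeffs_cont = full[:, hmax : hmax + n] / fs  # 'same' alignment

    t_idx = epochs.starts[:, None] + np.arange(epochs.epoch_samples)[None, :]
    coeffs = coeffs_cont[:, t_idx]  # [freq, epoch, time]
    coeffs = np.transpose(coeffs, (1, 0, 2))  # [epoch, freq, time]
    dist_edge = np.minimum(t_idx, n - 1 - t_idx)  # [epoch, time]
    valid = dist_edge[:, None, :] >= halves[None, :, None]
    return TimeFrequencyCoefficients(
        freqs=freqs,
        fs=fs,
        n_cycles=n_cycles,
        coeffs=coeffs,
        valid=valid,
        signal_variance=float(np.var(x)),
        structure=epochs.structure,
    )


def band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    return (freqs >= band[0]) & (freqs <= band[1])


def power_spectrum(
    coeffs: TimeFrequencyCoefficients,
    normalize: bool = True,
    bands: dict[str, tuple[float, float]] | None = None,
) -> SpectralResult:
    """Average |coefficient|^2 into a power spectrum with band means.

    ``power(f) = 2 * mean over valid epoch samples of |c(f,t)|^2`` (one-sided
    PSD scale). With ``normalize`` the power is divided by the signal
    variance, the impedance correction.
    """
    bands = BANDS if bands is None else bands
    mag2 = np.abs(coeffs.coeffs) ** 2
    w = coeffs.valid
    denom = w.sum(axis=(0, 2)).astype(float)
    if np.any(denom == 0):
        raise ValueError("some frequencies have no valid samples (recording too short)")
    power = 2.0 * (mag2 * w).sum(axis=(0, 2)) / denom
    if normalize:
        if coeffs.signal_variance == 0:
            raise ValueError("constant channel: zero variance, normalization undefined")
        power = power / coeffs.signal_variance
    band_means = {}
    for name, band in bands.items():
        m = band_mask(coeffs.freqs, band)
        band_means[name] = float(power[m].mean()) if m.any() else np.nan
    return SpectralResult(
        freqs=coeffs.freqs,
        power=power,
        band_means=band_means,
        structure=coeffs.structure,
        normalized=normalize,
    )


#: Bands excluded from the aperiodic (1/f) fit: the two oscillation bands
#: and the line-noise notch. Leaving the oscillatory bumps in the fit drags
#: the trend upward by an amount that varies with bump size, biasing the
#: flattened peak heights; the fit runs on aperiodic-only bins instead.
APERIODIC_FIT_EXCLUDE: tuple[tuple[float, float], ...] = (
    BANDS["low_frequency"],
    BANDS["beta"],
    NOTCH_EXCLUDE,
)


def _aperiodic_flatten(
    freqs: np.ndarray,
    power: np.ndarray,
    fit_exclude: tuple[tuple[float, float], ...] = APERIODIC_FIT_EXCLUDE,
) -> np.ndarray:
    """Residual of a linear fit of log10 power on log10 frequency.

    The fit runs over the aperiodic part of the spectrum (oscillation bands
    and the line-noise band excluded); the residual — the flattened
    spectrum, in log10 units — is returned on all positive-power bins.
    Falls back to a notch-only exclusion when the grid leaves too few
    aperiodic bins.
    """
    good = power > 0
    fit_mask = good.copy()
    for lo, hi in fit_exclude:
        fit_mask &= ~((freqs >= lo) & (freqs <= hi))
    if fit_mask.sum() < 3:
        fit_mask = good & ~((freqs >= NOTCH_EXCLUDE[0]) & (freqs <= NOTCH_EXCLUDE[1]))
    if fit_mask.sum() < 3:
        raise ValueError("too few positive-power bins for an aperiodic fit")
    lf = np.log10(freqs[fit_mask])
    lp = np.log10(power[fit_mask])
    slope, intercept = np.polyfit(lf, lp, 1)
    flattened = np.full_like(power, np.nan, dtype=float)
    flattened[good] = np.log10(power[good]) - (intercept + slope * np.log10(freqs[good]))
    return flattened


def peak_height(spec: "SpectralResult", band: str | tuple[float, float] = "low_frequency") -> float:
    """Maximum flattened (1/f-removed) log10 power inside a band.

    A background-robust summary of oscillatory band power: the height of
    the spectral bump above the aperiodic trend, insensitive to broadband
    scale and to the baseline that dilutes plain band means.
    """
    band_hz = BANDS[band] if isinstance(band, str) else band
    flat = _aperiodic_flatten(spec.freqs, spec.power)
    m = band_mask(spec.freqs, band_hz)
    if not m.any():
        raise ValueError("band not covered by the frequency grid")
    return float(np.nanmax(flat[m]))


def detect_peak(
    spec: SpectralResult,
    band: str | tuple[float, float] = "low_frequency",
    prominence_frac: float = 0.05,
    min_prominence: float = 1e-3,
) -> Peak | None:
    """Most prominent in-band local maximum of the flattened spectrum.

    The 1/f trend is removed (log-log linear fit), then local maxima inside
    the band are screened by prominence: a peak must exceed
    ``prominence_frac`` of the flattened in-band range (and a small absolute
    floor guarding against floating-point ripple on featureless spectra).
    Returns None when no maximum qualifies — absence is a valid outcome.
    """
    band_hz = BANDS[band] if isinstance(band, str) else band
    flat = _aperiodic_flatten(spec.freqs, spec.power)
    m = band_mask(spec.freqs, band_hz)
    if m.sum() < 3:
        raise ValueError("band is not covered by the frequency grid")
    seg = flat[m]
    if np.any(np.isnan(seg)):
        return None
    rng_ = float(np.nanmax(seg) - np.nanmin(seg))
    thresh = max(prominence_frac * rng_, min_prominence)
    # pad with the in-band minimum so band-edge maxima are detectable while
    # a flat segment yields no strict maximum at all
    pad = float(seg.min())
    padded = np.concatenate(([pad], seg, [pad]))
    locs, props = _sig.find_peaks(padded, prominence=thresh)
    if len(locs) == 0:
        return None
    best = np.argmax(seg[locs - 1])
    return Peak(
        freq_hz=float(spec.freqs[m][locs[best] - 1]),
        prominence=float(props["prominences"][best]),
    )


def flatten_align(
    specs: list[SpectralResult],
    band: str | tuple[float, float] = "low_frequency",
    prominence_frac: float = 0.05,
) -> dict:
    """Flatten spectra and align them at their individual peak frequencies.

    Spectra without a qualifying in-band peak are skipped (reported in the
    result). Aligned spectra are interpolated onto a common relative
    frequency grid (peak at 0); the group mean ignores missing bins.
    """
    band_hz = BANDS[band] if isinstance(band, str) else band
    used, skipped, flats, peaks = [], [], [], []
    for i, spec in enumerate(specs):
        pk = detect_peak(spec, band_hz, prominence_frac=prominence_frac)
        if pk is None:
            skipped.append(i)
            continue
        used.append(i)
        peaks.append(pk.freq_hz)
        flats.append(_aperiodic_flatten(spec.freqs, spec.power))
    if not used:
        raise ValueError("no spectrum has a detectable peak in the requested band")
    freqs = specs[used[0]].freqs
    step = float(np.median(np.diff(freqs)))
    half_span = band_hz[1] - band_hz[0]
    rel = np.round(np.arange(-half_span, half_span + step / 2, step), 6)
    aligned = np.full((len(used), len(rel)), np.nan)
    for row, (idx, pk_hz) in enumerate(zip(used, peaks)):
        f = specs[idx].freqs
        aligned[row] = np.interp(rel, f - pk_hz, flats[row], left=np.nan, right=np.nan)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        group_mean = np.nanmean(aligned, axis=0)
    return {
        "rel_freqs": rel,
        "aligned": aligned,
        "group_mean": group_mean,
        "peak_freqs": np.array(peaks),
        "used": used,
        "skipped": skipped,
    }
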