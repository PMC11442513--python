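"""Signal conditioning and epoching.

Raw channels are anti-alias decimated to 200 Hz, then zero-phase filtered:
high-pass 1 Hz, low-pass 98 Hz, band-stop 48-52 Hz for line noise. Filters
are forward-backward Butterworth (order 4 per pass), so no phase distortion
is introduced — a prerequisite for phase-based connectivity measures.

Epoching cuts the conditioned series into contiguous non-overlapping windows
(default 2 s). Epochs overlapping artifact-masked samples are dropped. The
epoch object retains the underlying continuous series so that the wavelet
transform can run on unbroken data and slice coefficients afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal


@dataclass
class PreprocessConfig:
    fs_out: float = 200.0
    hp_hz: float = 1.0
    lp_hz: float = 98.0
    notch_band: tuple[float, float] = (48.0, 52.0)
    filter_order: int = 4
    epoch_length_s: float = 2.0
    #: |z|-score threshold for the optional amplitude artifact mask; None = off.
    artifact_z: float | None = None


@dataclass
class EpochedChannel:
    """Conditioned channel cut into equal, non-overlapping epochs.

    ``data`` is the full conditioned series at ``fs_out``; ``starts`` holds
    the sample index at which each retained epoch begins. The ``epochs``
    property materializes the [n_epochs x epoch_samples] matrix.
    """

    fs_out: float
    data: np.ndarray
    starts: np.ndarray
    epoch_samples: int
    epoch_length_s: float
    structure: str | None = None
    n_dropped: int = 0

    @property
    def n_epochs(self) -> int:
        return len(self.starts)

    @property
    def epochs(self) -> np.ndarray:
        idx = self.starts[:, None] + np.arange(self.epoch_samples)[None, :]
        return self.data[idx]


def _sos_filters(fs: float, cfg: PreprocessConfig) -> list[np.ndarray]:
    nyq = fs / 2.0
    filts = [signal.butter(cfg.filter_order, cfg.hp_hz / nyq, btype="highpass", output="sos")]
    if cfg.lp_hz < nyq * 0.999:
        filts.append(signal.butter(cfg.filter_order, cfg.lp_hz / nyq, btype="lowpass", output="sos"))
    lo, hi = cfg.notch_band
    filts.append(signal.butter(cfg.filter_order, [lo / nyq, hi / nyq], btype="bandstop", output="sos"))
    return filts


def condition(x: np.ndarray, fs_in: float, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Decimate to ``cfg.fs_out`` with anti-aliasing, then zero-phase filter.

    Output length is ``round(len(x) * fs_out / fs_in)``. Raises when the
    input rate cannot honor the low-pass cutoff (``fs_in < 2 * lp_hz``).
    """
    cfg = cfg or PreprocessConfig()
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("condition expects a single channel (1-D array)")
    if fs_in < 2.0 * cfg.lp_hz:
        raise ValueError(
            f"input rate {fs_in} Hz cannot represent the {cfg.lp_hz} Hz low-pass band"
        )
    n_out = int(round(len(x) * cfg.fs_out / fs_in))
    if fs_in != cfg.fs_out:
        frac = Fraction(cfg.fs_out / fs_in).limit_denominator(10_000)
        y = signal.resample_poly(x, frac.numerator, frac.denominator)
        y = y[:n_out] if len(y) >= n_out else np.pad(y, (0, n_out - len(y)))
    else:
        y = x.copy()
    for sos in _sos_filters(cfg.fs_out, cfg):
        y = signal.sosfiltfilt(sos, y)
    return y


def amplitude_artifact_mask(x: np.ndarray, z: float) -> np.ndarray:
    """Boolean mask of samples whose |z-score| exceeds ``z``."""
    sd = np.std(x)
    if sd == 0:
        return np.zeros(len(x), dtype=bool)
    return np.abs((x - np.mean(x)) / sd) > z


def epoch(
    x: np.ndarray,
    fs: float,
    epoch_length_s: float = 2.0,
    artifact_mask: np.ndarray | None = None,
    structure: str | None = None,
) -> EpochedChannel:
    """Cut a conditioned series into contiguous non-overlapping epochs.

    Any epoch intersecting a True sample of ``artifact_mask`` is dropped.
    Raises when no epoch survives.
    """
    x = np.asarray(x, dtype=np.float64)
    n_len = int(round(epoch_length_s * fs))
    if n_len < 2:
        raise ValueError("epoch length must span at least two samples")
    n_total = len(x) // n_len
    if n_total < 1:
        raise ValueError(
            f"series of {len(x)} samples is shorter than one {epoch_length_s} s epoch"
        )
    starts = np.arange(n_total) * n_len
    if artifact_mask is not None:
        artifact_mask = np.asarray(artifact_mask, dtype=bool)
        if len(artifact_mask) != len(x):
            raise ValueError("artifact mask length must match the series")
        bad = np.array([artifact_mask[s : s + n_len].any() for s in starts])
        starts = starts[~bad]
    n_dropped = n_total - len(starts)
    if len(starts) == 0:
        raise ValueError("all epochs intersect artifact-masked samples; nothing left to analyze")
    return EpochedChannel(
        fs_out=fs,
        data=x,
        starts=starts,
        epoch_samples=n_len,
        epoch_length_s=epoch_length_s,
        structure=structure,
        n_dropped=n_dropped,
    )
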