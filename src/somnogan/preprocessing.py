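"""Raw labelled EEG → stage-labelled wavelet time–frequency images.

The offline pipeline mirrors standard sleep-EEG practice: Butterworth
low-pass filtering at 35 Hz (8th order), optional 50 Hz notch for mains
interference, R&K → AASM stage mapping (3/4 merged into N3, MOVEMENT and
UNKNOWN excluded), trimming to the sleep period plus configurable wake
margins, slicing into 30-s epochs, complex-Morlet continuous wavelet
transform, and rendering to fixed-size three-channel images in [−1, 1]
through a perceptually uniform colormap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

from .containers import REAL, ImageSet, Recording

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec", "CWTConfig", "Scalogram", "NoSleepError", "lowpass_filter",
    "notch_filter", "map_stages", "trim_recording", "slice_epochs",
    "cwt_scalogram", "render_tf_image", "preprocess_recording",
    "read_edf_recording",
]


class NoSleepError(ValueError):
    """Raised when a hypnogram contains no sleep epoch at all."""


@dataclass(frozen=True)
class FilterSpec:
    """IIR filter description.

    ``kind``: ``"lowpass"`` (Butterworth, ``cutoff_hz``/``order``) or
    ``"notch"`` (second-order IIR, ``cutoff_hz`` is the centre, ``q`` the
    quality factor).  ``application`` selects zero-phase forward–backward
    filtering (default, standard for offline EEG) or a causal single pass.
    """

    kind: str = "lowpass"
    cutoff_hz: float = 35.0
    order: int = 8
    q: float = 30.0
    application: str = "forward-backward"

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "notch"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.application not in ("forward-backward", "single-pass"):
            raise ValueError(f"unknown application {self.application!r}")


def lowpass_filter(x: np.ndarray, fs: float,
                   spec: FilterSpec | None = None) -> np.ndarray:
    """Butterworth low-pass filter (default: 8th order, 35 Hz cut-off)."""
    spec = spec or FilterSpec()
    if spec.kind != "lowpass":
        raise ValueError("lowpass_filter needs a lowpass FilterSpec")
    if not 0 < spec.cutoff_hz < fs / 2:
        raise ValueError(f"cutoff {spec.cutoff_hz} Hz not in (0, fs/2)")
    x = np.asarray(x, dtype=float)
    if len(x) <= 3 * spec.order:
        raise ValueError("signal too short for the requested filter order")
    sos = sps.butter(spec.order, spec.cutoff_hz, btype="low", fs=fs,
                     output="sos")
    if spec.application == "forward-backward":
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def notch_filter(x: np.ndarray, fs: float,
                 spec: FilterSpec | None = None) -> np.ndarray:
    """Narrow IIR notch (default 50 Hz, Q = 30) for mains interference."""
    spec = spec or FilterSpec(kind="notch", cutoff_hz=50.0)
    if spec.kind != "notch":
        raise ValueError("notch_filter needs a notch FilterSpec")
    if not 0 < spec.cutoff_hz < fs / 2:
        raise ValueError(f"notch centre {spec.cutoff_hz} Hz not in (0, fs/2)")
    x = np.asarray(x, dtype=float)
    b, a = sps.iirnotch(spec.cutoff_hz, spec.q, fs=fs)
    if spec.application == "forward-backward":
        return sps.filtfilt(b, a, x)
    return sps.lfilter(b, a, x)


# ---------------------------------------------------------------------------
# stage bookkeeping

_RK_TO_AASM = {"W": "Wake", "1": "N1", "2": "N2", "3": "N3", "4": "N3",
               "R": "REM"}
_EXCLUDED = {"MOVEMENT", "UNKNOWN"}


def map_stages(labels: list[str]) -> tuple[list[str | None], np.ndarray]:
    """Map R&K labels to AASM, merging 3/4 into N3.

    Returns ``(aasm_labels, keep_mask)``; MOVEMENT/UNKNOWN positions are
    ``None`` with ``keep_mask`` False, order preserved.
    """
    out: list[str | None] = []
    keep = np.ones(len(labels), dtype=bool)
    for i, lab in enumerate(labels):
        if lab in _RK_TO_AASM:
            out.append(_RK_TO_AASM[lab])
        elif lab in _EXCLUDED:
            out.append(None)
            keep[i] = False
        else:
            raise ValueError(f"unrecognised R&K label {lab!r} at index {i}")
    return out, keep


def trim_recording(hypnogram: list[str | None], pre_sleep_min: float = 15.0,
                   post_wake_min: float = 15.0,
                   epoch_len_s: float = 30.0) -> tuple[int, int]:
    """Half-open epoch range spanning sleep plus wake margins.

    Keeps ``pre_sleep_min`` minutes before the first non-Wake epoch and
    ``post_wake_min`` minutes after the last one, clamped to the hypnogram.
    """
    if not len(hypnogram):
        raise NoSleepError("empty hypnogram")
    sleep_idx = [i for i, s in enumerate(hypnogram)
                 if s is not None and s != "Wake"]
    if not sleep_idx:
        raise NoSleepError("hypnogram contains no sleep epochs")
    per_min = 60.0 / epoch_len_s
    start = max(0, sleep_idx[0] - int(round(pre_sleep_min * per_min)))
    end = min(len(hypnogram),
              sleep_idx[-1] + int(round(post_wake_min * per_min)) + 1)
    return start, end


def slice_epochs(rec: Recording) -> list[tuple[np.ndarray, str]]:
    """Cut the recording into 30-s (epoch, stage) pairs.

    The number of epochs is the minimum of what the signal and the hypnogram
    support; trailing partial samples are dropped.
    """
    n_per = int(round(rec.epoch_len_s * rec.fs))
    n_sig = len(rec.samples) // n_per
    n = min(n_sig, len(rec.hypnogram))
    if n_sig != len(rec.hypnogram):
        logger.warning("signal supports %d epochs but hypnogram has %d; "
                       "using %d", n_sig, len(rec.hypnogram), n)
    return [(rec.samples[i * n_per:(i + 1) * n_per], rec.hypnogram[i])
            for i in range(n)]


# ---------------------------------------------------------------------------
# time–frequency transform

@dataclass(frozen=True)
class CWTConfig:
    """Complex Morlet CWT over logarithmically spaced frequencies.

    ``n_freqs`` defaults to 96 so frequency rows map one-to-one onto image
    rows; the grid spans 0.5–35 Hz (the filtered band of interest).
    """

    wavelet: str = "cmor1.5-1.0"
    n_freqs: int = 96
    fmin_hz: float = 0.5
    fmax_hz: float = 35.0

    def freqs(self) -> np.ndarray:
        """Descending frequency grid (top image row = highest frequency)."""
        return np.logspace(np.log10(self.fmax_hz), np.log10(self.fmin_hz),
                           self.n_freqs)


@dataclass
class Scalogram:
    """CWT magnitude on a frequency × time grid; ``freqs`` is descending."""

    magnitude: np.ndarray
    freqs: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        if self.magnitude.shape != (len(self.freqs), len(self.times)):
            raise ValueError("magnitude shape inconsistent with axes")


def cwt_scalogram(epoch: np.ndarray, fs: float,
                  config: CWTConfig | None = None) -> Scalogram:
    if config is None:
        config = CWTConfig()
    epoch = np.asarray(epoch, dtype=float)
    if epoch.size < 2:
        raise ValueError("epoch must contain at least 2 samples")
    if not 0 < config.fmin_hz < config.fmax_hz <= fs / 2:
        raise ValueError("frequency grid must lie within (0, fs/2]")
    freqs = config.freqs()
    scales = pywt.frequency2scale(config.wavelet, freqs / fs)
    coefs, _ = pywt.cwt(epoch, scales, config.wavelet, sampling_period=1 / fs)
    return Scalogram(magnitude=np.abs(coefs), freqs=freqs,
                     times=np.arange(epoch.size) / fs)


def _bin_mean_columns(m: np.ndarray, w: int) -> np.ndarray:
    """Average time columns down to ``w`` bins (interpolate if upsampling)."""
    n = m.shape[1]
    if n == w:
        return m
    if n < w:
        xi = np.linspace(0, n - 1, w)
        return np.stack([np.interp(xi, np.arange(n), row) for row in m])
    edges = np.linspace(0, n, w + 1).astype(int)
    sums = np.add.reduceat(m, edges[:-1], axis=1)
    counts = np.diff(edges)
    return sums / counts


def _interp_rows(m: np.ndarray, h: int) -> np.ndarray:
    n = m.shape[0]
    if n == h:
        return m
    xi = np.linspace(0, n - 1, h)
    return np.stack([np.interp(xi, np.arange(n), m[:, j])
                     for j in range(m.shape[1])], axis=1)


def render_tf_image(scalogram: Scalogram, image_size: int | tuple[int, int]
                    = 96, colormap: str = "viridis") -> np.ndarray:
    """Render a scalogram to an (h, w, 3) image in [−1, 1].

    Deterministic: per-epoch min–max normalisation, fixed colormap; a
    constant scalogram maps to the colormap midpoint.
    """
    import matplotlib

    if np.isnan(scalogram.magnitude).any():
        raise ValueError("scalogram contains NaN")
    h, w = ((image_size, image_size) if isinstance(image_size, int)
            else image_size)
    m = _interp_rows(_bin_mean_columns(scalogram.magnitude, w), h)
    lo, hi = m.min(), m.max()
    norm = np.full_like(m, 0.5) if hi - lo < 1e-12 else (m - lo) / (hi - lo)
    rgb = matplotlib.colormaps[colormap](norm)[..., :3]
    return rgb * 2.0 - 1.0


# ---------------------------------------------------------------------------
# end-to-end preprocessing

def preprocess_recording(samples: np.ndarray, fs: float,
                         rk_labels: list[str],
                         lowpass: FilterSpec | None = None,
                         notch: FilterSpec | None = None,
                         pre_sleep_min: float = 15.0,
                         post_wake_min: float = 15.0,
                         cwt: CWTConfig | None = None,
                         image_size: int | tuple[int, int] = 96,
                         epoch_len_s: float = 30.0) -> ImageSet:
    """Full pipeline: filter → map stages → trim → slice → CWT → render.

    ``notch=None`` skips line-noise removal (pass a notch FilterSpec to
    enable it); the low-pass filter always runs (default 35 Hz / order 8).
    """
    x = lowpass_filter(samples, fs, lowpass)
    if notch is not None:
        x = notch_filter(x, fs, notch)
    aasm, keep = map_stages(rk_labels)
    start, end = trim_recording(aasm, pre_sleep_min, post_wake_min,
                                epoch_len_s)
    # Slice on the full grid, then keep trimmed+valid epochs only
    hyp_for_slice = [s if s is not None else "Wake" for s in aasm]
    rec = Recording(samples=x, fs=fs, hypnogram=hyp_for_slice,
                    epoch_len_s=epoch_len_s)
    pairs = slice_epochs(rec)
    pixels, stages = [], []
    for i, (epoch, _) in enumerate(pairs):
        if not (start <= i < end) or not keep[i]:
            continue
        sg = cwt_scalogram(epoch, fs, cwt)
        pixels.append(render_tf_image(sg, image_size))
        stages.append(aasm[i])
    if not pixels:
        size = (image_size, image_size) if isinstance(image_size, int) \
            else image_size
        return ImageSet.empty(size)
    return ImageSet(np.stack(pixels), np.array(stages, dtype=object),
                    np.full(len(stages), REAL, dtype=object))


def read_edf_recording(edf_path: str, channel: str = "EEG Fpz-Cz",
                       hypnogram_edf: str | None = None,
                       epoch_len_s: float = 30.0,
                       ) -> tuple[np.ndarray, float, list[str]]:
    """Read one EDF channel and R&K stage labels via MNE (optional extra).

    Returns ``(samples, fs, rk_labels)`` ready for
    :func:`preprocess_recording`.  Annotations of the usual
    ``"Sleep stage X"`` form are converted to single-letter R&K codes.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF requires the 'mne' package "
                          "(install somnogan[edf])") from exc
    raw = mne.io.read_raw_edf(edf_path, include=[channel], preload=True,
                              verbose="error")
    fs = float(raw.info["sfreq"])
    samples = raw.get_data(picks=[channel])[0] * 1e6  # volts -> µV
    ann_map = {"Sleep stage W": "W", "Sleep stage 1": "1",
               "Sleep stage 2": "2", "Sleep stage 3": "3",
               "Sleep stage 4": "4", "Sleep stage R": "R",
               "Movement time": "MOVEMENT", "Sleep stage ?": "UNKNOWN"}
    labels: list[str] = []
    if hypnogram_edf is not None:
        ann = mne.read_annotations(hypnogram_edf)
        for onset, duration, desc in zip(ann.onset, ann.duration,
                                         ann.description):
            code = ann_map.get(desc, "UNKNOWN")
            labels.extend([code] * int(round(duration / epoch_len_s)))
    return samples, fs, labels
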