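"""Synthetic stage-labelled EEG and class-distinct image fixtures.

Real overnight polysomnography (e.g. the Sleep-EDF Expanded database) is
large and cannot ship with the package, so this module emulates the two
kinds of input the rest of the pipeline consumes:

* **Recordings** — single-channel EEG at 100 Hz whose 30-s epochs carry the
  spectral signature of their AASM stage: posterior alpha (8–12 Hz) in Wake,
  low-amplitude theta in N1, theta plus 12–14 Hz spindle bursts in N2,
  high-amplitude delta in N3 and mixed low-amplitude theta/beta in REM, all
  over a 1/f background, with optional 50 Hz mains interference.

* **Image datasets** — class-distinct labelled texture images (oriented
  gratings plus a class-positioned blob) that stand in for time–frequency
  maps.  These deliberately bypass the signal-processing path so GAN and
  classifier tests do not depend on the preprocessing module.

Everything is driven by integer seeds and is bit-reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .containers import GENERATED, REAL, STAGES, ImageSet, Recording

__all__ = [
    "StageSpec", "DEFAULT_STAGE_SPECS", "synth_stage_signal",
    "synth_recording", "synth_image_dataset", "write_recording_csv",
    "read_recording_csv", "write_image_dataset", "read_image_dataset",
]


@dataclass(frozen=True)
class StageSpec:
    """Spectral recipe for one sleep stage.

    ``bands`` lists (centre frequency Hz, bandwidth Hz, amplitude µV); each
    band contributes a sinusoid at the centre frequency plus narrowband noise.
    ``burst`` optionally adds transient spindle-like oscillation bursts as
    (rate per minute, duration s, centre frequency Hz, amplitude µV).
    The background is 1/f^exponent noise with RMS ``noise_amp``.
    """

    stage: str
    bands: tuple[tuple[float, float, float], ...]
    burst: tuple[float, float, float, float] | None = None
    noise_exponent: float = 1.0
    noise_amp: float = 10.0

    def validate(self, fs: float) -> None:
        for f0, bw, amp in self.bands:
            if not 0 < f0 < fs / 2:
                raise ValueError(f"band centre {f0} Hz outside (0, fs/2)")
            if bw <= 0 or amp < 0:
                raise ValueError("bandwidth must be > 0 and amplitude >= 0")
        if self.burst is not None:
            rate, dur, f0, amp = self.burst
            if not 0 < f0 < fs / 2:
                raise ValueError(f"burst frequency {f0} Hz outside (0, fs/2)")
            if rate < 0 or dur <= 0 or amp < 0:
                raise ValueError("invalid burst parameters")
        if self.noise_amp < 0:
            raise ValueError("noise amplitude must be >= 0")


#: AASM-like default signatures (amplitudes in µV, loosely scaled to scalp EEG).
DEFAULT_STAGE_SPECS: dict[str, StageSpec] = {
    "Wake": StageSpec("Wake", bands=((10.0, 4.0, 30.0),), noise_amp=12.0),
    "N1": StageSpec("N1", bands=((5.5, 3.0, 15.0),), noise_amp=10.0),
    "N2": StageSpec("N2", bands=((5.5, 3.0, 25.0),),
                    burst=(4.0, 1.0, 13.0, 25.0), noise_amp=10.0),
    "N3": StageSpec("N3", bands=((1.25, 1.5, 75.0),), noise_amp=12.0),
    "REM": StageSpec("REM", bands=((5.5, 3.0, 15.0), (22.0, 15.0, 8.0)),
                     noise_amp=10.0),
}


def _band_noise(rng: np.random.Generator, n: int, fs: float, f0: float,
                bw: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited by a Gaussian spectral window."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = np.fft.rfft(rng.standard_normal(n))
    spec *= np.exp(-0.5 * ((freqs - f0) / (bw / 2.0)) ** 2)
    x = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                exponent: float) -> np.ndarray:
    """Unit-RMS 1/f^exponent (power) spectrally shaped Gaussian noise."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = np.fft.rfft(rng.standard_normal(n))
    with np.errstate(divide="ignore"):
        shaping = np.where(freqs > 0, freqs ** (-exponent / 2.0), 0.0)
    x = np.fft.irfft(spec * shaping, n)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def _synth_stage_signal(spec: StageSpec, n: int, fs: float,
                        rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / fs
    x = np.zeros(n)
    for f0, bw, amp in spec.bands:
        if amp == 0:
            continue
        phase = rng.uniform(0, 2 * np.pi)
        x += amp * (np.sin(2 * np.pi * f0 * t + phase)
                    + 0.5 * _band_noise(rng, n, fs, f0, bw))
    if spec.burst is not None:
        rate, dur, f0, amp = spec.burst
        n_burst = int(dur * fs)
        if amp > 0 and 0 < n_burst <= n:
            expected = rate * (n / fs) / 60.0
            k = rng.poisson(expected)
            window = np.hanning(n_burst)
            for _ in range(k):
                start = rng.integers(0, n - n_burst + 1)
                phase = rng.uniform(0, 2 * np.pi)
                burst = amp * window * np.sin(
                    2 * np.pi * f0 * t[:n_burst] + phase)
                x[start:start + n_burst] += burst
    if spec.noise_amp > 0:
        x += spec.noise_amp * _pink_noise(rng, n, fs, spec.noise_exponent)
    return x


def synth_stage_signal(spec: StageSpec, duration_s: float, fs: float = 100.0,
                       seed: int = 0) -> np.ndarray:
    """Synthesise one stage's EEG for ``duration_s`` seconds at ``fs`` Hz.

    Reproducible: identical (spec, duration, fs, seed) gives identical output.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    spec.validate(fs)
    n = int(round(duration_s * fs))
    return _synth_stage_signal(spec, n, fs, np.random.default_rng(seed))


def synth_recording(stage_sequence: list[str], fs: float = 100.0,
                    seed: int = 0, line_noise_amp: float = 0.0,
                    epoch_len_s: float = 30.0,
                    stage_specs: dict[str, StageSpec] | None = None,
                    ) -> Recording:
    """Concatenate per-epoch stage signals into a labelled recording.

    ``line_noise_amp`` adds a 50 Hz sinusoid (mains interference) of that
    amplitude over the whole recording.
    """
    if not stage_sequence:
        raise ValueError("stage_sequence must be non-empty")
    specs = stage_specs if stage_specs is not None else DEFAULT_STAGE_SPECS
    for i, s in enumerate(stage_sequence):
        if s not in specs:
            raise ValueError(f"unknown stage label {s!r} at epoch {i}")
    rng = np.random.default_rng(seed)
    n_epoch = int(round(epoch_len_s * fs))
    chunks = [_synth_stage_signal(specs[s], n_epoch, fs, rng)
              for s in stage_sequence]
    samples = np.concatenate(chunks)
    if line_noise_amp:
        t = np.arange(len(samples)) / fs
        samples = samples + line_noise_amp * np.sin(2 * np.pi * 50.0 * t)
    return Recording(samples=samples, fs=fs, hypnogram=list(stage_sequence),
                     epoch_len_s=epoch_len_s)


# ---------------------------------------------------------------------------
# class-distinct image fixtures

def _class_image(h: int, w: int, class_idx: int, n_classes: int,
                 rng: np.random.Generator) -> np.ndarray:
    """One (h, w, 3) texture image: an oriented grating whose orientation and
    frequency identify the class, plus a class-positioned Gaussian blob."""
    theta = np.pi * class_idx / max(n_classes, 1)
    freq = 2.0 + class_idx
    yy, xx = np.mgrid[0:h, 0:w] / max(h, w)
    phase = rng.uniform(-0.5, 0.5)
    grating = np.sin(2 * np.pi * freq * (xx * np.cos(theta)
                                         + yy * np.sin(theta)) + phase)
    # blob centre rotates around the image with the class index
    ang = 2 * np.pi * class_idx / max(n_classes, 1)
    cy = 0.5 + 0.25 * np.sin(ang) + rng.uniform(-0.04, 0.04)
    cx = 0.5 + 0.25 * np.cos(ang) + rng.uniform(-0.04, 0.04)
    blob = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 0.08 ** 2)))
    base = 0.45 * grating + 0.8 * blob - 0.2
    img = base[:, :, None] + 0.12 * rng.standard_normal((h, w, 3))
    return np.clip(img, -1.0, 1.0)


def synth_image_dataset(class_counts: dict[str, int],
                        image_size: tuple[int, int] = (32, 32),
                        seed: int = 0) -> ImageSet:
    """Draw a labelled image dataset with exactly the requested per-class
    counts.  Each class comes from a distinct deterministic texture family so
    the classes are separable by a linear probe."""
    h, w = image_size
    if h < 8 or w < 8:
        raise ValueError("image size must be at least 8x8")
    labels = [s for s in STAGES if s in class_counts]
    labels += sorted(k for k in class_counts if k not in STAGES)
    for lab in labels:
        if class_counts[lab] < 0:
            raise ValueError(f"negative count for class {lab!r}")
    rng = np.random.default_rng(seed)
    pixels, stages = [], []
    for idx, lab in enumerate(labels):
        for _ in range(class_counts[lab]):
            pixels.append(_class_image(h, w, idx, len(labels), rng))
            stages.append(lab)
    if not pixels:
        return ImageSet.empty(image_size)
    return ImageSet(np.stack(pixels), np.array(stages, dtype=object),
                    np.full(len(stages), REAL, dtype=object))


# ---------------------------------------------------------------------------
# plain-text / PNG persistence

def write_recording_csv(rec: Recording, signal_path: str | Path,
                        hypnogram_path: str | Path) -> None:
    """Write (time, value) samples and (epoch_index, stage) hypnogram CSVs."""
    t = np.arange(len(rec.samples)) / rec.fs
    with open(signal_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "value_uV"])
        for ti, vi in zip(t, rec.samples):
            writer.writerow([f"{ti:.6f}", f"{vi:.6f}"])
    with open(hypnogram_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch_index", "stage"])
        for i, s in enumerate(rec.hypnogram):
            writer.writerow([i, s])


def read_recording_csv(signal_path: str | Path, hypnogram_path: str | Path,
                       fs: float = 100.0, epoch_len_s: float = 30.0,
                       ) -> Recording:
    sig = np.genfromtxt(signal_path, delimiter=",", skip_header=1)
    hyp = []
    with open(hypnogram_path, newline="") as fh:
        reader = csv.reader(fh)
        next(reader)
        for row in reader:
            hyp.append(row[1])
    return Recording(samples=sig[:, 1], fs=fs, hypnogram=hyp,
                     epoch_len_s=epoch_len_s)


def write_image_dataset(images: ImageSet, out_dir: str | Path) -> None:
    """Write each image as an 8-bit PNG plus a CSV manifest
    (filename, stage, provenance).  The [−1, 1] range maps to [0, 255]."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "stage", "provenance"])
        for i in range(len(images)):
            u8 = np.clip((images.pixels[i] + 1.0) * 127.5, 0, 255)
            name = f"img_{i:06d}.png"
            Image.fromarray(u8.astype(np.uint8)).save(out / name)
            writer.writerow([name, images.stages[i], images.provenance[i]])


def read_image_dataset(in_dir: str | Path) -> ImageSet:
    """Read a PNG directory written by :func:`write_image_dataset`.

    Pixel values are quantised to 8 bits on disk, so round-tripping is exact
    only to within 1/127.5.
    """
    from PIL import Image

    src = Path(in_dir)
    pixels, stages, provenance = [], [], []
    with open(src / "manifest.csv", newline="") as fh:
        reader = csv.reader(fh)
        next(reader)
        for name, stage, prov in reader:
            arr = np.asarray(Image.open(src / name), dtype=float)
            pixels.append(arr / 127.5 - 1.0)
            stages.append(stage)
            provenance.append(prov)
    if not pixels:
        return ImageSet.empty((8, 8))
    return ImageSet(np.stack(pixels), np.array(stages, dtype=object),
                    np.array(provenance, dtype=object))
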