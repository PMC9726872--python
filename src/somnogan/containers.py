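"""Shared data containers: sleep stages, EEG recordings and image sets.

The currency passed between modules is the :class:`ImageSet` — a batch of
96×96×3 (or desk-scale 32×32×3) wavelet time–frequency images in [−1, 1],
each tagged with its AASM sleep stage and a provenance flag distinguishing
real images from GAN-generated ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: AASM sleep stages, in conventional order.
STAGES: tuple[str, ...] = ("Wake", "N1", "N2", "N3", "REM")

REAL = "real"
GENERATED = "generated"


@dataclass
class Recording:
    """Continuous single-channel EEG with an aligned hypnogram.

    ``samples`` are in µV at sampling rate ``fs`` (Hz); the hypnogram holds
    one AASM stage label per ``epoch_len_s``-second epoch.
    """

    samples: np.ndarray
    fs: float = 100.0
    hypnogram: list[str] = field(default_factory=list)
    epoch_len_s: float = 30.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def n_epochs_signal(self) -> int:
        return int(len(self.samples) // round(self.epoch_len_s * self.fs))


class ImageSet:
    """A labelled batch of time–frequency images.

    Attributes
    ----------
    pixels : (n, h, w, 3) float array in [−1, 1]
    stages : (n,) array of stage labels
    provenance : (n,) array, each ``"real"`` or ``"generated"``
    """

    def __init__(self, pixels: np.ndarray, stages, provenance=None) -> None:
        pixels = np.asarray(pixels, dtype=float)
        if pixels.ndim != 4 or pixels.shape[-1] != 3:
            raise ValueError(f"pixels must be (n, h, w, 3), got {pixels.shape}")
        stages = np.asarray(stages, dtype=object)
        if provenance is None:
            provenance = np.full(len(stages), REAL, dtype=object)
        provenance = np.asarray(provenance, dtype=object)
        if not (len(pixels) == len(stages) == len(provenance)):
            raise ValueError("pixels, stages and provenance lengths differ")
        self.pixels = pixels
        self.stages = stages
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.pixels)

    @property
    def image_shape(self) -> tuple[int, int, int]:
        return self.pixels.shape[1:]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.stages:
            out[s] = out.get(s, 0) + 1
        return out

    def subset(self, mask: np.ndarray) -> "ImageSet":
        mask = np.asarray(mask)
        return ImageSet(self.pixels[mask], self.stages[mask],
                        self.provenance[mask])

    def of_stage(self, stage: str) -> "ImageSet":
        return self.subset(self.stages == stage)

    def real_only(self) -> "ImageSet":
        return self.subset(self.provenance == REAL)

    @classmethod
    def concat(cls, sets: list["ImageSet"]) -> "ImageSet":
        sets = [s for s in sets if len(s)]
        if not sets:
            return cls.empty((8, 8))
        return cls(np.concatenate([s.pixels for s in sets]),
                   np.concatenate([s.stages for s in sets]),
                   np.concatenate([s.provenance for s in sets]))

    @classmethod
    def empty(cls, image_size: tuple[int, int]) -> "ImageSet":
        h, w = image_size
        return cls(np.empty((0, h, w, 3)), np.empty(0, dtype=object),
                   np.empty(0, dtype=object))
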