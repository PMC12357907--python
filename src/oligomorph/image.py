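"""Core image container shared by all processing stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

VALID_CHANNELS = ("DAPI", "O4", "MBP")


@dataclass
class ChannelImage:
    """A single-channel 2-D intensity grid plus acquisition metadata.

    Parameters
    ----------
    pixels
        2-D array of intensities.  After 8-bit conversion values are in
        ``[0, 255]``.
    channel
        One of ``DAPI``, ``O4``, ``MBP``.
    pixel_size_um
        Physical edge length of one pixel in micrometres.
    bit_depth
        Nominal bit depth of ``pixels`` (8 after :func:`~oligomorph.preprocess.to_8bit`).
    provenance
        Ordered log of operations applied so far; grows monotonically.
    """

    pixels: np.ndarray
    channel: str = "DAPI"
    pixel_size_um: float = 1.0
    bit_depth: int = 8
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D grid, got ndim={self.pixels.ndim}")
        if self.pixels.size == 0:
            raise ValueError("empty image")
        if self.channel not in VALID_CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {VALID_CHANNELS}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray, op: str) -> "ChannelImage":
        """Return a copy with new pixel data and ``op`` appended to provenance."""
        if pixels.shape != self.pixels.shape:
            raise ValueError("operations must preserve image shape")
        return replace(self, pixels=pixels, provenance=[*self.provenance, op])
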