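"""Shared containers, exceptions and small numeric helpers.

Conventions used throughout the package:

* image arrays are indexed ``[t, c, y, x]`` (time, channel, row, column),
  0-based;
* point coordinates are ``(x, y)`` floats in pixel units with the origin at
  the centre of pixel ``(0, 0)``;
* physical calibration travels with the pixel data as an :class:`ImageStack`.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np


# --------------------------------------------------------------------------
# exceptions
# --------------------------------------------------------------------------

class PolarpuncError(Exception):
    """Base class for package errors."""


class SceneTruncationError(PolarpuncError):
    """The simulated cell left the field of view.

    ``last_valid_frame`` is the index of the last frame in which the whole
    cell body still fits inside the image.
    """

    def __init__(self, last_valid_frame: int):
        self.last_valid_frame = last_valid_frame
        super().__init__(
            f"cell leaves the field of view; last valid frame is {last_valid_frame}"
        )


class CalibrationError(PolarpuncError):
    """Event-model calibration failed to meet its residual tolerance."""

    def __init__(self, residuals):
        self.residuals = tuple(residuals)
        super().__init__(f"calibration did not converge; residuals={self.residuals}")


class PackingError(PolarpuncError):
    """Requested bead density cannot satisfy the minimum separation."""


class GeometryError(PolarpuncError):
    """A window, line or ROI is degenerate or falls outside the image."""


class DegenerateInputError(PolarpuncError):
    """Input lacks the variation the operation requires (constant image, ...)."""


class InvalidFlatfieldError(PolarpuncError):
    """Flatfield contains non-positive pixels or has the wrong shape."""


class InvalidFitError(PolarpuncError):
    """A Gaussian fit did not converge where a converged fit is required."""


class NoCellError(PolarpuncError):
    """Segmentation found no connected component above the minimum area."""


class AmbiguousPolarityError(PolarpuncError):
    """Cell velocity is too small to orient the polarity axis automatically."""


class InsufficientDataError(PolarpuncError):
    """Too few points/frames/cells for the requested statistic."""


class EmptyInputError(PolarpuncError):
    """An operation received an empty selection or table."""


class FrameMismatchError(PolarpuncError):
    """A detection refers to a frame with no cell outline."""


class ConfigError(PolarpuncError):
    """Configuration is schema-invalid; the message names the field."""


class ClippingWarning(UserWarning):
    """Rendered intensities exceeded the output dtype range and were clipped."""


# --------------------------------------------------------------------------
# image stack container
# --------------------------------------------------------------------------

DEFAULT_CHANNELS = ("puncta_marker", "second_marker", "bead", "cytoplasm")


@dataclasses.dataclass
class ImageStack:
    """A calibrated T x C x Y x X intensity stack."""

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel_names: tuple = DEFAULT_CHANNELS

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("ImageStack data must be 4-D (t, c, y, x)")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel size and frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self):
        return self.data.shape[2:]

    def frame(self, t: int, c: int) -> np.ndarray:
        return self.data[t, c]

    def channel_index(self, name: str) -> int:
        return self.channel_names.index(name)

    def metadata(self) -> dict:
        return {
            "axes": "TCYX",
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_s": self.frame_interval_s,
            "channel_names": list(self.channel_names),
        }

    def save_sidecar(self, path) -> None:
        Path(path).write_text(json.dumps(self.metadata(), indent=2))


# --------------------------------------------------------------------------
# numeric helpers
# --------------------------------------------------------------------------

def robust_sd(values: np.ndarray) -> float:
    """1.4826 x median absolute deviation: a normal-consistent robust sigma."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        return 0.0
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def add_gaussian_spot(image: np.ndarray, x: float, y: float, amplitude: float,
                      sigma: float, truncate: float = 5.0) -> None:
    """Accumulate a symmetric 2-D Gaussian into ``image`` in place.

    The spot is evaluated at pixel centres on a window of half-width
    ``truncate * sigma`` so the discrete sum approximates ``2*pi*A*sigma**2``.
    """
    ny, nx = image.shape
    r = int(np.ceil(truncate * sigma))
    x0, y0 = int(round(x)), int(round(y))
    xlo, xhi = max(0, x0 - r), min(nx, x0 + r + 1)
    ylo, yhi = max(0, y0 - r), min(ny, y0 + r + 1)
    if xlo >= xhi or ylo >= yhi:
        return
    xs = np.arange(xlo, xhi) - x
    ys = np.arange(ylo, yhi) - y
    gx = np.exp(-(xs ** 2) / (2.0 * sigma ** 2))
    gy = np.exp(-(ys ** 2) / (2.0 * sigma ** 2))
    image[ylo:yhi, xlo:xhi] += amplitude * np.outer(gy, gx)


def odd_window(n: int, minimum: int = 5) -> int:
    """Round up to the nearest odd integer, at least ``minimum``."""
    n = max(int(n), minimum)
    return n if n % 2 == 1 else n + 1
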