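"""Centered unitary 2D Fourier transforms.

Every transform in this package uses the unitary (``norm="ortho"``) convention
with the DC sample at the array center.  Unitarity is what makes noise-level
bookkeeping trivial: white noise with unit standard deviation stays unit
standard deviation on both sides of the transform, so a single scalar chain
tracks the noise level through the whole reconstruction.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fft2c", "ifft2c"]


def fft2c(x: np.ndarray, axes: tuple[int, int] = (-2, -1)) -> np.ndarray:
    """Centered unitary 2D FFT (image -> k-space) over ``axes``."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def ifft2c(x: np.ndarray, axes: tuple[int, int] = (-2, -1)) -> np.ndarray:
    """Centered unitary 2D inverse FFT (k-space -> image) over ``axes``."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )
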