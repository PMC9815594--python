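"""Centered 2-D Fourier transforms shared by the simulator, detector and solver.

Convention (fixed package-wide): the DC component sits at index ``N // 2``
along each axis, the forward transform is unnormalized and the inverse
carries the ``1 / N`` factor.  Line detection and compressed sensing both
compare k-space data produced under this convention, so it must never vary
between modules.
"""

from __future__ import annotations

import numpy as np


def fft2c(image: np.ndarray) -> np.ndarray:
    """Centered 2-D forward FFT (unnormalized, DC at ``N // 2``)."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(image)))


def ifft2c(kspace: np.ndarray) -> np.ndarray:
    """Centered 2-D inverse FFT (carries the ``1 / N`` normalization)."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(kspace)))
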