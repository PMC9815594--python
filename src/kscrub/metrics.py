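"""Image-quality metrics on normalized magnitude images (data range 1)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .errors import ConfigurationError
from .phantoms import as_pixels


def psnr(image, reference) -> float:
    """10 log10(1 / MSE) in dB with data range 1; identical -> +infinity."""
    a, b = as_pixels(image), as_pixels(reference)
    if a.shape != b.shape:
        raise ConfigurationError(f"image shapes differ: {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return np.inf
    return 10.0 * np.log10(1.0 / mse)


def ssim(image, reference) -> float:
    """Mean local SSIM, 11x11 Gaussian window (sigma 1.5), K1 .01, K2 .03."""
    a, b = as_pixels(image), as_pixels(reference)
    if a.shape != b.shape:
        raise ConfigurationError(f"image shapes differ: {a.shape} vs {b.shape}")
    return float(
        structural_similarity(
            a,
            b,
            data_range=1.0,
            gaussian_weights=True,
            sigma=1.5,
            win_size=11,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


@dataclass
class QualityReport:
    """Metrics for one reconstruction stage of one simulated run."""

    stage: str  # corrupted | filtered | cs_fixed_35 | final
    motion_mode: float  # start fraction
    psnr: float
    ssim: float
    detection_error_lines: int | None = None
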