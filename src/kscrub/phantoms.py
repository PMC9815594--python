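"""Synthetic motion-free reference images.

Every downstream stage (simulation, filtering, line detection, compressed
sensing) is exercised on these phantoms, so their generation must be exactly
reproducible from ``(kind, size, seed)``.  Two kinds are provided:

``shepp_logan``
    The modified Shepp-Logan head phantom rasterized analytically on the
    requested grid.  Background is exactly zero and the skull rim has the
    maximum intensity, so per-image max normalization is exact.

``random_ellipses``
    A piecewise-constant sum of 5-12 random ellipses.  The draw protocol is
    part of the public contract (tests rasterize it independently): with
    ``rng = numpy.random.default_rng(seed)`` the number of ellipses is
    ``rng.integers(5, 13)``; then per ellipse, in order, ``cy ~ U(0.2 h,
    0.8 h)``, ``cx ~ U(0.2 w, 0.8 w)``, semi-axis (rows) ``~ U(0.05 h,
    0.3 h)``, semi-axis (cols) ``~ U(0.05 w, 0.3 w)``, rotation angle in
    degrees ``~ U(0, 180)`` and additive intensity ``~ U(0.2, 1.0)``.  A
    pixel at integer coordinates ``(r, c)`` belongs to an ellipse when the
    canonical quadratic form evaluates to <= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

DEFAULT_PIXEL_SPACING_MM = 0.9375

#: Modified Shepp-Logan ellipse table: (value, a, b, x0, y0, phi_deg) in the
#: canonical [-1, 1]^2 coordinate frame (x right, y up).
_SHEPP_LOGAN = (
    (1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.80, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.20, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.20, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.10, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.10, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.10, 0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.10, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
)


@dataclass
class ReferenceImage:
    """A normalized 2-D magnitude image used as motion-free ground truth.

    Invariants: all pixel values finite and >= 0; maximum value 1 after
    normalization (unless the image is identically zero).
    """

    pixels: np.ndarray
    pixel_spacing: float = DEFAULT_PIXEL_SPACING_MM

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def as_pixels(image) -> np.ndarray:
    """Accept either a :class:`ReferenceImage` or a bare 2-D array."""
    return np.asarray(getattr(image, "pixels", image), dtype=float)


def normalize(pixels: np.ndarray) -> np.ndarray:
    """Clip to >= 0 and scale so the maximum is exactly 1 (zero image kept)."""
    out = np.clip(np.asarray(pixels, dtype=float), 0.0, None)
    peak = out.max()
    if peak > 0:
        out = out / peak
    return out


def _rasterize_ellipses(height, width, params) -> np.ndarray:
    """Additively rasterize ellipses given as (value, cy, cx, sr, sc, deg)."""
    rr, cc = np.mgrid[0:height, 0:width].astype(float)
    out = np.zeros((height, width))
    for value, cy, cx, sr, sc, deg in params:
        t = np.deg2rad(deg)
        dr, dc = rr - cy, cc - cx
        u = np.cos(t) * dc + np.sin(t) * dr
        v = -np.sin(t) * dc + np.cos(t) * dr
        out[(u / sc) ** 2 + (v / sr) ** 2 <= 1.0] += value
    return out


def _shepp_logan(height: int, width: int) -> np.ndarray:
    params = []
    for value, a, b, x0, y0, phi in _SHEPP_LOGAN:
        # canonical frame -> pixel frame (y axis flips, unit half-width scales)
        cy = (1.0 - y0) * (height - 1) / 2.0
        cx = (1.0 + x0) * (width - 1) / 2.0
        sr = b * (height - 1) / 2.0
        sc = a * (width - 1) / 2.0
        params.append((value, cy, cx, sr, sc, -phi))
    return _rasterize_ellipses(height, width, params)


def _random_ellipses(height: int, width: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 13))
    params = []
    for _ in range(n):
        cy = rng.uniform(0.2 * height, 0.8 * height)
        cx = rng.uniform(0.2 * width, 0.8 * width)
        sr = rng.uniform(0.05 * height, 0.3 * height)
        sc = rng.uniform(0.05 * width, 0.3 * width)
        deg = rng.uniform(0.0, 180.0)
        amp = rng.uniform(0.2, 1.0)
        params.append((amp, cy, cx, sr, sc, deg))
    return _rasterize_ellipses(height, width, params)


def make_phantom(
    height: int = 256,
    width: int = 256,
    kind: str = "shepp_logan",
    seed: int = 0,
    pixel_spacing: float = DEFAULT_PIXEL_SPACING_MM,
) -> ReferenceImage:
    """Generate a deterministic synthetic reference image.

    Parameters
    ----------
    height, width
        Grid size in pixels; both must be >= 32.
    kind
        ``"shepp_logan"`` or ``"random_ellipses"`` (see module docstring).
    seed
        Seed for ``random_ellipses``; ignored by the deterministic
        Shepp-Logan phantom but still part of the reproducibility contract.
    """
    if height < 32 or width < 32:
        raise ConfigurationError(f"phantom size must be >= 32, got {height}x{width}")
    if kind == "shepp_logan":
        pixels = _shepp_logan(height, width)
    elif kind == "random_ellipses":
        pixels = _random_ellipses(height, width, seed)
    else:
        raise ConfigurationError(f"unknown phantom kind: {kind!r}")
    return ReferenceImage(normalize(pixels), pixel_spacing=pixel_spacing)
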