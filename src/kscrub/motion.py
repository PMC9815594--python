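"""Rigid-motion corruption of Cartesian k-space, acquired line by line.

The acquisition model: phase-encoding (PE) lines are sampled one per time
step in a pseudo-random order — the centered 15% block sequentially first,
then the remaining lines drawn without replacement under a Gaussian
preference for low spatial frequencies.  The object holds still until
``start_index`` and afterwards jumps to an independent random rigid pose
(|dx|, |dy| <= 5 px, |theta| <= 5 deg) after every line.  Each time step
copies one column of the centered FFT of the currently-posed image into the
corrupted k-space, so lines acquired before motion began are bit-identical
to the reference transform — the property the line detector exploits.

Axis convention: axis 0 = readout (rows), axis 1 = phase encode (columns);
``dy`` shifts along axis 0, ``dx`` along axis 1, ``theta`` is in degrees,
counter-clockwise positive, about the image center ``((H-1)/2, (W-1)/2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DegenerateInputError
from .fourier import fft2c, ifft2c
from .phantoms import ReferenceImage, as_pixels, normalize


@dataclass
class SamplingOrder:
    """Time-ordered permutation of PE indices.

    ``order[t]`` is the PE index sampled at time step ``t``.  The first
    ``floor(center_fraction * numPE)`` entries are the contiguous centered
    block in ascending order.
    """

    order: np.ndarray
    center_fraction: float
    sigma: float

    def __len__(self) -> int:
        return len(self.order)

    def times(self) -> np.ndarray:
        """Inverse permutation: sampling time of each PE index."""
        t = np.empty(len(self.order), dtype=np.int64)
        t[self.order] = np.arange(len(self.order))
        return t


@dataclass
class MotionTrack:
    """Per-time-step rigid pose (dx px, dy px, theta deg); zero before start."""

    poses: np.ndarray
    start_index: int

    def __len__(self) -> int:
        return len(self.poses)


@dataclass
class CorruptedAcquisition:
    """Complex corrupted k-space plus everything needed to score it."""

    k_motion: np.ndarray
    order: SamplingOrder
    track: MotionTrack
    true_start: int
    reference: ReferenceImage | None = None
    seed: int | None = None


def make_sampling_order(
    num_pe: int,
    center_fraction: float = 0.15,
    sigma: float | None = None,
    seed: int = 0,
) -> SamplingOrder:
    """Build the center-first, Gaussian-random PE sampling order.

    The centered block has ``floor(center_fraction * num_pe)`` lines and
    starts at index ``num_pe // 2 - block // 2``.  Remaining lines are drawn
    one at a time without replacement with weight proportional to
    ``exp(-(n - num_pe / 2)^2 / (2 sigma^2))`` over the not-yet-sampled
    indices ``n``.  ``sigma`` defaults to ``num_pe / 6``.
    """
    if num_pe < 8:
        raise ConfigurationError(f"num_pe must be >= 8, got {num_pe}")
    if not 0.0 < center_fraction <= 1.0:
        raise ConfigurationError(f"center_fraction must be in (0, 1], got {center_fraction}")
    if sigma is None:
        sigma = num_pe / 6.0
    if sigma <= 0:
        raise ConfigurationError(f"sigma must be positive, got {sigma}")
    block = int(np.floor(center_fraction * num_pe))
    start = num_pe // 2 - block // 2
    center = np.arange(start, start + block, dtype=np.int64)
    remaining = np.setdiff1d(np.arange(num_pe, dtype=np.int64), center)
    rng = np.random.default_rng(seed)
    tail = []
    weights = np.exp(-((remaining - num_pe / 2.0) ** 2) / (2.0 * sigma**2))
    while remaining.size:
        p = weights / weights.sum()
        j = rng.choice(remaining.size, p=p)
        tail.append(remaining[j])
        remaining = np.delete(remaining, j)
        weights = np.delete(weights, j)
    order = np.concatenate([center, np.asarray(tail, dtype=np.int64)])
    return SamplingOrder(order=order, center_fraction=center_fraction, sigma=float(sigma))


def make_motion_track(
    num_pe: int,
    start_fraction: float,
    max_translation: float = 5.0,
    max_rotation: float = 5.0,
    seed: int = 0,
) -> MotionTrack:
    """Draw a random rigid-pose track that starts after ``start_fraction``.

    ``start_index = round(start_fraction * num_pe)`` (half away from zero);
    poses before it are exactly zero, poses at/after it are i.i.d. with each
    component uniform on its range (absolute pose per line, not a walk).
    """
    if not 0.0 <= start_fraction <= 1.0:
        raise ConfigurationError(f"start_fraction must be in [0, 1], got {start_fraction}")
    if max_translation < 0 or max_rotation < 0:
        raise ConfigurationError("motion bounds must be non-negative")
    start = int(np.floor(start_fraction * num_pe + 0.5))
    poses = np.zeros((num_pe, 3))
    n_moving = num_pe - start
    if n_moving > 0:
        rng = np.random.default_rng(seed)
        draws = rng.uniform(-1.0, 1.0, size=(n_moving, 3))
        poses[start:] = draws * np.array([max_translation, max_translation, max_rotation])
    return MotionTrack(poses=poses, start_index=start)


def apply_rigid(image, dx: float, dy: float, theta: float):
    """Rotate about the image center then translate, with bilinear resampling.

    Zero fill outside the field of view; output has the input's size.  The
    two steps are applied as one composite affine map, so only a single
    interpolation pass occurs; integer translations at ``theta = 0`` move
    pixels exactly.
    """
    pix = as_pixels(image)
    if dx == 0.0 and dy == 0.0 and theta == 0.0:
        out = pix.copy()
    else:
        t = np.deg2rad(theta)
        c, s = np.cos(t), np.sin(t)
        # inverse rotation in (row, col) coordinates, CCW-positive theta
        rinv = np.array([[c, s], [-s, c]])
        ctr = (np.array(pix.shape, dtype=float) - 1.0) / 2.0
        shift = np.array([dy, dx])
        # input_coord = rinv @ (output_coord - shift - ctr) + ctr
        offset = ctr - rinv @ (shift + ctr)
        out = ndimage.affine_transform(
            pix, rinv, offset=offset, order=1, mode="constant", cval=0.0, prefilter=False
        )
    if isinstance(image, ReferenceImage):
        return ReferenceImage(out, pixel_spacing=image.pixel_spacing)
    return out


def simulate_kspace(
    reference: ReferenceImage,
    order: SamplingOrder,
    track: MotionTrack,
    seed: int | None = None,
) -> CorruptedAcquisition:
    """Acquire the corrupted k-space line by line under the motion track.

    At each time step the image under the current pose is Fourier
    transformed (centered 2-D) and the column at ``order[t]`` is copied into
    the corrupted k-space.  For exactly-zero poses the transform of the
    untouched reference is reused, which makes pre-motion columns
    bit-identical to the reference transform.
    """
    pix = as_pixels(reference)
    num_pe = pix.shape[1]
    if len(order) != num_pe or len(track) != num_pe:
        raise ConfigurationError(
            f"order/track length ({len(order)}/{len(track)}) must equal numPE ({num_pe})"
        )
    k_ref = fft2c(pix)
    k_motion = np.empty_like(k_ref)
    for t, pe in enumerate(order.order):
        dx, dy, theta = track.poses[t]
        if dx == 0.0 and dy == 0.0 and theta == 0.0:
            k_motion[:, pe] = k_ref[:, pe]
        else:
            moved = apply_rigid(pix, dx, dy, theta)
            k_motion[:, pe] = fft2c(moved)[:, pe]
    return CorruptedAcquisition(
        k_motion=k_motion,
        order=order,
        track=track,
        true_start=track.start_index,
        reference=reference,
        seed=seed,
    )


def corrupted_image(acq: CorruptedAcquisition) -> ReferenceImage:
    """Magnitude of the centered inverse FFT, normalized to max 1."""
    if not np.any(acq.k_motion):
        raise DegenerateInputError("all-zero k-space has no image")
    mag = np.abs(ifft2c(acq.k_motion))
    spacing = acq.reference.pixel_spacing if acq.reference is not None else None
    if spacing is None:
        return ReferenceImage(normalize(mag))
    return ReferenceImage(normalize(mag), pixel_spacing=spacing)
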