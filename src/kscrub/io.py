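"""On-disk artifacts: NIfTI image volumes, HDF5 acquisitions, PNG previews.

HDF5 acquisition layout::

    /kspace          complex (readout x PE)
    /sampling_order  int vector, time-ordered PE indices
    /motion_track    (T, 3) float: dx px, dy px, theta deg
    /true_start      int scalar (time index where motion begins)
    /reference       optional real image (motion-free ground truth)
    attrs: pixel_spacing_mm, seed, center_fraction
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .errors import ConfigurationError, FormatError
from .motion import CorruptedAcquisition, MotionTrack, SamplingOrder
from .phantoms import DEFAULT_PIXEL_SPACING_MM, ReferenceImage, as_pixels, normalize

log = logging.getLogger(__name__)


def save_volume(images, path, pixel_spacing: float = DEFAULT_PIXEL_SPACING_MM) -> None:
    """Stack 2-D images along the third axis and write a NIfTI-1 volume."""
    vol = np.stack([as_pixels(im) for im in images], axis=2)
    affine = np.diag([pixel_spacing, pixel_spacing, 1.0, 1.0])
    nib.save(nib.Nifti1Image(vol.astype(np.float64), affine), str(path))


def load_slices(path, slice_range: slice | None = None) -> list[ReferenceImage]:
    """Read a 3-D NIfTI volume and return normalized 2-D slices.

    Slices are taken along the third axis; each is normalized to max 1
    independently.  All-zero slices are skipped with a logged warning.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3-D volume, got {data.ndim}-D in {path}")
    zooms = img.header.get_zooms()
    spacing = float(zooms[0]) if len(zooms) else DEFAULT_PIXEL_SPACING_MM
    if slice_range is None:
        slice_range = slice(None)
    idx = range(*slice_range.indices(data.shape[2]))
    if len(idx) == 0:
        raise ConfigurationError(f"empty slice range {slice_range} for {path}")
    out, skipped = [], 0
    for k in idx:
        sl = np.asarray(data[:, :, k], dtype=float)
        if not np.any(sl):
            skipped += 1
            continue
        out.append(ReferenceImage(normalize(sl), pixel_spacing=spacing))
    if skipped:
        log.warning("skipped %d all-zero slice(s) in %s", skipped, path)
    return out


def save_acquisition(acq: CorruptedAcquisition, path) -> None:
    """Write an acquisition to HDF5; lossless at 64-bit-per-component."""
    with h5py.File(str(path), "w") as f:
        f.create_dataset("kspace", data=np.asarray(acq.k_motion, dtype=np.complex128))
        f.create_dataset("sampling_order", data=np.asarray(acq.order.order, dtype=np.int64))
        f.create_dataset("motion_track", data=np.asarray(acq.track.poses, dtype=np.float64))
        f.create_dataset("true_start", data=np.int64(acq.true_start))
        if acq.reference is not None:
            f.create_dataset("reference", data=as_pixels(acq.reference))
            f.attrs["pixel_spacing_mm"] = float(acq.reference.pixel_spacing)
        f.attrs["center_fraction"] = float(acq.order.center_fraction)
        f.attrs["sigma"] = float(acq.order.sigma)
        if acq.seed is not None:
            f.attrs["seed"] = int(acq.seed)


def load_acquisition(path) -> CorruptedAcquisition:
    """Read an acquisition written by :func:`save_acquisition`."""
    with h5py.File(str(path), "r") as f:
        for name in ("kspace", "sampling_order", "motion_track", "true_start"):
            if name not in f:
                raise FormatError(f"acquisition file {path} lacks dataset /{name}")
        kspace = f["kspace"][()]
        order = np.asarray(f["sampling_order"][()], dtype=np.int64)
        poses = np.asarray(f["motion_track"][()], dtype=np.float64)
        true_start = int(f["true_start"][()])
        reference = None
        if "reference" in f:
            spacing = float(f.attrs.get("pixel_spacing_mm", DEFAULT_PIXEL_SPACING_MM))
            reference = ReferenceImage(f["reference"][()], pixel_spacing=spacing)
        center_fraction = float(f.attrs.get("center_fraction", 0.15))
        sigma = float(f.attrs.get("sigma", len(order) / 6.0))
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
    sampling = SamplingOrder(order=order, center_fraction=center_fraction, sigma=sigma)
    track = MotionTrack(poses=poses, start_index=true_start)
    return CorruptedAcquisition(
        k_motion=kspace,
        order=sampling,
        track=track,
        true_start=true_start,
        reference=reference,
        seed=seed,
    )


def save_png(image, path) -> None:
    """Write an 8-bit min-max scaled preview of a magnitude image."""
    pix = as_pixels(image)
    lo, hi = pix.min(), pix.max()
    scaled = np.zeros_like(pix) if hi == lo else (pix - lo) / (hi - lo)
    iio.imwrite(Path(path), (scaled * 255).round().astype(np.uint8))
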