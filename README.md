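# kscrub

Retrospective motion-artifact removal for 2-D Cartesian MRI by k-space
phase-encoding (PE) line rejection and compressed-sensing reconstruction.

Patient motion during an MRI scan makes the acquired k-space lines mutually
inconsistent and produces ghosting and blurring in the image. When the
acquisition uses a pseudo-random sampling order — the central 15% of PE
lines sequentially first, then the rest drawn under a Gaussian preference
for low frequencies — the lines acquired *before* the motion began are
still perfectly consistent with the motionless object. `kscrub` finds
those lines and reconstructs the image from them alone:

1. **Simulate / acquire** a motion-corrupted k-space `k_motion` (line-wise
   rigid motion: per-line translations within ±5 px and rotations within
   ±5°, starting after a fraction of the scan).
2. **Filter** the corrupted image with a U-Net (25 convolutional layers,
   channels 32/64/128/256) trained to suppress motion artifacts — or, for
   analysis, with an `oracle` (ground truth) or `identity` filter.
3. **Detect** motion-affected lines by a per-line peak signal-to-noise
   ratio between `k_motion` and the filtered image's k-space,

       PSNR_k(n) = 10 log10( max_m |k_motion(m,n)|^2
                             / mean_m |k_motion(m,n) - k_filtered(m,n)|^2 ),

   split the scores into affected/unaffected groups with an exact Otsu
   threshold, and date the motion start at the first two consecutive
   failures in sampling-time order (ignoring the 40 outermost, low-SNR PE
   indices on each side).
4. **Reconstruct** the final image from the retained lines by
   split-Bregman total-variation compressed sensing,
   `min_u TV(u) + (mu/2) ||F_mask u - f||^2`.

Everything runs on synthetic phantoms (Shepp-Logan, random ellipses), so
the whole pipeline is testable without any data download; NIfTI volumes of
real slices are equally accepted. See `docs/methods.md` for the model
details and design choices.

## Worked example

```python
import kscrub as ks
from kscrub.phantoms import as_pixels

ph = ks.make_phantom(256, 256, "shepp_logan", seed=0)
order = ks.make_sampling_order(256, seed=5)            # center-first, Gaussian tail
track = ks.make_motion_track(256, start_fraction=0.40, seed=6)   # mode M40
acq = ks.simulate_kspace(ph, order, track)

corrupted = ks.corrupted_image(acq)
print(ks.psnr(corrupted, ph), ks.ssim(corrupted, ph))

res = ks.detect_lines(acq.k_motion, ks.fft2c(as_pixels(ph)),  # oracle filter
                      order, n_exclude_per_side=40)
print(res.detected_start, int(res.retained_mask.sum()))

final = ks.split_bregman_cs(acq.k_motion, res.retained_mask)
print(ks.psnr(final, ph), ks.ssim(final, ph))
```

Output:

```
corrupted PSNR: 21.13 dB, SSIM: 0.279
detected start: 102 | retained lines: 102
final PSNR: 40.27 dB, SSIM: 0.987
```

Motion began after line 102 of 256 (40% of the scan) and was detected at
exactly that time step; the 102 motion-free lines were kept, and the
compressed-sensing reconstruction recovers the phantom at 40.3 dB — a
19 dB improvement over the corrupted image.

The same pipeline is available from the shell:

```sh
kscrub simulate --phantom shepp_logan --start-frac 0.4 --seed 5 --out acq.h5
kscrub filter --kind oracle --acq acq.h5 --out filtered.nii.gz
kscrub detect --acq acq.h5 --filtered filtered.nii.gz --out detect.json
kscrub reconstruct --acq acq.h5 --detect detect.json --out final.nii.gz
kscrub run --config pipeline.yaml        # full multi-phantom study
```

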