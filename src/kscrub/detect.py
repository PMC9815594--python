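"""Detection of motion-affected phase-encoding lines.

Each PE line ``n`` of the corrupted k-space is scored against the same line
of the filtered image's k-space with a per-line peak signal-to-noise
ratio::

    MAX_k(n)  = max_m |k_motion(m, n)|
    MSE_k(n)  = sum_m |k_motion(m, n) - k_filtered(m, n)|^2 / numR
    PSNR_k(n) = 10 log10(MAX_k(n)^2 / MSE_k(n))

Lines acquired before the motion began are identical to the reference
transform when the filter is perfect, so their score is +infinity; heavily
corrupted lines score low.  Otsu's method splits the finite scores into two
groups (the higher-scoring group is called unaffected), and the motion
start is the first pair of two consecutive affected lines in sampling-time
order, after dropping the low-SNR outermost PE indices on each side.  All
lines sampled before that time are retained for reconstruction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DegenerateInputError
from .motion import SamplingOrder

log = logging.getLogger(__name__)


@dataclass
class DetectionResult:
    """Per-line scores, threshold, labels and the retained-line mask.

    ``labels[n] = 0`` iff ``psnr_k[n] >= threshold`` (0 = unaffected).
    ``detected_start`` is a time index into the sampling order, or ``None``
    when no two consecutive affected lines were found.  ``retained_mask``
    is per PE index and marks lines sampled before ``detected_start``.
    """

    psnr_k: np.ndarray
    threshold: float
    labels: np.ndarray
    excluded: np.ndarray
    detected_start: int | None
    retained_mask: np.ndarray


def compute_psnr_k(k_motion: np.ndarray, k_filtered: np.ndarray) -> np.ndarray:
    """Per-PE-line PSNR in dB; identical lines score +infinity.

    An all-zero corrupted line with nonzero difference scores -infinity and
    is logged as degenerate.  Scores are invariant to scaling both k-spaces
    by a common positive factor.
    """
    k_motion = np.asarray(k_motion)
    k_filtered = np.asarray(k_filtered)
    if k_motion.shape != k_filtered.shape:
        raise ConfigurationError(
            f"k-space shapes differ: {k_motion.shape} vs {k_filtered.shape}"
        )
    num_r = k_motion.shape[0]
    if num_r < 1:
        raise ConfigurationError("need at least one readout sample")
    max_k = np.abs(k_motion).max(axis=0)
    mse_k = (np.abs(k_motion - k_filtered) ** 2).sum(axis=0) / num_r
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = 10.0 * np.log10(max_k**2 / mse_k)
    scores = np.where(mse_k == 0.0, np.inf, scores)
    dead = (max_k == 0.0) & (mse_k > 0.0)
    if np.any(dead):
        log.warning("%d all-zero k-space line(s) scored -inf", int(dead.sum()))
        scores = np.where(dead, -np.inf, scores)
    return scores


def otsu_threshold(values) -> float:
    """Exact Otsu threshold of a 1-D score set.

    Evaluates the between-class variance at every split between consecutive
    distinct sorted values and returns the midpoint of the best gap.  This
    is the exact optimum (no histogram binning).  Requires at least two
    finite values that are not all equal.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 2 or not np.all(np.isfinite(v)):
        raise DegenerateInputError("Otsu needs >= 2 finite values")
    if v[0] == v[-1]:
        raise DegenerateInputError("all scores equal: single class")
    n = v.size
    csum = np.cumsum(v)
    i = np.arange(1, n)  # lower class = v[:i]
    w0 = i / n
    m0 = csum[:-1] / i
    m1 = (csum[-1] - csum[:-1]) / (n - i)
    bcv = w0 * (1.0 - w0) * (m0 - m1) ** 2
    valid = v[1:] > v[:-1]
    bcv = np.where(valid, bcv, -np.inf)
    best = int(np.argmax(bcv))
    return float((v[best] + v[best + 1]) / 2.0)


def detect_motion_start(
    scores: np.ndarray,
    threshold: float,
    order: SamplingOrder,
    n_exclude_per_side: int = 40,
) -> DetectionResult:
    """Label lines by threshold and find the first two consecutive failures.

    The 0/1 labels are arranged in sampling-time order; lines whose PE index
    lies in the outermost ``n_exclude_per_side`` indices on either side are
    removed from the sequence (low SNR in the high-frequency region), and
    the first adjacent pair of 1s in what remains marks the motion start.
    The detected start time is the earliest time consistent with that
    evidence: one step after the last unaffected line kept in the sequence
    (when excluded lines were sampled in between, they are treated as
    already moving rather than presumed still).  Without such a preceding
    line the pair's first sampling time is used.  In the common case of no
    intervening excluded lines this equals the sampling time of the pair's
    first line.  Every line sampled before the detected time — including
    excluded ones — is retained.  With no such pair, all lines are
    retained.
    """
    scores = np.asarray(scores, dtype=float)
    num_pe = len(order)
    if scores.shape != (num_pe,):
        raise ConfigurationError("scores length must equal numPE")
    if n_exclude_per_side < 0 or 2 * n_exclude_per_side >= num_pe:
        raise ConfigurationError(
            f"n_exclude_per_side = {n_exclude_per_side} leaves no usable lines"
        )
    labels = (scores < threshold).astype(np.int8)
    pe_index = np.arange(num_pe)
    excluded = (pe_index < n_exclude_per_side) | (pe_index >= num_pe - n_exclude_per_side)

    kept = [(t, int(labels[pe])) for t, pe in enumerate(order.order) if not excluded[pe]]
    detected: int | None = None
    for i in range(len(kept) - 1):
        if kept[i][1] == 1 and kept[i + 1][1] == 1:
            # the kept entry before the pair is necessarily a 0
            detected = kept[i - 1][0] + 1 if i > 0 else kept[i][0]
            break

    times = order.times()
    if detected is None:
        retained = np.ones(num_pe, dtype=bool)
    else:
        retained = times < detected
    return DetectionResult(
        psnr_k=scores,
        threshold=float(threshold),
        labels=labels,
        excluded=excluded,
        detected_start=detected,
        retained_mask=retained,
    )


def detect_lines(
    k_motion: np.ndarray,
    k_filtered: np.ndarray,
    order: SamplingOrder,
    n_exclude_per_side: int = 40,
) -> DetectionResult:
    """Score, threshold and locate the motion start in one call.

    With an imperfect filter every score is finite and Otsu's method splits
    them into affected and unaffected groups.  A +infinity score, however,
    means the corrupted and filtered lines agree exactly — under this
    simulator only lines acquired while the object was still can do that —
    so when exact-match lines exist they constitute the unaffected class
    outright and the threshold is placed above every finite score.  If the
    finite scores cannot be split (fewer than two, or all equal), every
    line is treated as unaffected.
    """
    scores = compute_psnr_k(k_motion, k_filtered)
    finite = scores[np.isfinite(scores)]
    if np.any(np.isposinf(scores)) and finite.size:
        threshold = float(np.nextafter(finite.max(), np.inf))
    else:
        try:
            threshold = otsu_threshold(finite)
        except DegenerateInputError:
            threshold = -np.inf  # single class: nothing is below it
    return detect_motion_start(scores, threshold, order, n_exclude_per_side)
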