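"""Preprocessing of serial immunofluorescence channels into a CMP image.

The chain mirrors the acquisition workflow of serial stain–image–bleach
microscopy: each marker's grayscale image is (1) registered to a reference
channel by integer translation, (2) background-subtracted with its matched
post-bleach re-image, (3) binarized, and (4) merged with all other channels
into a per-pixel combinatorial molecular phenotype (CMP) image.

The CMP image stores one integer code per pixel: bit ``m`` set means marker
``m`` present, so the code is ``sum(1 << m)`` over present markers.  The
bitstring form (leftmost character = marker 0) is derived on demand.  Pixels
within ``margin`` of any edge are never foreground; the default margin is
15 px, matching the excluded border of 2048x2048 acquisitions.
"""

from __future__ import annotations

import csv
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from skimage.filters import threshold_otsu

__all__ = [
    "CMPImage",
    "code_to_bitstring",
    "bitstring_to_code",
    "register_pair",
    "subtract_background",
    "binarize_channel",
    "merge_channels",
    "prep_sample",
]

DEFAULT_MARGIN = 15


def code_to_bitstring(code: int, n_markers: int) -> str:
    """Integer CMP code -> bitstring with marker 0 leftmost."""
    return "".join("1" if code >> m & 1 else "0" for m in range(n_markers))


def bitstring_to_code(bitstring: str) -> int:
    return sum(1 << m for m, c in enumerate(bitstring) if c == "1")


@dataclass(frozen=True)
class CMPImage:
    """Per-pixel CMP codes for one sample.

    Invariants: margin-border pixels are 0 (background); foreground means
    code > 0, i.e. at least one marker present.
    """

    codes: np.ndarray  # (H, W) unsigned integer
    n_markers: int
    margin: int = DEFAULT_MARGIN

    def __post_init__(self) -> None:
        if self.codes.ndim != 2:
            raise ValueError("CMP code image must be 2-D")
        m = self.margin
        if m > 0:
            border = self.codes.copy()
            border[m:-m or None, m:-m or None] = 0
            if border.any():
                raise ValueError("margin-border pixels must be background")

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def foreground(self) -> np.ndarray:
        return self.codes > 0

    def bitstring_at(self, row: int, col: int) -> str:
        return code_to_bitstring(int(self.codes[row, col]), self.n_markers)

    def pixel_multiset(self, mask: np.ndarray | None = None) -> Counter:
        """Multiset of foreground CMP bitstrings, optionally within ``mask``."""
        sel = self.foreground if mask is None else (self.foreground & mask)
        codes, counts = np.unique(self.codes[sel], return_counts=True)
        return Counter(
            {
                code_to_bitstring(int(c), self.n_markers): int(n)
                for c, n in zip(codes, counts)
            }
        )

    def save_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(path, self.codes.astype(np.uint32))

    def save_csv(self, path: str | Path) -> None:
        """CSV of (row, col, bitstring) for every foreground pixel."""
        rows, cols = np.nonzero(self.foreground)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, quoting=csv.QUOTE_NONNUMERIC)
            w.writerow(["row", "col", "cmp"])
            for r, c in zip(rows, cols):
                w.writerow([int(r), int(c), self.bitstring_at(r, c)])

    @classmethod
    def load_tiff(
        cls, path: str | Path, n_markers: int, margin: int = DEFAULT_MARGIN
    ) -> "CMPImage":
        return cls(tifffile.imread(path).astype(np.uint32), n_markers, margin)


def _overlap_views(moving: np.ndarray, dr: int, dc: int):
    """Views of (moving, reference-frame) overlap when moving is shifted by (dr, dc)."""
    h, w = moving.shape
    r0m, r1m = max(0, -dr), h - max(0, dr)
    c0m, c1m = max(0, -dc), w - max(0, dc)
    r0r, c0r = max(0, dr), max(0, dc)
    return (slice(r0m, r1m), slice(c0m, c1m)), (
        slice(r0r, r0r + (r1m - r0m)),
        slice(c0r, c0r + (c1m - c0m)),
    )


def register_pair(
    moving: np.ndarray,
    reference: np.ndarray,
    shift_max: int,
    smooth_sigma: float = 0.0,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Align ``moving`` to ``reference`` by integer translation.

    Searches all shifts within +/- ``shift_max`` and picks the one maximizing
    the Pearson correlation over the overlap region (zero-mean normalisation,
    so a constant illumination base does not bias the search toward zero
    shift through the shrinking overlap area).  Ties are broken toward the
    smallest L1 shift, then lexicographically, so a featureless image
    registers at (0, 0).  Out-of-frame pixels are filled with 0.

    ``smooth_sigma`` Gaussian-smooths both images *for scoring only*: the
    channels of a serial acquisition show different markers, so their
    alignment signal is the shared cell-scale structure, not pixel texture;
    smoothing suppresses the uncorrelated per-pixel signal that would
    otherwise drown the correlation peak.  The returned image is the
    unsmoothed ``moving`` at the chosen shift.
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise ValueError("moving and reference must have identical shape")
    if shift_max < 0:
        raise ValueError("shift_max must be >= 0")
    if shift_max >= min(moving.shape):
        raise ValueError("shift_max must be smaller than the image size")

    if smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter

        score_moving = gaussian_filter(moving, smooth_sigma)
        score_reference = gaussian_filter(reference, smooth_sigma)
    else:
        score_moving, score_reference = moving, reference

    best_score, best_shift = -np.inf, (0, 0)
    for dr in range(-shift_max, shift_max + 1):
        for dc in range(-shift_max, shift_max + 1):
            sl_m, sl_r = _overlap_views(score_moving, dr, dc)
            a = score_moving[sl_m]
            b = score_reference[sl_r]
            a = a - a.mean()
            b = b - b.mean()
            denom = np.sqrt((a * a).sum() * (b * b).sum())
            score = 0.0 if denom == 0 else float((a * b).sum() / denom)
            key = (score, -(abs(dr) + abs(dc)), -dr, -dc)
            best_key = (best_score, -(abs(best_shift[0]) + abs(best_shift[1])),
                        -best_shift[0], -best_shift[1])
            if key > best_key:
                best_score, best_shift = score, (dr, dc)

    dr, dc = best_shift
    shifted = np.zeros_like(moving)
    sl_m, sl_r = _overlap_views(moving, dr, dc)
    shifted[sl_r] = moving[sl_m]
    return shifted, best_shift


def subtract_background(signal: np.ndarray, bleached: np.ndarray) -> np.ndarray:
    """Pixel-wise ``max(signal - bleached, 0)`` for one channel pair."""
    signal = np.asarray(signal, dtype=float)
    bleached = np.asarray(bleached, dtype=float)
    if signal.shape != bleached.shape:
        raise ValueError("signal and bleached images must have identical shape")
    return np.clip(signal - bleached, 0, None)


def binarize_channel(
    image: np.ndarray,
    policy: str = "otsu",
    *,
    threshold: float | None = None,
    quantile: float | None = None,
) -> tuple[np.ndarray, float]:
    """Binarize one channel; returns (mask, resolved threshold).

    Policies: ``"otsu"`` (parameter-free default), ``"fixed"`` (explicit
    ``threshold``), ``"quantile"`` (threshold at the given intensity
    quantile).  The mask is true where intensity is *strictly* greater than
    the threshold, so threshold 0 excludes exact zeros.  A constant image
    under Otsu has no threshold; it yields an all-false mask with a warning.
    """
    image = np.asarray(image, dtype=float)
    if (image < 0).any():
        raise ValueError("channel intensities must be non-negative")
    if policy == "otsu":
        if np.ptp(image) == 0:
            warnings.warn(
                "constant channel: Otsu undefined, returning all-background mask",
                stacklevel=2,
            )
            return np.zeros(image.shape, dtype=bool), float(image.flat[0])
        thr = float(threshold_otsu(image))
    elif policy == "fixed":
        if threshold is None:
            raise ValueError("fixed policy requires a threshold")
        thr = float(threshold)
    elif policy == "quantile":
        if quantile is None or not 0 <= quantile <= 1:
            raise ValueError("quantile policy requires quantile in [0, 1]")
        thr = float(np.quantile(image, quantile))
    else:
        raise ValueError(f"unknown binarization policy {policy!r}")
    return image > thr, thr


def merge_channels(
    masks: list[np.ndarray], margin: int = DEFAULT_MARGIN
) -> CMPImage:
    """Merge ordered binary masks into a CMP image.

    List order defines marker indices: the first mask is marker #0.  Pixels
    true in no mask are background, as are all pixels within ``margin`` of
    an edge.
    """
    if not masks:
        raise ValueError("need at least one channel mask")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("all channel masks must have identical shape")
    codes = np.zeros(shape, dtype=np.uint32)
    for m, mask in enumerate(masks):
        codes |= mask.astype(np.uint32) << m
    if margin > 0:
        inner = codes[margin:-margin or None, margin:-margin or None].copy()
        codes[:] = 0
        codes[margin:-margin or None, margin:-margin or None] = inner
    return CMPImage(codes=codes, n_markers=len(masks), margin=margin)


def prep_sample(
    signal_stack: np.ndarray,
    background_stack: np.ndarray,
    *,
    margin: int = DEFAULT_MARGIN,
    policy: str = "otsu",
    threshold: float | None = None,
    quantile: float | None = None,
    shift_max: int = 0,
    reference_channel: int = -1,
    smooth_sigma: float = 0.0,
) -> CMPImage:
    """Full chain register -> subtract -> binarize -> merge for one sample.

    ``signal_stack`` and ``background_stack`` are (M, H, W) with one channel
    per marker.  Each channel (and its matched background) is registered to
    the reference channel's signal when ``shift_max > 0``.  The default
    reference is the *last* channel: panels conventionally end with a
    diffuse whole-cell stain (F-actin), which gives the strongest shared
    structure to align on.  A channel whose marker is essentially absent
    from the field carries no alignment information; its estimated shift is
    then arbitrary (but so is its content).
    """
    if signal_stack.shape != background_stack.shape:
        raise ValueError("signal and background stacks must have identical shape")
    reference_channel = reference_channel % signal_stack.shape[0]
    reference = signal_stack[reference_channel]
    masks = []
    for m in range(signal_stack.shape[0]):
        sig, bg = signal_stack[m], background_stack[m]
        if shift_max > 0 and m != reference_channel:
            sig, shift = register_pair(sig, reference, shift_max, smooth_sigma)
            dr, dc = shift
            bg_shifted = np.zeros_like(np.asarray(bg, dtype=float))
            sl_m, sl_r = _overlap_views(np.asarray(bg, dtype=float), dr, dc)
            bg_shifted[sl_r] = np.asarray(bg, dtype=float)[sl_m]
            bg = bg_shifted
        sub = subtract_background(sig, bg)
        mask, _ = binarize_channel(sub, policy, threshold=threshold, quantile=quantile)
        masks.append(mask)
    return merge_channels(masks, margin=margin)
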