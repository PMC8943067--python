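"""Per-cell CMP extraction, top-20 marker profiles, and panel reduction.

A cell's *profile* (its "signature") summarizes the CMP content of that
cell: rank the CMPs occurring in the cell's pixels by within-cell frequency,
keep the 20 most abundant, and count for each marker how many of those CMPs
contain it (k_m, an integer 0..20).  Fractions f_m = k_m / (CMPs actually
used) make cells with fewer than 20 distinct CMPs comparable.  Profiles are
the clustering input downstream.

Panel reduction (for cross-study comparison on a shared marker subset)
re-merges the kept channels and recomputes CMPs from scratch: a pixel whose
only markers are dropped becomes background in the reduced space, so
projecting existing bitstrings would miscount.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import compile_cmp_table, top_n
from .image_prep import CMPImage

__all__ = [
    "CellROI",
    "CellProfile",
    "rois_from_label_mask",
    "rois_from_csv",
    "extract_cell_pixels",
    "cell_profile",
    "cluster_mean_profile",
    "profiles_frame",
    "subset_panel_image",
    "subset_panel_masks",
]


@dataclass(frozen=True)
class CellROI:
    """Pixel addresses of one manually selected, non-touching cell."""

    cell_id: int
    sample_id: str
    pixels: np.ndarray  # (n, 2) int array of (row, col)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=int)
        if px.ndim != 2 or px.shape[1] != 2 or len(px) == 0:
            raise ValueError("ROI pixels must be a non-empty (n, 2) array")
        object.__setattr__(self, "pixels", px)


def rois_from_label_mask(mask: np.ndarray, sample_id: str) -> list[CellROI]:
    """One ROI per non-zero label of a cell-id label mask."""
    rois = []
    for cid in np.unique(mask):
        if cid == 0:
            continue
        rows, cols = np.nonzero(mask == cid)
        rois.append(CellROI(int(cid), sample_id, np.column_stack([rows, cols])))
    return rois


def rois_from_csv(path: str | Path, sample_id: str, one_based: bool = False) -> list[CellROI]:
    """Read (cell_id, row, col) pixel lists; ``one_based`` converts ImageJ
    1-based coordinates to the package's 0-based convention."""
    df = pd.read_csv(path)
    off = 1 if one_based else 0
    rois = []
    for cid, sub in df.groupby("cell_id"):
        px = sub[["row", "col"]].to_numpy(dtype=int) - off
        rois.append(CellROI(int(cid), sample_id, px))
    return rois


def extract_cell_pixels(
    cmp_image: CMPImage, roi: CellROI
) -> tuple[Counter, int]:
    """Multiset of foreground CMPs at the ROI's pixels.

    Background pixels inside the ROI (no marker present, or inside the
    excluded margin) are dropped; their count is returned alongside.  An ROI
    that is entirely background yields an empty multiset.
    """
    h, w = cmp_image.shape
    px = roi.pixels
    if (px < 0).any() or (px[:, 0] >= h).any() or (px[:, 1] >= w).any():
        raise ValueError(f"ROI {roi.cell_id} has pixels outside the image")
    codes = cmp_image.codes[px[:, 0], px[:, 1]]
    fg = codes > 0
    n_background = int((~fg).sum())
    vals, counts = np.unique(codes[fg], return_counts=True)
    from .image_prep import code_to_bitstring

    multiset = Counter(
        {
            code_to_bitstring(int(v), cmp_image.n_markers): int(n)
            for v, n in zip(vals, counts)
        }
    )
    return multiset, n_background


@dataclass(frozen=True)
class CellProfile:
    """Marker occurrence counts within a cell's top-k CMPs."""

    cell_id: int
    sample_id: str
    counts: np.ndarray  # k_m, ints in 0..top_k
    fractions: np.ndarray  # f_m = k_m / n_cmps_used
    n_cmps_used: int
    group: str | None = None
    sex: str | None = None

    @property
    def n_markers(self) -> int:
        return len(self.counts)


def cell_profile(
    multiset: Counter,
    n_markers: int,
    top_k: int = 20,
    *,
    cell_id: int = 0,
    sample_id: str = "",
    group: str | None = None,
    sex: str | None = None,
) -> CellProfile:
    """Build a cell's top-k marker profile from its CMP multiset.

    CMPs are ranked within the cell (frequency descending, lexicographic
    tie-break); the top ``min(top_k, distinct)`` CMPs are kept and each
    marker's occurrences among them counted.  Cells with fewer than
    ``top_k`` distinct CMPs use all of them, and fractions normalize by the
    number actually used.
    """
    if not multiset:
        raise ValueError("cell has no foreground CMPs")
    table = top_n(compile_cmp_table(multiset, n_markers=n_markers), top_k)
    used = len(table)
    counts = np.zeros(n_markers, dtype=int)
    for cmp_ in table.cmps:
        for m, c in enumerate(cmp_):
            if c == "1":
                counts[m] += 1
    return CellProfile(
        cell_id=cell_id,
        sample_id=sample_id,
        counts=counts,
        fractions=counts / used,
        n_cmps_used=used,
        group=group,
        sex=sex,
    )


def cluster_mean_profile(
    profiles: Sequence[CellProfile],
) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic mean (k, f) across cells — the inset "signature" curve."""
    if not profiles:
        raise ValueError("need at least one profile")
    if len({p.n_markers for p in profiles}) > 1:
        raise ValueError("profiles come from different marker panels")
    mean_k = np.mean([p.counts for p in profiles], axis=0)
    mean_f = np.mean([p.fractions for p in profiles], axis=0)
    return mean_k, mean_f


def profiles_frame(profiles: Sequence[CellProfile]) -> pd.DataFrame:
    """Tidy frame: cell_id, sample_id, group, sex, k_0.., f_0.., n_cmps_used."""
    if not profiles:
        raise ValueError("need at least one profile")
    M = profiles[0].n_markers
    rows = []
    for p in profiles:
        row = dict(cell_id=p.cell_id, sample_id=p.sample_id, group=p.group, sex=p.sex,
                   n_cmps_used=p.n_cmps_used)
        row.update({f"k_{m}": int(p.counts[m]) for m in range(M)})
        row.update({f"f_{m}": float(p.fractions[m]) for m in range(M)})
        rows.append(row)
    return pd.DataFrame(rows)


def subset_panel_masks(
    masks: Sequence[np.ndarray], keep: Sequence[int]
) -> list[np.ndarray]:
    """Reorder/restrict binary channel masks to ``keep`` (new marker order)."""
    if len(keep) == 0:
        raise ValueError("keep must be non-empty")
    if len(set(keep)) != len(keep):
        raise ValueError("duplicate markers in keep")
    return [masks[m] for m in keep]


def subset_panel_image(cmp_image: CMPImage, keep: Sequence[int]) -> CMPImage:
    """Re-merge a CMP image onto a marker subset, recomputing CMPs.

    ``keep`` is an ordered subset of the original panel; kept marker
    ``keep[j]`` becomes marker ``j`` of the reduced panel.  Pixels with no
    kept marker become background, so reduced-space foreground can shrink.
    """
    if len(keep) == 0:
        raise ValueError("keep must be non-empty")
    if len(set(keep)) != len(keep):
        raise ValueError("duplicate markers in keep")
    if any(not 0 <= m < cmp_image.n_markers for m in keep):
        raise ValueError("keep contains markers outside the panel")
    new_codes = np.zeros_like(cmp_image.codes)
    for j, m in enumerate(keep):
        new_codes |= ((cmp_image.codes >> m) & 1) << j
    return CMPImage(codes=new_codes, n_markers=len(keep), margin=cmp_image.margin)
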