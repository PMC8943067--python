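"""Synthetic multiplexed-immunofluorescence cohorts with known ground truth.

Emulates the study design the package targets: fields of sparse, round,
non-touching alveolar-macrophage-like cells; a panel of binary markers per
pixel with cell-level co-expression structure (each cell carries a
*phenotype*, a vector of per-marker expression probabilities); punctate
autofluorescence on marker 0; diffuse F-actin on the last marker; and
group-level effects (treatment changing phenotype diversity, sex shifting
phenotype prevalence).  Every sample retains full ground truth — the
per-pixel true marker matrix and the per-cell CMP multisets — so every
downstream stage can be checked against an oracle that bypasses image
processing entirely.

Pixel-level marker presence is Bernoulli given the cell's phenotype
probabilities, so a cell yields a *distribution* of CMPs rather than a
single one; this is what makes a per-cell "top-20 CMPs" summary meaningful.
Grayscale rendering is ``base + amplitude * presence + Gaussian noise``
(clipped at 0), and the matched post-bleach background image is
``bleach_residual * clean signal`` plus fresh noise, which makes background
subtraction and thresholding non-trivial but controllable.  With
``noise_sd = 0`` and ``bleach_residual = 0`` the preprocessing chain must
recover the ground truth exactly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .catalog import encode_cmp
from .image_prep import CMPImage

__all__ = [
    "SimConfig",
    "SampleMeta",
    "GroundTruth",
    "SimulatedSample",
    "PackingError",
    "default_phenotype_library",
    "simulate_field",
    "simulate_cohort",
    "ground_truth_cmp_image",
    "write_sample",
    "treatment_diversity_conditions",
    "sex_linked_conditions",
    "phenotype_recovery_conditions",
]


class PackingError(RuntimeError):
    """Raised when non-overlapping cell placement fails after bounded retries."""


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    group: str = "Vehicle"
    sex: str = "F"


def default_phenotype_library(
    n_markers: int = 12, n_phenotypes: int = 4
) -> list[np.ndarray]:
    """A simple, well-separated phenotype library.

    Each phenotype strongly expresses a distinct block of markers (p = 0.85)
    on a low common background (p = 0.05); the last marker (F-actin) is
    diffuse in every phenotype (p = 0.9).  Marker 0 carries only a weak base
    rate here because punctate autofluorescence is added separately.
    """
    lib = []
    # leave marker 0 (AF) and the last marker (F-actin) out of the blocks
    assignable = list(range(1, max(n_markers - 1, 2)))
    blocks = np.array_split(np.array(assignable), n_phenotypes)
    for b in blocks:
        p = np.full(n_markers, 0.05)
        p[b] = 0.85
        p[-1] = 0.9
        p[0] = 0.1
        lib.append(p)
    return lib


@dataclass
class SimConfig:
    """Generator settings; defaults give a fast test-scale field.

    ``field_size`` 512 is the test-scale default (2048 mimics real
    acquisitions); ``phenotype_weights_by_group`` maps ``(group, sex)`` to a
    probability vector over ``phenotype_library`` and defaults to uniform.
    """

    field_size: int = 512
    n_cells: int = 20
    cell_radius_range: tuple[int, int] = (8, 16)
    n_markers: int = 12
    phenotype_library: list[np.ndarray] | None = None
    phenotype_weights_by_group: Mapping[tuple[str, str], Sequence[float]] | None = None
    af_puncta_rate: float = 3.0
    noise_sd: float = 4.0
    bleach_residual: float = 0.1
    shift_max: int = 2
    margin: int = 15
    base_intensity: float = 10.0
    amplitude: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phenotype_library is None:
            self.phenotype_library = default_phenotype_library(self.n_markers)
        self.phenotype_library = [np.asarray(p, dtype=float) for p in self.phenotype_library]
        for p in self.phenotype_library:
            if len(p) != self.n_markers:
                raise ValueError("phenotype vector length must equal n_markers")
            if (p < 0).any() or (p > 1).any():
                raise ValueError("marker probabilities must lie in [0, 1]")
        if self.phenotype_weights_by_group is not None:
            for key, w in self.phenotype_weights_by_group.items():
                w = np.asarray(w, dtype=float)
                if len(w) != len(self.phenotype_library):
                    raise ValueError(f"weights for {key} must cover every phenotype")
                if (w < 0).any() or not np.isclose(w.sum(), 1.0):
                    raise ValueError(f"weights for {key} must be a probability vector")
        lo, hi = self.cell_radius_range
        if not 0 < lo <= hi:
            raise ValueError("invalid cell_radius_range")
        if self.n_cells < 0 or self.shift_max < 0 or self.noise_sd < 0:
            raise ValueError("n_cells, shift_max and noise_sd must be non-negative")
        if not 0 <= self.bleach_residual <= 1:
            raise ValueError("bleach_residual must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted truth for one simulated field."""

    cells: pd.DataFrame  # cell_id, row, col, radius, phenotype, sample_id, group, sex
    marker_truth: np.ndarray  # (M, H, W) bool, reference frame
    labels: np.ndarray  # (H, W) int32, 0 = background, cell ids from 1

    def cmp_multisets_by_cell(self) -> dict[int, Counter]:
        """Per-cell multiset of true foreground CMP bitstrings."""
        M = self.marker_truth.shape[0]
        codes = np.zeros(self.labels.shape, dtype=np.uint32)
        for m in range(M):
            codes |= self.marker_truth[m].astype(np.uint32) << m
        out: dict[int, Counter] = {}
        for cid in self.cells["cell_id"]:
            sel = (self.labels == cid) & (codes > 0)
            vals, counts = np.unique(codes[sel], return_counts=True)
            out[int(cid)] = Counter(
                {
                    encode_cmp([m for m in range(M) if v >> m & 1], M): int(n)
                    for v, n in zip(vals, counts)
                }
            )
        return out


@dataclass
class SimulatedSample:
    meta: SampleMeta
    signal: np.ndarray  # (M, H, W) uint16
    background: np.ndarray  # (M, H, W) uint16
    truth: GroundTruth
    applied_shifts: list[tuple[int, int]]  # per channel, (0,0) for channel 0


def _place_cells(cfg: SimConfig, rng: np.random.Generator) -> list[tuple[int, int, int]]:
    """Non-overlapping disk centers fully inside margin + shift slack."""
    lo, hi = cfg.cell_radius_range
    placed: list[tuple[int, int, int]] = []
    max_tries = 200 * max(cfg.n_cells, 1)
    tries = 0
    while len(placed) < cfg.n_cells:
        if tries >= max_tries:
            raise PackingError(
                f"could not place {cfg.n_cells} non-overlapping cells of radius "
                f"{cfg.cell_radius_range} in a {cfg.field_size}px field"
            )
        tries += 1
        r = int(rng.integers(lo, hi + 1))
        pad = cfg.margin + cfg.shift_max + r + 1
        if 2 * pad >= cfg.field_size:
            raise PackingError("field too small for margin + cell radius")
        cy = int(rng.integers(pad, cfg.field_size - pad))
        cx = int(rng.integers(pad, cfg.field_size - pad))
        if all((cy - y) ** 2 + (cx - x) ** 2 > (r + rr + 1) ** 2 for y, x, rr in placed):
            placed.append((cy, cx, r))
    return placed


def simulate_field(
    config: SimConfig, meta: SampleMeta, rng: np.random.Generator | None = None
) -> SimulatedSample:
    """Simulate one multi-channel field with matched post-bleach backgrounds.

    Deterministic given (config, meta, seed).  Channels other than the last
    (the diffuse F-actin channel, which serves as the registration anchor)
    are mis-registered by a random integer shift up to ``shift_max`` (signal
    and its background share the shift, as they come from the same
    acquisition cycle); ground truth stays in the anchor's frame.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    H = W = config.field_size
    M = config.n_markers

    centers = _place_cells(config, rng)
    labels = np.zeros((H, W), dtype=np.int32)
    weights = None
    if config.phenotype_weights_by_group is not None:
        weights = np.asarray(
            config.phenotype_weights_by_group[(meta.group, meta.sex)], dtype=float
        )
    n_phen = len(config.phenotype_library)
    rows = []
    truth = np.zeros((M, H, W), dtype=bool)
    yy, xx = np.mgrid[0:H, 0:W]
    for i, (cy, cx, r) in enumerate(centers, start=1):
        phen = int(rng.choice(n_phen, p=weights))
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        labels[disk] = i
        probs = config.phenotype_library[phen]
        n_px = int(disk.sum())
        draws = rng.random((n_px, M)) < probs[None, :]
        for m in range(M):
            truth[m][disk] = draws[:, m]
        # punctate autofluorescence: small bright granules on marker 0
        n_puncta = int(rng.poisson(config.af_puncta_rate))
        for _ in range(n_puncta):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, max(r - 2, 0))
            py, px = int(cy + rad * np.sin(ang)), int(cx + rad * np.cos(ang))
            pr = int(rng.integers(1, 3))
            puncta = (yy - py) ** 2 + (xx - px) ** 2 <= pr * pr
            truth[0][puncta & disk] = True
        rows.append(
            dict(cell_id=i, row=cy, col=cx, radius=r, phenotype=phen,
                 sample_id=meta.sample_id, group=meta.group, sex=meta.sex)
        )
    cells = pd.DataFrame(
        rows, columns=["cell_id", "row", "col", "radius", "phenotype",
                       "sample_id", "group", "sex"]
    )

    signal = np.zeros((M, H, W), dtype=np.uint16)
    background = np.zeros((M, H, W), dtype=np.uint16)
    shifts: list[tuple[int, int]] = []
    for m in range(M):
        clean = config.base_intensity + config.amplitude * truth[m]
        bg_clean = config.bleach_residual * clean
        if m == M - 1 or config.shift_max == 0:
            dr = dc = 0
        else:
            dr = int(rng.integers(-config.shift_max, config.shift_max + 1))
            dc = int(rng.integers(-config.shift_max, config.shift_max + 1))
        shifts.append((dr, dc))
        sig = _shift_fill(clean, dr, dc)
        bg = _shift_fill(bg_clean, dr, dc)
        if config.noise_sd > 0:
            sig = sig + rng.normal(0, config.noise_sd, sig.shape)
            bg = bg + rng.normal(0, config.noise_sd, bg.shape)
        signal[m] = np.clip(np.rint(sig), 0, 65535).astype(np.uint16)
        background[m] = np.clip(np.rint(bg), 0, 65535).astype(np.uint16)

    gt = GroundTruth(cells=cells, marker_truth=truth, labels=labels)
    return SimulatedSample(meta=meta, signal=signal, background=background,
                           truth=gt, applied_shifts=shifts)


def _shift_fill(img: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Translate by (dr, dc), filling exposed pixels with 0."""
    out = np.zeros_like(img, dtype=float)
    h, w = img.shape
    r0s, r1s = max(0, dr), h + min(0, dr)
    c0s, c1s = max(0, dc), w + min(0, dc)
    out[r0s:r1s, c0s:c1s] = img[r0s - dr:r1s - dr, c0s - dc:c1s - dc]
    return out


def simulate_cohort(
    config: SimConfig, design: Sequence[SampleMeta]
) -> list[SimulatedSample]:
    """Simulate one sample per design entry with per-sample substreams.

    Sample ``i`` uses seed ``config.seed + i`` (fixed arithmetic, so any
    sample can be regenerated in isolation).  Duplicate sample ids are
    rejected.
    """
    if not design:
        raise ValueError("design must be non-empty")
    ids = [m.sample_id for m in design]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in design")
    out = []
    for i, meta in enumerate(design):
        rng = np.random.default_rng(config.seed + i)
        out.append(simulate_field(config, meta, rng=rng))
    return out


def ground_truth_cmp_image(truth: GroundTruth, margin: int = 0) -> CMPImage:
    """Oracle CMP image straight from the true marker matrix (no imaging)."""
    M = truth.marker_truth.shape[0]
    codes = np.zeros(truth.labels.shape, dtype=np.uint32)
    for m in range(M):
        codes |= truth.marker_truth[m].astype(np.uint32) << m
    if margin > 0:
        inner = codes[margin:-margin or None, margin:-margin or None].copy()
        codes[:] = 0
        codes[margin:-margin or None, margin:-margin or None] = inner
    return CMPImage(codes=codes, n_markers=M, margin=margin)


def treatment_diversity_conditions(
    seed: int = 0,
) -> tuple[SimConfig, list[SampleMeta]]:
    """Cohort where treatment raises phenotype *diversity*, not identity.

    Five phenotypes share one base expression pattern; four are prevalence
    variants perturbing a few mid-range markers.  The Vehicle group draws
    cells almost exclusively from the first two phenotypes (weights .7/.3)
    while the treated group spreads uniformly over all five, so both groups
    express every marker at similar marginal rates but the treated group's
    CMP frequency ranking is flatter and varies more between replicate
    samples.  The expected downstream effect is the classic conservation
    asymmetry: the low-diversity group shows more 3-of-3/2-of-3 matches.

    Three samples per group, test-scale fields (160 px, 10 small cells,
    8 markers).
    """
    M = 8
    base = np.array([0.25, 0.7, 0.45, 0.6, 0.35, 0.55, 0.4, 0.9])
    rng = np.random.default_rng(7)  # fixed: the library is part of the design
    library = [base]
    for _ in range(4):
        p = base.copy()
        idx = rng.choice(np.arange(1, M - 1), 4, replace=False)
        p[idx] = np.clip(p[idx] + rng.choice([-0.35, 0.35], 4), 0.05, 0.95)
        library.append(p)
    weights = {
        ("Vehicle", "F"): np.array([0.7, 0.3, 0.0, 0.0, 0.0]),
        ("SP-A1 rescue", "F"): np.full(5, 0.2),
    }
    config = SimConfig(
        field_size=160, n_cells=10, cell_radius_range=(5, 9), n_markers=M,
        phenotype_library=library, phenotype_weights_by_group=weights,
        shift_max=0, af_puncta_rate=1.0, seed=seed,
    )
    design = [SampleMeta(f"V{i}", "Vehicle", "F") for i in range(1, 4)] + [
        SampleMeta(f"R{i}", "SP-A1 rescue", "F") for i in range(1, 4)
    ]
    return config, design


def sex_linked_conditions(seed: int = 0) -> tuple[SimConfig, list[SampleMeta]]:
    """2x2 cohort (treatment x sex) where only sex drives phenotype weights.

    Four phenotypes on a 7-marker panel; females draw almost entirely from
    the first two, males from the last two, identically in both treatment
    arms.  Clustering cell profiles should therefore separate sexes, not
    treatments: Cramér's V for sex x cluster is expected to exceed V for
    treatment x cluster.
    """
    M = 7
    base = np.array([0.2, 0.6, 0.3, 0.5, 0.35, 0.55, 0.9])
    tweaks = [(1, +0.35), (2, +0.45), (3, -0.3), (4, +0.45)]
    library = []
    for m, d in tweaks:
        p = base.copy()
        p[m] = np.clip(p[m] + d, 0.05, 0.95)
        p[(m % 5) + 1] = np.clip(p[(m % 5) + 1] - 0.2, 0.05, 0.95)
        library.append(p)
    w_f = np.array([0.45, 0.45, 0.05, 0.05])
    w_m = np.array([0.05, 0.05, 0.45, 0.45])
    weights = {
        (g, s): (w_f if s == "F" else w_m)
        for g in ("Vehicle", "SP-A1 rescue")
        for s in ("F", "M")
    }
    config = SimConfig(
        field_size=128, n_cells=8, cell_radius_range=(5, 9), n_markers=M,
        phenotype_library=library, phenotype_weights_by_group=weights,
        shift_max=0, af_puncta_rate=1.0, seed=seed,
    )
    design = [
        SampleMeta("FV", "Vehicle", "F"),
        SampleMeta("FR", "SP-A1 rescue", "F"),
        SampleMeta("MV", "Vehicle", "M"),
        SampleMeta("MR", "SP-A1 rescue", "M"),
    ]
    return config, design


def phenotype_recovery_conditions(seed: int = 0) -> tuple[SimConfig, list[SampleMeta]]:
    """Three well-separated planted phenotypes for cluster-recovery checks.

    Each phenotype strongly expresses its own pair of markers on a low
    common background; three replicate samples of 12 cells each.
    """
    M = 8
    library = []
    for i in range(3):
        p = np.full(M, 0.1)
        p[0] = 0.15
        p[-1] = 0.9
        p[1 + 2 * i] = 0.9
        p[2 + 2 * i] = 0.8
        library.append(p)
    config = SimConfig(
        field_size=160, n_cells=12, cell_radius_range=(6, 10), n_markers=M,
        phenotype_library=library, shift_max=0, af_puncta_rate=0.5, seed=seed,
    )
    design = [SampleMeta(f"S{i}", "Vehicle", "F") for i in range(1, 4)]
    return config, design


def write_sample(sample: SimulatedSample, outdir) -> None:
    """Write per-marker signal/background TIFFs, label mask and metadata CSV."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    M = sample.signal.shape[0]
    for m in range(M):
        tifffile.imwrite(outdir / f"marker{m:02d}_signal.tif", sample.signal[m])
        tifffile.imwrite(outdir / f"marker{m:02d}_background.tif", sample.background[m])
    tifffile.imwrite(outdir / "labels.tif", sample.truth.labels.astype(np.uint16))
    meta = sample.meta
    pd.DataFrame(
        [dict(sample_id=meta.sample_id, group=meta.group, sex=meta.sex)]
    ).to_csv(outdir / "metadata.csv", index=False)
    sample.truth.cells.to_csv(outdir / "cells.csv", index=False)
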