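"""Column-wise augmented matrix construction and region segmentation.

After ROI compression each sample is a (scans x union-ROI) matrix; the
K sample matrices are stacked row-wise into one augmented matrix D_aug
sharing the spectral (ROI) axis, so a single bilinear decomposition
resolves all samples simultaneously. Because the factorization is
row-wise, per-sample scan grids need not be aligned and retention-time
shifts between runs are tolerated by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .ms_io import ScanSet

__all__ = ["AugmentedMatrix", "trim_injection", "build_augmented", "segment_regions"]


@dataclass
class AugmentedMatrix:
    """D_aug: K sample blocks stacked row-wise over one union-ROI axis."""

    data: np.ndarray  # (sum of scan counts, n_union_rois), >= 0
    block_index: dict  # sample_id -> slice into rows, in design order
    col_mz: np.ndarray  # union-ROI m/z axis
    rt_axes: dict  # sample_id -> RT array (seconds) for its block
    rt_window: tuple | None = None  # (start, end) seconds covered by this (sub)matrix
    col_parent: np.ndarray | None = None  # column indices into the parent matrix (regions)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        n = sum(s.stop - s.start for s in self.block_index.values())
        if n != self.data.shape[0]:
            raise ValueError("block slices do not partition the rows")
        if self.col_mz.shape[0] != self.data.shape[1]:
            raise ValueError("column axis length mismatch")

    @property
    def K(self) -> int:
        return len(self.block_index)

    @property
    def sample_ids(self) -> list:
        return list(self.block_index)

    def block(self, sample_id: str) -> np.ndarray:
        return self.data[self.block_index[sample_id]]

    def tic(self) -> tuple:
        """Pooled (rt, summed intensity) points across all blocks."""
        rts = np.concatenate([self.rt_axes[s] for s in self.block_index])
        tic = self.data.sum(axis=1)
        return rts, tic


def trim_injection(scans: ScanSet, cutoff_s: float = 330.0) -> ScanSet:
    """Drop all scans before the injection-peak cutoff.

    The first minutes of a run hold unretained material (the injection
    peak) and carry no chromatographic information; they are excluded
    identically before ROI extraction and feature-table filtering.
    """
    if cutoff_s <= 0:
        return scans
    keep = scans.rts >= cutoff_s
    if not keep.any():
        raise ValueError("cutoff removes the entire run")
    idx = np.nonzero(keep)[0]
    return ScanSet(
        scans.sample_id,
        scans.rts[idx],
        [scans.mzs[i] for i in idx],
        [scans.intensities[i] for i in idx],
        scans.ionization_mode,
    )


def build_augmented(
    roi_sets: dict,
    union_axis: np.ndarray,
    col_mapping: dict,
    scansets: dict,
    design_order: list | None = None,
) -> AugmentedMatrix:
    """Stack per-sample ROI traces into the augmented matrix.

    Parameters
    ----------
    roi_sets : sample_id -> list of ROI (from :func:`roimcr.roi.extract_rois`).
    union_axis, col_mapping : from :func:`roimcr.roi.build_union_axis`.
    scansets : sample_id -> ScanSet (for scan grids / RT axes).
    design_order : block order; defaults to the roi_sets iteration order.
    """
    order = design_order or list(roi_sets)
    missing = [s for s in order if s not in roi_sets]
    if missing:
        raise ValueError(f"samples missing a ROI set: {missing}")
    n_cols = union_axis.shape[0]
    blocks = []
    block_index = {}
    rt_axes = {}
    row0 = 0
    for sid in order:
        scanset = scansets[sid]
        n_scans = scanset.n_scans
        block = np.zeros((n_scans, n_cols))
        cols = col_mapping[sid]
        for roi, col in zip(roi_sets[sid], cols):
            np.add.at(block[:, col], roi.scan_idx, roi.trace)
        blocks.append(block)
        block_index[sid] = slice(row0, row0 + n_scans)
        rt_axes[sid] = scanset.rts.copy()
        row0 += n_scans
    data = np.vstack(blocks) if blocks else np.zeros((0, n_cols))
    rt_all = np.concatenate([rt_axes[s] for s in order]) if order else np.zeros(0)
    window = (float(rt_all.min()), float(rt_all.max())) if rt_all.size else None
    return AugmentedMatrix(data, block_index, np.asarray(union_axis, float), rt_axes, window)


def _tic_valley_boundaries(aug: AugmentedMatrix, n_regions: int, bin_s: float = 2.0, smooth_bins: float = 5.0) -> list:
    """Cut points at local minima of the smoothed pooled TIC.

    Candidate boundaries are local minima of the binned, Gaussian-smoothed
    TIC; each of the ``n_regions - 1`` equal-width target positions snaps
    to the nearest candidate minimum, so cuts avoid splitting peaks while
    keeping regions of comparable width.
    """
    rts, tic = aug.tic()
    lo, hi = rts.min(), rts.max()
    edges = np.arange(lo, hi + bin_s, bin_s)
    idx = np.clip(np.digitize(rts, edges) - 1, 0, len(edges) - 2)
    binned = np.zeros(len(edges) - 1)
    np.add.at(binned, idx, tic)
    smooth = gaussian_filter1d(binned, smooth_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    interior = np.arange(1, len(smooth) - 1)
    is_min = (smooth[interior] <= smooth[interior - 1]) & (smooth[interior] <= smooth[interior + 1])
    cand = centers[interior[is_min]]
    targets = np.linspace(lo, hi, n_regions + 1)[1:-1]
    bounds = []
    for t in targets:
        if cand.size:
            b = float(cand[np.argmin(np.abs(cand - t))])
        else:
            b = float(t)
        if not bounds or b > bounds[-1]:
            bounds.append(b)
        else:
            bounds.append(float(t))  # degenerate snap; fall back to even split
    return bounds


def segment_regions(
    aug: AugmentedMatrix,
    strategy: str = "tic-valley",
    n_regions: int | None = None,
    boundaries: list | None = None,
) -> list:
    """Split the augmented matrix into chromatographic regions.

    Each region keeps all K blocks restricted to its RT window, and only
    the columns with nonzero signal inside the window (zero columns are
    restored as zero contributions on reassembly). Regions partition the
    RT range; every scan belongs to exactly one region.
    """
    lo, hi = aug.rt_window
    if strategy == "explicit":
        if not boundaries:
            raise ValueError("explicit strategy requires boundaries")
        bounds = sorted(float(b) for b in boundaries)
        if bounds[0] <= lo or bounds[-1] >= hi:
            raise ValueError("boundaries outside the RT range")
    elif strategy == "equal-width":
        if not n_regions or n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        bounds = list(np.linspace(lo, hi, n_regions + 1)[1:-1])
    elif strategy == "tic-valley":
        if not n_regions or n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        bounds = _tic_valley_boundaries(aug, n_regions) if n_regions > 1 else []
    else:
        raise ValueError(f"unknown strategy: {strategy!r}")
    edges = [lo - 1.0] + bounds + [hi + 1.0]

    regions = []
    for r in range(len(edges) - 1):
        a, b = edges[r], edges[r + 1]
        blocks, block_index, rt_axes = [], {}, {}
        row0 = 0
        for sid in aug.block_index:
            rts = aug.rt_axes[sid]
            mask = (rts >= a) & (rts < b)
            sub = aug.block(sid)[mask]
            blocks.append(sub)
            block_index[sid] = slice(row0, row0 + sub.shape[0])
            rt_axes[sid] = rts[mask]
            row0 += sub.shape[0]
        data = np.vstack(blocks)
        if data.shape[0] == 0:
            raise ValueError(f"region {r} is empty")
        nz = np.nonzero(data.any(axis=0))[0]
        regions.append(
            AugmentedMatrix(
                data[:, nz],
                block_index,
                aug.col_mz[nz],
                rt_axes,
                (max(a, lo), min(b, hi)),
                col_parent=nz,
            )
        )
    return regions


def reassemble(aug: AugmentedMatrix, regions: list) -> np.ndarray:
    """Sum region submatrices back onto the parent extent (invariant check)."""
    out = np.zeros_like(aug.data)
    for reg in regions:
        for sid in aug.block_index:
            rts = aug.rt_axes[sid]
            a, b = reg.rt_window
            # region row masks were built with half-open [a, b) windows on edges
            mask = (rts >= a) & ((rts < b) | (b == aug.rt_window[1]) & (rts <= b))
            rows = np.nonzero(mask)[0] + aug.block_index[sid].start
            out[np.ix_(rows, reg.col_parent)] += reg.block(sid)
    return out
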