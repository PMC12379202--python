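"""Histoimaging: voxel binning of localized events and TDD construction.

Three-photon events are binned directly into voxels by their TOF-localized
annihilation vertex — there is no tomographic reconstruction.  Each voxel
accumulates a time-difference distribution (TDD); the flat random-coincidence
background is fixed from the bins well before the prompt peak (centres below
-2.5 ns), and voxels whose background estimate is too noisy (relative error
of 20% or more) are excluded from lifetime images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .model import BACKGROUND_CUTOFF, BIN_WIDTH, HIST_RANGE

__all__ = [
    "VoxelGrid",
    "TDDHistogram",
    "bin_vertices",
    "build_tdd",
    "estimate_background",
    "with_background",
    "qc_filter",
    "QC_REL_ERR_MAX",
]

log = logging.getLogger(__name__)

#: QC acceptance threshold on the background relative error (strict "<")
QC_REL_ERR_MAX = 0.20


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel grid.

    Voxel ``(i, j, k)`` spans the half-open box
    ``[origin + idx * size, origin + (idx + 1) * size)``; a point exactly on a
    boundary belongs to the higher-index voxel.
    """

    origin: tuple
    voxel_size: tuple
    dims: tuple

    def __post_init__(self):
        origin = tuple(float(v) for v in self.origin)
        size = tuple(float(v) for v in self.voxel_size)
        dims = tuple(int(v) for v in self.dims)
        if len(origin) != 3 or len(size) != 3 or len(dims) != 3:
            raise ValueError("origin, voxel_size and dims must be 3-vectors")
        if any(s <= 0 for s in size) or any(d < 1 for d in dims):
            raise ValueError("degenerate grid")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "voxel_size", size)
        object.__setattr__(self, "dims", dims)

    @classmethod
    def from_box(cls, lo, hi, voxel_size) -> "VoxelGrid":
        """Grid of cubic-or-not voxels covering ``[lo, hi]``, centred on it."""
        lo = np.asarray(lo, float)
        hi = np.asarray(hi, float)
        size = np.broadcast_to(np.asarray(voxel_size, float), (3,))
        dims = np.maximum(np.ceil((hi - lo) / size - 1e-9), 1).astype(int)
        center = 0.5 * (lo + hi)
        origin = center - 0.5 * dims * size
        return cls(tuple(origin), tuple(size), tuple(dims))

    @property
    def shape(self):
        return self.dims

    def indices(self, points):
        """Voxel indices (floor rule) and an in-grid mask for ``points``."""
        p = np.atleast_2d(np.asarray(points, float))
        idx = np.floor((p - np.asarray(self.origin)) /
                       np.asarray(self.voxel_size)).astype(np.int64)
        inside = np.all((idx >= 0) & (idx < np.asarray(self.dims)), axis=1)
        return idx, inside

    def voxel_centers(self):
        axes = [
            self.origin[a] + self.voxel_size[a] * (np.arange(self.dims[a]) + 0.5)
            for a in range(3)
        ]
        return axes


@dataclass(frozen=True)
class TDDHistogram:
    """Binned time-difference distribution with its background estimate.

    ``background_b`` (counts per bin), ``background_rel_err`` and ``qc_pass``
    are ``None`` until :func:`estimate_background` has been applied.
    ``n_dropped`` counts values outside the histogram window.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    background_b: float | None = None
    background_rel_err: float | None = None
    qc_pass: bool | None = None
    n_dropped: int = 0

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, float)
        counts = np.asarray(self.counts)
        if len(counts) != len(edges) - 1:
            raise ValueError("len(counts) must equal len(bin_edges) - 1")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if self.background_b is not None and self.background_b < 0:
            raise ValueError("background must be non-negative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())


def build_tdd(deltas, bin_width: float = BIN_WIDTH, range=HIST_RANGE) -> TDDHistogram:
    """Bin time differences into a uniform half-open histogram.

    The number of bins is the largest integer count of full-width bins that
    fits in ``range``; values beyond the last full bin (or below the first)
    are dropped and reported in ``n_dropped`` so that event conservation can
    be checked exactly.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = float(range[0]), float(range[1])
    if lo >= hi:
        raise ValueError("empty range")
    n_bins = int(np.floor((hi - lo) / bin_width + 1e-9))
    if n_bins < 1:
        raise ValueError("range narrower than one bin")
    edges = lo + bin_width * np.arange(n_bins + 1)
    d = np.asarray(deltas, float).ravel()
    inside = (d >= edges[0]) & (d < edges[-1])
    counts, _ = np.histogram(d[inside], bins=edges)
    return TDDHistogram(edges, counts.astype(np.int64),
                        n_dropped=int(d.size - inside.sum()))


def estimate_background(hist: TDDHistogram, cutoff: float = BACKGROUND_CUTOFF):
    """Flat-background level from the pre-signal bins.

    ``b`` is the mean of the counts in bins whose centre lies below
    ``cutoff``; the relative error is the standard error of that mean divided
    by ``b``.  Returns ``(b, rel_err)``; ``b == 0`` gives an infinite relative
    error (the voxel then fails QC).
    """
    sel = hist.centers < cutoff
    n_bg = int(sel.sum())
    if n_bg < 2:
        raise ValueError("need at least 2 background bins below the cutoff")
    c = hist.counts[sel].astype(float)
    b = float(c.mean())
    if b == 0.0:
        return 0.0, float("inf")
    sem = float(c.std(ddof=1)) / np.sqrt(n_bg)
    return b, sem / b


def with_background(hist: TDDHistogram, cutoff: float = BACKGROUND_CUTOFF) -> TDDHistogram:
    """Return a copy of ``hist`` with background fields and QC flag set."""
    b, rel = estimate_background(hist, cutoff)
    return replace(hist, background_b=b, background_rel_err=rel,
                   qc_pass=bool(rel < QC_REL_ERR_MAX))


def bin_vertices(events, grid: VoxelGrid):
    """Assign events to voxels and collect per-voxel time differences.

    Parameters
    ----------
    events : pandas.DataFrame
        Three-photon event table with columns ``vx, vy, vz, delta_t_ns``.
    grid : VoxelGrid

    Returns
    -------
    (dict, int)
        Mapping ``(i, j, k) -> ndarray of delta_t`` for non-empty voxels, and
        the number of events falling outside the grid.
    """
    if len(events) == 0:
        return {}, 0
    pts = events[["vx", "vy", "vz"]].to_numpy(float)
    dt = events["delta_t_ns"].to_numpy(float)
    idx, inside = grid.indices(pts)
    n_dropped = int((~inside).sum())
    idx = idx[inside]
    dt = dt[inside]
    flat = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), grid.dims)
    order = np.argsort(flat, kind="stable")
    flat = flat[order]
    dt = dt[order]
    uniq, starts = np.unique(flat, return_index=True)
    out = {}
    bounds = np.append(starts, len(flat))
    for u, s, e in zip(uniq, bounds[:-1], bounds[1:]):
        out[tuple(int(v) for v in np.unravel_index(int(u), grid.dims))] = dt[s:e]
    if n_dropped:
        log.info("bin_vertices: dropped %d events outside the grid", n_dropped)
    return out, n_dropped


def qc_filter(hists: dict) -> dict:
    """Background-quality mask over a voxel -> TDDHistogram mapping.

    A voxel passes when its background relative error is strictly below 20%.
    Histograms without a background estimate are given one on the fly.
    """
    mask = {}
    for key, h in hists.items():
        if h.qc_pass is None:
            h = with_background(h)
        mask[key] = bool(h.qc_pass)
    n_pass = sum(mask.values())
    log.info("qc_filter: %d/%d voxels pass (rel_err < %.0f%%)",
             n_pass, len(mask), 100 * QC_REL_ERR_MAX)
    return mask
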