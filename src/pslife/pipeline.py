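"""End-to-end orchestration: simulate -> select -> histogram -> fit.

Simulation and selection run in time-interval chunks so that long
acquisitions never hold the full singles table in memory; singles within two
coincidence windows of a chunk boundary are carried into the next chunk, so
chunking is exact with respect to coincidence clustering.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .events import DEFAULT_COINCIDENCE_WIDTH, EnergyWindows, build_3g_events
from .histo import VoxelGrid, bin_vertices, build_tdd, with_background
from .phantom import ScannerSpec, emit_and_detect, inject_randoms, sample_decays

__all__ = ["simulate_singles", "select_events", "run_pipeline",
           "voxel_histograms"]

log = logging.getLogger(__name__)


def simulate_singles(phantom, scanner: ScannerSpec, duration_s: float,
                     seed=0) -> pd.DataFrame:
    """Single-shot simulation returning the full time-sorted singles table."""
    rng = np.random.default_rng(seed)
    decays = sample_decays(phantom, duration_s, rng=rng,
                           prompt_br=scanner.prompt_br_per_positron)
    singles = emit_and_detect(decays, scanner, rng=rng)
    singles = inject_randoms(singles, scanner, rng=rng, phantom=phantom)
    return singles.sort_values("t_ns", kind="stable", ignore_index=True)


def select_events(singles: pd.DataFrame,
                  windows: EnergyWindows | None = None,
                  coincidence_width: float = DEFAULT_COINCIDENCE_WIDTH
                  ) -> pd.DataFrame:
    return build_3g_events(singles, windows, coincidence_width)


def run_pipeline(phantom, scanner: ScannerSpec, duration_s: float, seed=0,
                 windows: EnergyWindows | None = None,
                 coincidence_width: float = DEFAULT_COINCIDENCE_WIDTH,
                 chunk_s: float | None = None) -> pd.DataFrame:
    """Simulate and select three-photon events, optionally chunked in time.

    Returns the concatenated event table.  With ``chunk_s`` set, each chunk
    is simulated and selected independently; trailing singles within
    ``2 * coincidence_width`` of a chunk's end are prepended to the next
    chunk so clusters crossing the boundary are preserved.
    """
    if chunk_s is None or chunk_s >= duration_s:
        singles = simulate_singles(phantom, scanner, duration_s, seed)
        return select_events(singles, windows, coincidence_width)

    ss = np.random.SeedSequence(seed)
    n_chunks = int(np.ceil(duration_s / chunk_s))
    child_seeds = ss.spawn(n_chunks)
    carried = None
    frames = []
    eid_offset = 0
    for i in range(n_chunks):
        t0 = i * chunk_s
        dur = min(chunk_s, duration_s - t0)
        rng = np.random.default_rng(child_seeds[i])
        decays = sample_decays(phantom, dur, rng=rng, t_offset_s=t0,
                               event_id_offset=eid_offset,
                               prompt_br=scanner.prompt_br_per_positron)
        eid_offset += len(decays)
        singles = emit_and_detect(decays, scanner, rng=rng)
        singles = inject_randoms(singles, scanner, rng=rng, phantom=phantom)
        singles = singles.sort_values("t_ns", kind="stable", ignore_index=True)
        if carried is not None and len(carried):
            singles = pd.concat([carried, singles], ignore_index=True)
            singles = singles.sort_values("t_ns", kind="stable",
                                          ignore_index=True)
        # hold back the trailing edge: its clusters may extend into the next chunk
        if i < n_chunks - 1 and len(singles):
            t_cut = singles["t_ns"].iloc[-1] - 2.0 * coincidence_width
            tail = singles["t_ns"] > t_cut
            carried = singles[tail].reset_index(drop=True)
            singles = singles[~tail].reset_index(drop=True)
        else:
            carried = None
        frames.append(select_events(singles, windows, coincidence_width))
        log.info("pipeline chunk %d/%d: %d events", i + 1, n_chunks,
                 len(frames[-1]))
    return pd.concat(frames, ignore_index=True)


def voxel_histograms(events: pd.DataFrame, grid: VoxelGrid,
                     bin_width: float | None = None,
                     hist_range=None) -> dict:
    """Per-voxel background-annotated TDDs from an event table."""
    from .model import BIN_WIDTH, HIST_RANGE

    bin_width = bin_width or BIN_WIDTH
    hist_range = hist_range or HIST_RANGE
    deltas, n_dropped = bin_vertices(events, grid)
    if n_dropped:
        log.info("voxel_histograms: %d events outside the grid", n_dropped)
    return {
        idx: with_background(build_tdd(d, bin_width, hist_range))
        for idx, d in deltas.items()
    }
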