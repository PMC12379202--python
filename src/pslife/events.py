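"""Three-photon event selection, TOF localization and time differences.

A three-photon event (3gE) is a time-coincident cluster of singles with
exactly two photons in the annihilation energy window [460, 545] keV and
exactly one in the prompt window [568, 639] keV (the 602.73 keV de-excitation
photon of I-124).  The annihilation vertex is placed on the line between the
two annihilation crystals from their time-of-flight difference; the event
time difference is the reconstructed annihilation time minus the
reconstructed prompt emission time, the quantity whose distribution carries
the positronium lifetime information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "C_MM_PER_NS",
    "EnergyWindows",
    "classify_energy",
    "classify_energies",
    "build_3g_events",
    "localize_tof",
    "time_difference",
    "DEFAULT_COINCIDENCE_WIDTH",
]

#: speed of light in mm/ns
C_MM_PER_NS = 299.792458

#: coincidence clustering window (ns); generous enough to cover the full
#: [-5, 8] ns TDD range plus flight-time spread inside the bore
DEFAULT_COINCIDENCE_WIDTH = 15.0


@dataclass(frozen=True)
class EnergyWindows:
    """Closed energy acceptance intervals in keV."""

    annihilation: tuple = (460.0, 545.0)
    prompt: tuple = (568.0, 639.0)

    def __post_init__(self):
        a, p = self.annihilation, self.prompt
        if not (a[0] < a[1] and p[0] < p[1]):
            raise ValueError("window bounds must be increasing")
        if max(a[0], p[0]) <= min(a[1], p[1]):
            raise ValueError("energy windows must not overlap")


def classify_energy(energy: float, windows: EnergyWindows | None = None) -> str:
    """Classify one deposited energy: 'annihilation', 'prompt' or 'reject'."""
    if energy <= 0:
        raise ValueError("energy must be positive")
    windows = windows or EnergyWindows()
    if windows.annihilation[0] <= energy <= windows.annihilation[1]:
        return "annihilation"
    if windows.prompt[0] <= energy <= windows.prompt[1]:
        return "prompt"
    return "reject"


def classify_energies(energies, windows: EnergyWindows | None = None):
    """Vectorized window membership; returns (is_annihilation, is_prompt)."""
    windows = windows or EnergyWindows()
    e = np.asarray(energies, float)
    is_ann = (e >= windows.annihilation[0]) & (e <= windows.annihilation[1])
    is_pr = (e >= windows.prompt[0]) & (e <= windows.prompt[1])
    return is_ann, is_pr


def _greedy_cluster_starts(t: np.ndarray, width: float) -> np.ndarray:
    """Start indices of greedy time clusters on a sorted time array.

    A cluster contains every record within ``width`` of its first record.
    Any gap larger than ``width`` is necessarily a cluster boundary, so the
    stream is first split at such gaps (vectorized) and the greedy rule is
    applied only inside the rare chained groups that span more than
    ``width``.
    """
    n = len(t)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    gap_starts = np.flatnonzero(np.diff(t) > width) + 1
    bounds = np.concatenate(([0], gap_starts, [n]))
    g0, g1 = bounds[:-1], bounds[1:]
    span_ok = t[g1 - 1] - t[g0] <= width
    pieces = [g0[span_ok]]
    for a, b in zip(g0[~span_ok], g1[~span_ok]):
        i = int(a)
        sub = []
        while i < b:
            sub.append(i)
            i = int(a + np.searchsorted(t[a:b], t[i] + width, side="right"))
        pieces.append(np.asarray(sub, dtype=np.int64))
    return np.sort(np.concatenate(pieces))


def localize_tof(pos_a, t_a, pos_b, t_b):
    """TOF vertex on the chord between two annihilation crystals.

    The photon arriving later travelled farther, so the vertex is displaced
    from the chord midpoint toward the earlier crystal:
    ``vertex = midpoint - (c/2) (t_b - t_a) u_ab`` with ``u_ab`` the unit
    vector from crystal A to crystal B.  The vertex is clamped to the chord.
    Accepts single positions (shape ``(3,)``) or batches (``(n, 3)``).
    """
    pa = np.atleast_2d(np.asarray(pos_a, float))
    pb = np.atleast_2d(np.asarray(pos_b, float))
    ta = np.atleast_1d(np.asarray(t_a, float))
    tb = np.atleast_1d(np.asarray(t_b, float))
    d = pb - pa
    L = np.linalg.norm(d, axis=1)
    if np.any(L == 0):
        raise ValueError("coincident crystals")
    u = d / L[:, None]
    shift = -0.5 * C_MM_PER_NS * (tb - ta)
    shift = np.clip(shift, -0.5 * L, 0.5 * L)
    v = 0.5 * (pa + pb) + shift[:, None] * u
    if np.ndim(pos_a) == 1:
        return v[0]
    return v


def time_difference(pos_a, t_a, pos_b, t_b, pos_p, t_p, vertex):
    """Annihilation-minus-prompt time difference, flight-time corrected.

    The annihilation time is the flight-corrected mean of the two
    annihilation detections; the prompt emission time is its detection time
    minus the flight from the (TOF-estimated) vertex, which doubles as the
    prompt emission point since the positron range is neglected.
    """
    pa = np.atleast_2d(np.asarray(pos_a, float))
    pb = np.atleast_2d(np.asarray(pos_b, float))
    pp = np.atleast_2d(np.asarray(pos_p, float))
    v = np.atleast_2d(np.asarray(vertex, float))
    ta = np.atleast_1d(np.asarray(t_a, float))
    tb = np.atleast_1d(np.asarray(t_b, float))
    tp = np.atleast_1d(np.asarray(t_p, float))
    d_a = np.linalg.norm(pa - v, axis=1)
    d_b = np.linalg.norm(pb - v, axis=1)
    d_p = np.linalg.norm(pp - v, axis=1)
    t_ann = 0.5 * ((ta - d_a / C_MM_PER_NS) + (tb - d_b / C_MM_PER_NS))
    t_prompt = tp - d_p / C_MM_PER_NS
    dt = t_ann - t_prompt
    if np.ndim(t_a) == 0:
        return float(dt[0])
    return dt


def build_3g_events(singles: pd.DataFrame,
                    windows: EnergyWindows | None = None,
                    coincidence_width: float = DEFAULT_COINCIDENCE_WIDTH) -> pd.DataFrame:
    """Select three-photon events from a time-sorted singles table.

    Clusters are formed greedily in time; a cluster is accepted iff it holds
    exactly two annihilation-window photons and exactly one prompt-window
    photon (out-of-window records in the cluster are ignored; clusters with
    extra in-window photons are discarded as ambiguous).  Every record is
    used at most once.

    Times are shifted to the cluster start before the vertex and
    time-difference arithmetic so that flight-time cancellation is exact to
    machine precision even for long acquisitions.

    Returns a DataFrame with columns ``vx, vy, vz, delta_t_ns, t_ns`` (cluster
    start time), ``is_random`` (any constituent tagged as injected random)
    and the provenance ids ``event_id_pair, event_id_prompt`` when the input
    carries ``event_id``.
    """
    if coincidence_width <= 0:
        raise ValueError("coincidence_width must be positive")
    windows = windows or EnergyWindows()
    t = singles["t_ns"].to_numpy(float)
    if np.any(np.diff(t) < 0):
        raise ValueError("singles must be sorted by time")
    E = singles["E_keV"].to_numpy(float)
    n = len(t)
    starts = _greedy_cluster_starts(t, coincidence_width)
    is_ann, is_pr = classify_energies(E, windows)
    n_ann = np.add.reduceat(is_ann.astype(np.int64), starts) if n else np.empty(0, int)
    n_pr = np.add.reduceat(is_pr.astype(np.int64), starts) if n else np.empty(0, int)
    ok = (n_ann == 2) & (n_pr == 1)
    if not ok.any():
        return pd.DataFrame(columns=["vx", "vy", "vz", "delta_t_ns", "t_ns",
                                     "is_random"])
    sizes = np.diff(np.append(starts, n))
    cluster_of = np.repeat(np.arange(len(starts)), sizes)
    rec_ok = ok[cluster_of]
    ai = np.flatnonzero(is_ann & rec_ok)  # exactly 2 per accepted cluster
    pi = np.flatnonzero(is_pr & rec_ok)   # exactly 1 per accepted cluster
    ia, ib = ai[0::2], ai[1::2]

    pos = singles[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
    t0 = t[starts[ok]]  # per-cluster reference time
    pa, pb, pp = pos[ia], pos[ib], pos[pi]
    ta, tb, tp = t[ia] - t0, t[ib] - t0, t[pi] - t0
    vtx = localize_tof(pa, ta, pb, tb)
    dt = time_difference(pa, ta, pb, tb, pp, tp, vtx)

    out = pd.DataFrame({
        "vx": vtx[:, 0], "vy": vtx[:, 1], "vz": vtx[:, 2],
        "delta_t_ns": dt, "t_ns": t0,
    })
    if "tag" in singles.columns:
        tag = np.asarray(singles["tag"])
        out["is_random"] = ((tag[ia] == "random") | (tag[ib] == "random")
                            | (tag[pi] == "random"))
    else:
        out["is_random"] = False
    if "event_id" in singles.columns:
        eid = singles["event_id"].to_numpy()
        # provenance: the pair id is defined only when both annihilation
        # photons stem from the same emission event (else -1, a mixed pair)
        out["event_id_pair"] = np.where(eid[ia] == eid[ib], eid[ia], -1)
        out["event_id_prompt"] = eid[pi]
    return out
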