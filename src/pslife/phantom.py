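"""Synthetic I-124 tube phantom and idealized cylindrical LAFOV scanner.

Generates singles list-mode data with the statistical structure the lifetime
analysis relies on:

* positron decays uniform inside cylindrical tubes, Poisson counts per tube
  set by the activity, acquisition time and the positron branch of I-124;
* a 602.73 keV prompt de-excitation photon accompanying 12.0% of positron
  decays (electron-capture branches carry no annihilation pair and are not
  generated);
* annihilation delays drawn from the three-component mixture
  (pPs 125 ps, direct 388 ps, oPs tau3 set by the tube material);
* back-to-back 511 keV photons from the decay position (positron range and
  acollinearity neglected), detected on an ideal cylindrical barrel with
  per-photon Gaussian timing smear and sqrt(E)-scaled Gaussian energy smear;
* optional injected random coincidences producing a flat time-difference
  background.

Detection geometry is barrel-only; photons that miss the cylinder are lost.
A fast path (:func:`sample_tdd_direct`) draws time differences straight from
the spectral model, bypassing transport, for fit-level studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .events import C_MM_PER_NS, EnergyWindows, classify_energies
from .model import TAU_DIRECT, TAU_PPS, LifetimeParams

__all__ = [
    "MaterialSpec",
    "TubeRegion",
    "ScannerSpec",
    "POSITRON_FRACTION_I124",
    "PROMPT_ENERGY_KEV",
    "ANNIHILATION_ENERGY_KEV",
    "sample_decays",
    "emit_and_detect",
    "inject_randoms",
    "sample_tdd_direct",
    "write_singles",
    "read_singles",
]

#: positron branching fraction of I-124 (beta+ decays per decay)
POSITRON_FRACTION_I124 = 0.228
#: prompt de-excitation photon energy of I-124 (keV)
PROMPT_ENERGY_KEV = 602.73
ANNIHILATION_ENERGY_KEV = 511.0
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

SINGLES_COLUMNS = ("x_mm", "y_mm", "z_mm", "t_ns", "E_keV", "tag", "event_id")
SINGLES_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class MaterialSpec:
    """oPs lifetime and branching fractions of a phantom material."""

    tau3: float
    br: tuple

    def __post_init__(self):
        br = np.asarray(self.br, float)
        if self.tau3 <= 0:
            raise ValueError("tau3 must be positive")
        if br.shape != (3,) or np.any(br < 0) or abs(br.sum() - 1.0) > 1e-12:
            raise ValueError("br must be a non-negative 3-vector summing to 1")
        object.__setattr__(self, "br", tuple(float(v) for v in br))


@dataclass(frozen=True)
class TubeRegion:
    """Homogeneous cylindrical activity region.

    ``activity_mbq`` is the total decay rate; positron decays occur at
    ``activity * POSITRON_FRACTION_I124``.
    """

    center: tuple
    radius: float
    half_length: float
    material: MaterialSpec
    activity_mbq: float = 1.0
    axis: tuple = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if self.radius <= 0 or self.half_length <= 0:
            raise ValueError("radius and half_length must be positive")
        if self.activity_mbq < 0:
            raise ValueError("activity must be non-negative")
        ax = np.asarray(self.axis, float)
        if not np.isclose(np.linalg.norm(ax), 1.0, atol=1e-9):
            raise ValueError("axis must be a unit vector")
        object.__setattr__(self, "center", tuple(float(v) for v in self.center))
        object.__setattr__(self, "axis", tuple(float(v) for v in ax))


@dataclass(frozen=True)
class ScannerSpec:
    """Idealized cylindrical (barrel-only) scanner.

    Defaults describe a commercial long-axial-FOV geometry; the per-photon
    timing smear of 95 ps gives a pair time-difference resolution of about
    134 ps, matching the 133 ps TDD bin width used downstream.
    """

    ring_radius: float = 410.0
    axial_half_length: float = 530.0
    timing_sigma: float = 0.095          # ns, per photon
    energy_fwhm_frac_511: float = 0.11   # fractional FWHM at 511 keV
    prompt_br_per_positron: float = 0.12
    randoms_rate_frac: float = 0.0       # fraction of accepted 3gE that are random

    def __post_init__(self):
        if min(self.ring_radius, self.axial_half_length) <= 0:
            raise ValueError("geometry must be positive")
        if self.timing_sigma < 0 or self.energy_fwhm_frac_511 <= 0:
            raise ValueError("invalid resolution parameters")
        if not 0.0 <= self.prompt_br_per_positron <= 1.0:
            raise ValueError("prompt_br_per_positron must be in [0, 1]")
        if not 0.0 <= self.randoms_rate_frac < 1.0:
            raise ValueError("randoms_rate_frac must be in [0, 1)")

    def energy_sigma(self, energy_kev):
        """Absolute energy smear SD, scaling as sqrt(E) from 511 keV."""
        e = np.asarray(energy_kev, float)
        frac = self.energy_fwhm_frac_511 * _FWHM_TO_SIGMA * np.sqrt(
            ANNIHILATION_ENERGY_KEV / e)
        return frac * e


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _tube_frame(tube: TubeRegion):
    """Orthonormal basis (e1, e2, axis) for a tube."""
    ax = np.asarray(tube.axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(ax[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(ax, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(ax, e1)
    return e1, e2, ax


def _tubes_overlap(a: TubeRegion, b: TubeRegion) -> bool:
    # exact test only for parallel z-aligned tubes; oblique tubes fall back
    # to a conservative bounding-sphere check
    za = np.allclose(a.axis, (0, 0, 1))
    zb = np.allclose(b.axis, (0, 0, 1))
    ca, cb = np.asarray(a.center), np.asarray(b.center)
    if za and zb:
        dxy = np.linalg.norm(ca[:2] - cb[:2])
        dz = abs(ca[2] - cb[2])
        return dxy < a.radius + b.radius and dz < a.half_length + b.half_length
    ra = np.hypot(a.radius, a.half_length)
    rb = np.hypot(b.radius, b.half_length)
    return float(np.linalg.norm(ca - cb)) < ra + rb


def sample_decays(phantom, duration_s: float, seed=None, *,
                  positron_fraction: float = POSITRON_FRACTION_I124,
                  prompt_br: float = 0.12, t_offset_s: float = 0.0,
                  event_id_offset: int = 0, rng=None) -> pd.DataFrame:
    """Sample positron decays (emission events) from a tube phantom.

    Per tube the number of positron decays is Poisson with mean
    ``activity * duration * positron_fraction``; positions are uniform inside
    the tube, decay times uniform over the acquisition window, the
    annihilation channel is drawn from the material branching fractions with
    an Exp(tau_channel) annihilation delay, and the prompt photon flag is
    Bernoulli(``prompt_br``).

    Returns a DataFrame with columns
    ``x, y, z (mm), t_ns, channel (0 pPs, 1 direct, 2 oPs), delay_ns,
    has_prompt, tube, event_id``.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    phantom = list(phantom)
    for i in range(len(phantom)):
        for j in range(i + 1, len(phantom)):
            if _tubes_overlap(phantom[i], phantom[j]):
                raise ValueError(f"tubes {i} and {j} overlap")
    rng = rng if rng is not None else _as_rng(seed)
    frames = []
    eid0 = int(event_id_offset)
    for k, tube in enumerate(phantom):
        mean = tube.activity_mbq * 1e6 * duration_s * positron_fraction
        n = int(rng.poisson(mean))
        if n == 0:
            continue
        e1, e2, ax = _tube_frame(tube)
        r = tube.radius * np.sqrt(rng.random(n))
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        h = rng.uniform(-tube.half_length, tube.half_length, n)
        pos = (np.asarray(tube.center)
               + np.outer(r * np.cos(phi), e1)
               + np.outer(r * np.sin(phi), e2)
               + np.outer(h, ax))
        taus = np.array([TAU_PPS, TAU_DIRECT, tube.material.tau3])
        channel = rng.choice(3, size=n, p=np.asarray(tube.material.br))
        delay = rng.exponential(taus[channel])
        t_ns = (t_offset_s + rng.uniform(0.0, duration_s, n)) * 1e9
        frames.append(pd.DataFrame({
            "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
            "t_ns": t_ns, "channel": channel.astype(np.int8),
            "delay_ns": delay,
            "has_prompt": rng.random(n) < prompt_br,
            "tube": np.full(n, k, dtype=np.int16),
            "event_id": np.arange(eid0, eid0 + n, dtype=np.int64),
        }))
        eid0 += n
    if not frames:
        return pd.DataFrame(columns=["x", "y", "z", "t_ns", "channel",
                                     "delay_ns", "has_prompt", "tube",
                                     "event_id"])
    return pd.concat(frames, ignore_index=True)


def _isotropic_directions(n: int, rng) -> np.ndarray:
    cos_t = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(1.0 - cos_t ** 2)
    return np.column_stack((sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t))


def _cylinder_hits(origin, direction, scanner: ScannerSpec):
    """Forward intersection with the detector barrel.

    Returns (hit mask, crystal positions, path lengths); origins must be
    inside the bore.
    """
    p = np.atleast_2d(origin)
    d = np.atleast_2d(direction)
    a = d[:, 0] ** 2 + d[:, 1] ** 2
    b = 2.0 * (p[:, 0] * d[:, 0] + p[:, 1] * d[:, 1])
    c = p[:, 0] ** 2 + p[:, 1] ** 2 - scanner.ring_radius ** 2
    ok = a > 1e-12
    s = np.full(len(p), np.nan)
    disc = np.where(ok, b * b - 4.0 * a * c, 1.0)
    root = np.sqrt(np.maximum(disc, 0.0))
    s[ok] = ((-b + root) / (2.0 * a))[ok]
    hit = ok & (s > 0)
    z_hit = p[:, 2] + s * d[:, 2]
    hit &= np.abs(z_hit) <= scanner.axial_half_length
    crystals = p + s[:, None] * d
    return hit, crystals, s


def emit_and_detect(decays: pd.DataFrame, scanner: ScannerSpec,
                    seed=None, *, rng=None) -> pd.DataFrame:
    """Emit annihilation and prompt photons and detect them on the barrel.

    Two 511 keV photons leave the decay position back-to-back in an isotropic
    direction at ``t + delay``; the prompt photon (602.73 keV) leaves the same
    position at the decay time when ``has_prompt`` is set.  Detection applies
    the flight time, the Gaussian per-photon timing smear and the Gaussian
    energy smear; photons missing the barrel are dropped.

    Returns a singles DataFrame (unsorted) with columns
    ``x_mm, y_mm, z_mm, t_ns, E_keV, tag, event_id``.
    """
    rng = rng if rng is not None else _as_rng(seed)
    if len(decays) == 0:
        return pd.DataFrame(columns=list(SINGLES_COLUMNS))
    pos = decays[["x", "y", "z"]].to_numpy(float)
    if np.any(np.hypot(pos[:, 0], pos[:, 1]) >= scanner.ring_radius) or \
       np.any(np.abs(pos[:, 2]) >= scanner.axial_half_length):
        raise ValueError("decay positions must lie inside the scanner bore")
    n = len(decays)
    t_ann = decays["t_ns"].to_numpy(float) + decays["delay_ns"].to_numpy(float)
    d = _isotropic_directions(n, rng)

    parts = []
    for direction in (d, -d):
        hit, crystals, s = _cylinder_hits(pos, direction, scanner)
        parts.append(_detected_frame(
            crystals[hit], t_ann[hit] + s[hit] / C_MM_PER_NS,
            ANNIHILATION_ENERGY_KEV, "annih",
            decays["event_id"].to_numpy()[hit], scanner, rng))

    has_p = decays["has_prompt"].to_numpy(bool)
    if has_p.any():
        dp = _isotropic_directions(int(has_p.sum()), rng)
        hit, crystals, s = _cylinder_hits(pos[has_p], dp, scanner)
        t_emit = decays["t_ns"].to_numpy(float)[has_p]
        parts.append(_detected_frame(
            crystals[hit], t_emit[hit] + s[hit] / C_MM_PER_NS,
            PROMPT_ENERGY_KEV, "prompt",
            decays["event_id"].to_numpy()[has_p][hit], scanner, rng))
    return pd.concat(parts, ignore_index=True)


def _detected_frame(crystals, t_arrive, energy, tag, event_id,
                    scanner: ScannerSpec, rng) -> pd.DataFrame:
    n = len(crystals)
    t = t_arrive + rng.normal(0.0, scanner.timing_sigma, n) \
        if scanner.timing_sigma > 0 else t_arrive
    e = energy + rng.normal(0.0, 1.0, n) * scanner.energy_sigma(energy)
    return pd.DataFrame({
        "x_mm": crystals[:, 0], "y_mm": crystals[:, 1], "z_mm": crystals[:, 2],
        "t_ns": t, "E_keV": np.maximum(e, 1e-6),
        "tag": tag, "event_id": np.asarray(event_id, np.int64),
    })


def _count_signal_triplets(singles: pd.DataFrame,
                           windows: EnergyWindows) -> int:
    """Events whose detected photons form a clean (2 annih + 1 prompt) triplet."""
    if len(singles) == 0:
        return 0
    is_ann, is_pr = classify_energies(singles["E_keV"].to_numpy(), windows)
    tag = np.asarray(singles["tag"])
    real = tag != "random"
    eid = singles["event_id"].to_numpy()
    eid_c = eid - eid.min()
    size = int(eid_c.max()) + 1
    n_ann = np.bincount(eid_c[is_ann & real], minlength=size)
    n_pr = np.bincount(eid_c[is_pr & real], minlength=size)
    return int(np.sum((n_ann == 2) & (n_pr == 1)))


# time-offset range (ns) for injected random prompts; chosen so the flat
# time-difference background comfortably covers the [-5, 8] ns histogram
# while the whole triplet still fits inside the coincidence window
_RANDOM_OFFSET_RANGE = (-6.0, 12.5)


def _sample_tube_positions(phantom, n: int, rng) -> np.ndarray:
    """Positions uniform within tubes, tubes weighted by activity."""
    acts = np.array([t.activity_mbq * t.radius ** 2 * t.half_length
                     for t in phantom], float)
    which = rng.choice(len(phantom), size=n, p=acts / acts.sum())
    out = np.empty((n, 3))
    for k, tube in enumerate(phantom):
        m = int((which == k).sum())
        if m == 0:
            continue
        e1, e2, ax = _tube_frame(tube)
        r = tube.radius * np.sqrt(rng.random(m))
        phi = rng.uniform(0.0, 2.0 * np.pi, m)
        h = rng.uniform(-tube.half_length, tube.half_length, m)
        out[which == k] = (np.asarray(tube.center)
                           + np.outer(r * np.cos(phi), e1)
                           + np.outer(r * np.sin(phi), e2)
                           + np.outer(h, ax))
    return out


def inject_randoms(singles: pd.DataFrame, scanner: ScannerSpec,
                   seed=None, *, windows: EnergyWindows | None = None,
                   phantom=None, rng=None) -> pd.DataFrame:
    """Add uncorrelated triple coincidences producing a flat background.

    A random 3gE pairs an annihilation-photon pair with a prompt photon from
    an unrelated decay: the injected pair is emitted consistently from a
    random vertex while the prompt emission time is offset uniformly, which
    makes the reconstructed time difference uniform.  Vertices follow the
    activity distribution when ``phantom`` is given (randoms pile up where
    the activity is, as in a measurement), else they are uniform in the
    central bore.  The number of injected triplets is Poisson-matched so
    that the expected fraction of accepted 3gE tagged ``random`` equals
    ``scanner.randoms_rate_frac``.  Injected energies are drawn inside the
    acceptance windows.  The returned table is time-sorted.
    """
    rng = rng if rng is not None else _as_rng(seed)
    windows = windows or EnergyWindows()
    frac = scanner.randoms_rate_frac
    out = singles
    if frac > 0 and len(singles):
        n_sig = _count_signal_triplets(singles, windows)
        n_inj = int(rng.poisson(frac / (1.0 - frac) * n_sig))
        if n_inj > 0:
            out = pd.concat(
                [singles,
                 _random_triplets(n_inj, singles, scanner, windows, rng,
                                  phantom)],
                ignore_index=True)
    return out.sort_values("t_ns", kind="stable", ignore_index=True)


def _random_triplets(n: int, singles: pd.DataFrame, scanner: ScannerSpec,
                     windows: EnergyWindows, rng, phantom=None) -> pd.DataFrame:
    if phantom is not None:
        vtx = _sample_tube_positions(phantom, n, rng)
    else:
        # vertices well inside the bore so every photon can reach the barrel
        r = 0.4 * scanner.ring_radius * np.sqrt(rng.random(n))
        phi = rng.uniform(0, 2 * np.pi, n)
        z = rng.uniform(-0.4, 0.4, n) * scanner.axial_half_length
        vtx = np.column_stack((r * np.cos(phi), r * np.sin(phi), z))
    t0 = rng.uniform(singles["t_ns"].min(), singles["t_ns"].max(), n)

    def _detect(origin, t_emit, window, tag, redraw_dir):
        m = len(origin)
        crystals = np.empty((m, 3))
        t_arr = np.empty(m)
        todo = np.arange(m)
        dirs = redraw_dir(m)
        while len(todo):
            hit, cr, s = _cylinder_hits(origin[todo], dirs, scanner)
            done = todo[hit]
            crystals[done] = cr[hit]
            t_arr[done] = t_emit[done] + s[hit] / C_MM_PER_NS
            todo = todo[~hit]
            dirs = redraw_dir(len(todo))
        lo, hi = window
        mean = 0.5 * (lo + hi)
        sd = scanner.energy_sigma(mean)
        a, b = (lo - mean) / sd, (hi - mean) / sd
        e = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=m,
                                random_state=rng)
        t = t_arr + (rng.normal(0.0, scanner.timing_sigma, m)
                     if scanner.timing_sigma > 0 else 0.0)
        return pd.DataFrame({
            "x_mm": crystals[:, 0], "y_mm": crystals[:, 1],
            "z_mm": crystals[:, 2], "t_ns": t, "E_keV": e,
            "tag": tag, "event_id": np.full(m, -1, dtype=np.int64),
        })

    # back-to-back pair with consistent flight times -> TOF vertex = vtx;
    # joint rejection: resample the shared direction until both photons hit
    d = _isotropic_directions(n, rng)
    crystals_a = np.empty((n, 3)); crystals_b = np.empty((n, 3))
    s_a = np.empty(n); s_b = np.empty(n)
    todo = np.arange(n)
    dirs = d
    while len(todo):
        hit_a, cr_a, sa = _cylinder_hits(vtx[todo], dirs, scanner)
        hit_b, cr_b, sb = _cylinder_hits(vtx[todo], -dirs, scanner)
        hit = hit_a & hit_b
        done = todo[hit]
        crystals_a[done], crystals_b[done] = cr_a[hit], cr_b[hit]
        s_a[done], s_b[done] = sa[hit], sb[hit]
        todo = todo[~hit]
        dirs = _isotropic_directions(len(todo), rng)

    frames = []
    for crystals, s in ((crystals_a, s_a), (crystals_b, s_b)):
        lo, hi = windows.annihilation
        mean = 0.5 * (lo + hi)
        sd = scanner.energy_sigma(mean)
        e = stats.truncnorm.rvs((lo - mean) / sd, (hi - mean) / sd,
                                loc=mean, scale=sd, size=n, random_state=rng)
        t = t0 + s / C_MM_PER_NS
        if scanner.timing_sigma > 0:
            t = t + rng.normal(0.0, scanner.timing_sigma, n)
        frames.append(pd.DataFrame({
            "x_mm": crystals[:, 0], "y_mm": crystals[:, 1],
            "z_mm": crystals[:, 2], "t_ns": t, "E_keV": e,
            "tag": "random", "event_id": np.full(n, -1, dtype=np.int64),
        }))

    # uncorrelated prompt: emitted from the same point but offset in time, so
    # the reconstructed annihilation-minus-prompt difference is exactly the
    # (uniform) offset plus timing noise
    offset = rng.uniform(*_RANDOM_OFFSET_RANGE, n)
    frames.append(_detect(vtx, t0 - offset, windows.prompt, "random",
                          lambda m: _isotropic_directions(m, rng)))
    return pd.concat(frames, ignore_index=True)


def sample_tdd_direct(params: LifetimeParams, n_signal: int, n_background: int,
                      window=(-5.0, 8.0), seed=None, *, rng=None) -> np.ndarray:
    """Draw time differences straight from the spectral model (fast path).

    Signal values are Exp(tau_k) delays (k drawn from the branching
    fractions) plus Normal(delta, sigma) resolution noise; background values
    are uniform on ``window``.  The returned array is shuffled.
    """
    if n_signal < 0 or n_background < 0:
        raise ValueError("counts must be non-negative")
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must be increasing")
    rng = rng if rng is not None else _as_rng(seed)
    taus = np.array([params.tau1, params.tau2, params.tau3])
    k = rng.choice(3, size=n_signal, p=np.asarray(params.br))
    sig = rng.exponential(taus[k]) + rng.normal(params.delta, params.sigma,
                                                n_signal)
    bg = rng.uniform(lo, hi, n_background)
    out = np.concatenate((sig, bg))
    rng.shuffle(out)
    return out


def write_singles(singles: pd.DataFrame, path) -> None:
    """Write a singles table to HDF5 (``.h5``) or CSV by extension."""
    path = str(path)
    df = singles[list(SINGLES_COLUMNS)]
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["schema_version"] = SINGLES_SCHEMA_VERSION
            for col in SINGLES_COLUMNS:
                if col == "tag":
                    codes = pd.Categorical(
                        df["tag"], categories=["annih", "prompt", "random"])
                    f.create_dataset("tag", data=codes.codes.astype(np.int8))
                    f["tag"].attrs["legend"] = "0=annih,1=prompt,2=random"
                else:
                    f.create_dataset(col, data=df[col].to_numpy())
    else:
        df.to_csv(path, index=False)


def read_singles(path) -> pd.DataFrame:
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as f:
            data = {}
            for col in SINGLES_COLUMNS:
                if col == "tag":
                    legend = np.array(["annih", "prompt", "random"])
                    data["tag"] = legend[f["tag"][...]]
                else:
                    data[col] = f[col][...]
        return pd.DataFrame(data)
    return pd.read_csv(path)
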