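"""Seeded generators of membrane scenes and downstream raw data.

Every estimator in this package is validated closed-loop: a scene of
pentamers diffusing in a 2D membrane plane is simulated with known ground
truth, rendered through the acquisition geometry of the instrument being
emulated (raster-scanning confocal or TIRF camera), and the analysis is
required to recover the truth. This module provides those generators:

* :func:`simulate_trajectories` — 2D Brownian motion on a periodic box,
  with optional bright, slowly diffusing clusters and dual-color label
  bookkeeping (co-diffusing fraction, per-subunit fluorophore maturation).
* :func:`render_confocal_series` — raster-scanned image formation: pixels
  are visited in row-major order and particle positions advance while the
  beam scans (line granularity by default, per-pixel in high-accuracy
  mode), so the scan timing is encoded in the spatial correlations exactly
  as in a real confocal series. Photon shot noise is Poisson.
* :func:`render_camera_series` — widefield/TIRF snapshots: integrated 2D
  Gaussian PSFs sampled mid-exposure per channel, alternating two-color
  excitation within each frame, Poisson plus Gaussian read noise.
* :func:`simulate_bleach_traces` — stepwise-photobleaching spot traces
  that are the generative twin of the binomial step-count model.
* :func:`simulate_channel_trace` — two-state Markov gating current traces
  for single-channel amplitude analysis.

All generators are deterministic given (parameters, seed). Trajectories
are replayed lazily from their seed so that a raster rendering over tens
of thousands of scan lines never has to materialize the full fine-grained
position history in memory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from numba import njit

from .core_io import AcquisitionGeometry, CurrentTrace, ImageSeries, IntensityTrace

__all__ = [
    "ClusterSpec",
    "SceneParams",
    "BleachSimParams",
    "ChannelSimParams",
    "TrajectorySet",
    "simulate_trajectories",
    "render_confocal_series",
    "render_camera_series",
    "simulate_bleach_traces",
    "simulate_channel_trace",
    "binomial_step_pmf",
    "heteromer_step_pmf",
]


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterSpec:
    """High-brightness cluster population added on top of single pentamers."""

    count: int = 0
    brightness_multiple: float = 30.0   # × single-pentamer brightness
    diffusion: float = 0.01             # µm²/s
    radius: float = 0.2                 # Gaussian radial SD of the blob, µm


@dataclass(frozen=True)
class SceneParams:
    """Ground-truth membrane scene description.

    Defaults emulate the intermediate-expression confocal regime (a few
    tens of receptors per µm², ~50 kHz per-complex brightness, ~1 kHz
    background). Dual-color fields only matter for camera rendering with
    two channels.
    """

    box_size: tuple[float, float] = (25.6, 25.6)   # µm, periodic
    density: float = 50.0                          # particles / µm²
    diffusion: float = 0.1                         # D_true, µm²/s
    brightness: float = 50.0                       # ε_true, kHz at beam center
    background: float = 1.0                        # kHz per pixel
    clusters: ClusterSpec = field(default_factory=ClusterSpec)
    codiffusing_fraction: float = 0.0              # q, dual color
    maturation_prob: float = 1.0                   # p_m_true, per channel label
    channel_overlap: float = 1.0                   # red-channel waist ratio
    registration_offset: tuple[float, float] = (0.0, 0.0)  # px (row, col)
    read_noise_sd: float = 0.0                     # camera counts, Gaussian

    def __post_init__(self) -> None:
        if not self.density > 0:
            raise ValueError("density must be positive")
        if self.diffusion < 0:
            raise ValueError("diffusion constant cannot be negative")
        if not 0.0 <= self.codiffusing_fraction <= 1.0:
            raise ValueError("codiffusing_fraction must be in [0, 1]")
        if not 0.0 < self.maturation_prob <= 1.0:
            raise ValueError("maturation_prob must be in (0, 1]")
        if any(s <= 0 for s in self.box_size):
            raise ValueError("box dimensions must be positive")


@dataclass(frozen=True)
class BleachSimParams:
    """Generative parameters for stepwise-photobleaching spot traces."""

    order: int = 5                     # pentamer order n
    maturation_prob: float = 0.47      # p_m_true
    nonoverlap_fraction: float = 0.88  # A_true: spots holding one complex
    homomer_fraction: float = 1.0      # H_true; 1-H are heteromers
    heteromer_order: int = 3           # het_true, labeled subunits per heteromer
    unit_intensity: float = 1.0        # per surviving fluorophore
    noise_sd: float = 0.1
    mean_bleach_frames: float = 60.0   # geometric mean lifetime, frames
    trace_length: int = 600            # frames

    def __post_init__(self) -> None:
        if not 1 <= self.heteromer_order <= self.order:
            raise ValueError("heteromer order must satisfy 1 <= het <= n")
        for name in ("maturation_prob", "nonoverlap_fraction", "homomer_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class ChannelSimParams:
    """Two-state single-channel gating model."""

    baseline: float = 0.0        # pA
    amplitude: float = 4.0       # open-channel current, pA
    open_rate: float = 10.0      # s⁻¹, closed→open
    close_rate: float = 20.0     # s⁻¹, open→closed
    noise_sd: float = 0.3        # pA
    sampling_rate: float = 5000.0  # Hz

    def __post_init__(self) -> None:
        if self.open_rate <= 0 or self.close_rate <= 0:
            raise ValueError("dwell rates must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def open_probability(self) -> float:
        return self.open_rate / (self.open_rate + self.close_rate)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


@dataclass
class TrajectorySet:
    """Brownian trajectory ensemble, replayable from its seed.

    Positions are generated lazily: :meth:`iter_positions` yields the
    (n_particles, 2) position array at t = 0, dt, 2·dt, …, always producing
    the same draws for the same seed. :meth:`positions` materializes the
    full (n_steps+1, n, 2) history for small problems (oracle tests).
    Coordinates are unwrapped; apply ``% box`` for in-box positions.
    """

    params: SceneParams
    duration: float
    time_step: float
    seed: int
    x0: np.ndarray            # (n, 2) µm, in-box
    diffusion: np.ndarray     # (n,) per-particle D
    brightness: np.ndarray    # (n,) kHz at center (clusters already scaled)
    extra_sigma: np.ndarray   # (n,) µm, 0 for point particles
    is_cluster: np.ndarray    # (n,) bool
    label_green: np.ndarray   # (n,) bool — matured green fluorophore
    label_red: np.ndarray     # (n,) bool
    codiffusing: np.ndarray   # (n,) bool — carries both color species
    n_steps: int

    @property
    def n_particles(self) -> int:
        return self.x0.shape[0]

    def iter_positions(self) -> Iterator[np.ndarray]:
        rng = np.random.default_rng(self.seed + 1)
        pos = self.x0.astype(np.float64).copy()
        sd = np.sqrt(2.0 * self.diffusion * self.time_step)[:, None]
        yield pos.copy()
        for _ in range(self.n_steps):
            pos += rng.standard_normal(pos.shape) * sd
            yield pos.copy()

    def positions(self) -> np.ndarray:
        out = np.empty((self.n_steps + 1, self.n_particles, 2))
        for i, p in enumerate(self.iter_positions()):
            out[i] = p
        return out


def simulate_trajectories(params: SceneParams, duration: float,
                          time_step: float, seed: int) -> TrajectorySet:
    """Simulate 2D Brownian trajectories on a periodic box.

    Each axis increment per step is drawn independently with SD
    √(2·D·Δt); clusters move with their own diffusion constant. Dual-color
    species identity and per-channel fluorophore maturation are drawn here
    so downstream oracles can read the ground truth off the trajectory set.
    """
    if not time_step > 0:
        raise ValueError("time_step must be positive")
    if not duration > 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    bx, by = params.box_size
    area = bx * by
    n = rng.poisson(params.density * area)
    n = max(int(n), 1)
    ncl = params.clusters.count

    x0 = np.empty((n + ncl, 2))
    x0[:, 0] = rng.uniform(0, bx, n + ncl)
    x0[:, 1] = rng.uniform(0, by, n + ncl)
    diffusion = np.full(n + ncl, params.diffusion)
    brightness = np.full(n + ncl, params.brightness)
    extra_sigma = np.zeros(n + ncl)
    is_cluster = np.zeros(n + ncl, dtype=bool)
    if ncl:
        diffusion[n:] = params.clusters.diffusion
        brightness[n:] = params.brightness * params.clusters.brightness_multiple
        extra_sigma[n:] = params.clusters.radius
        is_cluster[n:] = True

    # Dual-color species: a fraction q carries both colors, the remainder
    # splits evenly into green-only and red-only. Each carried fluorophore
    # matures independently with probability p_m.
    q = params.codiffusing_fraction
    u = rng.uniform(size=n + ncl)
    codiff = u < q
    green_only = (~codiff) & (u < q + (1 - q) / 2)
    red_only = ~codiff & ~green_only
    pm = params.maturation_prob
    label_green = (codiff | green_only) & (rng.uniform(size=n + ncl) < pm)
    label_red = (codiff | red_only) & (rng.uniform(size=n + ncl) < pm)
    # Clusters are bright aggregates visible in both channels.
    label_green[is_cluster] = True
    label_red[is_cluster] = True

    n_steps = int(math.ceil(duration / time_step))
    return TrajectorySet(
        params=params, duration=duration, time_step=time_step, seed=seed,
        x0=x0, diffusion=diffusion, brightness=brightness,
        extra_sigma=extra_sigma, is_cluster=is_cluster,
        label_green=label_green, label_red=label_red, codiffusing=codiff,
        n_steps=n_steps)


# ---------------------------------------------------------------------------
# Numba rendering kernels
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _render_raster_block(pos, amp, effw2, oy, ox, dr, nx, row0, out):
    """Accumulate beam-profile photon rates for a block of scan lines.

    pos: (L, n, 2) particle positions (µm, in-box) at each line's time.
    out: (L, nx) photon rate (kHz) added in place. Row of line ``l`` in
    the image is ``row0 + l``; pixel centers at ox + (j+0.5)·dr.
    """
    L, n = pos.shape[0], pos.shape[1]
    for l in range(L):
        y_line = oy + (row0 + l + 0.5) * dr
        for p in range(n):
            w2 = effw2[p]
            rc2 = 8.0 * w2          # 4σ cutoff: (4·w/2)² = 4w² → use 8w² margin
            dy = pos[l, p, 1] - y_line
            dy2 = dy * dy
            if dy2 > rc2:
                continue
            rc = math.sqrt(rc2)
            xc = pos[l, p, 0]
            j0 = int(math.floor((xc - rc - ox) / dr - 0.5))
            j1 = int(math.ceil((xc + rc - ox) / dr - 0.5))
            if j1 < 0 or j0 >= nx:
                continue
            if j0 < 0:
                j0 = 0
            if j1 > nx - 1:
                j1 = nx - 1
            a = amp[p]
            inv = 2.0 / w2
            for j in range(j0, j1 + 1):
                dx = ox + (j + 0.5) * dr - xc
                out[l, j] += a * math.exp(-(dx * dx + dy2) * inv)


@njit(cache=True, fastmath=True)
def _render_camera_frame(pos, flux, sig, oy, ox, dr, ny, nx, out):
    """Splat integrated Gaussian PSFs onto one camera frame.

    flux: expected photons per particle for this exposure; sig: per-particle
    Gaussian SD (µm). Pixel (i, j) spans [o + k·dr, o + (k+1)·dr).
    """
    n = pos.shape[0]
    inv_sqrt2 = 1.0 / math.sqrt(2.0)
    for p in range(n):
        s = sig[p]
        rc = 4.0 * s
        xc, yc = pos[p, 0], pos[p, 1]
        j0 = max(0, int(math.floor((xc - rc - ox) / dr)))
        j1 = min(nx - 1, int(math.ceil((xc + rc - ox) / dr)))
        i0 = max(0, int(math.floor((yc - rc - oy) / dr)))
        i1 = min(ny - 1, int(math.ceil((yc + rc - oy) / dr)))
        if j1 < j0 or i1 < i0:
            continue
        f = flux[p]
        for i in range(i0, i1 + 1):
            ylo = (oy + i * dr - yc) / s * inv_sqrt2
            yhi = (oy + (i + 1) * dr - yc) / s * inv_sqrt2
            gy = 0.5 * (math.erf(yhi) - math.erf(ylo))
            for j in range(j0, j1 + 1):
                xlo = (ox + j * dr - xc) / s * inv_sqrt2
                xhi = (ox + (j + 1) * dr - xc) / s * inv_sqrt2
                gx = 0.5 * (math.erf(xhi) - math.erf(xlo))
                out[i, j] += f * gx * gy


# ---------------------------------------------------------------------------
# Confocal raster rendering
# ---------------------------------------------------------------------------


def render_confocal_series(traj: TrajectorySet, geometry: AcquisitionGeometry,
                           params: SceneParams, n_frames: int, seed: int,
                           pixel_accurate: bool = False,
                           frame_shape: tuple[int, int] = (256, 256)
                           ) -> ImageSeries:
    """Render a raster-scanned confocal series from a trajectory set.

    Pixels are visited in row-major order. Each pixel's expected count is
    τ_p × [background + Σ_particles ε·exp(−2 r²/ω_r²)] with particle
    positions advanced to that pixel's acquisition time — at line
    granularity by default (the trajectory time step must then equal the
    line time), or per pixel when ``pixel_accurate`` (trajectory time step
    = pixel dwell). The realized count is Poisson. Intensities are
    returned as counts; divide by τ_p to convert to kHz.
    """
    if geometry.modality != "raster":
        raise ValueError("confocal rendering needs a raster geometry")
    ny, nx = frame_shape
    tau_p, tau_l, dr = geometry.pixel_dwell, geometry.line_time, geometry.pixel_size
    step = tau_p if pixel_accurate else tau_l
    if traj.time_step > tau_l * (1 + 1e-9):
        raise ValueError("trajectory time_step must not exceed the line time")
    if not math.isclose(traj.time_step, step, rel_tol=1e-6):
        raise ValueError(
            f"trajectory time_step {traj.time_step} does not match the "
            f"rendering granularity {step}")
    needed = n_frames * ny * (nx if pixel_accurate else 1)
    if traj.n_steps + 1 < needed:
        raise ValueError("trajectory too short for the requested frames")

    bx, by = params.box_size
    fov_y, fov_x = ny * dr, nx * dr
    oy, ox = (by - fov_y) / 2.0, (bx - fov_x) / 2.0
    wr2 = geometry.focal_waist ** 2
    effw2 = (wr2 + 4.0 * traj.extra_sigma ** 2).astype(np.float64)
    amp = traj.brightness.astype(np.float64)

    rng = np.random.default_rng(seed + 17)
    rate = np.zeros((n_frames, ny, nx))
    it = traj.iter_positions()

    if pixel_accurate:
        # One position snapshot per pixel: render pixel-by-pixel (small
        # scenes only; backs the line-granularity approximation in tests).
        for f in range(n_frames):
            for i in range(ny):
                block = np.empty((nx, traj.n_particles, 2), dtype=np.float64)
                for j in range(nx):
                    block[j] = next(it)
                block[:, :, 0] %= bx
                block[:, :, 1] %= by
                # reuse the line kernel one pixel at a time
                for j in range(nx):
                    buf = np.zeros((1, nx))
                    _render_raster_block(block[j:j + 1], amp, effw2, oy, ox,
                                         dr, nx, i, buf)
                    rate[f, i, j] = buf[0, j]
    else:
        for f in range(n_frames):
            block = np.empty((ny, traj.n_particles, 2), dtype=np.float64)
            for i in range(ny):
                block[i] = next(it)
            block[:, :, 0] %= bx
            block[:, :, 1] %= by
            out = np.zeros((ny, nx))
            _render_raster_block(block, amp, effw2, oy, ox, dr, nx, 0, out)
            rate[f] = out

    # rates are in kHz: 1 kHz × τ_p[s] × 1e3 = expected counts per pixel
    expected = (rate + params.background) * 1e3 * tau_p
    counts = rng.poisson(expected).astype(np.float64)
    return ImageSeries(data=[counts], geometry=geometry,
                       channel_names=["confocal"])


# ---------------------------------------------------------------------------
# Camera rendering
# ---------------------------------------------------------------------------


def render_camera_series(traj: TrajectorySet, geometry: AcquisitionGeometry,
                         params: SceneParams, n_frames: int, seed: int,
                         n_channels: int = 1, exposure: float = 0.02,
                         frame_shape: tuple[int, int] = (256, 256)
                         ) -> ImageSeries:
    """Render a widefield/TIRF camera series from a trajectory set.

    Each frame sums integrated 2D Gaussian PSFs (waist ω_r) over the
    particles carrying the channel's label, sampled mid-exposure, times the
    exposure, plus background; noise is Poisson plus Gaussian read noise.
    For two channels the excitation alternates within each frame (green
    first, red offset by one exposure window), as in alternating-excitation
    TIRF. The trajectory time step must equal half the frame time for two
    channels (or the frame time for one), so that each channel's
    mid-exposure sample lies on the trajectory's time grid.
    """
    if geometry.modality != "camera":
        raise ValueError("camera rendering needs a camera geometry")
    if n_channels not in (1, 2):
        raise ValueError("channel count must be 1 or 2")
    ny, nx = frame_shape
    dt_f, dr = geometry.frame_time, geometry.pixel_size
    step = dt_f / n_channels
    if not math.isclose(traj.time_step, step, rel_tol=1e-6):
        raise ValueError(
            f"trajectory time_step {traj.time_step} must equal {step} "
            f"for {n_channels}-channel rendering")
    if traj.n_steps + 1 < n_frames * n_channels:
        raise ValueError("trajectory too short for the requested frames")

    bx, by = params.box_size
    oy, ox = (by - ny * dr) / 2.0, (bx - nx * dr) / 2.0
    sigma_g = geometry.focal_waist / 2.0          # 1/e² waist → Gaussian SD
    sigma_r = sigma_g * params.channel_overlap
    off_y, off_x = (params.registration_offset[0] * dr,
                    params.registration_offset[1] * dr)
    rng = np.random.default_rng(seed + 29)

    if n_channels == 1:
        # single-color imaging sees every particle; the dual-color species
        # split and per-channel maturation only apply to two-channel scenes
        ch_labels = [np.ones(traj.n_particles, dtype=bool)]
    else:
        ch_labels = [traj.label_green, traj.label_red]
    ch_sigma = [sigma_g, sigma_r]
    data = [np.zeros((n_frames, ny, nx)) for _ in range(n_channels)]

    it = traj.iter_positions()
    for f in range(n_frames):
        for c in range(n_channels):
            pos = next(it).copy()
            pos[:, 0] %= bx
            pos[:, 1] %= by
            sel = ch_labels[c]
            if c == 1:
                pos = pos[sel] + np.array([off_x, off_y])
            else:
                pos = pos[sel]
            flux = traj.brightness[sel] * 1e3 * exposure  # kHz → counts
            base = ch_sigma[c]
            sig = np.sqrt(base ** 2 + traj.extra_sigma[sel] ** 2)
            frame = np.zeros((ny, nx))
            _render_camera_frame(np.ascontiguousarray(pos), flux, sig,
                                 oy, ox, dr, ny, nx, frame)
            frame += params.background * 1e3 * exposure
            frame = rng.poisson(frame).astype(np.float64)
            if params.read_noise_sd > 0:
                frame += rng.normal(0.0, params.read_noise_sd, frame.shape)
                np.clip(frame, 0.0, None, out=frame)
            data[c][f] = frame

    names = ["green", "red"][:n_channels]
    return ImageSeries(data=data, geometry=geometry, channel_names=names)


# ---------------------------------------------------------------------------
# Binomial step-count models (generative side)
# ---------------------------------------------------------------------------


def binomial_step_pmf(x: np.ndarray, p_m: float, A: float, n: int = 5
                      ) -> np.ndarray:
    """Two-binomial step-count pmf.

    Likelihood of observing ``x`` bleaching steps from a spot that holds a
    single complex of ``n`` labeled subunits with probability ``A`` or two
    such complexes (2n subunits) with probability 1−A, each subunit carrying
    a mature, unbleached fluorophore with probability ``p_m``.
    """
    from scipy.stats import binom

    x = np.asarray(x)
    return A * binom.pmf(x, n, p_m) + (1.0 - A) * binom.pmf(x, 2 * n, p_m)


def heteromer_step_pmf(x: np.ndarray, H: float, p_m: float, A: float,
                       n: int = 5, het: int = 3) -> np.ndarray:
    """Homo/heteromer mixture pmf.

    ``H`` is the homopentamer fraction (order ``n`` labeled subunits) and
    1−H the heteromer fraction carrying only ``het`` labeled subunits; each
    branch keeps the single/double-complex overlap mixture with fraction A.
    """
    return (H * binomial_step_pmf(x, p_m, A, n)
            + (1.0 - H) * binomial_step_pmf(x, p_m, A, het))


def simulate_bleach_traces(params: BleachSimParams, n_spots: int, seed: int
                           ) -> tuple[list[IntensityTrace], np.ndarray]:
    """Simulate stepwise-photobleaching spot traces with known step counts.

    Per spot: the number of complexes is 1 with probability A else 2; each
    complex is a homopentamer (order n) with probability H else a heteromer
    carrying ``het`` labelable subunits; its mature-label count is
    Binomial(order, p_m). Each label bleaches once, at a geometrically
    distributed frame; the trace is unit intensity × surviving labels plus
    Gaussian noise. Returns the traces and the true per-spot step counts.
    """
    if n_spots < 1:
        raise ValueError("need at least one spot")
    rng = np.random.default_rng(seed)
    p = params
    traces: list[IntensityTrace] = []
    true_counts = np.empty(n_spots, dtype=np.int64)
    geom_p = 1.0 / p.mean_bleach_frames
    for s in range(n_spots):
        n_complexes = 1 if rng.uniform() < p.nonoverlap_fraction else 2
        labels = 0
        for _ in range(n_complexes):
            order = (p.order if rng.uniform() < p.homomer_fraction
                     else p.heteromer_order)
            labels += rng.binomial(order, p.maturation_prob)
        true_counts[s] = labels
        trace = np.zeros(p.trace_length)
        if labels:
            bleach = rng.geometric(geom_p, size=labels)
            bleach = np.minimum(bleach, p.trace_length)
            for t in bleach:
                trace[:t] += p.unit_intensity
        if p.noise_sd > 0:
            trace += rng.normal(0.0, p.noise_sd, trace.shape)
        traces.append(IntensityTrace(values=trace, frame_interval=0.1,
                                     center=(s, 0)))
    return traces, true_counts


# ---------------------------------------------------------------------------
# Single-channel current traces
# ---------------------------------------------------------------------------


def simulate_channel_trace(params: ChannelSimParams, duration: float,
                           seed: int) -> tuple[CurrentTrace, float]:
    """Simulate a two-state (closed/open) gating current trace.

    Continuous-time Markov gating with the given opening/closing rates;
    current = baseline + amplitude while open, plus Gaussian noise. Returns
    the trace and the true open-channel amplitude.
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    p = params
    n = int(round(duration * p.sampling_rate))
    dt = 1.0 / p.sampling_rate
    state = rng.uniform() < p.open_probability
    open_mask = np.zeros(n, dtype=bool)
    t = 0.0
    i = 0
    while i < n:
        rate = p.close_rate if state else p.open_rate
        dwell = rng.exponential(1.0 / rate)
        j = min(n, int(math.ceil((t + dwell) / dt)))
        if state:
            open_mask[i:j] = True
        t += dwell
        i = j
        state = not state
    values = p.baseline + p.amplitude * open_mask.astype(float)
    if p.noise_sd > 0:
        values = values + rng.normal(0.0, p.noise_sd, n)
    trace = CurrentTrace(values=values, sampling_interval=dt)
    return trace, p.amplitude
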