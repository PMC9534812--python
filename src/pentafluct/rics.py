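"""Raster image correlation spectroscopy (RICS / ARICS).

A raster-scanned confocal frame encodes diffusion in its *spatial*
correlations: neighbouring pixels along the fast scan axis are recorded
µs apart, successive lines ms apart, so the decay of the spatial
autocorrelation G(ξ, ψ) with lag reports µs–ms mobility. The pipeline is

1. :func:`moving_average_correct` — remove slow drifts (cell movement)
   by subtracting a short per-pixel temporal local mean,
2. :func:`spatial_correlate` — masked spatial autocorrelation with each
   lag normalized by its count of valid (both-included) pixel pairs,
3. :func:`fit_rics` — weighted fit of the one-component 2D-diffusion
   model with a Gaussian point spread function,
4. :func:`brightness` — molecular brightness ε = F / N, the mean photon
   rate per diffusing complex, which reports stoichiometry.

The fit model over spatial lags (ξ, ψ) in pixels is::

    G(ξ, ψ) = γ/N · (1 + 4D·|ξ·τ_p + ψ·τ_l| / ω_r²)⁻¹
              · exp(− δr²(ξ² + ψ²) / (ω_r² + 4D·|ξ·τ_p + ψ·τ_l|))

with shape factor γ = 2^(−3/2), N the mean number of molecules in focus,
D the diffusion constant, τ_p/τ_l the pixel/line times, δr the pixel size
and ω_r the focal waist.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.fft import irfft2, rfft2

from .core_io import AcquisitionGeometry, ImageSeries
from .masking import MaskStack

logger = logging.getLogger("pentafluct")

__all__ = [
    "GAMMA_2D_GAUSSIAN",
    "SpatialACF",
    "RICSFit",
    "BrightnessResult",
    "moving_average_correct",
    "spatial_correlate",
    "rics_model",
    "fit_rics",
    "brightness",
]

#: Shape factor of the Gaussian focal volume used by the diffusion model.
GAMMA_2D_GAUSSIAN = 2.0 ** -1.5


@dataclass
class SpatialACF:
    """Frame-averaged spatial autocorrelation surface.

    ``G[i, j]`` is the correlation at line lag ``psi_lags[i]`` and fast-axis
    lag ``xi_lags[j]``; ``counts`` holds the valid-pair count per lag and
    ``sd`` the across-frame standard deviation. Lags with zero valid pairs
    are NaN and excluded from fits.
    """

    G: np.ndarray
    xi_lags: np.ndarray
    psi_lags: np.ndarray
    counts: np.ndarray
    sd: np.ndarray
    n_frames: int


@dataclass
class RICSFit:
    """Fitted one-component RICS diffusion model.

    ``offset`` is a fitted additive constant absorbing the long-range
    correlation pedestal that the moving-average correction leaves behind
    (the correction high-pass filters in time, which suppresses slowly
    relaxing long-wavelength concentration modes and offsets the surface).
    """

    N: float
    D: float
    N_sd: float
    D_sd: float
    offset: float = 0.0
    gamma: float = GAMMA_2D_GAUSSIAN
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True
    message: str = ""

    @property
    def amplitude(self) -> float:
        """Model zero-lag amplitude G(0,0) = γ/N."""
        return self.gamma / self.N


@dataclass
class BrightnessResult:
    """Molecular brightness from mean intensity and fitted N."""

    epsilon: float            # kHz per diffusing complex
    mean_intensity: float     # F, kHz, over included pixels
    n_acf1: float             # bias-corrected N
    bias_factor: float        # amplitude correction applied


# ---------------------------------------------------------------------------
# Detrending
# ---------------------------------------------------------------------------


def moving_average_correct(series: ImageSeries, delta_f: int = 1
                           ) -> ImageSeries:
    """Remove slow per-pixel drifts with a moving-average correction.

    Per pixel and frame f the output is I − ⟨I⟩_[f−ΔF, f+ΔF] + ⟨I⟩_all,
    the local temporal mean over a (2ΔF+1)-frame window (truncated at the
    series ends) replaced by the global mean. The output's global mean is
    restored to the input's global mean exactly.
    """
    if delta_f < 1:
        raise ValueError("delta_f must be >= 1")
    n = series.n_frames
    if n < 2 * delta_f + 1:
        raise ValueError(
            f"need at least {2 * delta_f + 1} frames for delta_f={delta_f}")
    out_data = []
    for stack in series.data:
        csum = np.cumsum(stack, axis=0)
        local = np.empty_like(stack)
        for f in range(n):
            lo, hi = max(0, f - delta_f), min(n - 1, f + delta_f)
            tot = csum[hi] - (csum[lo - 1] if lo > 0 else 0)
            local[f] = tot / (hi - lo + 1)
        gmean = stack.mean()
        out = stack - local + gmean
        out += gmean - out.mean()   # exact global-mean restoration
        out_data.append(out)
    return series.with_data(out_data)


# ---------------------------------------------------------------------------
# Masked spatial autocorrelation
# ---------------------------------------------------------------------------


def _masked_xcorr_fft(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Zero-padded spatial cross-correlation Σ a(x,y)·b(x+ξ,y+ψ) via FFT.

    Returns the full surface with lag 0 at the center, shape
    (2·ny−1, 2·nx−1).
    """
    ny, nx = a.shape
    fy, fx = 2 * ny - 1, 2 * nx - 1
    fa = rfft2(a, s=(fy, fx))
    fb = rfft2(b, s=(fy, fx))
    corr = irfft2(np.conj(fa) * fb, s=(fy, fx))
    return np.fft.fftshift(corr)


def spatial_correlate(series: ImageSeries, mask: MaskStack,
                      max_lag: tuple[int, int] = (32, 32),
                      channel: int = 0) -> SpatialACF:
    """Masked (arbitrary-region) spatial autocorrelation, frame-averaged.

    Per frame, fluctuations δI are computed against the mean of included
    pixels; the numerator at lag (ξ, ψ) averages δI(x,y)·δI(x+ξ,y+ψ) over
    pairs where *both* pixels are included, and is normalized by the
    squared mean of the included pixels. Surfaces are averaged over frames
    with a per-lag SD retained for fit weighting.
    """
    mask.check_shape(series)
    stack = series.channel(channel)
    n_frames = stack.shape[0]
    psi_max, xi_max = max_lag[1], max_lag[0]
    ny, nx = series.frame_shape
    psi_max = min(psi_max, ny - 1)
    xi_max = min(xi_max, nx - 1)
    cy, cx = ny - 1, nx - 1   # center index of the fftshifted surface

    surfaces = np.empty((n_frames, 2 * psi_max + 1, 2 * xi_max + 1))
    counts_f = np.empty_like(surfaces)
    sl = (slice(cy - psi_max, cy + psi_max + 1),
          slice(cx - xi_max, cx + xi_max + 1))
    for f in range(n_frames):
        m = mask.frame(f).astype(np.float64)
        n_inc = m.sum()
        if n_inc < 2:
            raise ValueError(f"frame {f}: mask includes fewer than 2 pixels")
        img = stack[f]
        mean_inc = (img * m).sum() / n_inc
        if mean_inc == 0:
            raise ValueError(f"frame {f}: zero mean over included pixels")
        delta = (img - mean_inc) * m
        num = _masked_xcorr_fft(delta, delta)[sl]
        cnt = _masked_xcorr_fft(m, m)[sl]
        cnt = np.round(cnt)
        with np.errstate(invalid="ignore", divide="ignore"):
            surfaces[f] = np.where(cnt >= 1, num / cnt, np.nan) / mean_inc ** 2
        counts_f[f] = cnt

    counts = counts_f.min(axis=0)
    valid = counts >= 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        G = np.nanmean(surfaces, axis=0)
        sd = np.nanstd(surfaces, axis=0, ddof=1) if n_frames > 1 else \
            np.full(G.shape, np.nan)
    G[~valid] = np.nan
    xi = np.arange(-xi_max, xi_max + 1)
    psi = np.arange(-psi_max, psi_max + 1)
    return SpatialACF(G=G, xi_lags=xi, psi_lags=psi, counts=counts, sd=sd,
                      n_frames=n_frames)


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------


def rics_model(xi: np.ndarray, psi: np.ndarray, N: float, D: float,
               geometry: AcquisitionGeometry,
               gamma: float = GAMMA_2D_GAUSSIAN) -> np.ndarray:
    """One-component 2D-diffusion RICS model evaluated at integer lags."""
    tau = np.abs(xi * geometry.pixel_dwell + psi * geometry.line_time)
    w2 = geometry.focal_waist ** 2
    denom = 1.0 + 4.0 * D * tau / w2
    spread = w2 + 4.0 * D * tau
    r2 = geometry.pixel_size ** 2 * (xi ** 2 + psi ** 2)
    return gamma / N / denom * np.exp(-r2 / spread)


def fit_rics(acf: SpatialACF, geometry: AcquisitionGeometry,
             fit_radius: tuple[int, int] = (16, 8),
             gamma: float = GAMMA_2D_GAUSSIAN,
             fit_offset: bool = True) -> RICSFit:
    """Weighted least-squares fit of the RICS diffusion model.

    Uses lags with |ξ| ≤ fit_radius[0] and |ψ| ≤ fit_radius[1], excluding
    the (0,0) lag (uncorrelated shot noise) and lags without valid pairs.
    Weights are 1/SD per lag. Returns N and D with 1σ uncertainties.

    With ``fit_offset`` (default) an additive constant is co-fitted: the
    moving-average correction removes slowly relaxing long-wavelength
    concentration modes, which shifts the correlation surface by a small
    nearly-flat pedestal over the fit window; without the offset that
    pedestal biases D low.
    """
    if geometry.modality != "raster":
        raise ValueError("RICS fitting requires a raster geometry")
    XI, PSI = np.meshgrid(acf.xi_lags, acf.psi_lags)
    sel = (np.abs(XI) <= fit_radius[0]) & (np.abs(PSI) <= fit_radius[1])
    sel &= ~((XI == 0) & (PSI == 0))
    sel &= np.isfinite(acf.G)
    xi, psi, g = XI[sel].astype(float), PSI[sel].astype(float), acf.G[sel]
    sd = acf.sd[sel]
    if xi.size < 4:
        raise ValueError("not enough valid lags to fit")
    amp0 = np.nanmax(g)
    if amp0 <= 0:
        raise ValueError("non-positive ACF amplitude; nothing to fit")
    if np.all(np.isfinite(sd)) and np.all(sd > 0):
        sigma = sd / np.sqrt(acf.n_frames)
    else:
        sigma = None

    w2 = geometry.focal_waist ** 2
    d0 = w2 / (4.0 * geometry.line_time * 4.0)   # decay over ~4 lines
    if fit_offset:
        def model(_x, N, D, c):
            return rics_model(xi, psi, N, D, geometry, gamma) + c
        p0 = (gamma / amp0, d0, 0.0)
        bounds = ([1e-12, 0.0, -np.inf], [np.inf, np.inf, np.inf])
    else:
        def model(_x, N, D):
            return rics_model(xi, psi, N, D, geometry, gamma)
        p0 = (gamma / amp0, d0)
        bounds = ([1e-12, 0.0], [np.inf, np.inf])
    try:
        popt, pcov = optimize.curve_fit(
            model, xi, g, p0=p0, sigma=sigma, absolute_sigma=False,
            bounds=bounds, maxfev=20000)
        perr = np.sqrt(np.diag(pcov))
        resid = g - model(None, *popt)
        offset = float(popt[2]) if fit_offset else 0.0
        return RICSFit(N=float(popt[0]), D=float(popt[1]),
                       N_sd=float(perr[0]), D_sd=float(perr[1]),
                       offset=offset, gamma=gamma, residuals=resid)
    except RuntimeError as exc:
        logger.warning("RICS fit did not converge: %s", exc)
        return RICSFit(N=float(p0[0]), D=float(p0[1]), N_sd=np.nan,
                       D_sd=np.nan, gamma=gamma, converged=False,
                       message=str(exc))


def brightness(series: ImageSeries, mask: MaskStack, fit: RICSFit,
               delta_f: int = 1, bias_factor: float | None = None,
               channel: int = 0) -> BrightnessResult:
    """Molecular brightness ε = F / N_ACF1 in kHz per complex.

    ``F`` is the mean intensity over included pixels converted from counts
    per pixel to kHz via the pixel dwell time. The moving-average
    correction deflates the correlation amplitude of frame-uncorrelated
    fluctuations by 2ΔF/(2ΔF+1), inflating the fitted N by the inverse;
    N is therefore multiplied by 2ΔF/(2ΔF+1) (i.e. the amplitude is
    corrected by ``bias_factor`` = (2ΔF+1)/(2ΔF), 3/2 at ΔF=1) before the
    division. Pass ``bias_factor`` explicitly to override.
    """
    if series.geometry.modality != "raster":
        raise ValueError(
            "brightness is defined for photon-counting raster data")
    if not fit.converged or not fit.N > 0:
        raise ValueError("need a converged fit with positive N")
    if bias_factor is None:
        bias_factor = (2.0 * delta_f + 1.0) / (2.0 * delta_f)
    logger.info("brightness: applying moving-average amplitude bias "
                "factor %.4f to the fitted N", bias_factor)
    mask.check_shape(series)
    stack = series.channel(channel)
    if mask.is_static:
        sel = np.broadcast_to(mask.grids, stack.shape)
    else:
        sel = mask.grids
    counts = stack[sel]
    tau_p = series.geometry.pixel_dwell
    F = counts.mean() / tau_p / 1e3   # counts/pixel → Hz → kHz
    n_corr = fit.N / bias_factor
    if not n_corr > 0:
        raise ValueError("bias-corrected N must be positive")
    return BrightnessResult(epsilon=F / n_corr, mean_intensity=F,
                            n_acf1=n_corr, bias_factor=bias_factor)
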