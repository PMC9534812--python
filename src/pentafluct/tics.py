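"""Temporal image correlation spectroscopy (TICS) and dual-color TICCS.

A camera frame series samples each pixel every Δt_f (tens of ms), so the
*temporal* autocorrelation of a pixel's intensity trace decays on the
timescale molecules need to diffuse across the focal spot — sensitive to
much slower mobility (ms–s) than RICS. Cross-correlating the two color
channels of an alternating-excitation series reports co-diffusion: only
complexes carrying both labels contribute to the cross-correlation
amplitude.

Pipeline: :func:`detrend_frames` equalizes frame-to-frame intensity
variation, :func:`temporal_correlate` computes per-pixel auto-/cross-
correlation curves averaged over included pixels, :func:`fit_tics` fits
the one-component 2D diffusion model::

    G(τ) = A_D · (1 + 4Dτ/ω_r²)⁻¹ + A_0

over lags 1..12 frames, and :func:`relative_cc` forms the relative
cross-correlation Rel.CC = G_CCF(0) / mean(G_ACF1(0), G_ACF2(0)), a proxy
for the co-diffusing fraction.

The fit model ignores the finite pixel size (and the uniform TIRF
excitation profile); at 150 nm pixels with a ~300 nm waist this biases D
by roughly 10–20%, shrinking with pixel size. This known model bias is
documented and covered by tests rather than corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.fft import irfft, rfft

from .core_io import AcquisitionGeometry, ImageSeries
from .masking import MaskStack

logger = logging.getLogger("pentafluct")

__all__ = [
    "TemporalCF",
    "TICSFit",
    "CrossCorrResult",
    "detrend_frames",
    "temporal_correlate",
    "tics_model",
    "fit_tics",
    "relative_cc",
]


@dataclass
class TemporalCF:
    """Mean temporal correlation curve with across-pixel 95% CIs."""

    G: np.ndarray          # mean curve over included pixels
    lags: np.ndarray       # lag times, s (τ = m·Δt_f)
    ci95: np.ndarray       # 95% confidence half-width of the mean per lag
    kind: str              # "auto1" | "auto2" | "cross"
    n_pixels: int = 0


@dataclass
class TICSFit:
    """Fitted one-component 2D-diffusion temporal correlation model."""

    A_D: float
    D: float
    A_0: float
    A_D_sd: float
    D_sd: float
    A_0_sd: float
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True
    message: str = ""

    @property
    def zero_lag_amplitude(self) -> float:
        """Fitted model evaluated at τ = 0: A_D + A_0."""
        return self.A_D + self.A_0


@dataclass
class CrossCorrResult:
    """Relative cross-correlation of a dual-color series."""

    rel_cc: float
    ccf_amplitude: float
    acf1_amplitude: float
    acf2_amplitude: float


# ---------------------------------------------------------------------------
# Detrending
# ---------------------------------------------------------------------------


def detrend_frames(series: ImageSeries) -> ImageSeries:
    """Equalize frame-to-frame intensity variation.

    Per pixel and frame: I − ⟨I(t)⟩_XY + ⟨I⟩_XY, replacing each frame's
    spatial mean with the global mean, so every output frame has the same
    spatial mean.
    """
    if series.n_frames < 2:
        raise ValueError("detrending needs at least 2 frames")
    out = []
    for stack in series.data:
        frame_means = stack.mean(axis=(1, 2), keepdims=True)
        out.append(stack - frame_means + stack.mean())
    return series.with_data(out)


# ---------------------------------------------------------------------------
# Temporal correlation
# ---------------------------------------------------------------------------


def _lagged_products(d1: np.ndarray, d2: np.ndarray, max_lag: int
                     ) -> np.ndarray:
    """Σ_t d1(t)·d2(t+m) for m = 0..max_lag via zero-padded FFT.

    d1, d2: (T, P) fluctuation traces; returns (max_lag+1, P).
    """
    T = d1.shape[0]
    nfft = 2 * T
    f1 = rfft(d1, n=nfft, axis=0)
    f2 = rfft(d2, n=nfft, axis=0)
    corr = irfft(np.conj(f1) * f2, n=nfft, axis=0)
    return corr[: max_lag + 1]


def temporal_correlate(series_1: ImageSeries, series_2: ImageSeries | None = None,
                       mask: MaskStack | None = None, channel_1: int = 0,
                       channel_2: int | None = None, max_lag: int | None = None
                       ) -> TemporalCF:
    """Pixel-based temporal auto- or cross-correlation.

    For each included pixel the fluctuation trace δI = I(t) − ⟨I(x,y)⟩_t is
    correlated with the (possibly second-channel) trace at lags τ = m·Δt_f,
    normalized by the product of the two temporal means and the unbiased
    (T − m) term count. Curves are averaged with equal weight over included
    pixels; the per-lag 95% CI is that of the mean across pixels.

    With ``series_2`` (or ``channel_2``) omitted this is the
    autocorrelation. Per-frame masks are reduced to their across-frame
    intersection: a dynamic mask cannot yield gap-free pixel time traces.
    """
    if series_2 is None:
        series_2 = series_1
        if channel_2 is None:
            channel_2 = channel_1
    elif channel_2 is None:
        channel_2 = 0
    s1 = series_1.channel(channel_1)
    s2 = series_2.channel(channel_2)
    if s1.shape != s2.shape:
        raise ValueError("both channels must share shape and frame count")
    T = s1.shape[0]
    dt = series_1.geometry.frame_time
    if dt is None:
        raise ValueError("temporal correlation needs a camera frame time")
    if max_lag is None:
        max_lag = min(T - 1, max(12, T // 4))
    max_lag = min(max_lag, T - 1)

    if mask is None:
        grid = np.ones(series_1.frame_shape, dtype=bool)
    else:
        mask.check_shape(series_1)
        grid = mask.static_grid()
    if grid.sum() < 2:
        raise ValueError("fewer than 2 included pixels")

    x1 = s1[:, grid]                  # (T, P)
    x2 = s2[:, grid]
    m1 = x1.mean(axis=0)
    m2 = x2.mean(axis=0)
    ok = (m1 != 0) & (m2 != 0)
    if not ok.all():
        logger.warning("skipping %d zero-mean pixel(s)", int((~ok).sum()))
        x1, x2, m1, m2 = x1[:, ok], x2[:, ok], m1[ok], m2[ok]
    if m1.size < 2:
        raise ValueError("fewer than 2 usable pixels after skipping")

    d1 = x1 - m1
    d2 = x2 - m2
    raw = _lagged_products(d1, d2, max_lag)
    nterms = (T - np.arange(max_lag + 1))[:, None]
    curves = raw / nterms / (m1 * m2)[None, :]

    G = curves.mean(axis=1)
    n_pix = curves.shape[1]
    ci95 = 1.96 * curves.std(axis=1, ddof=1) / np.sqrt(n_pix)
    same = series_2 is series_1 and channel_2 == channel_1
    kind = "auto1" if same else "cross"
    lags = np.arange(max_lag + 1) * dt
    return TemporalCF(G=G, lags=lags, ci95=ci95, kind=kind, n_pixels=n_pix)


# ---------------------------------------------------------------------------
# Fitting and relative cross-correlation
# ---------------------------------------------------------------------------


def tics_model(tau: np.ndarray, A_D: float, D: float, A_0: float,
               focal_waist: float) -> np.ndarray:
    """One-component 2D diffusion model G(τ) = A_D(1+4Dτ/ω²)⁻¹ + A_0."""
    return A_D / (1.0 + 4.0 * D * tau / focal_waist ** 2) + A_0


def fit_tics(cf: TemporalCF, geometry: AcquisitionGeometry,
             max_lag_frames: int = 12) -> TICSFit:
    """Weighted fit of the diffusion model over lags 1..max_lag_frames.

    The zero lag is excluded (uncorrelated shot/read noise); the fit range
    is truncated at 12 frames by default to avoid very slow drift
    contributions. Raises if fewer than 4 usable lags remain.
    """
    dt = geometry.frame_time
    if dt is None:
        raise ValueError("TICS fitting needs a camera frame time")
    w = geometry.focal_waist
    sel = (cf.lags > 0) & (cf.lags <= max_lag_frames * dt * (1 + 1e-9))
    sel &= np.isfinite(cf.G)
    tau, g = cf.lags[sel], cf.G[sel]
    if tau.size < 4:
        raise ValueError("fewer than 4 usable lags for the TICS fit")
    ci = cf.ci95[sel]
    sigma = ci if np.all(np.isfinite(ci)) and np.all(ci > 0) else None

    a0 = g[-1]
    ad0 = max(g[0] - a0, 1e-12)
    d0 = w ** 2 / (4.0 * max(tau[len(tau) // 2], dt))
    try:
        popt, pcov = optimize.curve_fit(
            lambda t, A_D, D, A_0: tics_model(t, A_D, D, A_0, w),
            tau, g, p0=(ad0, d0, a0), sigma=sigma, absolute_sigma=False,
            bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000)
        perr = np.sqrt(np.diag(pcov))
        resid = g - tics_model(tau, *popt, w)
        return TICSFit(A_D=float(popt[0]), D=float(popt[1]),
                       A_0=float(popt[2]), A_D_sd=float(perr[0]),
                       D_sd=float(perr[1]), A_0_sd=float(perr[2]),
                       residuals=resid)
    except RuntimeError as exc:
        logger.warning("TICS fit did not converge: %s", exc)
        return TICSFit(A_D=float(ad0), D=float(d0), A_0=float(a0),
                       A_D_sd=np.nan, D_sd=np.nan, A_0_sd=np.nan,
                       converged=False, message=str(exc))


def relative_cc(fit_ccf: TICSFit, fit_acf1: TICSFit, fit_acf2: TICSFit
                ) -> CrossCorrResult:
    """Relative cross-correlation from three fitted zero-lag amplitudes.

    Rel.CC = G_CCF(0) / ((G_ACF1(0) + G_ACF2(0)) / 2), with each G(0) the
    fitted model at τ = 0 (A_D + A_0). A negative cross-correlation
    amplitude is floored at 0 with a warning.
    """
    g_ccf = fit_ccf.zero_lag_amplitude
    g1 = fit_acf1.zero_lag_amplitude
    g2 = fit_acf2.zero_lag_amplitude
    if g1 <= 0 and g2 <= 0:
        raise ValueError("both autocorrelation amplitudes are non-positive")
    if g_ccf < 0:
        logger.warning("negative CCF amplitude %.3g floored at 0", g_ccf)
        g_ccf = 0.0
    rel = g_ccf / ((g1 + g2) / 2.0)
    return CrossCorrResult(rel_cc=rel, ccf_amplitude=g_ccf,
                           acf1_amplitude=g1, acf2_amplitude=g2)
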