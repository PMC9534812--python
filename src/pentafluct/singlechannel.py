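"""Cell-attached single-channel current analysis.

Single-receptor openings appear as discrete ~1–10 pA excursions from the
baseline. The analysis chain: a zero-phase digital Gaussian low-pass
filter (100 Hz cutoff at −3 dB) suppresses high-frequency noise while
preserving plateau mean currents; short (< 1 s) windows containing
openings are summarized by fitting a double Gaussian to the sample
histogram, where the component nearer zero is the baseline and the
difference of the two component means is the mean open current; window
mean currents from one cell are grouped by similarity so cells contribute
group means rather than raw window counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .core_io import CurrentTrace

logger = logging.getLogger("pentafluct")

__all__ = [
    "CurrentWindow",
    "CurrentGroup",
    "gaussian_lowpass",
    "gaussian_kernel_sigma",
    "gaussian_noise_gain",
    "analyze_window",
    "group_currents",
    "propose_windows",
]


@dataclass
class CurrentWindow:
    """Double-Gaussian summary of one analysis window."""

    start: float                 # s
    end: float                   # s
    baseline_mean: float         # pA
    peak_mean: float             # pA
    mean_current: float          # |peak − baseline|, pA
    n_samples: int
    flagged: bool = False        # True when the mixture collapsed
    message: str = ""
    cell_id: str = "cell0"


@dataclass
class CurrentGroup:
    """Windows with similar mean currents from one cell."""

    members: np.ndarray          # member window mean currents, pA
    mean: float                  # group mean, pA
    cell_id: str = "cell0"


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def gaussian_kernel_sigma(cutoff: float, sampling_rate: float) -> float:
    """Gaussian kernel SD in samples for a −3 dB cutoff frequency.

    The kernel's frequency response is exp(−2π²σ_t²f²); the −3 dB point
    (|H| = 1/√2) gives σ_t = √(ln 2) / (2π·f_c).
    """
    sigma_t = math.sqrt(math.log(2.0)) / (2.0 * math.pi * cutoff)
    return sigma_t * sampling_rate


def gaussian_noise_gain(sigma_samples: float) -> float:
    """Factor by which the kernel reduces white-noise SD: (2σ√π)^(−1/2)."""
    return 1.0 / math.sqrt(2.0 * sigma_samples * math.sqrt(math.pi))


def gaussian_lowpass(trace: CurrentTrace, cutoff: float = 100.0
                     ) -> CurrentTrace:
    """Zero-phase Gaussian low-pass filter, −3 dB at ``cutoff`` Hz.

    Length-preserving (reflective padding); plateau means are preserved
    because the kernel has unit DC gain.
    """
    nyquist = trace.sampling_rate / 2.0
    if cutoff >= nyquist:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below the Nyquist frequency "
            f"{nyquist} Hz")
    sigma = gaussian_kernel_sigma(cutoff, trace.sampling_rate)
    filtered = ndimage.gaussian_filter1d(trace.values, sigma, mode="reflect")
    return CurrentTrace(values=filtered,
                        sampling_interval=trace.sampling_interval,
                        holding_potential=trace.holding_potential)


# ---------------------------------------------------------------------------
# Window analysis
# ---------------------------------------------------------------------------


def _double_gauss(x, a1, mu1, s1, a2, mu2, s2):
    return (a1 * np.exp(-0.5 * ((x - mu1) / s1) ** 2)
            + a2 * np.exp(-0.5 * ((x - mu2) / s2) ** 2))


def analyze_window(trace: CurrentTrace, window: tuple[float, float],
                   bin_width: float = 0.1, cell_id: str = "cell0"
                   ) -> CurrentWindow:
    """Fit a double Gaussian to the sample histogram of a short window.

    The window must be shorter than 1 s and contain both closed and open
    levels. The mixture component nearer zero current is taken as the
    baseline; mean current = |peak mean − baseline mean|. If the two
    components collapse onto each other (separation below the larger
    component width) the result is flagged: no opening in the window.
    """
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window end must exceed its start")
    if t1 - t0 >= 1.0:
        raise ValueError("analysis windows must be shorter than 1 s")
    i0 = max(0, int(round(t0 / trace.sampling_interval)))
    i1 = min(trace.values.size, int(round(t1 / trace.sampling_interval)))
    samples = trace.values[i0:i1]
    if samples.size < 20:
        raise ValueError("window contains too few samples")

    lo, hi = samples.min(), samples.max()
    span = max(hi - lo, bin_width)
    edges = np.arange(lo - bin_width, hi + 2 * bin_width, bin_width)
    counts, edges = np.histogram(samples, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    mu1_0 = np.percentile(samples, 15)
    mu2_0 = np.percentile(samples, 85)
    s0 = max(samples.std() / 2, bin_width / 2)
    a0 = counts.max()
    p0 = (a0, mu1_0, s0, a0 / 2, mu2_0, s0)
    flagged = False
    msg = ""
    try:
        popt, _ = optimize.curve_fit(
            _double_gauss, centers, counts, p0=p0, maxfev=20000,
            bounds=([0, lo - span, 1e-6, 0, lo - span, 1e-6],
                    [np.inf, hi + span, span, np.inf, hi + span, span]))
        a1, mu1, s1, a2, mu2, s2 = popt
        if (abs(mu1 - mu2) < 1.5 * max(s1, s2)
                or min(a1, a2) < 0.02 * max(a1, a2)):
            flagged = True
            msg = "mixture collapsed to a single component"
    except RuntimeError as exc:
        flagged = True
        msg = f"fit did not converge: {exc}"
        mu1 = mu2 = float(np.mean(samples))

    if flagged:
        base, peak = float(np.mean(samples)), float(np.mean(samples))
    else:
        # component nearer zero current = baseline
        if abs(mu1) <= abs(mu2):
            base, peak = float(mu1), float(mu2)
        else:
            base, peak = float(mu2), float(mu1)
    return CurrentWindow(start=t0, end=t1, baseline_mean=base,
                         peak_mean=peak, mean_current=abs(peak - base),
                         n_samples=int(samples.size), flagged=flagged,
                         message=msg, cell_id=cell_id)


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------


def group_currents(windows: list[CurrentWindow], tolerance: float = 1.0
                   ) -> list[CurrentGroup]:
    """Group similar window mean currents of one cell.

    One-dimensional agglomeration: currents are sorted and greedily split
    whenever adding the next value would stretch the group's spread beyond
    ``tolerance``. For sorted 1D data this yields the minimum number of
    groups subject to the maximum within-group spread constraint.
    """
    usable = [w for w in windows if not w.flagged]
    if not usable:
        return []
    cells = {w.cell_id for w in usable}
    if len(cells) > 1:
        raise ValueError("group_currents expects windows from one cell")
    values = np.sort([w.mean_current for w in usable])
    groups: list[CurrentGroup] = []
    start = 0
    for i in range(1, values.size + 1):
        if i == values.size or values[i] - values[start] > tolerance:
            members = values[start:i]
            groups.append(CurrentGroup(members=members,
                                       mean=float(members.mean()),
                                       cell_id=usable[0].cell_id))
            start = i
    return groups


def propose_windows(trace: CurrentTrace, window_length: float = 0.5,
                    min_sd_factor: float = 1.5) -> list[tuple[float, float]]:
    """Suggest candidate analysis windows by variance-burst detection.

    Convenience helper only — window selection is normally manual. Tiles
    the trace into ``window_length`` segments and returns those whose
    sample SD exceeds ``min_sd_factor`` × the quietest segment's SD.
    """
    n_per = int(round(window_length / trace.sampling_interval))
    if n_per < 20:
        raise ValueError("window_length too short for the sampling rate")
    n_win = trace.values.size // n_per
    sds = np.array([trace.values[i * n_per:(i + 1) * n_per].std()
                    for i in range(n_win)])
    if sds.size == 0:
        return []
    ref = sds.min()
    out = []
    for i, sd in enumerate(sds):
        if sd > min_sd_factor * ref:
            out.append((i * n_per * trace.sampling_interval,
                        (i + 1) * n_per * trace.sampling_interval))
    return out
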