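"""Single-molecule subunit counting by stepwise photobleaching.

Each fluorescent protein in a diffraction-limited spot bleaches in a
single discrete step, so the number of downward intensity steps in the
spot's trace counts its mature fluorophores. The observed step-count
distribution over many spots is then fitted with a binomial mixture to
infer the maturation probability p_m, the fraction A of spots holding a
single complex, and — for co-expression experiments — the heteromer
fraction and labeled-subunit order.

Pipeline:

* :func:`detect_spots` — candidate spots from local maxima of the
  first-frames average with a δF/F contrast threshold; partially
  overlapping 5×5 windows are discarded; traces extracted as 3×3 sums.
* :func:`find_steps` — change-point step localization by iterative
  information-criterion fitting (Kalafut–Visscher style SIC), followed by
  the acceptance filters: every dwell ≥ 3 frames, every step amplitude
  within 60% of the median step amplitude, step signal-to-noise ≥ 2, and
  a monotone staircase ending at the lowest level.
* :func:`build_histogram` — per-field 10% acceptance gate, aggregation.
* :func:`fit_binomial` / :func:`scan_heteromer_orders` — least-squares
  fits of the step-count mixture models with χ² goodness-of-fit.

Step-count models (``x`` = number of observed steps, order ``n`` = 5)::

    B(x; n+2n, p_m)  = A·Binom(x; n, p_m) + (1−A)·Binom(x; 2n, p_m)
    B_het(x)         = H·B(x; n+2n, p_m) + (1−H)·B(x; het+2·het, p_m)

Spots with zero detected steps are unobservable, so the pmf is
renormalized over x ≥ 1 for fitting (switchable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .core_io import ImageSeries, IntensityTrace
from .synthgen import binomial_step_pmf, heteromer_step_pmf

logger = logging.getLogger("pentafluct")

__all__ = [
    "SpotRecord",
    "StepResult",
    "StepHistogram",
    "BinomialModel",
    "detect_spots",
    "find_steps",
    "build_histogram",
    "fit_binomial",
    "scan_heteromer_orders",
]


# ---------------------------------------------------------------------------
# Spot detection
# ---------------------------------------------------------------------------


@dataclass
class SpotRecord:
    """A detected spot with its extracted trace and step-finding outcome."""

    center: tuple[int, int]
    trace: IntensityTrace
    field_id: str = "field0"
    step_count: int | None = None
    rejection: str | None = None

    @property
    def accepted(self) -> bool:
        return self.step_count is not None and self.rejection is None


def detect_spots(series: ImageSeries, snr_threshold: float = 0.20,
                 n_avg_frames: int = 10, channel: int = 0,
                 field_id: str = "field0") -> list[SpotRecord]:
    """Detect single-molecule spots and extract their intensity traces.

    Local maxima of the average over the first ``n_avg_frames`` frames
    whose contrast δF/F over the local background exceeds
    ``snr_threshold`` become 5×5-pixel candidates. The local background is
    the mean of an 11×11 surround excluding the central 5×5. Candidates
    whose 5×5 windows intersect are all discarded (partial overlap rule),
    as are windows touching the frame border. Traces are 3×3 sums about
    each center across all frames.
    """
    from scipy import ndimage

    if series.geometry.modality != "camera":
        raise ValueError("spot detection expects a camera series")
    stack = series.channel(channel)
    n_avg = min(n_avg_frames, stack.shape[0])
    avg = stack[:n_avg].mean(axis=0)
    ny, nx = avg.shape

    localmax = ndimage.maximum_filter(avg, size=5, mode="nearest")
    cand = np.argwhere((avg == localmax))
    centers = []
    for r, c in cand:
        if r < 5 or c < 5 or r >= ny - 5 or c >= nx - 5:
            continue
        win = avg[r - 5:r + 6, c - 5:c + 6].copy()
        inner = avg[r - 2:r + 3, c - 2:c + 3]
        surround = win.sum() - inner.sum()
        n_surround = win.size - inner.size
        bg = surround / n_surround
        if bg <= 0:
            continue
        if (avg[r, c] - bg) / bg >= snr_threshold:
            centers.append((int(r), int(c)))

    # partial-overlap rule: 5×5 windows intersect iff |Δr| ≤ 4 and |Δc| ≤ 4
    keep = []
    for i, (r, c) in enumerate(centers):
        clash = any(j != i and abs(r - r2) <= 4 and abs(c - c2) <= 4
                    for j, (r2, c2) in enumerate(centers))
        if not clash:
            keep.append((r, c))

    dt = series.geometry.frame_time or 0.1
    spots = []
    for r, c in keep:
        tr = stack[:, r - 1:r + 2, c - 1:c + 2].sum(axis=(1, 2))
        spots.append(SpotRecord(center=(r, c), field_id=field_id,
                                trace=IntensityTrace(values=tr,
                                                     frame_interval=dt,
                                                     center=(r, c))))
    return spots


# ---------------------------------------------------------------------------
# Step finding
# ---------------------------------------------------------------------------


@dataclass
class StepResult:
    """Outcome of step finding on one trace."""

    step_count: int | None
    rejection: str | None
    changepoints: list[int] = field(default_factory=list)
    levels: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def accepted(self) -> bool:
        return self.rejection is None


def _best_split(y: np.ndarray, csum: np.ndarray, csum2: np.ndarray,
                lo: int, hi: int) -> tuple[int, float]:
    """Best single changepoint in y[lo:hi]: (index, RSS reduction)."""
    n = hi - lo
    if n < 2:
        return -1, 0.0
    s = csum[hi] - csum[lo]
    seg_rss = (csum2[hi] - csum2[lo]) - s * s / n
    ks = np.arange(lo + 1, hi)
    nl = ks - lo
    nr = hi - ks
    sl = csum[ks] - csum[lo]
    sr = s - sl
    rss_split = ((csum2[ks] - csum2[lo]) - sl * sl / nl) + \
                ((csum2[hi] - csum2[ks]) - sr * sr / nr)
    i = int(np.argmin(rss_split))
    return int(ks[i]), float(seg_rss - rss_split[i])


def _sic_changepoints(y: np.ndarray, max_steps: int = 30,
                      penalty_factor: float = 2.0) -> list[int]:
    """Iterative changepoint insertion minimizing the Schwarz criterion.

    SIC(k) = λ·(k + 2)·ln N + N·ln(RSS/N) for a piecewise-constant fit
    with k changepoints; candidates are added greedily while the SIC
    decreases. The bare Schwarz penalty (λ = 1) is known to over-segment
    long traces — the extreme-order statistic of a spurious split grows
    like ln N too — so the penalty is inflated by ``penalty_factor``
    (the analogue of a step-finder's sensitivity setting).
    """
    n = y.size
    csum = np.concatenate([[0.0], np.cumsum(y)])
    csum2 = np.concatenate([[0.0], np.cumsum(y * y)])
    cps: list[int] = []
    rss = float(csum2[n] - csum[n] ** 2 / n)

    def sic(k: int, rss_val: float) -> float:
        v = max(rss_val / n, 1e-300)
        return penalty_factor * (k + 2) * np.log(n) + n * np.log(v)

    current = sic(0, rss)
    # ignore float-dust "reductions" once the fit is numerically exact
    tiny = 1e-12 * max(rss, n * 1e-12)
    while len(cps) < max_steps:
        bounds = [0] + sorted(cps) + [n]
        best = (-1, 0.0)
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            k, red = _best_split(y, csum, csum2, lo, hi)
            if red > best[1]:
                best = (k, red)
        if best[0] < 0 or best[1] <= tiny:
            break
        new_rss = rss - best[1]
        new_sic = sic(len(cps) + 1, new_rss)
        if new_sic >= current:
            break
        cps.append(best[0])
        rss, current = new_rss, new_sic
    return sorted(cps)


def find_steps(trace: IntensityTrace, min_dwell: int = 3,
               amp_tolerance: float = 0.60, step_snr_min: float = 2.0
               ) -> StepResult:
    """Locate bleaching steps and apply the acceptance filters.

    A trace is accepted iff the idealized staircase has every dwell ≥
    ``min_dwell`` frames, every downward step amplitude within
    ``amp_tolerance`` (fractional deviation from the *median* step
    amplitude), every step's signal-to-noise (amplitude over the pooled SD
    of the two adjacent dwells) ≥ ``step_snr_min``, no upward steps, and
    the final level is the lowest. Returns the number of downward steps or
    a rejection reason.
    """
    y = trace.values
    cps = _sic_changepoints(y)
    bounds = [0] + cps + [y.size]
    levels = np.array([y[lo:hi].mean() for lo, hi in
                       zip(bounds[:-1], bounds[1:])])
    dwells = np.diff(bounds)
    res = StepResult(step_count=None, rejection=None, changepoints=cps,
                     levels=levels)
    if len(cps) == 0:
        res.rejection = "no_steps"
        return res
    if dwells.min() < min_dwell:
        res.rejection = "dwell"
        return res
    diffs = np.diff(levels)
    if np.any(diffs > 0):
        res.rejection = "upward_step"
        return res
    amps = -diffs
    med = np.median(amps)
    if med <= 0 or np.any(np.abs(amps - med) / med > amp_tolerance):
        res.rejection = "amplitude"
        return res
    # step SNR: amplitude over pooled SD of the two adjacent dwells
    for i, k in enumerate(cps):
        lo, hi = bounds[i], bounds[i + 2]
        left = y[lo:k]
        right = y[k:hi]
        pooled_var = (left.var(ddof=0) * left.size +
                      right.var(ddof=0) * right.size) / (left.size + right.size)
        sd = np.sqrt(pooled_var)
        if sd > 0 and amps[i] / sd < step_snr_min:
            res.rejection = "snr"
            return res
    if levels[-1] > levels.min() + 1e-12:
        res.rejection = "final_level"
        return res
    res.step_count = int(len(cps))
    return res


# ---------------------------------------------------------------------------
# Histogram
# ---------------------------------------------------------------------------


@dataclass
class StepHistogram:
    """Frequency of accepted step counts x = 1..x_max."""

    counts: np.ndarray          # counts[x-1] = spots with x steps
    total_accepted: int
    rejected_by_reason: dict = field(default_factory=dict)
    is_empty: bool = False

    @property
    def x(self) -> np.ndarray:
        return np.arange(1, self.counts.size + 1)

    @classmethod
    def from_step_counts(cls, steps, x_max: int | None = None
                         ) -> "StepHistogram":
        steps = np.asarray([s for s in steps if s >= 1], dtype=int)
        if steps.size == 0:
            return cls(counts=np.zeros(0, dtype=int), total_accepted=0,
                       is_empty=True)
        if x_max is None:
            x_max = int(steps.max())
        counts = np.bincount(steps, minlength=x_max + 1)[1:x_max + 1]
        return cls(counts=counts, total_accepted=int(counts.sum()))


def build_histogram(spots: list[SpotRecord], min_accept_fraction: float = 0.10
                    ) -> StepHistogram:
    """Aggregate accepted step counts, gating fields by acceptance rate.

    Spots are grouped by ``field_id`` (cell / field of view); fields whose
    fraction of accepted traces is below ``min_accept_fraction`` are
    dropped entirely before aggregation.
    """
    fields: dict[str, list[SpotRecord]] = {}
    for s in spots:
        fields.setdefault(s.field_id, []).append(s)
    kept: list[int] = []
    rejected: dict[str, int] = {}
    for fid, members in fields.items():
        n_acc = sum(1 for s in members if s.accepted)
        if len(members) == 0 or n_acc / len(members) < min_accept_fraction:
            logger.info("field %s dropped: %d/%d accepted", fid, n_acc,
                        len(members))
            continue
        for s in members:
            if s.accepted:
                kept.append(s.step_count)
            elif s.rejection:
                rejected[s.rejection] = rejected.get(s.rejection, 0) + 1
    hist = StepHistogram.from_step_counts(kept)
    hist.rejected_by_reason = rejected
    if hist.is_empty:
        logger.warning("all fields dropped; histogram is empty")
    return hist


# ---------------------------------------------------------------------------
# Binomial mixture fitting
# ---------------------------------------------------------------------------


@dataclass
class BinomialModel:
    """Binomial step-count mixture with fitted/fixed parameters.

    With ``het`` None this is the single-population two-binomial model
    (homomers of order n, overlap fraction 1−A); with ``het`` set it is
    the homo/heteromer mixture with homomer fraction H.
    """

    n: int = 5
    p_m: float = 0.5
    A: float = 0.9
    H: float = 1.0
    het: int | None = None
    free: tuple[str, ...] = ("p_m", "A")
    chi2: float = np.nan
    p_value: float = np.nan
    dof: int = 0
    param_sd: dict = field(default_factory=dict)
    truncate_zero: bool = True

    def pmf(self, x: np.ndarray) -> np.ndarray:
        if self.het is None:
            p = binomial_step_pmf(x, self.p_m, self.A, self.n)
        else:
            p = heteromer_step_pmf(x, self.H, self.p_m, self.A, self.n,
                                   self.het)
        return np.asarray(p)

    def pmf_renormalized(self, x: np.ndarray) -> np.ndarray:
        """pmf over the observable support x ≥ 1."""
        p = self.pmf(x)
        if self.truncate_zero:
            p0 = float(self.pmf(np.array([0]))[0])
            p = p / (1.0 - p0)
        return p

    @property
    def x_max(self) -> int:
        return 2 * self.n


def fit_binomial(hist: StepHistogram, model: BinomialModel) -> BinomialModel:
    """Least-squares fit of a binomial step-count mixture to a histogram.

    Expected counts are total × pmf (renormalized over x ≥ 1 when
    ``model.truncate_zero``). The parameters named in ``model.free``
    (subset of {"p_m", "A", "H"}) are fitted within [0, 1]; the rest are
    fixed at the values carried by ``model``. χ² is computed over occupied
    bins with dof = occupied − n_free − 1.
    """
    if hist.is_empty or hist.total_accepted == 0:
        raise ValueError("cannot fit an empty histogram")
    free = list(model.free)
    for name in free:
        if name not in ("p_m", "A", "H"):
            raise ValueError(f"unknown free parameter {name!r}")
    x = np.arange(1, max(model.x_max, hist.counts.size) + 1)
    obs = np.zeros(x.size)
    obs[:hist.counts.size] = hist.counts
    total = hist.total_accepted
    occupied = int((obs > 0).sum())
    if len(free) >= occupied:
        raise ValueError("free parameters must be fewer than occupied bins")

    def expected(theta: np.ndarray) -> np.ndarray:
        m = BinomialModel(n=model.n, p_m=model.p_m, A=model.A, H=model.H,
                          het=model.het, truncate_zero=model.truncate_zero)
        for name, v in zip(free, theta):
            setattr(m, name, float(v))
        return total * m.pmf_renormalized(x)

    theta0 = np.array([np.clip(getattr(model, name), 0.05, 0.95)
                       for name in free])
    if free:
        res = optimize.least_squares(
            lambda th: expected(th) - obs, theta0, bounds=(0.0, 1.0),
            xtol=1e-12, ftol=1e-12)
        theta = res.x
        # 1σ from the Gauss-Newton approximation
        try:
            jtj = res.jac.T @ res.jac
            dof_ls = max(x.size - len(free), 1)
            cov = np.linalg.inv(jtj) * 2 * res.cost / dof_ls
            sds = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            sds = np.full(len(free), np.nan)
    else:
        theta = theta0[:0]
        sds = theta

    fitted = BinomialModel(n=model.n, p_m=model.p_m, A=model.A, H=model.H,
                           het=model.het, free=tuple(free),
                           truncate_zero=model.truncate_zero)
    for name, v, sd in zip(free, theta, sds):
        setattr(fitted, name, float(v))
        fitted.param_sd[name] = float(sd)

    exp = total * fitted.pmf_renormalized(x)
    occ = obs > 0
    chi2 = float(np.sum((obs[occ] - exp[occ]) ** 2 / exp[occ]))
    dof = occupied - len(free) - 1
    fitted.chi2 = chi2
    fitted.dof = dof
    fitted.p_value = float(stats.chi2.sf(chi2, dof)) if dof > 0 else np.nan
    return fitted


def scan_heteromer_orders(hist: StepHistogram, p_m: float, A: float,
                          n: int = 5, orders: tuple[int, ...] = (1, 2, 3, 4)
                          ) -> list[BinomialModel]:
    """Fit the homo/heteromer mixture for each candidate labeled order.

    p_m and A are held fixed (taken from the homomer experiment); only the
    homomer fraction H is fitted per order. Results are returned ranked by
    χ² goodness-of-fit p-value, best first.
    """
    fits = []
    for het in orders:
        spec = BinomialModel(n=n, p_m=p_m, A=A, H=0.5, het=het, free=("H",))
        fits.append(fit_binomial(hist, spec))
    return sorted(fits, key=lambda m: (np.isnan(m.p_value), -m.p_value))
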