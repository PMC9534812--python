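import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pentafluct import (BinomialModel, ImageSeries, IntensityTrace,
                        StepHistogram, binomial_step_pmf, build_histogram,
                        detect_spots, find_steps, fit_binomial,
                        heteromer_step_pmf, scan_heteromer_orders)
from pentafluct.experiments import draw_step_counts
from pentafluct.stepcount import SpotRecord


def staircase(levels, dwells, noise_sd=0.0, rng=None):
    vals = np.concatenate([np.full(d, lv) for lv, d in zip(levels, dwells)])
    if noise_sd and rng is not None:
        vals = vals + rng.normal(0, noise_sd, vals.size)
    return IntensityTrace(values=vals, frame_interval=0.1)


class TestFindSteps:
    @pytest.mark.parametrize("n_steps", [1, 2, 3, 5, 8])
    def test_noiseless_staircase_exact(self, n_steps):
        levels = list(range(n_steps, -1, -1))
        dwells = [5] * (n_steps + 1)
        res = find_steps(staircase(levels, dwells))
        assert res.accepted and res.step_count == n_steps

    def test_noiseless_exact_for_all_dwells_at_least_min(self, rng):
        for trial in range(10):
            g = np.random.default_rng(trial)
            n = int(g.integers(1, 7))
            dwells = g.integers(3, 12, n + 1)
            amps = g.uniform(0.5, 2.0, n)          # resolvable step sizes
            levels = np.concatenate([[amps.sum()], amps.sum() -
                                     np.cumsum(amps)])
            res = find_steps(staircase(levels, dwells), amp_tolerance=10.0,
                             step_snr_min=0.0)
            assert res.step_count == n

    def test_two_frame_dwell_rejected(self):
        res = find_steps(staircase([3, 2, 1, 0], [5, 2, 5, 5]))
        assert res.rejection == "dwell"

    def test_oversized_step_amplitude_rejected(self):
        # one step 2.2× the median amplitude violates the 60% rule
        res = find_steps(staircase([4.2, 2.0, 1.0, 0.0], [5, 5, 5, 5]))
        assert res.rejection == "amplitude"

    def test_upward_step_rejected(self):
        res = find_steps(staircase([2.0, 1.0, 1.9, 0.1], [6, 6, 6, 6]),
                         amp_tolerance=10.0)
        assert res.rejection in ("upward_step", "amplitude", "final_level")

    def test_low_snr_step_rejected(self, rng):
        tr = staircase([1.0, 0.0], [30, 30], noise_sd=1.0, rng=rng)
        res = find_steps(tr, step_snr_min=2.0)
        assert not res.accepted

    def test_flat_trace_has_no_steps(self, rng):
        tr = staircase([1.0], [60], noise_sd=0.05, rng=rng)
        res = find_steps(tr)
        assert res.rejection == "no_steps"

    def test_noisy_staircase_recovered(self, rng):
        tr = staircase([3.0, 2.0, 1.0, 0.0], [20, 20, 20, 20],
                       noise_sd=0.08, rng=rng)
        res = find_steps(tr)
        assert res.accepted and res.step_count == 3


def psf_spot(frame, r, c, amp=50.0, sigma=1.2):
    y, x = np.mgrid[:frame.shape[0], :frame.shape[1]]
    frame += amp * np.exp(-((y - r) ** 2 + (x - c) ** 2) / (2 * sigma ** 2))


class TestDetectSpots:
    def make_series(self, centers, rng, shape=(48, 48), n_frames=12,
                    geometry=None):
        from conftest import make_series as mk
        geometry = geometry or mk(rng).geometry
        from pentafluct import AcquisitionGeometry
        geom = AcquisitionGeometry(pixel_size=0.15, focal_waist=0.3,
                                   modality="camera", frame_time=0.08)
        data = 10.0 + rng.standard_normal((n_frames, *shape)) * 0.3
        for f in range(n_frames):
            for (r, c) in centers:
                psf_spot(data[f], r, c)
        return ImageSeries(data=[data], geometry=geom)

    def test_blank_noise_yields_no_spots(self, rng):
        series = self.make_series([], rng)
        assert detect_spots(series) == []

    def test_two_separated_spots_found_at_centers(self, rng):
        series = self.make_series([(15, 15), (15, 25)], rng)
        spots = detect_spots(series)
        assert len(spots) == 2
        found = sorted(s.center for s in spots)
        for (fr, fc), (tr, tc) in zip(found, [(15, 15), (15, 25)]):
            assert abs(fr - tr) <= 1 and abs(fc - tc) <= 1

    def test_overlapping_spots_all_discarded(self, rng):
        series = self.make_series([(20, 20), (20, 23)], rng)
        assert detect_spots(series) == []

    def test_trace_is_3x3_sum(self, rng):
        series = self.make_series([(20, 20)], rng)
        spots = detect_spots(series)
        assert len(spots) == 1
        r, c = spots[0].center
        expected = series.channel(0)[:, r - 1:r + 2, c - 1:c + 2].sum(
            axis=(1, 2))
        np.testing.assert_allclose(spots[0].trace.values, expected)


class TestBuildHistogram:
    def spot(self, steps, field="f0", reject=None):
        tr = IntensityTrace(values=np.zeros(4), frame_interval=0.1)
        return SpotRecord(center=(0, 0), trace=tr, field_id=field,
                          step_count=steps, rejection=reject)

    def test_low_acceptance_field_dropped(self):
        spots = [self.spot(3)] * 5 + [self.spot(None, reject="dwell")] * 95
        hist = build_histogram(spots)
        assert hist.is_empty

    def test_half_accepted_field_included(self):
        spots = [self.spot(2)] * 50 + [self.spot(None, reject="snr")] * 50
        hist = build_histogram(spots)
        assert hist.total_accepted == 50
        assert hist.counts[1] == 50

    def test_aggregation_is_additive_over_fields(self):
        f1 = [self.spot(1, "a")] * 10 + [self.spot(4, "a")] * 5
        f2 = [self.spot(4, "b")] * 7
        hist = build_histogram(f1 + f2)
        h1 = build_histogram(f1)
        h2 = build_histogram(f2)
        n = max(h1.counts.size, h2.counts.size)
        summed = (np.pad(h1.counts, (0, n - h1.counts.size)) +
                  np.pad(h2.counts, (0, n - h2.counts.size)))
        np.testing.assert_array_equal(hist.counts[:n], summed)


class TestStepPmf:
    def test_full_maturation_single_complex_is_deterministic(self):
        xs = np.arange(0, 11)
        p = binomial_step_pmf(xs, p_m=1.0, A=1.0, n=5)
        assert p[5] == pytest.approx(1.0)
        assert p.sum() == pytest.approx(1.0)
        assert np.all(p[np.arange(11) != 5] < 1e-12)

    def test_half_maturation_zero_bin(self):
        # C(5,0)·0.5⁵ = 0.03125
        assert binomial_step_pmf(np.array([0]), 0.5, 1.0)[0] == \
            pytest.approx(0.03125)

    def test_double_complex_tail_bin(self):
        # x=10 only reachable via the two-complex branch:
        # (1−A)·C(10,10)·0.5¹⁰ with A=0.5 → 0.5·0.5¹⁰ ≈ 4.883e-4
        val = binomial_step_pmf(np.array([10]), 0.5, 0.5)[0]
        assert val == pytest.approx(0.5 * 0.5 ** 10, rel=1e-9)
        assert val == pytest.approx(4.883e-4, rel=1e-3)

    @given(p_m=st.floats(0.05, 1.0), A=st.floats(0.0, 1.0),
           H=st.floats(0.0, 1.0), het=st.integers(1, 5))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_pmfs_normalized_over_support(self, p_m, A, H, het):
        xs = np.arange(0, 11)
        assert binomial_step_pmf(xs, p_m, A).sum() == pytest.approx(1.0)
        assert heteromer_step_pmf(xs, H, p_m, A, 5, het).sum() == \
            pytest.approx(1.0)


class TestFitBinomial:
    @pytest.mark.parametrize("p_m,A", [(0.47, 0.88), (0.6, 0.75),
                                       (0.8, 0.95), (0.35, 0.85)])
    def test_parameter_recovery_within_monte_carlo_error(self, p_m, A):
        # Monte-Carlo SD estimated from repeated draws at the same truth
        n_spots, reps = 400, 12
        fits = []
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            x = draw_step_counts(n_spots, rng, p_m=p_m, A=A)
            hist = StepHistogram.from_step_counts(x, x_max=10)
            m = fit_binomial(hist, BinomialModel(n=5, free=("p_m", "A")))
            fits.append((m.p_m, m.A))
        fits = np.array(fits)
        for truth, col in ((p_m, 0), (A, 1)):
            sd = fits[:, col].std(ddof=1)
            assert abs(fits[:, col].mean() - truth) < 3 * max(sd, 0.01)

    def test_true_heteromer_order_wins_plurality(self):
        # neighbouring orders fit almost as well (the expected χ² advantage
        # of the true order is ~1), so require a plurality, not a majority
        rng = np.random.default_rng(0)
        wins = {1: 0, 2: 0, 3: 0, 4: 0}
        for _ in range(40):
            x = draw_step_counts(300, rng, p_m=0.47, A=0.88, H=0.64, het=3)
            hist = StepHistogram.from_step_counts(x, x_max=10)
            fits = scan_heteromer_orders(hist, p_m=0.47, A=0.88)
            wins[fits[0].het] += 1
        assert wins[3] == max(wins.values())

    def test_empty_histogram_rejected(self):
        hist = StepHistogram.from_step_counts([])
        with pytest.raises(ValueError, match="empty"):
            fit_binomial(hist, BinomialModel())

    def test_too_many_free_parameters_rejected(self):
        hist = StepHistogram.from_step_counts([2, 3])
        with pytest.raises(ValueError, match="free parameters"):
            fit_binomial(hist, BinomialModel(het=3, free=("p_m", "A", "H")))

    def test_chi2_pvalue_reasonable_for_true_model(self):
        rng = np.random.default_rng(5)
        x = draw_step_counts(477, rng, p_m=0.47, A=0.88)
        hist = StepHistogram.from_step_counts(x, x_max=10)
        m = fit_binomial(hist, BinomialModel(n=5, free=("p_m", "A")))
        assert m.p_value > 0.05
        assert m.dof == int((np.pad(hist.counts, (0, 0)) > 0).sum()) - 3


class TestClosedLoopTraces:
    def test_noiseless_traces_counted_exactly_when_accepted(self):
        from pentafluct import BleachSimParams, simulate_bleach_traces
        params = BleachSimParams(maturation_prob=0.6, noise_sd=0.0,
                                 mean_bleach_frames=40, trace_length=400)
        traces, truth = simulate_bleach_traces(params, 60, seed=3)
        n_acc = 0
        for tr, t in zip(traces, truth):
            res = find_steps(tr)
            if res.accepted:
                n_acc += 1
                assert res.step_count == t
        assert n_acc >= 15      # a healthy fraction passes the filters
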