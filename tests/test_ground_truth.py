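"""Juxtacellular spike detection, triggered averaging, footprints,
amplitude-distance analysis and propagation velocity."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import pairedval as pv
from pairedval.ground_truth import (
    JTAResult,
    SpikeTrain,
    amplitude_distance_curve,
    compute_jta,
    detect_juxta_spikes,
    fit_amplitude_decay,
    interpolate_footprint,
    p2p_footprint,
    propagation_velocity,
)
from pairedval.probe_io import PairMetadata
from pairedval.signal import ANALYSIS_BAND, bandpass_filtfilt
from pairedval.synth import (
    DECAY_LAMBDA_UM,
    NeuronSpec,
    SynthConfig,
    amplitude_at_distance,
    make_template,
)

FS = 30000.0


def inject(trace, template, times, peak_offset):
    for t in times:
        s = t - peak_offset
        trace[s : s + len(template)] += template
    return trace


class TestDetectJuxtaSpikes:
    def test_flat_trace_empty_train(self):
        train = detect_juxta_spikes(np.zeros(10000), 1.0, FS)
        assert len(train) == 0

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            detect_juxta_spikes(np.array([]), 1.0, FS)

    def test_injected_templates_found_at_peaks(self):
        rng = np.random.default_rng(0)
        tmpl = make_template("biphasic-positive-first", 3.0, FS) * 4.0  # ~4 mV p2p
        peak = int(np.argmax(tmpl))
        trace = rng.normal(0, 0.05, size=int(FS))
        true = np.arange(10) * 2800 + 1500
        inject(trace, tmpl, true, peak)
        train = detect_juxta_spikes(trace, 1.0, FS)
        assert len(train) == 10
        assert np.all(np.abs(train.times - true) <= 1)

    def test_negative_first_polarity_aligns_on_minimum(self):
        tmpl = make_template("biphasic-negative-first", 3.0, FS) * 2.0
        trough = int(np.argmin(tmpl))
        trace = np.zeros(30000)
        inject(trace, tmpl, [10000], trough)
        train = detect_juxta_spikes(trace, 0.5, FS, polarity="negative-first")
        assert list(train.times) == [10000]

    def test_close_peaks_both_rejected(self):
        trace = np.zeros(30000)
        for t in (10000, 10015):  # 0.5 ms apart
            trace[t - 3 : t + 4] = 2.0
            trace[t] = 3.0
        trace[10007] = 0.0  # separate the two excursions
        train = detect_juxta_spikes(trace, 1.0, FS, isolation_ms=1.0)
        assert len(train) == 0

    def test_isolated_pair_far_apart_both_kept(self):
        trace = np.zeros(30000)
        for t in (10000, 10090):  # 3 ms apart
            trace[t] = 3.0
        train = detect_juxta_spikes(trace, 1.0, FS, isolation_ms=1.0)
        assert list(train.times) == [10000, 10090]


class TestComputeJTA:
    def make_scene(self, n_events, noise_sd, seed=0, n_ch=4):
        rng = np.random.default_rng(seed)
        tmpl = make_template("biphasic-negative-first", 2.0, FS) * 50.0
        half = int(round(2e-3 * FS))
        spacing = 4 * half
        times = (np.arange(n_events) + 1) * spacing
        n = int(times[-1] + spacing)
        extra = rng.normal(0, noise_sd, size=(n_ch, n)) if noise_sd else np.zeros((n_ch, n))
        window = np.zeros(2 * half + 1)
        lo = half - len(tmpl) // 2
        window[lo : lo + len(tmpl)] = tmpl
        for ch in range(n_ch):
            for t in times:
                extra[ch, t - half : t + half + 1] += window
        return extra, SpikeTrain(times, FS), window

    def test_zero_noise_average_equals_template(self):
        extra, spikes, window = self.make_scene(200, 0.0)
        jta = compute_jta(extra, spikes)
        assert jta.n_events == 200
        for ch in range(extra.shape[0]):
            assert jta.waveforms[ch] == pytest.approx(window, abs=1e-9)

    def test_noise_shrinks_as_standard_error(self):
        devs = []
        for seed in range(20):
            extra, spikes, window = self.make_scene(100, 5.0, seed=seed, n_ch=1)
            jta = compute_jta(extra, spikes)
            devs.append(np.sqrt(np.mean((jta.waveforms[0] - window) ** 2)))
        assert np.mean(devs) <= 1.5 * 5.0 / np.sqrt(100)

    def test_single_event_is_verbatim_window(self):
        extra, spikes, _ = self.make_scene(3, 2.0)
        one = SpikeTrain(spikes.times[:1], FS)
        jta = compute_jta(extra, one)
        half = jta.center
        t = one.times[0]
        assert jta.waveforms == pytest.approx(
            extra[:, t - half : t + half + 1]
        )

    def test_edge_events_excluded_and_counted(self):
        extra, spikes, _ = self.make_scene(10, 0.0)
        times = np.r_[5, spikes.times, extra.shape[1] - 5]
        jta = compute_jta(extra, SpikeTrain(times, FS))
        assert jta.n_events == 10
        assert jta.n_excluded == 2

    def test_no_includable_event_rejected(self):
        with pytest.raises(ValueError, match="window"):
            compute_jta(np.zeros((2, 200)), SpikeTrain([5], FS))

    def test_jta_linear_in_noise_convergence(self):
        # averaging noise away: deviation from the clean JTA falls ~1/sqrt(n)
        extra, spikes, window = self.make_scene(400, 8.0, seed=1, n_ch=1)
        errs = {}
        for n in (10, 100, 400):
            jta = compute_jta(extra, SpikeTrain(spikes.times[:n], FS))
            errs[n] = np.sqrt(np.mean((jta.waveforms[0] - window) ** 2))
        assert errs[400] < errs[100] < errs[10]


class TestP2PFootprint:
    def make_jta(self, waveforms):
        return JTAResult(waveforms=waveforms, n_events=1, rate_hz=FS)

    def test_zero_jta_zero_amplitudes(self):
        jta = self.make_jta(np.zeros((5, 121)))
        assert p2p_footprint(jta) == pytest.approx(np.zeros(5))

    def test_sine_cycle_gives_twice_amplitude(self):
        wf = np.zeros((2, 121))
        t = np.arange(30)
        wf[1, 45:75] = 3.0 * np.sin(2 * np.pi * t / 30)
        jta = self.make_jta(wf)
        p2p = p2p_footprint(jta)
        assert p2p[0] == 0.0
        assert p2p[1] == pytest.approx(6.0, rel=0.01)

    def test_trough_outside_window_excluded(self):
        wf = np.zeros((1, 121))
        center = 60
        wf[0, center] = 5.0  # in-window peak
        wf[0, center + 45] = -20.0  # trough at +1.5 ms
        jta = self.make_jta(wf)
        assert p2p_footprint(jta, window_ms=1.0)[0] == pytest.approx(5.0)
        assert wf[0].max() - wf[0].min() == pytest.approx(25.0)

    def test_window_larger_than_stored_rejected(self):
        jta = self.make_jta(np.zeros((1, 61)))  # +/-1 ms stored
        with pytest.raises(ValueError, match="exceeds"):
            p2p_footprint(jta, window_ms=2.0)

    def test_offset_invariance_and_scaling(self):
        rng = np.random.default_rng(4)
        wf = rng.normal(size=(3, 121))
        base = p2p_footprint(self.make_jta(wf))
        shifted = p2p_footprint(self.make_jta(wf + 7.5))
        scaled = p2p_footprint(self.make_jta(wf * 3.0))
        assert shifted == pytest.approx(base, abs=1e-12)
        assert scaled == pytest.approx(3.0 * base, rel=1e-12)


class TestFootprintInterpolation:
    def test_uniform_amplitudes_uniform_map(self, poly3):
        fp = interpolate_footprint(np.full(32, 7.0), poly3, resolution_um=5.0)
        inside = fp.values_uv[~np.isnan(fp.values_uv)]
        assert inside == pytest.approx(7.0)

    def test_linear_field_reproduced(self, poly3):
        amps = 0.1 * poly3.site_xz_um[:, 1] + 2.0
        fp = interpolate_footprint(amps, poly3, resolution_um=5.0)
        zz = np.broadcast_to(fp.grid_z_um[:, None], fp.values_uv.shape)
        expected = 0.1 * zz + 2.0
        mask = ~np.isnan(fp.values_uv)
        assert fp.values_uv[mask] == pytest.approx(expected[mask], rel=1e-6)

    def test_exact_at_sites(self, poly3):
        rng = np.random.default_rng(5)
        amps = rng.uniform(1, 50, size=32)
        fp = interpolate_footprint(amps, poly3)
        from scipy.interpolate import LinearNDInterpolator

        interp = LinearNDInterpolator(fp.site_xz_um, fp.site_amplitudes_uv)
        at_sites = interp(poly3.site_xz_um)
        assert at_sites == pytest.approx(amps, rel=1e-9)

    def test_collinear_sites_rejected(self):
        from pairedval.probe_io import ProbeGeometry

        line = ProbeGeometry(
            site_ids=np.arange(4),
            site_xz_um=[(0, 25.0 * k) for k in range(4)],
            site_area_um2=100.0,
        )
        with pytest.raises(ValueError, match="triangulate"):
            interpolate_footprint(np.ones(4), line)


def _cohort_points(distances, duration_s=12.0, rate_hz=8.0, noise_sd=5.0):
    """One synthetic pair per distance; JTA computed through the full chain."""
    geometry = pv.make_probe_32ch_poly3()
    points = []
    for i, d in enumerate(distances):
        target = NeuronSpec(
            position_um=(0.0, float(d), 125.0), rate_hz=rate_hz,
            is_juxta_target=True,
        )
        cfg = SynthConfig(
            geometry=geometry,
            duration_s=duration_s,
            noise_sd_uv=noise_sd,
            neurons=[target],
            seed=100 + i,
            pair_id=f"synth_{i}",
        )
        bundle = pv.generate_pair(cfg)
        extra = bandpass_filtfilt(bundle.extracellular_uv, ANALYSIS_BAND, FS)
        jta = compute_jta(extra, bundle.juxta_spikes)
        points.append((bundle.metadata, jta))
    return amplitude_distance_curve(points)


@pytest.fixture(scope="module")
def cohort():
    distances = np.r_[48.0, np.linspace(20.0, 200.0, 19)]
    return _cohort_points(distances)


class TestAmplitudeDistance:
    def test_sub_floor_pair_flagged(self):
        jta = JTAResult(waveforms=np.zeros((2, 121)), n_events=5, rate_hz=FS)
        jta.waveforms[0, 60] = 3.0
        jta.p2p_uv = p2p_footprint(jta)
        meta = PairMetadata("far", 250.0, 1000.0, 1.0)
        (pt,) = amplitude_distance_curve([(meta, jta)])
        assert pt.artifact_flagged
        assert pt.max_p2p_uv == pytest.approx(3.0)

    def test_amplitude_decreases_with_distance(self, cohort):
        d = [p.distance_um for p in cohort]
        a = [p.max_p2p_uv for p in cohort]
        rho = spearmanr(d, a).statistic
        assert rho < -0.8

    def test_near_neuron_beats_all_beyond_150um(self, cohort):
        near = [p for p in cohort if abs(p.distance_um - 48.0) < 1.0]
        far = [p for p in cohort if p.distance_um > 150.0]
        assert near and far
        assert near[0].max_p2p_uv > max(p.max_p2p_uv for p in far)

    def test_decay_constant_recovered(self, cohort):
        _, lam, _ = fit_amplitude_decay(cohort)
        assert lam == pytest.approx(DECAY_LAMBDA_UM, rel=0.15)

    def test_points_sorted_by_distance(self, cohort):
        d = [p.distance_um for p in cohort]
        assert d == sorted(d)


class TestPropagationVelocity:
    def make_jta_with_delay(self, geometry, site_a, site_b, delay_ms,
                            center_offset_ms=-0.25):
        n = 121  # +/-2 ms at 30 kHz
        t_ms = (np.arange(n) - n // 2) / FS * 1000.0
        wf = np.zeros((geometry.n_sites, n))
        ia, ib = geometry.site_index(site_a), geometry.site_index(site_b)
        wf[ia] = -np.exp(-0.5 * ((t_ms - center_offset_ms) / 0.15) ** 2)
        wf[ib] = -np.exp(
            -0.5 * ((t_ms - center_offset_ms - delay_ms) / 0.15) ** 2
        )
        return JTAResult(waveforms=wf, n_events=1, rate_hz=FS)

    def test_full_span_half_ms_delay(self, poly3):
        # center column ends are 275 um apart (sites 0 and 11)
        jta = self.make_jta_with_delay(poly3, 0, 11, 0.5)
        v = propagation_velocity(jta, 0, 11, poly3)
        assert v == pytest.approx(0.55, rel=1e-3)

    def test_antisymmetric_under_site_swap(self, poly3):
        jta = self.make_jta_with_delay(poly3, 0, 11, 0.5)
        assert propagation_velocity(jta, 11, 0, poly3) == pytest.approx(
            -propagation_velocity(jta, 0, 11, poly3)
        )

    def test_zero_delay_rejected(self, poly3):
        jta = self.make_jta_with_delay(poly3, 0, 11, 0.0)
        with pytest.raises(ValueError, match="undefined"):
            propagation_velocity(jta, 0, 11, poly3)

    def test_no_negative_peak_rejected(self, poly3):
        jta = JTAResult(waveforms=np.ones((32, 121)), n_events=1, rate_hz=FS)
        with pytest.raises(ValueError, match="negative deflection"):
            propagation_velocity(jta, 0, 11, poly3)

    def test_synthetic_propagation_speed_recovered(self, poly3):
        # literature-scale backpropagation speed programmed into the generator
        v_true = 0.67
        target = NeuronSpec(
            position_um=(0.0, 30.0, 0.0), rate_hz=5.0,
            velocity_m_s=v_true, is_juxta_target=True,
        )
        cfg = SynthConfig(
            geometry=poly3, duration_s=5.0, noise_sd_uv=0.0,
            neurons=[target], juxta_noise_sd_mv=0.0, seed=2,
        )
        bundle = pv.generate_pair(cfg)
        jta = compute_jta(bundle.extracellular_uv, bundle.juxta_spikes)
        v = propagation_velocity(jta, 0, 11, poly3, core_window_ms=2.0)
        dist_m = 275e-6
        assert abs(dist_m / v - dist_m / v_true) <= 1.0 / FS
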