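"""Action-potential propagation speed from inter-site peak delays.

Two computations: the textbook worked example (negative peaks 0.5 ms apart
on sites spanning the probe's full 275 um axial extent), and recovery of a
programmed backpropagation velocity from a synthetic pair's JTA.
"""

import numpy as np

import pairedval as pv
from pairedval.ground_truth import JTAResult, compute_jta, propagation_velocity

FS = 30000.0
probe = pv.make_probe_32ch_poly3()

# worked example: 275 um span, 0.5 ms delay
n = 121
t_ms = (np.arange(n) - n // 2) / FS * 1000.0
wf = np.zeros((probe.n_sites, n))
wf[probe.site_index(0)] = -np.exp(-0.5 * ((t_ms + 0.25) / 0.15) ** 2)
wf[probe.site_index(11)] = -np.exp(-0.5 * ((t_ms - 0.25) / 0.15) ** 2)
jta = JTAResult(waveforms=wf, n_events=1, rate_hz=FS)
v = propagation_velocity(jta, 0, 11, probe)
print(f"275 um span / 0.5 ms delay -> {v:.2f} m/s")

# generator round-trip at a literature-scale speed
v_true = 0.67
target = pv.NeuronSpec(
    position_um=(0.0, 30.0, 0.0), rate_hz=5.0, velocity_m_s=v_true,
    is_juxta_target=True,
)
config = pv.SynthConfig(
    geometry=probe, duration_s=5.0, noise_sd_uv=0.0, neurons=[target],
    juxta_noise_sd_mv=0.0, seed=2,
)
bundle = pv.generate_pair(config)
jta2 = compute_jta(bundle.extracellular_uv, bundle.juxta_spikes)
v2 = propagation_velocity(jta2, 0, 11, probe, core_window_ms=2.0)
print(f"programmed {v_true} m/s, recovered {v2:.2f} m/s")

# Sub-sample (parabolic) peak interpolation matters here: at 30 kHz one
# sample of delay quantization across 275 um would shift the estimate by
# ~0.04 m/s.
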