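"""Seeded generator of synthetic paired recordings with known ground truth.

The generator emulates the statistics of a paired juxtacellular /
extracellular recording in anesthetized rat cortex:

* the juxtacellular trace carries large (~4 mV peak-to-peak) biphasic
  positive-before-negative spikes from a single target neuron firing at
  ~1 Hz,
* each neuron's extracellular action potential is a propagating template
  whose per-site amplitude decays exponentially with distance from the
  site — calibrated so a neuron 50 um away leaves 38 uV and one 150 um away
  only 5 uV,
* background units fire as independent Poisson processes, noise is white
  Gaussian, and an optional sub-5-uV cross-talk artifact (a scaled copy of
  the juxtacellular waveform, identical on every channel) can be mixed in.

All randomness flows from one seed through named substreams (spike times,
noise, placement), so any component can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coreg import (
    AffineCorrection,
    CalibrationPair,
    ManipulatorReading,
    Position3D,
    calibration_grid,
    reference_to_tilt,
)
from .ground_truth import SpikeTrain
from .probe_io import (
    DEFAULT_SCALE_UV_PER_BIT,
    PairMetadata,
    ProbeGeometry,
    RawRecording,
)

__all__ = [
    "NeuronSpec",
    "SynthConfig",
    "GroundTruthBundle",
    "amplitude_at_distance",
    "DECAY_LAMBDA_UM",
    "DECAY_A0_UV",
    "make_template",
    "generate_pair",
    "generate_calibration_scene",
    "random_misalignment",
    "place_background_neurons",
]

# Exponential amplitude-distance decay A(d) = A0 * exp(-d / lambda),
# pinned to 38 uV at 50 um and 5 uV at 150 um. This two-point calibration
# is the package's model choice; the underlying observations form a scatter,
# not a fitted curve.
DECAY_LAMBDA_UM = 100.0 / np.log(38.0 / 5.0)  # ~49.3 um
DECAY_A0_UV = 38.0 * np.exp(50.0 / DECAY_LAMBDA_UM)  # ~104.8 uV

JUXTA_P2P_MV = 4.0
DEFAULT_VELOCITY_M_S = 0.55
REFRACTORY_MS = 1.0


def amplitude_at_distance(d_um) -> np.ndarray | float:
    """Peak-to-peak EAP amplitude scale (uV) at distance ``d_um`` (um)."""
    d = np.asarray(d_um, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    out = DECAY_A0_UV * np.exp(-d / DECAY_LAMBDA_UM)
    return float(out) if np.isscalar(d_um) else out


def make_template(
    shape: str, duration_ms: float = 2.0, rate_hz: float = 30000.0
) -> np.ndarray:
    """Unit peak-to-peak spike template.

    Shapes: ``"biphasic-positive-first"`` (juxtacellular loose-patch
    waveform: positive lobe then negative), ``"biphasic-negative-first"``
    (canonical extracellular somatic spike), ``"triphasic"`` (small positive,
    deep negative, recovering positive). Zero mean outside the spike core,
    peak-to-peak normalized to 1.
    """
    if duration_ms < 1.0:
        raise ValueError("template duration must be >= 1 ms")
    n = int(round(duration_ms * 1e-3 * rate_hz))
    t = (np.arange(n) - n / 2) / rate_hz * 1000.0  # ms, centered
    w_fast, w_slow = 0.12, 0.25  # lobe widths, ms

    def lobe(center_ms: float, width_ms: float) -> np.ndarray:
        return np.exp(-0.5 * ((t - center_ms) / width_ms) ** 2)

    if shape == "biphasic-positive-first":
        wave = lobe(-0.15, w_fast) - 0.7 * lobe(0.25, w_slow)
    elif shape == "biphasic-negative-first":
        wave = -lobe(-0.1, w_fast) + 0.45 * lobe(0.35, w_slow)
    elif shape == "triphasic":
        wave = 0.25 * lobe(-0.4, w_fast) - lobe(0.0, w_fast) + 0.4 * lobe(0.45, w_slow)
    else:
        raise ValueError(f"unknown template shape {shape!r}")
    p2p = wave.max() - wave.min()
    return wave / p2p


@dataclass(frozen=True)
class NeuronSpec:
    """Ground-truth parameters of one simulated neuron.

    ``position_um`` is (lateral, out-of-plane, axial) relative to the probe
    plane: the probe's sites live at out-of-plane coordinate 0.
    """

    position_um: tuple[float, float, float]
    p2p_at_soma_uv: float | None = None  # None -> amplitude_at_distance
    rate_hz: float = 1.0
    template: str = "biphasic-negative-first"
    template_duration_ms: float = 2.0
    velocity_m_s: float = DEFAULT_VELOCITY_M_S
    is_juxta_target: bool = False

    def __post_init__(self) -> None:
        if self.rate_hz < 0:
            raise ValueError("rate_hz must be non-negative")


@dataclass
class SynthConfig:
    """Full description of a synthetic paired-recording scene."""

    geometry: ProbeGeometry
    duration_s: float = 60.0
    rate_hz: float = 30000.0
    noise_sd_uv: float = 10.0
    neurons: list[NeuronSpec] = field(default_factory=list)
    crosstalk_uv: float = 0.0
    juxta_noise_sd_mv: float = 0.05
    scale_uv_per_bit: float = DEFAULT_SCALE_UV_PER_BIT
    seed: int = 0
    pair_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.noise_sd_uv < 0:
            raise ValueError("noise_sd_uv must be non-negative")
        if not 0 <= self.crosstalk_uv < 5.0:
            raise ValueError(
                "crosstalk_uv must be in [0, 5): larger common-mode artifacts "
                "are not what this generator emulates"
            )
        targets = [n for n in self.neurons if n.is_juxta_target]
        if len(targets) > 1:
            raise ValueError("at most one neuron may be the juxtacellular target")

    @property
    def target(self) -> NeuronSpec | None:
        for n in self.neurons:
            if n.is_juxta_target:
                return n
        return None


@dataclass
class GroundTruthBundle:
    """A synthetic recorded pair plus the truth needed to score analyses."""

    extracellular: RawRecording
    extracellular_uv: np.ndarray  # unquantized channels x time, uV
    juxta_mv: np.ndarray
    true_spikes: dict[int, SpikeTrain]  # neuron index -> spike train
    metadata: PairMetadata
    config: SynthConfig

    @property
    def juxta_spikes(self) -> SpikeTrain:
        idx = next(
            i for i, n in enumerate(self.config.neurons) if n.is_juxta_target
        )
        return self.true_spikes[idx]


def _substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator derived from (seed, name)."""
    tag = int.from_bytes(name.encode(), "big") % (2**32)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(tag,)))


def _poisson_refractory_times(
    rng: np.random.Generator, rate_hz: float, duration_s: float,
    fs: float, refractory_ms: float = REFRACTORY_MS,
) -> np.ndarray:
    """Poisson spike times (sample indices) with an absolute refractory period."""
    if rate_hz <= 0:
        return np.array([], dtype=np.int64)
    n_expect = int(rate_hz * duration_s * 2 + 20)
    isis = rng.exponential(1.0 / rate_hz, size=n_expect) + refractory_ms * 1e-3
    times_s = np.cumsum(isis)
    times_s = times_s[times_s < duration_s]
    return np.unique((times_s * fs).astype(np.int64))


def site_distances_um(
    geometry: ProbeGeometry, position_um: Sequence[float]
) -> np.ndarray:
    """Euclidean distance from a 3D neuron position to every probe site."""
    pos = np.asarray(position_um, dtype=float)
    sites3d = np.column_stack(
        [
            geometry.site_xz_um[:, 0],
            np.zeros(geometry.n_sites),
            geometry.site_xz_um[:, 1],
        ]
    )
    return np.linalg.norm(sites3d - pos, axis=1)


def generate_pair(config: SynthConfig) -> GroundTruthBundle:
    """Render a complete synthetic paired recording.

    Per neuron: seeded Poisson spike times (1 ms refractory); extracellular
    contribution = template scaled by ``amplitude_at_distance`` of each
    site's true distance, delayed per site by axial offset / propagation
    velocity. The juxtacellular trace is the positive-first biphasic
    template scaled to ~4 mV peak-to-peak at the target's spike times plus
    Gaussian noise. Bit-identical for identical configs.
    """
    fs = config.rate_hz
    n_t = int(round(config.duration_s * fs))
    n_ch = config.geometry.n_sites
    extra = np.zeros((n_ch, n_t))

    spike_rng = _substream(config.seed, "spikes")
    noise_rng = _substream(config.seed, "noise")

    true_spikes: dict[int, SpikeTrain] = {}
    for i, neuron in enumerate(config.neurons):
        times = _poisson_refractory_times(spike_rng, neuron.rate_hz,
                                          config.duration_s, fs)
        true_spikes[i] = SpikeTrain(times, fs, polarity="positive-first")
        if times.size == 0:
            continue
        template = make_template(neuron.template, neuron.template_duration_ms, fs)
        dists = site_distances_um(config.geometry, neuron.position_um)
        if neuron.p2p_at_soma_uv is None:
            amps = amplitude_at_distance(dists)
        else:
            amps = neuron.p2p_at_soma_uv * np.exp(
                -(dists - dists.min()) / DECAY_LAMBDA_UM
            )
        axial = config.geometry.site_xz_um[:, 1]
        delays_s = (axial - neuron.position_um[2]) * 1e-6 / neuron.velocity_m_s
        delay_samples = np.round(delays_s * fs).astype(int)
        n_tmpl = len(template)
        for ch in range(n_ch):
            starts = times - n_tmpl // 2 + delay_samples[ch]
            wave = template * amps[ch]
            for s in starts:
                lo, hi = max(s, 0), min(s + n_tmpl, n_t)
                if lo >= hi:
                    continue
                extra[ch, lo:hi] += wave[lo - s : hi - s]

    if config.noise_sd_uv > 0:
        extra += noise_rng.normal(0.0, config.noise_sd_uv, size=extra.shape)

    # juxtacellular channel
    juxta = np.zeros(n_t)
    target = config.target
    distance_um = float("nan")
    if target is not None:
        t_idx = next(
            i for i, n in enumerate(config.neurons) if n.is_juxta_target
        )
        jt = make_template("biphasic-positive-first", 3.0, fs) * JUXTA_P2P_MV
        n_tmpl = len(jt)
        # align template so its positive peak sits exactly on the spike time
        peak_off = int(np.argmax(jt))
        for s0 in true_spikes[t_idx].times:
            s = s0 - peak_off
            lo, hi = max(s, 0), min(s + n_tmpl, n_t)
            if lo >= hi:
                continue
            juxta[lo:hi] += jt[lo - s : hi - s]
        if config.crosstalk_uv > 0:
            # common-mode copy of the juxta waveform on every channel
            xt = jt / (jt.max() - jt.min()) * config.crosstalk_uv
            for s0 in true_spikes[t_idx].times:
                s = s0 - peak_off
                lo, hi = max(s, 0), min(s + n_tmpl, n_t)
                if lo >= hi:
                    continue
                extra[:, lo:hi] += xt[lo - s : hi - s]
        distance_um = float(
            site_distances_um(config.geometry, target.position_um).min()
        )
    if config.juxta_noise_sd_mv > 0:
        juxta += noise_rng.normal(0.0, config.juxta_noise_sd_mv, size=n_t)

    quantized = np.clip(
        np.round(extra / config.scale_uv_per_bit), -32768, 32767
    ).astype(np.int16)
    recording = RawRecording(
        samples=quantized,
        scale_uv_per_bit=config.scale_uv_per_bit,
        rate_hz=fs,
    )
    metadata = PairMetadata(
        pair_id=config.pair_id,
        distance_um=0.0 if np.isnan(distance_um) else distance_um,
        depth_um=float("nan"),
        juxta_threshold=JUXTA_P2P_MV / 4.0,
    )
    return GroundTruthBundle(
        extracellular=recording,
        extracellular_uv=extra,
        juxta_mv=juxta,
        true_spikes=true_spikes,
        metadata=metadata,
        config=config,
    )


def place_background_neurons(
    geometry: ProbeGeometry,
    density_per_mm3: float = 50000.0,
    slab_depth_um: float = 200.0,
    margin_um: float = 50.0,
    rate_range_hz: tuple[float, float] = (0.5, 5.0),
    seed: int = 0,
) -> list[NeuronSpec]:
    """Uniform background population in a slab in front of the probe.

    The slab spans the probe footprint plus ``margin_um`` laterally/axially
    and ``slab_depth_um`` out of plane; the count follows the cortical
    density (default 50,000 neurons/mm^3, the middle of the 40-60k range).
    """
    rng = _substream(seed, "placement")
    x = geometry.site_xz_um[:, 0]
    z = geometry.site_xz_um[:, 1]
    lx = (x.max() - x.min()) + 2 * margin_um
    lz = (z.max() - z.min()) + 2 * margin_um
    volume_mm3 = (lx * 1e-3) * (slab_depth_um * 1e-3) * (lz * 1e-3)
    count = rng.poisson(density_per_mm3 * volume_mm3)
    neurons = []
    for _ in range(count):
        pos = (
            float(rng.uniform(x.min() - margin_um, x.max() + margin_um)),
            float(rng.uniform(5.0, slab_depth_um)),
            float(rng.uniform(z.min() - margin_um, z.max() + margin_um)),
        )
        neurons.append(
            NeuronSpec(
                position_um=pos,
                rate_hz=float(rng.uniform(*rate_range_hz)),
                template=str(rng.choice(["biphasic-negative-first", "triphasic"])),
            )
        )
    return neurons


# ---------------------------------------------------------------------------
# Calibration scenes for the co-registration module
# ---------------------------------------------------------------------------

def random_misalignment(
    seed: int,
    max_rotation_deg: float = 2.0,
    max_scale_error: float = 0.01,
    max_offset_um: float = 50.0,
    raw_error_target_um: float | None = None,
) -> AffineCorrection:
    """Random small affine misalignment (rotations <= 2 deg, per-axis scale
    within 1%, offset <= 50 um).

    With ``raw_error_target_um`` the deviation from identity is rescaled so
    that the mean raw position error over the default calibration lattice
    equals the target exactly (the error is linear in the deviation).
    """
    rng = _substream(seed, "misalign")
    angles = np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg, 3))
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    rot_x = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    rot_y = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rot_z = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    scale = np.diag(1.0 + rng.uniform(-max_scale_error, max_scale_error, 3))
    linear = rot_x @ rot_y @ rot_z @ scale
    offset = rng.uniform(-max_offset_um, max_offset_um, 3)
    if raw_error_target_um is not None:
        grid = np.array([p.as_array() for p in calibration_grid()])
        errs = np.linalg.norm(grid @ (linear - np.eye(3)).T + offset, axis=1)
        c = raw_error_target_um / errs.mean()
        linear = np.eye(3) + c * (linear - np.eye(3))
        offset = c * offset
    return AffineCorrection(linear, offset)


def generate_calibration_scene(
    true_affine: AffineCorrection,
    n_points: int = 15,
    noise_sd_um: float = 3.0,
    seed: int = 0,
    extent_um: Sequence[float] = (5000.0, 5000.0, 5000.0),
    step_um: float = 1000.0,
    theta_deg: float = 48.2,
) -> list[CalibrationPair]:
    """Simulated calibration session: grid points observed in both frames.

    Reference positions are a seeded lattice subsample; the tilted
    manipulator's readings are the inverse-mapped positions plus Gaussian
    per-axis measurement noise (microscope zeroing + readout error).
    """
    if n_points < 4:
        raise ValueError("need at least 4 calibration points")
    refs = calibration_grid(extent_um, step_um, n_points=n_points, seed=seed)
    rng = _substream(seed, "calib-noise")
    inv = np.linalg.inv(true_affine.linear)
    pairs = []
    for ref in refs:
        p = inv @ (ref.as_array() - true_affine.offset)
        reading = reference_to_tilt(Position3D(*p), theta_deg=theta_deg)
        noisy = reading.as_array() + rng.normal(0.0, noise_sd_um, 3)
        pairs.append(
            CalibrationPair(
                reference=ref,
                moving=ManipulatorReading(*noisy, theta_deg=theta_deg),
            )
        )
    return pairs
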