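"""End-to-end pipelines tying the analysis stages together.

These functions are the library face of the command-line interface: they
chain filtering, juxtacellular spike detection, triggered averaging,
footprint mapping, flood-fill detection and PETH/matching into one
validation report per recorded pair, and handle on-disk scene simulation
with a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coreg import (
    AffineCorrection,
    CalibrationPair,
    DistanceErrorSummary,
    distance_errors,
    fit_affine_correction,
)
from .detection import (
    DetectionParams,
    MatchResult,
    PETHResult,
    compute_peth,
    detect_floodfill,
    match_events,
)
from .ground_truth import (
    AmplitudeDistancePoint,
    JTAResult,
    SpikeTrain,
    amplitude_distance_curve,
    compute_jta,
    detect_juxta_spikes,
    interpolate_footprint,
)
from .probe_io import (
    PairMetadata,
    ProbeGeometry,
    RawRecording,
    make_probe_128ch,
    make_probe_32ch_poly3,
    read_geometry,
    read_raw,
    write_geometry,
    write_pair_table,
    write_raw,
)
from .signal import ANALYSIS_BAND, DETECTION_BAND, FilterSpec, bandpass_filtfilt
from .synth import GroundTruthBundle, NeuronSpec, SynthConfig, generate_pair

__all__ = [
    "StageError",
    "ValidationReport",
    "run_validation",
    "simulate_to_dir",
    "load_pair_dir",
    "calibrate",
    "scene_from_toml",
    "export_jta_csv",
    "export_footprint_csv",
    "export_peth_csv",
    "export_events_csv",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for reporting."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ValidationReport:
    """Everything the validation pipeline computes for one pair."""

    pair_id: str
    juxta_spikes: SpikeTrain
    jta: JTAResult
    amplitude_point: AmplitudeDistancePoint
    peth: PETHResult
    match: MatchResult
    n_detected: int

    def summary_dict(self) -> dict:
        return {
            "pair_id": self.pair_id,
            "n_juxta_spikes": len(self.juxta_spikes),
            "n_jta_events": self.jta.n_events,
            "max_p2p_uv": self.amplitude_point.max_p2p_uv,
            "distance_um": self.amplitude_point.distance_um,
            "artifact_flagged": self.amplitude_point.artifact_flagged,
            "n_detected_events": self.n_detected,
            "peth_zero_bin_count": self.peth.zero_bin_count,
            "hits": self.match.hits,
            "misses": self.match.misses,
            "hit_rate": self.match.hit_rate,
            "false_positives_in_window": self.match.false_positives_in_window,
        }


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc

    return wrap


def run_validation(
    extracellular_uv: np.ndarray,
    juxta: np.ndarray,
    geometry: ProbeGeometry,
    rate_hz: float,
    metadata: PairMetadata,
    analysis_band: FilterSpec = ANALYSIS_BAND,
    detection_params: DetectionParams | None = None,
    jta_window_ms: float = 2.0,
) -> ValidationReport:
    """Run the full ground-truth validation chain on one pair.

    Filters both traces, detects juxtacellular spikes at the pair's
    threshold and polarity, computes the JTA and its footprint amplitudes,
    runs flood-fill detection on the detection band, and scores detection
    against the juxtacellular train with a PETH and greedy matching.
    """
    if detection_params is None:
        detection_params = DetectionParams(
            adjacency_radius_um=geometry.adjacency_radius_um
        )
    extra_f = _stage("bandpass_extracellular")(
        bandpass_filtfilt, extracellular_uv, analysis_band, rate_hz
    )
    juxta_f = _stage("bandpass_juxta")(bandpass_filtfilt, juxta, analysis_band, rate_hz)
    spikes = _stage("detect_juxta_spikes")(
        detect_juxta_spikes,
        juxta_f,
        metadata.juxta_threshold,
        rate_hz,
        polarity=metadata.polarity,
    )
    if len(spikes) == 0:
        raise StageError(
            "detect_juxta_spikes",
            ValueError("no juxtacellular spikes above threshold"),
        )
    jta = _stage("compute_jta")(compute_jta, extra_f, spikes, jta_window_ms)
    point = _stage("amplitude_distance_curve")(
        amplitude_distance_curve, [(metadata, jta)]
    )[0]
    extra_det = _stage("bandpass_detection")(
        bandpass_filtfilt, extracellular_uv, detection_params.band, rate_hz
    )
    events = _stage("detect_floodfill")(
        detect_floodfill, extra_det, detection_params, geometry, rate_hz
    )
    times = np.array([e.peak_time for e in events], dtype=np.int64)
    peth = _stage("compute_peth")(compute_peth, times, spikes)
    match = _stage("match_events")(match_events, times, spikes)
    return ValidationReport(
        pair_id=metadata.pair_id,
        juxta_spikes=spikes,
        jta=jta,
        amplitude_point=point,
        peth=peth,
        match=match,
        n_detected=len(events),
    )


# ---------------------------------------------------------------------------
# Scene simulation on disk
# ---------------------------------------------------------------------------

_PROBE_FACTORIES = {
    "poly3-32": make_probe_32ch_poly3,
    "grid-128": make_probe_128ch,
}


def scene_from_toml(path) -> SynthConfig:
    """Build a :class:`SynthConfig` from a TOML scene description.

    Layout::

        [scene]
        probe = "poly3-32"          # or "grid-128"
        duration_s = 60.0
        noise_sd_uv = 10.0
        crosstalk_uv = 0.0
        seed = 0
        pair_id = "synthetic"

        [[neuron]]
        position_um = [10.0, 30.0, 120.0]
        rate_hz = 1.0
        is_juxta_target = true
    """
    import tomllib

    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    scene = doc.get("scene", {})
    probe = scene.pop("probe", "poly3-32")
    if probe not in _PROBE_FACTORIES:
        raise ValueError(
            f"unknown probe {probe!r}; choose from {sorted(_PROBE_FACTORIES)}"
        )
    neurons = [
        NeuronSpec(
            position_um=tuple(n.pop("position_um")),
            **n,
        )
        for n in doc.get("neuron", [])
    ]
    return SynthConfig(geometry=_PROBE_FACTORIES[probe](), neurons=neurons, **scene)


def _config_hash(config: SynthConfig) -> str:
    payload = {
        "probe": config.geometry.name,
        "duration_s": config.duration_s,
        "rate_hz": config.rate_hz,
        "noise_sd_uv": config.noise_sd_uv,
        "crosstalk_uv": config.crosstalk_uv,
        "seed": config.seed,
        "neurons": [
            (n.position_um, n.rate_hz, n.template, n.is_juxta_target)
            for n in config.neurons
        ],
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def simulate_to_dir(config: SynthConfig, outdir) -> GroundTruthBundle:
    """Generate a scene and write the pair-directory layout.

    Files: ``extracellular.bin`` (int16 interleaved), ``juxta.bin``
    (float64 mV), ``geometry.csv``, ``true_spikes.csv``,
    ``pair_metadata.csv`` and ``manifest.json`` (seed, version, config
    hash — identical manifests imply identical outputs).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = generate_pair(config)
    write_raw(bundle.extracellular, outdir / "extracellular.bin")
    bundle.juxta_mv.astype("<f8").tofile(outdir / "juxta.bin")
    write_geometry(config.geometry, outdir / "geometry.csv")
    rows = []
    for idx, train in bundle.true_spikes.items():
        for t in train.times:
            rows.append(
                {
                    "neuron": idx,
                    "sample": int(t),
                    "time_s": t / train.rate_hz,
                    "is_juxta_target": config.neurons[idx].is_juxta_target,
                }
            )
    pd.DataFrame(
        rows, columns=["neuron", "sample", "time_s", "is_juxta_target"]
    ).to_csv(outdir / "true_spikes.csv", index=False)
    write_pair_table([bundle.metadata], outdir / "pair_metadata.csv")
    manifest = {
        "package": "pairedval",
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_channels": config.geometry.n_sites,
        "rate_hz": config.rate_hz,
        "scale_uv_per_bit": config.scale_uv_per_bit,
        "duration_s": config.duration_s,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle


def load_pair_dir(path) -> tuple[np.ndarray, np.ndarray, ProbeGeometry, PairMetadata, float]:
    """Read a pair directory back: (extracellular uV, juxta mV, geometry,
    metadata, rate_hz)."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    geometry = read_geometry(path / "geometry.csv")
    rec = read_raw(
        path / "extracellular.bin",
        n_channels=manifest["n_channels"],
        scale_uv_per_bit=manifest["scale_uv_per_bit"],
        rate_hz=manifest["rate_hz"],
    )
    juxta = np.fromfile(path / "juxta.bin", dtype="<f8")
    from .probe_io import read_pair_table

    metadata = read_pair_table(path / "pair_metadata.csv")[0]
    return rec.to_uv(), juxta, geometry, metadata, manifest["rate_hz"]


def calibrate(
    pairs: list[CalibrationPair],
) -> tuple[AffineCorrection, DistanceErrorSummary, DistanceErrorSummary]:
    """Fit the software correction and report errors before and after."""
    before = distance_errors(pairs, correction=None)
    correction = fit_affine_correction(pairs)
    after = distance_errors(pairs, correction=correction)
    return correction, before, after


# ---------------------------------------------------------------------------
# CSV exports
# ---------------------------------------------------------------------------

def export_jta_csv(jta: JTAResult, geometry: ProbeGeometry, path) -> None:
    t_ms = jta.time_ms()
    rows = {
        "t_ms": t_ms,
        **{
            f"ch_{geometry.site_ids[c]}": jta.waveforms[c]
            for c in range(jta.n_channels)
        },
    }
    pd.DataFrame(rows).to_csv(path, index=False)


def export_footprint_csv(p2p: np.ndarray, geometry: ProbeGeometry, path) -> None:
    pd.DataFrame(
        {
            "site_id": geometry.site_ids,
            "x_um": geometry.site_xz_um[:, 0],
            "z_um": geometry.site_xz_um[:, 1],
            "p2p_uv": p2p,
        }
    ).to_csv(path, index=False)


def export_peth_csv(peth: PETHResult, path) -> None:
    pd.DataFrame(
        {"bin_center_ms": peth.bin_centers_ms, "count": peth.counts}
    ).to_csv(path, index=False)


def export_events_csv(events, rate_hz: float, path) -> None:
    pd.DataFrame(
        [
            {
                "peak_time_s": e.peak_time / rate_hz,
                "peak_channel": e.peak_channel,
                "n_channels": len(e.channels),
                "peak_uv": e.peak_amplitude_uv,
            }
            for e in events
        ],
        columns=["peak_time_s", "peak_channel", "n_channels", "peak_uv"],
    ).to_csv(path, index=False)
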