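"""Dual-threshold flood-fill spike detection and evaluation against a
reference spike train.

Detection follows the two-threshold scheme used for dense polytrodes: a
strong threshold (default 4.5 sigma per channel) seeds an event and a weak
threshold (2 sigma) grows it across temporally contiguous samples and
spatially adjacent channels, producing spatiotemporally localized events.
Evaluation against juxtacellular "ground truth" spike times uses a
peri-event time histogram (PETH, 1-ms bins centered on 0) and greedy
nearest-neighbour matching within +/-0.5 ms.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .probe_io import ProbeGeometry
from .signal import DETECTION_BAND, FilterSpec, estimate_noise_sd
from .ground_truth import SpikeTrain

__all__ = [
    "DetectedEvent",
    "DetectionParams",
    "PETHResult",
    "MatchResult",
    "detect_floodfill",
    "compute_peth",
    "match_events",
]


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds and context for flood-fill detection.

    ``strong_sd``/``weak_sd`` multiply each channel's own noise SD.
    ``polarity`` selects which deflections count: extracellular somatic
    spikes are negative-first, so the default looks at negative deflections
    only; ``"both"`` uses the absolute value.
    """

    strong_sd: float = 4.5
    weak_sd: float = 2.0
    band: FilterSpec = DETECTION_BAND
    adjacency_radius_um: float = 30.0
    min_separation_ms: float = 0.5
    polarity: str = "negative"
    robust_sd: bool = False

    def __post_init__(self) -> None:
        if not self.strong_sd > self.weak_sd > 0:
            raise ValueError(
                f"need strong_sd > weak_sd > 0, got "
                f"({self.strong_sd}, {self.weak_sd})"
            )
        if self.polarity not in ("negative", "both"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


@dataclass
class DetectedEvent:
    """One spatiotemporally localized spike event."""

    peak_time: int
    channels: frozenset
    peak_channel: object
    peak_amplitude_uv: float

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("event channel set is empty")
        if self.peak_channel not in self.channels:
            raise ValueError("peak_channel must belong to the event's channels")


def _deflection(data: np.ndarray, polarity: str) -> np.ndarray:
    return np.abs(data) if polarity == "both" else -data


def detect_floodfill(
    data: np.ndarray,
    params: DetectionParams,
    geometry: ProbeGeometry,
    rate_hz: float = 30000.0,
    noise_sd_uv: np.ndarray | None = None,
) -> list[DetectedEvent]:
    """Detect spikes as connected components of the weak-threshold mask.

    ``data`` must already be filtered with ``params.band`` (channels x time,
    uV, rows ordered like ``geometry.site_ids``). Per-channel noise SD is
    estimated on the same data unless supplied. Components connect samples
    that exceed the weak threshold and are adjacent in time (+/-1 sample)
    on the same channel or simultaneous/adjacent-in-time on neighbouring
    channels (inter-site distance <= adjacency radius). Components with no
    sample above the strong threshold are discarded. Each surviving
    component yields one event at its largest deflection; events whose peaks
    are closer than ``min_separation_ms`` with overlapping channel sets are
    merged into the larger-deflection event.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_ch, n_t = data.shape
    if n_ch != geometry.n_sites:
        raise ValueError(
            f"data has {n_ch} channels but geometry has {geometry.n_sites} sites"
        )
    if noise_sd_uv is None:
        noise_sd_uv = np.array(
            [estimate_noise_sd(data[c], robust=params.robust_sd) for c in range(n_ch)]
        )
    noise_sd_uv = np.asarray(noise_sd_uv, dtype=float)
    flat = np.nonzero(noise_sd_uv == 0)[0]
    if flat.size:
        raise ValueError(
            f"flat channel(s) with zero noise SD: sites "
            f"{[geometry.site_ids[i] for i in flat]}"
        )

    defl = _deflection(data, params.polarity)
    weak = defl > params.weak_sd * noise_sd_uv[:, None]
    strong = defl > params.strong_sd * noise_sd_uv[:, None]
    if not strong.any():
        return []

    adj = geometry.adjacency()
    neighbors = [np.nonzero(adj[c])[0] for c in range(n_ch)]

    labels = np.full((n_ch, n_t), -1, dtype=np.int32)
    events: list[DetectedEvent] = []
    components: list[tuple[int, set, float, int]] = []  # peak_t, chans, amp, peak_ch

    # BFS over the sparse weak mask; candidate starts restricted to strong
    # samples since only components containing one survive.
    strong_coords = np.argwhere(strong)
    next_label = 0
    for c0, t0 in strong_coords:
        if labels[c0, t0] != -1:
            continue
        label = next_label
        next_label += 1
        queue = deque([(int(c0), int(t0))])
        labels[c0, t0] = label
        member_chans: set = set()
        # peak = largest deflection; ties broken by earliest sample, then
        # lowest channel index, so results are order-independent
        peak_key = (-np.inf, 0, 0)
        peak_val, peak_ch, peak_t = -np.inf, int(c0), int(t0)
        while queue:
            c, t = queue.popleft()
            member_chans.add(c)
            key = (defl[c, t], -t, -c)
            if key > peak_key:
                peak_key = key
                peak_val, peak_ch, peak_t = defl[c, t], c, t
            for tn in (t - 1, t, t + 1):
                if tn < 0 or tn >= n_t:
                    continue
                if tn != t and weak[c, tn] and labels[c, tn] == -1:
                    labels[c, tn] = label
                    queue.append((c, tn))
                for cn in neighbors[c]:
                    if weak[cn, tn] and labels[cn, tn] == -1:
                        labels[cn, tn] = label
                        queue.append((int(cn), tn))
        components.append((peak_t, member_chans, peak_val, peak_ch))

    # merge near-coincident components with overlapping channel sets
    components.sort(key=lambda comp: comp[0])
    min_sep = params.min_separation_ms * 1e-3 * rate_hz
    merged: list[list] = []
    for comp in components:
        peak_t, chans, amp, pch = comp
        target = None
        for m in merged:
            if abs(peak_t - m[0]) < min_sep and m[1] & chans:
                target = m
                break
        if target is None:
            merged.append([peak_t, set(chans), amp, pch])
        else:
            target[1] |= chans
            if amp > target[2]:
                target[0], target[2], target[3] = peak_t, amp, pch
    for peak_t, chans, amp, pch in merged:
        events.append(
            DetectedEvent(
                peak_time=int(peak_t),
                channels=frozenset(geometry.site_ids[i] for i in chans),
                peak_channel=geometry.site_ids[pch],
                peak_amplitude_uv=float(data[pch, peak_t]),
            )
        )
    events.sort(key=lambda e: e.peak_time)
    return events


@dataclass
class PETHResult:
    """Histogram of detected-event lags relative to reference spikes.

    Bins are aligned so that 0 ms is a bin *center* (one bin spans
    -bin/2 .. +bin/2); ``zero_bin_count`` is that bin's count.
    """

    bin_edges_ms: np.ndarray
    counts: np.ndarray
    n_juxta: int
    zero_bin_count: int = field(init=False)

    def __post_init__(self) -> None:
        self.bin_edges_ms = np.asarray(self.bin_edges_ms, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        centers = self.bin_centers_ms
        zero = int(np.argmin(np.abs(centers)))
        self.zero_bin_count = int(self.counts[zero])

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_ms[:-1] + self.bin_edges_ms[1:])


def compute_peth(
    detected_times: np.ndarray,
    reference: SpikeTrain,
    bin_ms: float = 1.0,
    half_range_ms: float = 50.0,
) -> PETHResult:
    """Peri-event time histogram of detected events around reference spikes.

    For every reference spike, all detected-event lags within
    ``+/-half_range_ms`` are histogrammed in ``bin_ms`` bins centered at 0.
    """
    if len(reference) == 0:
        raise ValueError("reference spike train is empty")
    detected_times = np.asarray(detected_times, dtype=float)
    lags_ms = (
        (detected_times[None, :] - reference.times[:, None])
        / reference.rate_hz
        * 1000.0
    ).ravel()
    n_half = int(np.ceil(half_range_ms / bin_ms))
    edges = (np.arange(2 * n_half + 2) - n_half - 0.5) * bin_ms
    counts, _ = np.histogram(lags_ms[np.abs(lags_ms) <= edges[-1]], bins=edges)
    return PETHResult(bin_edges_ms=edges, counts=counts, n_juxta=len(reference))


@dataclass
class MatchResult:
    """Outcome of matching detected events to reference spikes."""

    hits: int
    misses: int
    false_positives_in_window: int
    matched_pairs: list[tuple[int, int]]  # (reference index, detected index)

    @property
    def hit_rate(self) -> float:
        total = self.hits + self.misses
        return self.hits / total if total else float("nan")


def match_events(
    detected_times: np.ndarray,
    reference: SpikeTrain,
    tolerance_ms: float = 0.5,
) -> MatchResult:
    """Greedy nearest-neighbour matching of detected events to reference spikes.

    Candidate (reference, detected) pairs within ``+/-tolerance_ms`` are
    taken in order of increasing |lag|; each detected event and each
    reference spike participates in at most one match. ``hits + misses``
    equals the number of reference spikes; detected events inside some
    reference's tolerance window that remain unmatched are counted as false
    positives in-window.
    """
    detected_times = np.asarray(detected_times, dtype=np.int64)
    tol = tolerance_ms * 1e-3 * reference.rate_hz
    ref = reference.times
    cand = []
    for j, dt in enumerate(detected_times):
        lags = np.abs(ref - dt)
        for i in np.nonzero(lags <= tol)[0]:
            cand.append((float(lags[i]), int(i), int(j)))
    cand.sort()
    used_ref: set[int] = set()
    used_det: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in cand:
        if i in used_ref or j in used_det:
            continue
        used_ref.add(i)
        used_det.add(j)
        pairs.append((i, j))
    in_window = {j for _, _, j in [(lag, i, j) for lag, i, j in cand]}
    fp = len(in_window - used_det)
    return MatchResult(
        hits=len(pairs),
        misses=len(ref) - len(pairs),
        false_positives_in_window=fp,
        matched_pairs=sorted(pairs),
    )
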