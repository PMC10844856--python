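"""Signal conditioning and sliding-window segmentation.

Cardiac channels (BVP, ECG) are band-pass filtered with a zero-phase
Butterworth filter whose pass band corresponds to the physiological heart
rate range (38–220 beats/min, i.e. 0.633–3.667 Hz by the BPM/60 conversion).
All other channels are smoothed with a Savitzky–Golay filter (polynomial
order 3, window 10 samples, rounded up to the 11-sample odd window the
filter requires).  The conditioned channels are then cut into aligned
sliding windows — 50 s long, advancing by 8 s — each carrying the majority
per-sample condition label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, ValidationError
from .recording_io import Channel, Recording

logger = logging.getLogger(__name__)

#: channels treated as cardiac (band-passed rather than smoothed)
CARDIAC_CHANNELS = ("BVP", "ECG")


@dataclass
class FilterConfig:
    """Conditioning parameters.

    ``hr_low_bpm``/``hr_high_bpm`` bound the heart-rate pass band; the Hz
    cutoffs are ``bpm / 60`` (``bpm_to_hz`` makes the conversion explicit
    and overridable).
    """

    hr_low_bpm: float = 38.0
    hr_high_bpm: float = 220.0
    butter_order: int = 3
    smooth_poly_order: int = 3
    smooth_window_samples: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.hr_low_bpm < self.hr_high_bpm:
            raise ConfigurationError("need 0 < hr_low_bpm < hr_high_bpm")
        if self.smooth_poly_order >= self.smooth_window_samples:
            raise ConfigurationError("smooth_poly_order must be < smooth_window_samples")
        if self.butter_order < 1:
            raise ConfigurationError("butter_order must be >= 1")

    @staticmethod
    def bpm_to_hz(bpm: float) -> float:
        return bpm / 60.0

    @property
    def band_hz(self) -> tuple[float, float]:
        return self.bpm_to_hz(self.hr_low_bpm), self.bpm_to_hz(self.hr_high_bpm)


@dataclass
class SegmentationConfig:
    """Sliding-window parameters: window length W and stride S, in seconds."""

    window_s: float = 50.0
    stride_s: float = 8.0

    def __post_init__(self) -> None:
        if not self.window_s > 0 or not self.stride_s > 0:
            raise ConfigurationError("window_s and stride_s must be > 0")


@dataclass
class Segment:
    """One aligned window over all channels: [start_s, start_s + W)."""

    start_s: float
    end_s: float
    label: int
    slices: dict[str, np.ndarray]  # key "device/name"


@dataclass
class SegmentSet:
    """The sliding-window decomposition of one recording."""

    subject_id: str
    window_s: float
    stride_s: float
    channel_rates: dict[str, float]  # key "device/name"
    segments: list[Segment]
    n_dropped_label: int = 0  # modal label share <= 50% or tie
    drop_report: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.segments], dtype=int)


def bandpass_cardiac(channel: Channel, config: FilterConfig) -> Channel:
    """Zero-phase Butterworth band-pass of a cardiac channel.

    Forward–backward application keeps the filtered series aligned with the
    label stream (no group delay), at the cost of doubling the effective
    filter order.
    """
    if channel.name not in CARDIAC_CHANNELS:
        raise ValidationError(f"bandpass_cardiac expects BVP/ECG, got {channel.name!r}")
    low_hz, high_hz = config.band_hz
    nyquist = channel.sampling_rate_hz / 2.0
    if high_hz >= nyquist:
        raise ConfigurationError(
            f"high cutoff {high_hz:.3f} Hz >= Nyquist {nyquist:.3f} Hz of {channel.name}"
        )
    sos = sps.butter(
        config.butter_order,
        [low_hz, high_hz],
        btype="bandpass",
        fs=channel.sampling_rate_hz,
        output="sos",
    )
    return channel.replace_samples(sps.sosfiltfilt(sos, channel.samples))


def smooth_channel(channel: Channel, config: FilterConfig) -> Channel:
    """Savitzky–Golay smoothing of a non-cardiac channel.

    An even window is rounded up to the next odd integer (the filter needs a
    centred window); the effective window is logged.
    """
    if channel.name == "BVP":
        raise ValidationError("BVP is band-passed, not smoothed")
    window = config.smooth_window_samples
    if window % 2 == 0:
        window += 1
        logger.info(
            "smooth_channel(%s): even window %d rounded up to effective window %d",
            channel.name,
            config.smooth_window_samples,
            window,
        )
    if window > channel.samples.size:
        raise ValidationError(
            f"smoothing window {window} exceeds series length {channel.samples.size}"
        )
    smoothed = sps.savgol_filter(channel.samples, window, config.smooth_poly_order)
    return channel.replace_samples(smoothed)


def _unmasked_runs(recording: Recording) -> list[tuple[int, int]]:
    """Contiguous [i0, i1) runs of usable label samples."""
    n = recording.labels.size
    if recording.mask is None:
        return [(0, n)]
    runs = []
    m = recording.mask
    i = 0
    while i < n:
        if m[i]:
            j = i
            while j < n and m[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def expected_segment_count(duration_s: float, window_s: float, stride_s: float) -> int:
    """floor((T − W)/S) + 1 for T ≥ W, else 0 (before any label-based drops)."""
    if duration_s < window_s - 1e-9:
        return 0
    return int(np.floor((duration_s - window_s) / stride_s + 1e-9)) + 1


def segment(recording: Recording, config: SegmentationConfig) -> SegmentSet:
    """Cut a recording into aligned sliding windows with majority labels.

    Windows are placed from t = 0 of each contiguous unmasked run; a window
    never straddles masked samples and no partial trailing window is
    emitted, so each run of usable duration T contributes exactly
    floor((T − W)/S) + 1 candidate windows.  A candidate is dropped (and
    counted) when its modal label covers ≤ 50% of the window's label
    samples or ties with another label.
    """
    W, S = config.window_s, config.stride_s
    lr = recording.label_rate_hz
    rates = {f"{c.device}/{c.name}": c.sampling_rate_hz for c in recording.channels}
    segments: list[Segment] = []
    n_dropped = 0
    drop_report: list[dict] = []

    for i0, i1 in _unmasked_runs(recording):
        t0 = i0 / lr
        run_T = (i1 - i0) / lr
        for k in range(expected_segment_count(run_T, W, S)):
            start = t0 + k * S
            end = start + W
            li0 = int(round(start * lr))
            li1 = int(round(end * lr))
            window_labels = recording.labels[li0:li1]
            counts = np.bincount(window_labels, minlength=3)
            modal = int(np.argmax(counts))
            share = counts[modal] / window_labels.size
            tie = int(np.sum(counts == counts[modal])) > 1
            if share <= 0.5 or tie:
                n_dropped += 1
                drop_report.append(
                    {"start_s": start, "reason": "tie" if tie else "low_modal_share",
                     "modal_share": float(share)}
                )
                continue
            slices = {}
            for ch in recording.channels:
                r = ch.sampling_rate_hz
                s0 = int(round(start * r))
                s1 = int(round(end * r))
                slices[f"{ch.device}/{ch.name}"] = ch.samples[s0:s1]
            segments.append(Segment(start, end, modal, slices))

    if not segments and recording.duration_s < W:
        logger.warning(
            "recording %s shorter (%.1fs) than one window (%.1fs): empty SegmentSet",
            recording.subject_id,
            recording.duration_s,
            W,
        )
    return SegmentSet(
        subject_id=recording.subject_id,
        window_s=W,
        stride_s=S,
        channel_rates=rates,
        segments=segments,
        n_dropped_label=n_dropped,
        drop_report=drop_report,
    )


def preprocess_recording(
    recording: Recording,
    filt: FilterConfig | None = None,
    seg: SegmentationConfig | None = None,
) -> SegmentSet:
    """Condition every channel, then segment.

    Smoothing is applied to all non-BVP channels first; cardiac channels
    (ECG after smoothing, BVP raw) are then band-passed.  Filters run on the
    whole series before any windowing, so filtering and segmenting commute
    by construction.
    """
    filt = filt or FilterConfig()
    seg = seg or SegmentationConfig()
    conditioned = []
    for ch in recording.channels:
        out = ch
        if ch.name != "BVP":
            out = smooth_channel(out, filt)
        if ch.name in CARDIAC_CHANNELS:
            out = bandpass_cardiac(out, filt)
        conditioned.append(out)
    filtered = Recording(
        subject_id=recording.subject_id,
        channels=conditioned,
        labels=recording.labels,
        label_rate_hz=recording.label_rate_hz,
        mask=recording.mask,
    )
    return segment(filtered, seg)
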