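"""Seeded generator of labelled multimodal wearable recordings.

The generator emulates, channel by channel, the structure a wrist- and
chest-worn device pair records across a block protocol of baseline,
amusement and stress conditions:

* **BVP / ECG** — a unit sinusoid at the instantaneous heart rate (Hz =
  BPM/60) plus a 0.3-amplitude second harmonic and Gaussian noise.  Heart
  rate is drawn per subject and condition (baseline 70±5, amusement 80±5,
  stress 95±5 BPM) and moves between blocks through 10 s linear ramps, so
  block boundaries leak no discontinuity artefacts.
* **EDA** — a tonic random-walk level plus phasic skin-conductance
  responses: Poisson events (baseline 0.03/s, amusement 0.06/s, stress
  0.15/s) convolved with a bi-exponential kernel (1 s rise, 4 s decay).
* **sweat** — a low-pass rendering of the tonic EDA level plus noise: a
  slow humidity-like signal correlated with, but not identical to, EDA.
* **TEMP** — an AR(1) process around 33 °C with a condition-dependent
  drift slope.
* **EMG** — Gaussian noise whose standard deviation is multiplied by a
  condition-dependent burst scale during Poisson-arriving bursts.
* **RESP** — a sinusoid at the condition's respiration rate.
* **ACC** — (0, 0, 1) gravity plus Poisson motion episodes of band-limited
  noise, condition-independent (motion is context, not affect).

Channel sampling rates default to the hardware roster the pipeline targets
(wrist: BVP 64 Hz, EDA/TEMP/sweat 4 Hz, ACC 32 Hz; chest: 700 Hz), so
synthetic bundles are drop-in analogues of imported device data.  The
output is fully determined by (master seed, subject index).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError
from .recording_io import Channel, Recording, write_bundle

CONDITION_CODES = {"baseline": 0, "stress": 1, "amusement": 2}

DEFAULT_SCHEDULE = (
    ("baseline", 240.0),
    ("amusement", 120.0),
    ("stress", 240.0),
    ("baseline", 120.0),
)

WRIST_RATES = {"BVP": 64.0, "EDA": 4.0, "TEMP": 4.0, "sweat": 4.0, "ACC": 32.0}
CHEST_RATE = 700.0


def _per_condition(baseline, amusement, stress) -> dict[str, float]:
    return {"baseline": baseline, "amusement": amusement, "stress": stress}


@dataclass
class SynthConfig:
    """Study conditions for the simulator; a config + seed uniquely fixes output."""

    n_subjects: int = 8
    schedule: tuple = DEFAULT_SCHEDULE
    devices: tuple = ("wrist",)
    label_rate_hz: float = 4.0
    wrist_rates: dict = field(default_factory=lambda: dict(WRIST_RATES))
    chest_rate_hz: float = CHEST_RATE
    # state-dependent parameters
    hr_mean_bpm: dict = field(default_factory=lambda: _per_condition(70.0, 80.0, 95.0))
    hr_sd_bpm: dict = field(default_factory=lambda: _per_condition(5.0, 5.0, 5.0))
    scr_rate_per_s: dict = field(default_factory=lambda: _per_condition(0.03, 0.06, 0.15))
    emg_burst_rate_per_s: dict = field(default_factory=lambda: _per_condition(0.05, 0.10, 0.20))
    emg_burst_scale: dict = field(default_factory=lambda: _per_condition(2.0, 3.0, 5.0))
    resp_rate_hz: dict = field(default_factory=lambda: _per_condition(0.25, 0.28, 0.35))
    temp_slope_c_per_s: dict = field(
        default_factory=lambda: _per_condition(0.0, 0.0002, -0.001)
    )
    acc_motion_rate_per_s: float = 0.02
    acc_motion_duration_s: float = 2.0
    hr_transition_s: float = 10.0
    scr_rise_s: float = 1.0
    scr_decay_s: float = 4.0
    # per-channel additive noise standard deviations
    noise_sd: dict = field(
        default_factory=lambda: {
            "BVP": 0.10,
            "ECG": 0.10,
            "EDA": 0.02,
            "sweat": 0.01,
            "TEMP": 0.01,
            "EMG": 0.05,
            "RESP": 0.05,
            "ACC": 0.02,
        }
    )
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        for name, dur in self.schedule:
            if name not in CONDITION_CODES:
                raise ConfigurationError(f"unknown condition {name!r} in schedule")
            if not dur > 0:
                raise ConfigurationError("schedule durations must be > 0")
        for dev in self.devices:
            if dev not in ("wrist", "chest"):
                raise ConfigurationError(f"unknown device {dev!r}")

    @property
    def duration_s(self) -> float:
        return float(sum(d for _, d in self.schedule))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schedule"] = [list(b) for b in self.schedule]
        d["devices"] = list(self.devices)
        return d


def null_config(config: SynthConfig) -> SynthConfig:
    """A copy with every condition-dependent delta removed (null calibration).

    All per-condition parameters are set to their baseline values, so the
    labels carry no signal and any classifier should score at chance.
    """
    flat = {}
    for name in (
        "hr_mean_bpm",
        "hr_sd_bpm",
        "scr_rate_per_s",
        "emg_burst_rate_per_s",
        "emg_burst_scale",
        "resp_rate_hz",
        "temp_slope_c_per_s",
    ):
        base = getattr(config, name)["baseline"]
        flat[name] = _per_condition(base, base, base)
    return replace(config, **flat)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def _condition_series(config: SynthConfig, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """(condition name index array, per-sample code array) at ``rate``."""
    names = []
    for name, dur in config.schedule:
        names.extend([name] * int(round(dur * rate)))
    codes = np.array([CONDITION_CODES[n] for n in names], dtype=int)
    return np.array(names), codes


def _piecewise_with_ramps(
    values_per_block: list[float], config: SynthConfig, rate: float
) -> np.ndarray:
    """Block-constant series with linear ramps over the first ramp seconds."""
    out = []
    prev = values_per_block[0]
    ramp_n = int(round(config.hr_transition_s * rate))
    for (name, dur), val in zip(config.schedule, values_per_block):
        n = int(round(dur * rate))
        block = np.full(n, val)
        r = min(ramp_n, n)
        if out and r > 0:
            block[:r] = np.linspace(prev, val, r, endpoint=False)
        out.append(block)
        prev = val
    return np.concatenate(out)


def _poisson_events(rng: np.random.Generator, rate_per_s: np.ndarray, fs: float) -> np.ndarray:
    """Bernoulli thinning of a (possibly time-varying) Poisson process."""
    p = np.clip(np.asarray(rate_per_s) / fs, 0.0, 1.0)
    return rng.random(p.shape) < p


def _scr_kernel(config: SynthConfig, fs: float) -> np.ndarray:
    t = np.arange(0.0, 5.0 * config.scr_decay_s, 1.0 / fs)
    k = np.exp(-t / config.scr_decay_s) - np.exp(-t / config.scr_rise_s)
    peak = k.max()
    return k / peak if peak > 0 else k


def _cardiac(
    rng: np.random.Generator, config: SynthConfig, fs: float, noise_sd: float
) -> np.ndarray:
    hr_blocks = [
        rng.normal(config.hr_mean_bpm[name], config.hr_sd_bpm[name])
        for name, _ in config.schedule
    ]
    hr = _piecewise_with_ramps(hr_blocks, config, fs)
    phase = 2.0 * np.pi * np.cumsum(hr / 60.0) / fs
    return np.sin(phase) + 0.3 * np.sin(2.0 * phase) + rng.normal(0, noise_sd, hr.size)


def _eda_pair(
    rng: np.random.Generator, config: SynthConfig, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """(EDA, sweat) at rate ``fs`` — sweat is a slow low-pass of the tonic level."""
    _, codes = _condition_series(config, fs)
    n = codes.size
    tonic = 2.0 + np.cumsum(rng.normal(0.0, 0.003, n))
    rate = _per_sample_param(config, fs, config.scr_rate_per_s)
    events = _poisson_events(rng, rate, fs)
    amplitudes = np.where(events, rng.uniform(0.2, 0.8, n), 0.0)
    phasic = np.convolve(amplitudes, _scr_kernel(config, fs))[:n]
    eda = tonic + phasic + rng.normal(0, config.noise_sd["EDA"], n)
    # slow sweat channel: heavily smoothed tonic + phasic trace
    win = max(3, int(round(10.0 * fs)) | 1)
    if win >= n:
        win = (n - 1) | 1 if n > 2 else 3
    sweat = sps.savgol_filter(tonic + 0.5 * phasic, win, 2) + rng.normal(
        0, config.noise_sd["sweat"], n
    )
    return eda, sweat


def _per_sample_param(config: SynthConfig, fs: float, table: dict[str, float]) -> np.ndarray:
    """Expand a per-condition parameter to a per-sample series at ``fs``."""
    parts = [
        np.full(int(round(dur * fs)), table[name]) for name, dur in config.schedule
    ]
    return np.concatenate(parts)


def _temp(rng: np.random.Generator, config: SynthConfig, fs: float) -> np.ndarray:
    slope = _per_sample_param(config, fs, config.temp_slope_c_per_s)
    n = slope.size
    drift = np.cumsum(slope / fs)
    ar = np.empty(n)
    ar[0] = 0.0
    rho = 0.995
    w = rng.normal(0, config.noise_sd["TEMP"], n)
    for i in range(1, n):
        ar[i] = rho * ar[i - 1] + w[i]
    return 33.0 + drift + ar


def _emg(rng: np.random.Generator, config: SynthConfig, fs: float) -> np.ndarray:
    rate = _per_sample_param(config, fs, config.emg_burst_rate_per_s)
    scale = _per_sample_param(config, fs, config.emg_burst_scale)
    n = rate.size
    starts = _poisson_events(rng, rate, fs)
    burst = np.zeros(n, dtype=bool)
    dur_n = max(1, int(round(0.5 * fs)))
    for i in np.flatnonzero(starts):
        burst[i : i + dur_n] = True
    sd = config.noise_sd["EMG"] * np.where(burst, scale, 1.0)
    return rng.normal(0, 1.0, n) * sd


def _resp(rng: np.random.Generator, config: SynthConfig, fs: float) -> np.ndarray:
    rate_hz = _per_sample_param(config, fs, config.resp_rate_hz)
    phase = 2.0 * np.pi * np.cumsum(rate_hz) / fs
    return 0.5 * np.sin(phase) + rng.normal(0, config.noise_sd["RESP"], rate_hz.size)


def _acc(rng: np.random.Generator, config: SynthConfig, fs: float) -> dict[str, np.ndarray]:
    n = int(round(config.duration_s * fs))
    starts = rng.random(n) < config.acc_motion_rate_per_s / fs
    moving = np.zeros(n, dtype=bool)
    dur_n = max(1, int(round(config.acc_motion_duration_s * fs)))
    for i in np.flatnonzero(starts):
        moving[i : i + dur_n] = True
    axes = {}
    kernel = np.hanning(max(3, int(round(0.25 * fs))))
    kernel /= kernel.sum()
    for axis, gravity in (("x", 0.0), ("y", 0.0), ("z", 1.0)):
        band = np.convolve(rng.normal(0, 1.0, n), kernel, mode="same")
        axes[f"ACC_{axis}"] = (
            gravity
            + np.where(moving, 0.5 * band, 0.0)
            + rng.normal(0, config.noise_sd["ACC"], n)
        )
    return axes


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def generate_recording(config: SynthConfig, subject_index: int) -> Recording:
    """Simulate one subject; fully determined by (master_seed, subject_index)."""
    rng = np.random.default_rng(config.master_seed + subject_index)
    channels: list[Channel] = []

    if "wrist" in config.devices:
        r = config.wrist_rates
        channels.append(
            Channel("BVP", "wrist", r["BVP"], _cardiac(rng, config, r["BVP"], config.noise_sd["BVP"]))
        )
        eda, sweat = _eda_pair(rng, config, r["EDA"])
        channels.append(Channel("EDA", "wrist", r["EDA"], eda))
        channels.append(Channel("sweat", "wrist", r["sweat"], sweat))
        channels.append(Channel("TEMP", "wrist", r["TEMP"], _temp(rng, config, r["TEMP"])))
        for name, series in _acc(rng, config, r["ACC"]).items():
            channels.append(Channel(name, "wrist", r["ACC"], series))

    if "chest" in config.devices:
        fs = config.chest_rate_hz
        channels.append(
            Channel("ECG", "chest", fs, _cardiac(rng, config, fs, config.noise_sd["ECG"]))
        )
        eda, sweat = _eda_pair(rng, config, fs)
        channels.append(Channel("EDA", "chest", fs, eda))
        channels.append(Channel("sweat", "chest", fs, sweat))
        channels.append(Channel("TEMP", "chest", fs, _temp(rng, config, fs)))
        channels.append(Channel("EMG", "chest", fs, _emg(rng, config, fs)))
        channels.append(Channel("RESP", "chest", fs, _resp(rng, config, fs)))

    _, labels = _condition_series(config, config.label_rate_hz)
    return Recording(
        subject_id=f"synth{subject_index:02d}",
        channels=channels,
        labels=labels,
        label_rate_hz=config.label_rate_hz,
    )


def generate_cohort(
    config: SynthConfig, out_dir: str | Path | None = None
) -> list[Recording]:
    """Simulate ``config.n_subjects`` recordings; optionally write bundles.

    When ``out_dir`` is given, one bundle directory per subject is written
    via :mod:`stresscare.recording_io`, alongside a ground-truth parameter
    JSON recording the generating configuration.
    """
    recordings = [generate_recording(config, i) for i in range(config.n_subjects)]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec in recordings:
            write_bundle(rec, out_dir / rec.subject_id)
            with open(out_dir / rec.subject_id / "ground_truth.json", "w") as fh:
                json.dump(
                    {"subject_id": rec.subject_id, "config": config.to_dict()}, fh, indent=2
                )
    return recordings
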