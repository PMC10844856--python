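"""Read, validate and write multichannel labelled physiological recordings.

A *recording bundle* is a directory holding a JSON manifest, one
single-column headered CSV per channel, and a label CSV at a fixed label
rate.  The format is language-neutral and diffable, and is exactly what the
synthetic generator emits, so simulated and imported data flow through the
same code path.

Condition codes are fixed package-wide: 0 = baseline, 1 = stress,
2 = amusement.  Importers of external data remap into this coding.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ExternalDataError, FormatError, ValidationError

logger = logging.getLogger(__name__)

FORMAT_VERSION = "stresscare-bundle-1"

LABEL_CODES = {0: "baseline", 1: "stress", 2: "amusement"}

#: Channel names permitted per device placement.
WRIST_CHANNELS = frozenset({"sweat", "BVP", "EDA", "TEMP", "ACC_x", "ACC_y", "ACC_z"})
CHEST_CHANNELS = frozenset(
    {"sweat", "ECG", "RESP", "EMG", "TEMP", "EDA", "ACC_x", "ACC_y", "ACC_z"}
)


@dataclass
class Channel:
    """One sampled physiological signal from a wrist- or chest-worn device."""

    name: str
    device: str  # "wrist" | "chest"
    sampling_rate_hz: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.device not in ("wrist", "chest"):
            raise ValidationError(f"unknown device {self.device!r}")
        allowed = WRIST_CHANNELS if self.device == "wrist" else CHEST_CHANNELS
        if self.name not in allowed:
            raise ValidationError(
                f"channel {self.name!r} is not a valid {self.device} placement"
            )
        if not self.sampling_rate_hz > 0:
            raise ValidationError("sampling_rate_hz must be > 0")
        if self.samples.size == 0:
            raise ValidationError(f"channel {self.name}: empty sample series")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz

    def replace_samples(self, samples: np.ndarray) -> "Channel":
        return Channel(self.name, self.device, self.sampling_rate_hz, samples)


@dataclass
class Recording:
    """A subject's multichannel labelled session — the unit of I/O.

    ``labels`` is a per-sample condition series at ``label_rate_hz``.
    ``mask`` (optional) marks samples usable for analysis; ``False`` entries
    (e.g. non-study protocol phases of an imported dataset) are excluded
    from segmentation.
    """

    subject_id: str
    channels: list[Channel]
    labels: np.ndarray
    label_rate_hz: float
    mask: np.ndarray | None = None
    label_codes: dict[int, str] = field(default_factory=lambda: dict(LABEL_CODES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.labels.shape:
                raise ValidationError("mask and labels must have equal length")
        # deterministic channel order: device then name
        self.channels = sorted(self.channels, key=lambda c: (c.device, c.name))
        self.validate()

    def validate(self) -> None:
        if not self.label_rate_hz > 0:
            raise ValidationError("label_rate_hz must be > 0")
        if self.labels.size == 0:
            raise ValidationError("empty label series")
        usable = self.labels if self.mask is None else self.labels[self.mask]
        bad = set(np.unique(usable)) - set(self.label_codes)
        if bad:
            raise ValidationError(f"unknown label code(s) {sorted(bad)}")
        names = [(c.device, c.name) for c in self.channels]
        if len(names) != len(set(names)):
            raise ValidationError("duplicate channel name within a device")
        tol = 1.0 / self.label_rate_hz
        ldur = self.labels.size / self.label_rate_hz
        for ch in self.channels:
            if abs(ch.duration_s - ldur) > tol + 1e-9:
                raise ValidationError(
                    f"channel {ch.device}/{ch.name}: duration {ch.duration_s:.3f}s "
                    f"!= label duration {ldur:.3f}s beyond one label sample"
                )

    @property
    def duration_s(self) -> float:
        return self.labels.size / self.label_rate_hz

    def channel(self, name: str, device: str | None = None) -> Channel:
        hits = [
            c
            for c in self.channels
            if c.name == name and (device is None or c.device == device)
        ]
        if not hits:
            raise ValidationError(f"channel {name!r} not present in recording")
        return hits[0]

    def has_channel(self, name: str, device: str | None = None) -> bool:
        return any(
            c.name == name and (device is None or c.device == device)
            for c in self.channels
        )

    def devices(self) -> set[str]:
        return {c.device for c in self.channels}


@dataclass
class BundleManifest:
    subject_id: str
    format_version: str
    label_rate_hz: float
    labels_file: str
    channels: list[dict]  # name, device, sampling_rate_hz, file


def _channel_filename(ch: Channel) -> str:
    return f"{ch.device}_{ch.name}.csv"


def write_bundle(recording: Recording, path: str | Path) -> BundleManifest:
    """Serialise ``recording`` as a bundle directory readable by :func:`read_bundle`.

    Numeric samples are written at full double precision (``%.17g``).
    """
    path = Path(path)
    try:
        path.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise OSError(f"cannot create bundle directory {path}: {exc}") from exc

    entries = []
    for ch in recording.channels:
        fname = _channel_filename(ch)
        np.savetxt(path / fname, ch.samples, fmt="%.17g", header="value", comments="")
        entries.append(
            {
                "name": ch.name,
                "device": ch.device,
                "sampling_rate_hz": ch.sampling_rate_hz,
                "file": fname,
            }
        )

    label_df = pd.DataFrame({"code": recording.labels})
    if recording.mask is not None:
        label_df["mask"] = recording.mask.astype(int)
    label_df.to_csv(path / "labels.csv", index=False)

    manifest = BundleManifest(
        subject_id=recording.subject_id,
        format_version=FORMAT_VERSION,
        label_rate_hz=recording.label_rate_hz,
        labels_file="labels.csv",
        channels=entries,
    )
    with open(path / "manifest.json", "w") as fh:
        json.dump(
            {
                "format_version": manifest.format_version,
                "subject_id": manifest.subject_id,
                "label_rate_hz": manifest.label_rate_hz,
                "labels_file": manifest.labels_file,
                "channels": manifest.channels,
            },
            fh,
            indent=2,
        )
    return manifest


def read_bundle(path: str | Path) -> Recording:
    """Read and validate a bundle directory written by :func:`write_bundle`."""
    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise FormatError(f"no manifest.json in {path}")
    try:
        raw = json.loads(mpath.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"manifest.json is not valid JSON: {exc}") from exc

    for key in ("format_version", "subject_id", "label_rate_hz", "labels_file", "channels"):
        if key not in raw:
            raise FormatError(f"manifest missing required field {key!r}")
    if raw["format_version"] != FORMAT_VERSION:
        raise FormatError(f"unsupported format_version {raw['format_version']!r}")

    channels = []
    for entry in raw["channels"]:
        for key in ("name", "device", "sampling_rate_hz", "file"):
            if key not in entry:
                raise FormatError(f"channel entry missing field {key!r}: {entry}")
        fpath = path / entry["file"]
        if not fpath.exists():
            raise FormatError(f"referenced channel file missing: {fpath}")
        values = pd.read_csv(fpath, float_precision="round_trip")["value"].to_numpy(
            dtype=float
        )
        channels.append(
            Channel(entry["name"], entry["device"], float(entry["sampling_rate_hz"]), values)
        )

    lpath = path / raw["labels_file"]
    if not lpath.exists():
        raise FormatError(f"referenced label file missing: {lpath}")
    ldf = pd.read_csv(lpath)
    if "code" not in ldf.columns:
        raise FormatError("labels file lacks a 'code' column")
    labels = ldf["code"].to_numpy(dtype=int)
    mask = ldf["mask"].to_numpy(dtype=bool) if "mask" in ldf.columns else None

    return Recording(
        subject_id=str(raw["subject_id"]),
        channels=channels,
        labels=labels,
        label_rate_hz=float(raw["label_rate_hz"]),
        mask=mask,
    )


# ---------------------------------------------------------------------------
# WESAD import (optional; requires the externally downloaded dataset)
# ---------------------------------------------------------------------------

#: native sampling rates of the Empatica E4 wrist signals
_WESAD_WRIST_RATES = {"ACC": 32.0, "BVP": 64.0, "EDA": 4.0, "TEMP": 4.0}
_WESAD_CHEST_RATE = 700.0
#: WESAD condition coding -> package coding (all other codes are masked out)
_WESAD_LABEL_MAP = {1: 0, 2: 1, 3: 2}  # baseline, stress, amusement


def import_wesad_subject(
    path: str | Path, sweat_alias: str = "EDA"
) -> Recording:
    """Import one WESAD per-subject pickle file as a :class:`Recording`.

    Chest channels come in at the device's common 700 Hz rate and wrist
    channels at their native per-channel rates.  WESAD's condition codes are
    remapped to the package coding {0 baseline, 1 stress, 2 amusement}; every
    other protocol code (transients, meditation, ...) is masked out and never
    reaches segmentation.

    The study design this package follows treats "sweat" as a sensor in its
    own right, but WESAD carries no separate sweat channel.  ``sweat_alias``
    names the WESAD signal mirrored under the name ``sweat`` (default: EDA),
    and the substitution is logged loudly.
    """
    path = Path(path)
    if not path.exists():
        raise ExternalDataError(
            f"external data not available: WESAD subject file {path} not found "
            "(the WESAD dataset must be downloaded separately)"
        )
    import pickle

    try:
        with open(path, "rb") as fh:
            data = pickle.load(fh, encoding="latin1")
        signals = data["signal"]
        raw_labels = np.asarray(data["label"], dtype=int).ravel()
        chest = signals["chest"]
        wrist = signals["wrist"]
        subject = str(data.get("subject", path.stem))
    except ExternalDataError:
        raise
    except Exception as exc:
        raise FormatError(f"unexpected WESAD subject structure in {path}: {exc}") from exc

    channels: list[Channel] = []

    def _add(name: str, device: str, rate: float, arr: np.ndarray) -> None:
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 2 and arr.shape[1] == 1:
            arr = arr[:, 0]
        channels.append(Channel(name, device, rate, arr))

    for key, arr in chest.items():
        arr = np.asarray(arr, dtype=float)
        if key == "ACC":
            for i, axis in enumerate(("x", "y", "z")):
                _add(f"ACC_{axis}", "chest", _WESAD_CHEST_RATE, arr[:, i])
        elif key in ("ECG", "EDA", "EMG", "Resp", "RESP", "Temp", "TEMP"):
            name = {"Resp": "RESP", "Temp": "TEMP"}.get(key, key)
            _add(name, "chest", _WESAD_CHEST_RATE, arr)

    for key, arr in wrist.items():
        arr = np.asarray(arr, dtype=float)
        if key == "ACC":
            for i, axis in enumerate(("x", "y", "z")):
                _add(f"ACC_{axis}", "wrist", _WESAD_WRIST_RATES["ACC"], arr[:, i])
        elif key in _WESAD_WRIST_RATES:
            _add(key, "wrist", _WESAD_WRIST_RATES[key], arr)

    logger.warning(
        "WESAD has no dedicated sweat sensor: mirroring %s as 'sweat' on both "
        "devices (configurable via sweat_alias)",
        sweat_alias,
    )
    for device in ("wrist", "chest"):
        src = [c for c in channels if c.device == device and c.name == sweat_alias]
        if src:
            _add("sweat", device, src[0].sampling_rate_hz, src[0].samples.copy())

    labels = np.zeros_like(raw_labels)
    mask = np.zeros(raw_labels.shape, dtype=bool)
    for wesad_code, code in _WESAD_LABEL_MAP.items():
        sel = raw_labels == wesad_code
        labels[sel] = code
        mask[sel] = True

    return Recording(
        subject_id=subject,
        channels=channels,
        labels=labels,
        label_rate_hz=_WESAD_CHEST_RATE,
        mask=mask,
    )
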