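"""Per-segment feature extraction.

Each channel slice contributes a fixed, documented set of eleven
statistical and spectral features; sensor pairs within a device contribute
Pearson correlations (after block-mean downsampling of the higher-rate
channel); the wrist accelerometer contributes per-axis features plus
axis correlations and features of the magnitude series — these motion
features (and EMG features on the chest) serve as the *context* input to
the gating model.

The canonical per-channel feature set, in column order:

==================  =====================================================
mean                sample mean
std                 population standard deviation (ddof = 0)
min / max           extrema
dynamic_range       max − min
slope               least-squares linear trend against time in seconds
absolute_integral   sum of |x| divided by the sampling rate (unit·s)
peak_frequency      argmax of the mean-removed periodogram, Hz
                    (zero-frequency bin excluded; 0 for a constant slice)
band_power          total periodogram power excluding the zero-frequency
                    bin; by Parseval this equals the population variance
diff_mean           mean of the first difference
diff_std            population std of the first difference
==================  =====================================================

Zero-variance (degenerate) slices yield peak_frequency 0 and correlation 0
rather than NaN, and each row carries a ``degenerate_count`` column so
downstream code can see how many statistics were patched.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .preprocessing import SegmentSet

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "mean",
    "std",
    "min",
    "max",
    "dynamic_range",
    "slope",
    "absolute_integral",
    "peak_frequency",
    "band_power",
    "diff_mean",
    "diff_std",
)

#: non-feature columns present in every FeatureTable
META_COLUMNS = ("subject_id", "segment_start_s", "label", "degenerate_count")


def channel_features(x: np.ndarray, rate: float) -> dict[str, float]:
    """Compute the canonical eleven features of one channel slice."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValidationError("empty slice")
    n = x.size
    t = np.arange(n) / rate
    out: dict[str, float] = {}
    out["mean"] = float(np.mean(x))
    out["std"] = float(np.std(x))
    out["min"] = float(np.min(x))
    out["max"] = float(np.max(x))
    out["dynamic_range"] = out["max"] - out["min"]
    if n > 1:
        out["slope"] = float(np.polyfit(t, x, 1)[0])
    else:
        out["slope"] = 0.0
    out["absolute_integral"] = float(np.sum(np.abs(x)) / rate)

    centred = x - out["mean"]
    if n > 1 and np.any(centred != 0.0):
        spectrum = np.abs(np.fft.rfft(centred)) ** 2
        freqs = np.fft.rfftfreq(n, d=1.0 / rate)
        k = int(np.argmax(spectrum[1:])) + 1
        out["peak_frequency"] = float(freqs[k])
    else:
        logger.warning("constant slice: peak_frequency undefined, reported as 0")
        out["peak_frequency"] = 0.0
    # Parseval: sum_{k != 0} |X_k|^2 / N^2 == population variance
    out["band_power"] = float(np.mean(centred**2))

    d = np.diff(x)
    out["diff_mean"] = float(np.mean(d)) if d.size else 0.0
    out["diff_std"] = float(np.std(d)) if d.size else 0.0
    return out


def block_mean_downsample(x: np.ndarray, factor: int) -> np.ndarray:
    """Non-overlapping block means; trailing partial block discarded."""
    if factor < 1:
        raise ValidationError("downsample factor must be >= 1")
    if factor == 1:
        return np.asarray(x, dtype=float)
    n = (len(x) // factor) * factor
    return np.asarray(x[:n], dtype=float).reshape(-1, factor).mean(axis=1)


def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """Pearson r; (0, degenerate=True) when either series has zero variance."""
    n = min(len(a), len(b))
    a, b = a[:n], b[:n]
    sa, sb = np.std(a), np.std(b)
    if sa == 0.0 or sb == 0.0 or n < 2:
        return 0.0, True
    return float(np.corrcoef(a, b)[0, 1]), False


def pairwise_correlation(
    x: np.ndarray, rate_x: float, y: np.ndarray, rate_y: float
) -> tuple[float, bool]:
    """Pearson correlation of two slices that may be sampled at different rates.

    The higher-rate series is reduced to the lower rate by non-overlapping
    block means before correlating.  Returns ``(r, degenerate)``.
    """
    if rate_x > rate_y:
        x = block_mean_downsample(x, int(round(rate_x / rate_y)))
    elif rate_y > rate_x:
        y = block_mean_downsample(y, int(round(rate_y / rate_x)))
    return _pearson(np.asarray(x, float), np.asarray(y, float))


def acc_features(
    segment_slices: dict[str, np.ndarray], rate: float, device: str = "wrist"
) -> tuple[dict[str, float], int]:
    """Motion-context features from a 3-axis accelerometer.

    Per-axis canonical features, pairwise axis correlations, and canonical
    features of the magnitude series sqrt(x² + y² + z²).  Returns
    ``(features, degenerate_count)``.
    """
    axes = {}
    for axis in ("x", "y", "z"):
        key = f"{device}/ACC_{axis}"
        if key not in segment_slices:
            raise ValidationError(f"missing accelerometer axis {key}")
        axes[axis] = np.asarray(segment_slices[key], dtype=float)

    feats: dict[str, float] = {}
    degenerate = 0
    for axis, x in axes.items():
        for fname, val in channel_features(x, rate).items():
            feats[f"ACC_{axis}__{fname}"] = val
    for a, b in combinations(("x", "y", "z"), 2):
        r, bad = _pearson(axes[a], axes[b])
        feats[f"corr__ACC_{a}__ACC_{b}"] = r
        degenerate += bad
    mag = np.sqrt(axes["x"] ** 2 + axes["y"] ** 2 + axes["z"] ** 2)
    for fname, val in channel_features(mag, rate).items():
        feats[f"ACC_mag__{fname}"] = val
    return feats, degenerate


def build_feature_table(
    segments: SegmentSet,
    modalities: list[str],
    device: str = "wrist",
    include_correlations: bool = True,
) -> pd.DataFrame:
    """One row per surviving segment; deterministic column order.

    ``modalities`` is an ordered list of channel names on ``device``; the
    special name ``"ACC"`` expands to the full motion-context block (three
    axes, axis correlations, magnitude).  Feature columns are named
    ``<channel>__<feature>``; correlation columns ``corr__<a>__<b>`` follow,
    in the order the pairs arise from the modality list.
    """
    for m in modalities:
        if m == "ACC":
            needed = [f"{device}/ACC_{ax}" for ax in ("x", "y", "z")]
        else:
            needed = [f"{device}/{m}"]
        for key in needed:
            if key not in segments.channel_rates:
                raise ValidationError(f"requested modality channel {key!r} not in recording")

    rows = []
    for seg in segments.segments:
        row: dict[str, float] = {}
        degenerate = 0
        plain = [m for m in modalities if m != "ACC"]
        for m in plain:
            key = f"{device}/{m}"
            feats = channel_features(seg.slices[key], segments.channel_rates[key])
            for fname, val in feats.items():
                row[f"{m}__{fname}"] = val
        if include_correlations:
            for a, b in combinations(plain, 2):
                ka, kb = f"{device}/{a}", f"{device}/{b}"
                r, bad = pairwise_correlation(
                    seg.slices[ka],
                    segments.channel_rates[ka],
                    seg.slices[kb],
                    segments.channel_rates[kb],
                )
                row[f"corr__{a}__{b}"] = r
                degenerate += bad
        if "ACC" in modalities:
            rate = segments.channel_rates[f"{device}/ACC_x"]
            feats, bad = acc_features(seg.slices, rate, device)
            row.update(feats)
            degenerate += bad
        row["subject_id"] = segments.subject_id
        row["segment_start_s"] = seg.start_s
        row["label"] = seg.label
        row["degenerate_count"] = degenerate
        rows.append(row)

    if not rows:
        return pd.DataFrame(columns=list(META_COLUMNS))
    df = pd.DataFrame(rows)
    feature_cols = [c for c in df.columns if c not in META_COLUMNS]
    df = df[list(META_COLUMNS) + feature_cols]
    bad = df[feature_cols].to_numpy()
    if not np.all(np.isfinite(bad)):
        raise ValidationError("non-finite feature value produced")
    return df


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The model-input columns of a feature table (meta columns excluded)."""
    return [c for c in table.columns if c not in META_COLUMNS]
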