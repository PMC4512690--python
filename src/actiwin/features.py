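"""Sliding-window segmentation and the time-domain feature bank.

A recording is cut into fixed-length windows (default 5 s advanced by 1 s at
100 Hz, i.e. N = 500 samples with a 4 s overlap between successive windows),
each wholly inside one single-activity segment.  Per window and per axis a
bank of time-domain statistics is computed — mean absolute value and two
weighted variants, harmonic mean, variance, RMS, skewness, kurtosis,
cumulative length, zero-crossing count, Willison amplitude and slope-sign
changes — plus the three pairwise Pearson correlations between the x, y and
z axes.  With the default 12 per-axis statistics one sensor yields
12 x 3 + 3 = 39 features; three sensors fused give 117.

The signal energy (simple squared integral, SSI = N * RMS^2) is implemented
and available behind ``include_ssi`` but excluded from the default bank: it
is a deterministic monotone function of RMS and carries no additional
information, and dropping it is what reconciles the 13 listed statistics
with the 39/117 feature-set widths the pipeline is built around.

All features are pure functions of the window's samples; guard rules map
mathematically undefined cases (zero sample in the harmonic mean, zero
variance in skewness/kurtosis/correlation) to 0 so the emitted matrix is
always finite.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AlignmentError, DomainError, SchemaError
from .signal_io import Recording, contiguous_segments

#: Frozen default per-axis feature order (axis-major layout: the full x block,
#: then y, then z, then corr_xy, corr_xz, corr_yz).
DEFAULT_PER_AXIS_FEATURES = (
    "mav", "wmav1", "wmav2", "hm", "variance", "rms",
    "skewness", "kurtosis", "cl", "zc", "wa", "ssc",
)

AXES = ("x", "y", "z")
CORR_PAIRS = ("xy", "xz", "yz")


@dataclass(frozen=True)
class FeatureBankConfig:
    """Windowing and feature-bank parameters.

    window_seconds / slide_seconds
        Window length w_t and advance between successive window starts, in
        seconds.  N = round(f_s * w_t) samples per window.
    willison_threshold
        epsilon (m/s^2) for the Willison amplitude count.
    include_ssi
        Add the signal energy to the per-axis bank (13 per axis, 42 per
        sensor) instead of the default 12/39.
    demean
        Subtract each window's per-axis mean before computing features
        (gravity removal); off by default — the bank is applied to raw
        acceleration so postural DC offsets remain discriminative.
    degenerate_tolerance
        Standard-deviation cutoff below which skewness, kurtosis and
        correlations fall back to the guard value 0.
    missing_max_frac
        Windows whose fraction of missing samples exceeds this are dropped;
        smaller amounts are filled by within-window linear interpolation.
    """

    window_seconds: float = 5.0
    slide_seconds: float = 1.0
    willison_threshold: float = 0.5
    include_ssi: bool = False
    demean: bool = False
    degenerate_tolerance: float = 1e-12
    missing_max_frac: float = 0.1
    feature_list: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.window_seconds <= 0 or self.slide_seconds <= 0:
            raise DomainError("window_seconds and slide_seconds must be positive")
        if self.willison_threshold < 0:
            raise DomainError("willison_threshold must be >= 0")

    @property
    def per_axis_features(self) -> tuple[str, ...]:
        if self.feature_list is not None:
            return tuple(self.feature_list)
        if self.include_ssi:
            return DEFAULT_PER_AXIS_FEATURES + ("ssi",)
        return DEFAULT_PER_AXIS_FEATURES

    def n_samples(self, sampling_rate: float) -> int:
        return int(round(sampling_rate * self.window_seconds))

    def step(self, sampling_rate: float) -> int:
        return int(round(sampling_rate * self.slide_seconds))


@dataclass
class Window:
    """One fixed-length slice of one sensor's tri-axial samples."""

    placement: str
    activity: int
    samples: np.ndarray  # (N, 3)
    start: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise DomainError("window samples must be an (N, 3) array")


@dataclass
class FeatureMatrix:
    """Instances x named features with aligned class labels."""

    names: list[str]
    values: np.ndarray  # (n_instances, n_features)
    labels: np.ndarray  # (n_instances,)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).reshape(-1, len(self.names))
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.labels) != len(self.values):
            raise AlignmentError("labels and feature rows differ in length")

    @property
    def width(self) -> int:
        return len(self.names)

    def __len__(self) -> int:
        return len(self.values)

    def select(self, indices) -> "FeatureMatrix":
        """Column subset by integer indices (order preserved as given)."""
        idx = list(indices)
        return FeatureMatrix([self.names[i] for i in idx], self.values[:, idx], self.labels)

    def take(self, rows) -> "FeatureMatrix":
        rows = np.asarray(rows)
        return FeatureMatrix(list(self.names), self.values[rows], self.labels[rows])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df["activity"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, float_precision="round_trip")
        if "activity" not in df.columns:
            raise SchemaError(f"{path}: feature CSV lacks the 'activity' label column")
        labels = df.pop("activity").to_numpy(dtype=np.int64)
        return cls(list(df.columns), df.to_numpy(dtype=np.float64), labels)

    def cache_save(self, path) -> None:
        """Compact binary cache (npz) of the matrix."""
        np.savez_compressed(
            path, values=self.values, labels=self.labels,
            names=np.array(json.dumps(self.names)),
        )

    @classmethod
    def cache_load(cls, path) -> "FeatureMatrix":
        with np.load(path, allow_pickle=False) as z:
            return cls(json.loads(str(z["names"])), z["values"], z["labels"])


# --------------------------------------------------------------------------
# Windowing
# --------------------------------------------------------------------------


def segment(
    rec: Recording,
    cfg: FeatureBankConfig | None = None,
    include_transient: bool = False,
) -> dict[str, list[Window]]:
    """Cut a recording into per-sensor fixed-length windows.

    Windows are index-based (sample counts, not wall-clock), never straddle
    an activity boundary, and advance by ``round(f_s * slide_seconds)``
    within each contiguous single-activity segment.  Transient/break
    segments are excluded unless ``include_transient``.  Windows whose
    missing-sample fraction exceeds ``cfg.missing_max_frac`` are dropped;
    remaining gaps inside kept windows are linearly interpolated so every
    emitted window is finite.
    """
    cfg = cfg or FeatureBankConfig()
    n = cfg.n_samples(rec.sampling_rate)
    step = cfg.step(rec.sampling_rate)
    segments = [
        s for s in contiguous_segments(rec) if include_transient or not s.is_transient
    ]
    out: dict[str, list[Window]] = {}
    for placement, stream in rec.sensors.items():
        data = stream.as_array()
        windows: list[Window] = []
        for seg in segments:
            for start in range(seg.start, seg.stop - n + 1, step):
                block = data[start : start + n]
                miss = np.isnan(block).any(axis=1)
                if miss.mean() > cfg.missing_max_frac:
                    continue
                if miss.any():
                    block = _fill_window(block)
                windows.append(Window(placement, seg.code, block, start))
        out[placement] = windows
    return out


def _fill_window(block: np.ndarray) -> np.ndarray:
    """Per-axis linear interpolation of NaNs inside one window (edges held)."""
    block = block.copy()
    idx = np.arange(len(block))
    for a in range(block.shape[1]):
        col = block[:, a]
        bad = np.isnan(col)
        if bad.any():
            col[bad] = np.interp(idx[bad], idx[~bad], col[~bad])
    return block


# --------------------------------------------------------------------------
# Per-axis features: vectorized kernels over (m, N) window stacks
# --------------------------------------------------------------------------


def _wmav_weights(n: int, window_id: int) -> np.ndarray:
    """Weight vectors w1/w2 over 1-based sample index i.

    w1 is 1 on the central band 0.25N <= i <= 0.75N and 0.5 outside it;
    w2 is 1 on the same band and ramps linearly (4i/N rising, 4(N-i)/N
    falling) outside it.
    """
    i = np.arange(1, n + 1, dtype=np.float64)
    band = (i >= 0.25 * n) & (i <= 0.75 * n)
    if window_id == 1:
        return np.where(band, 1.0, 0.5)
    if window_id == 2:
        w = np.where(i < 0.25 * n, 4.0 * i / n, 4.0 * (n - i) / n)
        return np.where(band, 1.0, w)
    raise DomainError(f"window_id must be 1 or 2, got {window_id}")


def _kernel_bank(X: np.ndarray, cfg: FeatureBankConfig) -> dict[str, np.ndarray]:
    """All per-axis statistics for a stack of windows X of shape (m, N)."""
    m, n = X.shape
    tol = cfg.degenerate_tolerance
    absX = np.abs(X)
    diffs = np.diff(X, axis=1)
    mu = X.mean(axis=1)
    var = X.var(axis=1)  # population (divide by N)
    sigma = np.sqrt(var)
    rms = np.sqrt((X * X).mean(axis=1))

    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(X != 0.0, 1.0 / np.where(X == 0.0, 1.0, X), 0.0)
        # extended precision: the reciprocal sum is cancellation-prone
        inv_sum = inv.astype(np.longdouble).sum(axis=1)
        hm = np.asarray(n / inv_sum, dtype=np.float64)
    hm[(X == 0.0).any(axis=1) | ~np.isfinite(hm)] = 0.0

    degenerate = sigma < tol
    skew = sps.skew(X, axis=1, bias=True)
    kurt = sps.kurtosis(X, axis=1, fisher=False, bias=True)
    skew = np.where(degenerate, 0.0, np.nan_to_num(skew))
    kurt = np.where(degenerate, 0.0, np.nan_to_num(kurt))

    out = {
        "mav": absX.mean(axis=1),
        "wmav1": (absX * _wmav_weights(n, 1)).mean(axis=1),
        "wmav2": (absX * _wmav_weights(n, 2)).mean(axis=1),
        "hm": hm,
        "variance": var,
        "rms": rms,
        "skewness": skew,
        "kurtosis": kurt,
        "cl": np.abs(diffs).sum(axis=1),
        "zc": (
            ((X[:, :-1] > 0) & (X[:, 1:] < 0)) | ((X[:, :-1] < 0) & (X[:, 1:] > 0))
        ).sum(axis=1).astype(np.float64),
        "wa": (np.abs(diffs) > cfg.willison_threshold).sum(axis=1).astype(np.float64),
        "ssc": (
            ((X[:, 1:-1] > X[:, :-2]) & (X[:, 1:-1] > X[:, 2:]))
            | ((X[:, 1:-1] < X[:, :-2]) & (X[:, 1:-1] < X[:, 2:]))
        ).sum(axis=1).astype(np.float64),
        "ssi": (X * X).sum(axis=1),
        "_mu": mu, "_sigma": sigma,
    }
    return out


def _pairwise_corr(stack: np.ndarray, tol: float) -> np.ndarray:
    """Pearson correlations (xy, xz, yz) for a stack of (m, N, 3) windows."""
    centered = stack - stack.mean(axis=1, keepdims=True)
    sigma = centered.std(axis=1)  # (m, 3), population
    out = np.zeros((stack.shape[0], 3))
    pairs = ((0, 1), (0, 2), (1, 2))
    for k, (a, b) in enumerate(pairs):
        cov = (centered[:, :, a] * centered[:, :, b]).mean(axis=1)
        denom = sigma[:, a] * sigma[:, b]
        ok = (sigma[:, a] >= tol) & (sigma[:, b] >= tol)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = cov / denom
        out[:, k] = np.where(ok, np.nan_to_num(np.clip(r, -1.0, 1.0)), 0.0)
    return out


# --------------------------------------------------------------------------
# Scalar reference surface (single-series operations)
# --------------------------------------------------------------------------


def _as_series(x, min_len: int = 1) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise DomainError("expected a one-dimensional sample series")
    if len(x) < min_len:
        raise DomainError(f"series of length {len(x)} below minimum {min_len}")
    return x


def mav(x) -> float:
    """Mean absolute value: (1/N) * sum |x_i|."""
    return float(np.abs(_as_series(x)).mean())


def wmav(x, window_id: int) -> float:
    """Windowed MAV with trapezoid-like weight w1 (id 1) or w2 (id 2)."""
    x = _as_series(x)
    return float((np.abs(x) * _wmav_weights(len(x), window_id)).mean())


def harmonic_mean(x) -> float:
    """Harmonic mean N / sum(1/x_i) of the raw signed samples; 0 if any sample is 0."""
    x = _as_series(x)
    if (x == 0.0).any():
        return 0.0
    # fsum: reciprocals of signed samples may cancel to near zero, where
    # plain summation order would visibly perturb the quotient
    s = math.fsum(1.0 / x)
    if s == 0.0:
        return 0.0
    val = len(x) / s
    return float(val) if np.isfinite(val) else 0.0


def central_moments(x, degenerate_tolerance: float = 1e-12):
    """(variance, rms, skewness, kurtosis) with population normalization.

    Skewness and kurtosis fall back to 0 when the standard deviation is
    below ``degenerate_tolerance`` (constant windows).
    """
    x = _as_series(x)
    var = float(x.var())
    rms = float(np.sqrt((x * x).mean()))
    sigma = np.sqrt(var)
    if sigma < degenerate_tolerance:
        return var, rms, 0.0, 0.0
    return (
        var, rms,
        float(sps.skew(x, bias=True)),
        float(sps.kurtosis(x, fisher=False, bias=True)),
    )


def cumulative_length(x) -> float:
    """Waveform length: sum of absolute first differences."""
    return float(np.abs(np.diff(_as_series(x, 2))).sum())


def zero_crossings(x) -> int:
    """Count of strict sign changes between adjacent samples (zeros never count)."""
    x = _as_series(x, 2)
    a, b = x[:-1], x[1:]
    return int((((a > 0) & (b < 0)) | ((a < 0) & (b > 0))).sum())


def willison_amplitude(x, threshold: float) -> int:
    """Count of adjacent-sample absolute differences strictly above ``threshold``."""
    if threshold < 0:
        raise DomainError("threshold must be >= 0")
    return int((np.abs(np.diff(_as_series(x, 2))) > threshold).sum())


def slope_sign_changes(x) -> int:
    """Count of strict interior local extrema (plateaus never count)."""
    x = _as_series(x, 3)
    mid, left, right = x[1:-1], x[:-2], x[2:]
    return int((((mid > left) & (mid > right)) | ((mid < left) & (mid < right))).sum())


def simple_squared_integral(x) -> float:
    """Signal energy: sum of squared samples (= N * RMS^2)."""
    x = _as_series(x)
    return float((x * x).sum())


def axis_correlations(w: Window, degenerate_tolerance: float = 1e-12):
    """Pearson correlations (r_xy, r_xz, r_yz); 0 if either axis is constant."""
    if len(w.samples) < 2:
        raise DomainError("correlation needs at least 2 samples")
    r = _pairwise_corr(w.samples[None, :, :], degenerate_tolerance)[0]
    return float(r[0]), float(r[1]), float(r[2])


# --------------------------------------------------------------------------
# Feature-matrix assembly
# --------------------------------------------------------------------------


def feature_names(placement: str, cfg: FeatureBankConfig | None = None) -> list[str]:
    """The frozen column order for one sensor: x block, y block, z block, correlations."""
    cfg = cfg or FeatureBankConfig()
    names = [f"{placement}.{ax}.{f}" for ax in AXES for f in cfg.per_axis_features]
    names += [f"{placement}.corr.{p}" for p in CORR_PAIRS]
    return names


def extract_features(windows: list[Window], cfg: FeatureBankConfig | None = None) -> FeatureMatrix:
    """Compute the feature bank for a list of same-sensor, same-length windows.

    Emits one row per window in input order; columns follow
    :func:`feature_names`.  Guard rules guarantee a finite matrix.
    """
    cfg = cfg or FeatureBankConfig()
    if not windows:
        names = feature_names("sensor", cfg)
        return FeatureMatrix(names, np.empty((0, len(names))), np.empty(0, dtype=np.int64))
    placement = windows[0].placement
    n = len(windows[0].samples)
    for w in windows:
        if w.placement != placement or len(w.samples) != n:
            raise AlignmentError("all windows must share one sensor and window length")
    stack = np.stack([w.samples for w in windows])  # (m, N, 3)
    if cfg.demean:
        stack = stack - stack.mean(axis=1, keepdims=True)
    enabled = cfg.per_axis_features
    blocks = []
    for a in range(3):
        bank = _kernel_bank(stack[:, :, a], cfg)
        blocks.append(np.column_stack([bank[f] for f in enabled]))
    corr = _pairwise_corr(stack, cfg.degenerate_tolerance)
    values = np.hstack(blocks + [corr])
    values = np.nan_to_num(values, nan=0.0, posinf=0.0, neginf=0.0)
    labels = np.array([w.activity for w in windows], dtype=np.int64)
    return FeatureMatrix(feature_names(placement, cfg), values, labels)


def fuse(matrices: list[FeatureMatrix]) -> FeatureMatrix:
    """Column-concatenate per-sensor matrices with aligned instances.

    Labels must agree instance-by-instance and feature names must be
    disjoint (they are namespaced by placement).
    """
    if not matrices:
        raise DomainError("fuse needs at least one matrix")
    if len(matrices) == 1:
        return matrices[0]
    first = matrices[0]
    names: list[str] = []
    for fm in matrices:
        if len(fm) != len(first):
            raise AlignmentError("instance counts differ across sensors")
        if not np.array_equal(fm.labels, first.labels):
            raise AlignmentError("labels are not aligned across sensors")
        overlap = set(names) & set(fm.names)
        if overlap:
            raise AlignmentError(f"duplicate feature names across matrices: {sorted(overlap)[:5]}")
        names.extend(fm.names)
    values = np.hstack([fm.values for fm in matrices])
    return FeatureMatrix(names, values, first.labels)


def extract_recording(
    rec: Recording,
    cfg: FeatureBankConfig | None = None,
    placements: tuple[str, ...] | None = None,
) -> dict[str, FeatureMatrix]:
    """Convenience: segment a recording and extract one matrix per sensor."""
    cfg = cfg or FeatureBankConfig()
    per_sensor = segment(rec, cfg)
    keep = placements or tuple(per_sensor)
    return {p: extract_features(per_sensor[p], cfg) for p in keep}
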