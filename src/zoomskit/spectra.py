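"""MALDI-TOF spectrum handling: I/O, baseline, smoothing, peak picking.

The preprocessing contract is explicit so results are reproducible: a
rolling-minimum baseline (window a fraction of the m/z span) linearised by a
moving average and subtracted; Savitzky-Golay smoothing; noise estimated as
the MAD of intensities in a sliding m/z window, scaled to a Gaussian
sigma-equivalent; peaks are local maxima above an S/N threshold (3.0-5.0 is
the conventional MALDI range) with the apex refined by three-point parabolic
interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import minimum_filter1d, uniform_filter1d
from scipy.signal import savgol_filter

_MAD_TO_SIGMA = 1.4826


@dataclass
class Spectrum:
    """A MALDI spectrum: ascending m/z with nonnegative intensities."""

    sample_id: str
    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("m/z and intensity must be equal-length 1-D arrays")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")
        if len(self.mz) > 1 and np.any(np.diff(self.mz) <= 0):
            if np.any(np.diff(np.sort(self.mz)) == 0):
                raise ValueError("duplicate m/z values")
            warnings.warn("m/z not ascending; sorting", stacklevel=2)
            order = np.argsort(self.mz)
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class Peak:
    """A picked peak with its local signal-to-noise ratio."""

    mz: float
    intensity: float
    snr: float

    def __post_init__(self) -> None:
        if self.snr < 0:
            raise ValueError("snr must be >= 0")


@dataclass(frozen=True)
class PreprocessParams:
    """Baseline / smoothing / noise / picking parameters.

    baseline_frac: rolling-minimum window as a fraction of the m/z span.
    smooth_points, smooth_order: Savitzky-Golay window (odd) and poly order.
    noise_window: sliding window (Da) for the MAD noise estimate.
    snr_threshold: minimum S/N for a reported peak (conventionally 3.0-5.0).
    """

    baseline_frac: float = 0.05
    smooth_points: int = 7
    smooth_order: int = 2
    noise_window: float = 100.0
    snr_threshold: float = 3.0

    def __post_init__(self) -> None:
        if self.baseline_frac <= 0 or self.noise_window <= 0:
            raise ValueError("windows must be positive")
        if self.smooth_points < 3 or self.smooth_points % 2 == 0:
            raise ValueError("smooth_points must be odd and >= 3")
        if self.smooth_order >= self.smooth_points:
            raise ValueError("smooth_order must be < smooth_points")
        if self.snr_threshold <= 0:
            raise ValueError("snr threshold must be > 0")


def read_spectrum(path, dialect: str = "peaklist", sample_id: str | None = None) -> Spectrum:
    """Read a spectrum from a two-column text peak list or an mzML file.

    The peak-list dialect accepts whitespace- or comma-separated columns,
    ``#`` comments and a single non-numeric header line.
    """
    sid = sample_id or str(path)
    if dialect == "mzml":
        from pyteomics import mzml as _mzml

        with _mzml.MzML(str(path)) as reader:
            spec = next(iter(reader))
        return Spectrum(sid, spec["m/z array"], spec["intensity array"])
    if dialect != "peaklist":
        raise ValueError(f"unknown dialect {dialect!r}")
    mzs, intens = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            try:
                x, y = float(parts[0]), float(parts[1])
            except (ValueError, IndexError):
                if not mzs:  # tolerate one header line
                    continue
                raise ValueError(f"unparseable peak-list line: {line!r}")
            mzs.append(x)
            intens.append(y)
    return Spectrum(sid, np.array(mzs), np.array(intens))


def write_peaklist(spectrum: Spectrum, path, fmt: str = "%.6g") -> None:
    """Write a spectrum (or picked peaks) as a two-column text peak list."""
    with open(path, "w") as fh:
        fh.write("# m/z intensity\n")
        for x, y in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{fmt % x}\t{fmt % y}\n")


def is_centroided(s: Spectrum, min_profile_spacing: float = 0.5) -> bool:
    """Heuristic: sparse point spacing indicates centroided (stick) data."""
    if len(s) < 3:
        return True
    return float(np.median(np.diff(s.mz))) > min_profile_spacing


def estimate_baseline(s: Spectrum, p: PreprocessParams = PreprocessParams()) -> np.ndarray:
    """Rolling-minimum baseline, linearised by a moving average."""
    n = len(s)
    w = max(3, int(round(p.baseline_frac * n)))
    if w > n:
        raise ValueError("baseline window larger than spectrum")
    base = minimum_filter1d(s.intensity, size=w, mode="nearest")
    return uniform_filter1d(base, size=w, mode="nearest")


def preprocess(s: Spectrum, p: PreprocessParams = PreprocessParams()) -> Spectrum:
    """Baseline-subtract and smooth a profile spectrum (intensities >= 0)."""
    if len(s) == 0:
        raise ValueError("empty spectrum")
    if p.smooth_points > len(s):
        raise ValueError("smoothing window larger than spectrum")
    y = s.intensity - estimate_baseline(s, p)
    np.clip(y, 0.0, None, out=y)
    y = savgol_filter(y, p.smooth_points, p.smooth_order)
    np.clip(y, 0.0, None, out=y)
    return Spectrum(s.sample_id, s.mz.copy(), y, dict(s.metadata))


def _local_stats(s: Spectrum, window: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-point (local median, sigma-scaled MAD) from ``window``-Da segments.

    Segment statistics are computed from the start of the spectrum and
    linearly interpolated at each point, which keeps the estimate cheap and
    makes it equivariant under a global m/z shift.
    """
    if len(s) == 0:
        return np.zeros(0), np.zeros(0)
    edges = np.arange(s.mz[0], s.mz[-1] + window, window)
    centers, meds, levels = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (s.mz >= lo) & (s.mz < hi)
        if not np.any(sel):
            continue
        seg = s.intensity[sel]
        med = np.median(seg)
        mad = np.median(np.abs(seg - med))
        centers.append(0.5 * (lo + hi))
        meds.append(med)
        levels.append(_MAD_TO_SIGMA * mad)
    if not centers:
        return np.zeros(len(s)), np.zeros(len(s))
    center = np.interp(s.mz, centers, meds)
    noise = np.interp(s.mz, centers, levels)
    floor = max(1e-12, 1e-6 * float(np.max(s.intensity)) or 1e-12)
    return center, np.maximum(noise, floor)


def noise_profile(s: Spectrum, window: float = 100.0) -> np.ndarray:
    """Per-point noise level: sigma-scaled MAD in ``window``-Da segments."""
    return _local_stats(s, window)[1]


def pick_peaks(s: Spectrum, p: PreprocessParams = PreprocessParams()) -> list[Peak]:
    """Local maxima with S/N >= threshold; apex refined parabolically.

    Centroided input (sparse sticks) is returned as peaks directly, with S/N
    against the global noise level. Peaks are sorted by m/z.
    """
    n = len(s)
    if n == 0:
        return []
    if is_centroided(s):
        seg = s.intensity
        mad = np.median(np.abs(seg - np.median(seg)))
        sigma = max(_MAD_TO_SIGMA * mad, 1e-12)
        return [
            Peak(float(x), float(y), float(y / sigma))
            for x, y in zip(s.mz, s.intensity)
            if y / sigma >= p.snr_threshold
        ]
    y = s.intensity
    center, noise = _local_stats(s, p.noise_window)
    idx = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])) + 1
    # S/N of a candidate apex: height above the local noise-floor median,
    # relative to the sigma-equivalent MAD of the same window
    snr = (y[idx] - center[idx]) / noise[idx]
    keep = snr >= p.snr_threshold
    idx, snr = idx[keep], snr[keep]
    denom = y[idx - 1] - 2 * y[idx] + y[idx + 1]
    shift = np.where(
        denom < 0,
        np.clip(0.5 * (y[idx - 1] - y[idx + 1]) / np.where(denom < 0, denom, -1.0), -0.5, 0.5),
        0.0,
    )
    dx = 0.5 * (s.mz[idx + 1] - s.mz[idx - 1])
    apex = s.mz[idx] + shift * dx
    return [
        Peak(float(x), float(h), float(r))
        for x, h, r in zip(apex, y[idx], snr)
    ]
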