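"""Per-cell Myo-II intensity / basal-area dynamics and their coupling.

Rates are first differences over the frame interval (shortest memory at 6 s
sampling; an optional 3-point moving average is off by default). The
area-reduction rate is the negated area rate, so positive means contraction.
Cross-correlograms use the convention R(tau) = corr(x(t), y(t + tau)): a
*positive* peak offset means the intensity rate precedes the area-reduction
rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .angular import compare_groups
from .errors import ConfigurationError


@dataclass
class PulseSeries:
    """Time-aligned mean Myo-II intensity and basal area of one cell."""

    cell_id: int
    times: np.ndarray      # s, uniform
    intensity: np.ndarray  # A.U.
    area: np.ndarray       # µm²

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        n = self.times.size
        if not (self.intensity.size == n and self.area.size == n):
            raise ConfigurationError(
                f"cell {self.cell_id}: series lengths differ")
        if n < 10:
            raise ConfigurationError(
                f"cell {self.cell_id}: needs >= 10 time points, got {n}")
        dt = np.diff(self.times)
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
            raise ConfigurationError(
                f"cell {self.cell_id}: non-uniform sampling")
        if np.any(self.area <= 0):
            raise ConfigurationError(f"cell {self.cell_id}: area must be > 0")

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])


def series_from_table(table: pd.DataFrame) -> list[PulseSeries]:
    """Split a tidy (cell_id, time_s, intensity, area_um2) table per cell."""
    out = []
    for cid, g in table.groupby("cell_id", sort=True):
        g = g.sort_values("time_s")
        out.append(PulseSeries(int(cid), g["time_s"].to_numpy(),
                               g["intensity"].to_numpy(),
                               g["area_um2"].to_numpy()))
    return out


def extract_pulse_series(movie, background: str = "median-outside"
                         ) -> list[PulseSeries]:
    """Per-cell mean intensity and area series from a movie + label mask.

    Intensity is the background-subtracted mean over each cell's mask;
    background is the per-frame median over unlabelled pixels (0 if the
    labels tile the whole frame).
    """
    if movie.labels is None:
        raise ConfigurationError("movie has no label mask")
    px = movie.metadata.pixel_size
    times = movie.times_s
    cells = [c for c in np.unique(movie.labels) if c != 0]
    intens = {c: [] for c in cells}
    areas = {c: [] for c in cells}
    for f in range(movie.n_frames):
        img = movie.data[f].astype(float)
        lab = movie.labels[f]
        outside = img[lab == 0]
        bg = float(np.median(outside)) if outside.size else 0.0
        for c in cells:
            mask = lab == c
            n = int(mask.sum())
            intens[c].append(img[mask].mean() - bg if n else np.nan)
            areas[c].append(n * px ** 2)
    return [PulseSeries(int(c), times, np.array(intens[c]),
                        np.array(areas[c])) for c in cells]


# ---------------------------------------------------------------------------
# Rates, amplitudes, contraction
# ---------------------------------------------------------------------------

def rate_of_change(values, frame_interval: float,
                   smooth: bool = False) -> np.ndarray:
    """First difference / frame interval; length n-1."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ConfigurationError("rate_of_change needs >= 3 points")
    rate = np.diff(v) / frame_interval
    if smooth:
        rate = np.convolve(rate, np.ones(3) / 3.0, mode="same")
    return rate


def intensity_rate(series: PulseSeries, smooth: bool = False) -> np.ndarray:
    return rate_of_change(series.intensity, series.frame_interval, smooth)


def area_reduction_rate(series: PulseSeries,
                        smooth: bool = False) -> np.ndarray:
    """Negated area rate: positive while the cell contracts."""
    return -rate_of_change(series.area, series.frame_interval, smooth)


def amplitude(values, detrend: bool = False) -> float:
    """max - min of the (optionally linearly detrended) series."""
    v = np.asarray(values, dtype=float)
    if v.size < 10:
        raise ConfigurationError("amplitude needs >= 10 points")
    if detrend:
        t = np.arange(v.size)
        v = v - np.polyval(np.polyfit(t, v, 1), t)
    return float(v.max() - v.min())


def area_contraction_ratio(area) -> float:
    """min(area) / max(area), in (0, 1]; 1 = no contraction."""
    a = np.asarray(area, dtype=float)
    if np.any(a <= 0):
        raise ConfigurationError("area must be positive throughout")
    return float(a.min() / a.max())


# ---------------------------------------------------------------------------
# Cross-correlograms
# ---------------------------------------------------------------------------

@dataclass
class Correlogram:
    """Correlation-vs-offset curve; positive offset = x precedes y."""

    offsets_s: np.ndarray
    R: np.ndarray
    peak_offset_s: float
    peak_R: float
    n_cells: int = 1
    R_sem: np.ndarray | None = None
    excluded: list = field(default_factory=list)

    @property
    def mean_R(self) -> float:
        """Scalar summary: mean correlation over all offsets."""
        return float(np.nanmean(self.R))


def _peak(offsets: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    """Argmax with ties broken toward the smallest |offset| (then the
    earlier offset)."""
    finite = np.isfinite(r)
    if not finite.any():
        raise ConfigurationError("correlogram has no finite values")
    rmax = np.max(r[finite])
    tied = np.nonzero(finite & np.isclose(r, rmax, rtol=0, atol=1e-12))[0]
    best = tied[np.lexsort((offsets[tied], np.abs(offsets[tied])))[0]]
    return float(offsets[best]), float(r[best])


def _correlation_curve(x, y, max_offset_frames: int) -> np.ndarray:
    """R(tau) for integer-frame offsets in [-max, +max]; NaN where a
    segment has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ConfigurationError("series must have equal length")
    n = x.size
    if n - max_offset_frames < 10:
        raise ConfigurationError(
            f"need >= 10 overlapping points at every offset: series of "
            f"length {n} with max offset {max_offset_frames}")
    offsets = np.arange(-max_offset_frames, max_offset_frames + 1)
    r = np.empty(offsets.size)
    for i, k in enumerate(offsets):
        if k >= 0:
            a, b = x[:n - k], y[k:]
        else:
            a, b = x[-k:], y[:n + k]
        if a.std() == 0 or b.std() == 0:
            r[i] = np.nan
        else:
            r[i] = float(np.corrcoef(a, b)[0, 1])
    return r


def cross_correlogram(x, y, frame_interval: float,
                      max_offset_frames: int = 10) -> Correlogram:
    """Pearson correlation of two equally-sampled series at every integer
    frame offset in [-max, +max]; R(tau) = corr(x(t), y(t + tau))."""
    r = _correlation_curve(x, y, max_offset_frames)
    offsets = np.arange(-max_offset_frames, max_offset_frames + 1)
    peak_off, peak_r = _peak(offsets * frame_interval, r)
    return Correlogram(offsets_s=offsets * frame_interval, R=r,
                       peak_offset_s=peak_off, peak_R=peak_r)


def cell_averaged_correlogram(series_list: list[PulseSeries],
                              max_offset_frames: int = 10,
                              smooth: bool = False) -> Correlogram:
    """Condition-level correlogram: unweighted mean of per-cell R(tau)
    between intensity rate and area-reduction rate, one value per offset.

    Cells with a zero-variance segment at some offset are excluded at that
    offset (recorded in ``excluded``). The peak offset is the argmax of the
    averaged curve, ties toward the smallest |offset|.
    """
    if not series_list:
        raise ConfigurationError("no pulse series given")
    dt = series_list[0].frame_interval
    curves = []
    excluded = []
    offsets_frames = np.arange(-max_offset_frames, max_offset_frames + 1)
    for s in series_list:
        if abs(s.frame_interval - dt) > 1e-9:
            raise ConfigurationError("series have differing frame intervals")
        r = _correlation_curve(intensity_rate(s, smooth),
                               area_reduction_rate(s, smooth),
                               max_offset_frames)
        if np.isnan(r).any():
            excluded.append((s.cell_id,
                             (offsets_frames[np.isnan(r)] * dt).tolist()))
        curves.append(r)
    stack = np.vstack(curves)
    mean_r = np.nanmean(stack, axis=0)
    with np.errstate(invalid="ignore"):
        sem = np.nanstd(stack, axis=0, ddof=1) / np.sqrt(
            np.sum(np.isfinite(stack), axis=0))
    offsets_s = np.arange(-max_offset_frames, max_offset_frames + 1) * dt
    peak_off, peak_r = _peak(offsets_s, mean_r)
    return Correlogram(offsets_s=offsets_s, R=mean_r,
                       peak_offset_s=peak_off, peak_R=peak_r,
                       n_cells=len(series_list), R_sem=sem,
                       excluded=excluded)


# ---------------------------------------------------------------------------
# Condition comparison
# ---------------------------------------------------------------------------

def compare_pulses(cells_a: list[PulseSeries],
                   cells_b: list[PulseSeries],
                   detrend: bool = False) -> pd.DataFrame:
    """Two-sided t-tests comparing per-cell pulse statistics of two
    conditions: amplitude of intensity change, amplitude of area change,
    and area contraction ratio."""
    if len(cells_a) < 2 or len(cells_b) < 2:
        raise ConfigurationError("each condition needs >= 2 cells")
    rows = []
    metrics = {
        "intensity_amplitude": lambda s: amplitude(s.intensity, detrend),
        "area_amplitude": lambda s: amplitude(s.area, detrend),
        "area_contraction_ratio": lambda s: area_contraction_ratio(s.area),
    }
    for name, fn in metrics.items():
        res = compare_groups([fn(s) for s in cells_a],
                             [fn(s) for s in cells_b])
        rows.append({"metric": name, **res})
    return pd.DataFrame(rows)
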