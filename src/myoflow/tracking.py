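"""Detection, size estimation and linking of dot-like Myo-II puncta.

Detection is a scale-normalized Laplacian-of-Gaussian band-pass tuned to the
expected dot size, followed by 8-connected local maxima above a robust
SNR threshold and sub-pixel refinement by a local 2D Gaussian fit; the dot
"size" reported everywhere in this package is the FWHM of that fit.

Linking is gap-free optimal nearest-neighbour assignment per frame pair
(Hungarian algorithm on inter-frame distances, gated by ``max_step``): dots
are dense and short-lived, so gap closing would fabricate steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_laplace, maximum_filter
from scipy.optimize import curve_fit, linear_sum_assignment

from .errors import CalibrationError, ConfigurationError
from .geometry import movement_angle, pixels_to_um
from .io import Movie

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))  # sigma -> FWHM factor (2.355)

SPOT_COLUMNS = ["frame", "x_um", "y_um", "diameter_um", "intensity", "snr",
                "cell_id"]


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_spots(image: np.ndarray, pixel_size: float,
                 expected_diameter: float, snr_threshold: float = 5.0,
                 estimate_size: bool = True, frame: int = 0,
                 labels: np.ndarray | None = None) -> pd.DataFrame:
    """Detect puncta in one calibrated frame.

    Parameters
    ----------
    image : 2D array, one movie frame.
    pixel_size : µm per pixel (must be provided; units are never assumed).
    expected_diameter : expected dot FWHM in µm; sets the band-pass scale.
    snr_threshold : local-maximum threshold in units of the robust noise SD
        of the band-pass response.
    estimate_size : fit a local 2D Gaussian per spot (sub-pixel position and
        FWHM). If False, positions come from an intensity-weighted centroid
        and ``diameter_um`` is the expected value (faster; used when only
        positions are needed).

    Returns a table with columns frame, x_um, y_um, diameter_um, intensity
    (peak above local background), snr and cell_id (0 unless ``labels``).
    """
    if pixel_size is None or pixel_size <= 0:
        raise CalibrationError(f"pixel_size must be > 0, got {pixel_size}")
    fwhm_px = expected_diameter / pixel_size
    if fwhm_px < 2.0:
        raise ConfigurationError(
            f"expected_diameter = {expected_diameter} µm is below 2 pixels "
            f"({fwhm_px:.2f} px) at {pixel_size} µm/px")
    img = np.asarray(image, dtype=float)
    if np.issubdtype(np.asarray(image).dtype, np.integer) and \
            img.max() >= np.iinfo(np.asarray(image).dtype).max:
        warnings.warn("frame contains saturated pixels; sizes and positions "
                      "of saturated spots are unreliable", stacklevel=2)

    # band-pass at the blob scale: sigma_det = FWHM / 2.355 / sqrt(2)
    sigma_det = fwhm_px / _FWHM / np.sqrt(2.0)
    response = -(sigma_det ** 2) * gaussian_laplace(img, sigma_det)
    med = np.median(response)
    noise = 1.4826 * np.median(np.abs(response - med)) + 1e-12

    is_max = (response == maximum_filter(response, size=3))
    is_max &= response > med + snr_threshold * noise
    half = max(3, int(np.ceil(fwhm_px)))
    is_max[:half, :] = is_max[-half:, :] = False
    is_max[:, :half] = is_max[:, -half:] = False
    rows, cols = np.nonzero(is_max)

    records = []
    sigma0 = fwhm_px / _FWHM
    for r, c in zip(rows, cols):
        win = img[r - half:r + half + 1, c - half:c + half + 1]
        fit = _fit_spot(win, sigma0, do_fit=estimate_size)
        if fit is None:
            continue
        dr, dc, sigma, amp = fit
        # a fit pushing against the window edge means the spot is wider than
        # the expected scale: refit with a window matched to the fitted width
        if estimate_size and sigma > 0.55 * half:
            half2 = int(np.ceil(3.0 * sigma)) + 1
            rlo, rhi = r - half2, r + half2 + 1
            clo, chi = c - half2, c + half2 + 1
            if rlo >= 0 and clo >= 0 and rhi <= img.shape[0] \
                    and chi <= img.shape[1]:
                refit = _fit_spot(img[rlo:rhi, clo:chi], sigma,
                                  do_fit=True)
                if refit is not None:
                    dr, dc, sigma, amp = refit
        records.append((frame, r + dr, c + dc,
                        sigma * _FWHM * pixel_size, amp,
                        (response[r, c] - med) / noise))
    if not records:
        return pd.DataFrame(columns=SPOT_COLUMNS)
    out = pd.DataFrame(records, columns=["frame", "row", "col",
                                         "diameter_um", "intensity", "snr"])
    if not estimate_size:
        out["diameter_um"] = expected_diameter
    x, y = pixels_to_um(out.pop("row"), out.pop("col"),
                        img.shape[0], pixel_size)
    out.insert(1, "x_um", x)
    out.insert(2, "y_um", y)
    out["cell_id"] = 0
    if labels is not None:
        rr = np.clip(np.rint(img.shape[0] - 1 - y / pixel_size).astype(int),
                     0, labels.shape[0] - 1)
        cc = np.clip(np.rint(x / pixel_size).astype(int),
                     0, labels.shape[1] - 1)
        out["cell_id"] = labels[rr, cc]
    return out


def _gauss2d(coords, amp, r0, c0, sigma, offset):
    rr, cc = coords
    return (offset + amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2)
                                  / (2.0 * sigma ** 2))).ravel()


def _fit_spot(win: np.ndarray, sigma0: float, do_fit: bool):
    """Refine one local maximum. Returns (drow, dcol, sigma, amplitude)
    relative to the window centre, or None if the window is degenerate."""
    if win.size == 0 or win.shape[0] != win.shape[1]:
        return None
    half = win.shape[0] // 2
    bg = float(np.median(np.concatenate([win[0], win[-1],
                                         win[:, 0], win[:, -1]])))
    sub = np.clip(win - bg, 0.0, None)
    total = sub.sum()
    if total <= 0:
        return None
    rr, cc = np.meshgrid(np.arange(win.shape[0]), np.arange(win.shape[1]),
                         indexing="ij")
    r_cm = float((rr * sub).sum() / total) - half
    c_cm = float((cc * sub).sum() / total) - half
    amp0 = float(win[half, half] - bg)
    if not do_fit:
        return r_cm, c_cm, sigma0, amp0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _gauss2d, (rr, cc), win.ravel(),
                p0=(max(amp0, 1.0), half + r_cm, half + c_cm, sigma0, bg),
                bounds=([0, 0, 0, 0.3, -np.inf],
                        [np.inf, win.shape[0], win.shape[1], 2.5 * half,
                         np.inf]),
                maxfev=200)
        amp, r0, c0, sigma, _ = popt
        return float(r0 - half), float(c0 - half), float(sigma), float(amp)
    except (RuntimeError, ValueError):
        return r_cm, c_cm, sigma0, amp0


def detect_movie(movie: Movie, expected_diameter: float,
                 snr_threshold: float = 5.0,
                 estimate_size: bool = True) -> pd.DataFrame:
    """Run :func:`detect_spots` on every frame of a calibrated movie."""
    px = movie.metadata.pixel_size
    frames = []
    for f in range(movie.n_frames):
        lab = movie.labels[f] if movie.labels is not None else None
        frames.append(detect_spots(movie.data[f], px, expected_diameter,
                                   snr_threshold, estimate_size, frame=f,
                                   labels=lab))
    out = pd.concat(frames, ignore_index=True)
    out["frame"] = out["frame"].astype(int)
    return out


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------

def link_tracks(spots: pd.DataFrame, max_step: float,
                min_track_length: int = 3) -> pd.DataFrame:
    """Link per-frame detections into tracks (no gap closing).

    Frame-to-frame assignment minimizes total squared displacement subject
    to a hard ``max_step`` (µm) gate; a spot absent for one frame therefore
    splits its track. Tracks shorter than ``min_track_length`` spots are
    discarded. Returns the spot table with a ``track_id`` column, sorted by
    (track_id, frame).
    """
    if max_step <= 0:
        raise ConfigurationError(f"max_step must be > 0 µm, got {max_step}")
    if spots.empty or spots["frame"].nunique() < 2:
        raise ConfigurationError("linking requires spots from >= 2 frames")

    spots = spots.sort_values("frame", kind="mergesort").reset_index(drop=True)
    track_of = np.full(len(spots), -1, dtype=int)
    next_track = 0
    prev_idx: np.ndarray | None = None
    prev_frame = None
    big = 1e12

    for f, group in spots.groupby("frame", sort=True):
        idx = group.index.to_numpy()
        if prev_idx is not None and f == prev_frame + 1:
            pxy = spots.loc[prev_idx, ["x_um", "y_um"]].to_numpy()
            cxy = spots.loc[idx, ["x_um", "y_um"]].to_numpy()
            d = np.linalg.norm(pxy[:, None, :] - cxy[None, :, :], axis=2)
            cost = np.where(d <= max_step, d ** 2, big)
            ri, ci = linear_sum_assignment(cost)
            matched = np.zeros(len(idx), dtype=bool)
            for a, b in zip(ri, ci):
                if d[a, b] <= max_step:
                    track_of[idx[b]] = track_of[prev_idx[a]]
                    matched[b] = True
            for j in np.nonzero(~matched)[0]:
                track_of[idx[j]] = next_track
                next_track += 1
        else:
            for j in idx:
                track_of[j] = next_track
                next_track += 1
        prev_idx, prev_frame = idx, f

    spots = spots.assign(track_id=track_of)
    lengths = spots.groupby("track_id")["frame"].size()
    keep = lengths.index[lengths >= min_track_length]
    out = spots[spots["track_id"].isin(keep)]
    # renumber tracks densely, in first-appearance order
    remap = {t: i for i, t in enumerate(pd.unique(out["track_id"]))}
    out = out.assign(track_id=out["track_id"].map(remap))
    return out.sort_values(["track_id", "frame"],
                           kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Tracks: steps, angles, speed
# ---------------------------------------------------------------------------

@dataclass
class Track:
    """One linked punctum: ordered positions and per-step kinematics."""

    track_id: int
    frames: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    diameter_um: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.frames) <= 0):
            raise ConfigurationError(
                f"track {self.track_id}: frames must be strictly increasing")

    @classmethod
    def from_table(cls, group: pd.DataFrame) -> "Track":
        g = group.sort_values("frame", kind="mergesort")
        return cls(track_id=int(g["track_id"].iloc[0]),
                   frames=g["frame"].to_numpy(int),
                   x_um=g["x_um"].to_numpy(float),
                   y_um=g["y_um"].to_numpy(float),
                   diameter_um=g["diameter_um"].to_numpy(float),
                   intensity=g["intensity"].to_numpy(float))

    @property
    def steps(self) -> np.ndarray:
        """(n-1, 2) per-step displacement vectors in µm."""
        return np.column_stack([np.diff(self.x_um), np.diff(self.y_um)])

    def step_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.steps, axis=1)


def iter_tracks(table: pd.DataFrame):
    for _, group in table.groupby("track_id", sort=True):
        yield Track.from_table(group)


def compute_step_angles(track: Track, metadata) -> tuple[np.ndarray, int]:
    """Per-step movement angles (degrees, [0, 360); 0 = anterior, 90 = Up).

    Zero-length steps have no direction: they are dropped, and their count
    is returned alongside the angles.
    """
    ap = getattr(metadata, "ap_angle", metadata if np.isscalar(metadata)
                 else None)
    if ap is None:
        raise CalibrationError("ap_angle missing: cannot orient step angles")
    steps = track.steps
    nonzero = np.linalg.norm(steps, axis=1) > 0
    angles = movement_angle(steps[nonzero, 0], steps[nonzero, 1], ap)
    return angles, int((~nonzero).sum())


def compute_track_speed(track: Track, frame_interval: float) -> float:
    """Mean per-step speed in µm/min (mean step length / frame interval)."""
    lengths = track.step_lengths()
    if lengths.size == 0:
        raise ConfigurationError(
            f"track {track.track_id}: needs >= 1 step for a speed")
    return float(lengths.mean() / frame_interval * 60.0)


def steps_table(tracks: pd.DataFrame, metadata) -> pd.DataFrame:
    """Flatten a track table to one row per (nonzero) step.

    Columns: track_id, frame (of the step start), angle_deg, step_um,
    cell_id, chamber_id. The number of dropped zero-length steps is recorded
    in ``out.attrs['n_zero_steps']``.
    """
    rows = []
    n_zero = 0
    has_cell = "cell_id" in tracks.columns
    has_chamber = "chamber_id" in tracks.columns
    for track_id, group in tracks.groupby("track_id", sort=True):
        track = Track.from_table(group)
        angles, nz = compute_step_angles(track, metadata)
        n_zero += nz
        lengths = track.step_lengths()
        nonzero = lengths > 0
        g = group.sort_values("frame", kind="mergesort").iloc[:-1]
        g = g[nonzero]
        rows.append(pd.DataFrame({
            "track_id": track_id,
            "frame": g["frame"].to_numpy(int),
            "angle_deg": angles,
            "step_um": lengths[nonzero],
            "cell_id": g["cell_id"].to_numpy() if has_cell else 0,
            "chamber_id": g["chamber_id"].to_numpy() if has_chamber else 0,
        }))
    out = (pd.concat(rows, ignore_index=True) if rows
           else pd.DataFrame(columns=["track_id", "frame", "angle_deg",
                                      "step_um", "cell_id", "chamber_id"]))
    out.attrs["n_zero_steps"] = n_zero
    return out


def mean_speed(tracks: pd.DataFrame, frame_interval: float) -> pd.Series:
    """Per-track mean speed (µm/min), indexed by track_id."""
    speeds = {t.track_id: compute_track_speed(t, frame_interval)
              for t in iter_tracks(tracks)}
    return pd.Series(speeds, name="speed_um_per_min")


# ---------------------------------------------------------------------------
# Large-dot classification
# ---------------------------------------------------------------------------

def classify_large_dots(spots: pd.DataFrame,
                        diameter_cutoff: float = 0.7) -> pd.DataFrame:
    """Flag spots with estimated FWHM >= ``diameter_cutoff`` µm as "large".

    Returns the large subset; a summary (count, mean and SD of large-dot
    diameter) is attached as ``out.attrs['summary']``.
    """
    large = spots[spots["diameter_um"] >= diameter_cutoff].copy()
    large["large"] = True
    d = large["diameter_um"]
    large.attrs["summary"] = {
        "n_large": int(len(large)),
        "mean_diameter_um": float(d.mean()) if len(large) else float("nan"),
        "sd_diameter_um": float(d.std(ddof=1)) if len(large) > 1
        else float("nan"),
        "cutoff_um": float(diameter_cutoff),
    }
    return large
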