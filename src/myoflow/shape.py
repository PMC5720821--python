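"""Per-cell basal shape metrics and tissue-level motion.

Roundness is 4*area / (pi * major_axis**2) (major-axis convention: 1 for a
circle, b/a for an ellipse with semi-axes a >= b); circularity
4*pi*area / perimeter**2 is computed alongside for comparison. Orientations
are axial angles in [0, 180) measured from the anterior direction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .errors import ConfigurationError
from .geometry import (axial_difference, axial_mean, pixels_to_um, wrap180)

SHAPE_COLUMNS = ["cell_id", "frame", "area_um2", "perimeter_um",
                 "major_axis_um", "minor_axis_um", "orientation_deg",
                 "roundness", "circularity", "touches_border"]


# ---------------------------------------------------------------------------
# Shape measurement
# ---------------------------------------------------------------------------

def measure_shape(labels: np.ndarray, cell_id: int, pixel_size: float,
                  ap_angle: float = 0.0, frame: int = 0) -> dict:
    """Shape descriptors of one labelled cell region in one frame.

    Area and perimeter come from the pixel region; orientation and the
    ellipse axes from the second central moments of the pixel coordinates
    (in µm, physical frame). Regions touching the image border are flagged
    (their shape is clipped, hence biased).
    """
    mask = labels == cell_id
    n_px = int(mask.sum())
    if n_px < 20:
        raise ConfigurationError(
            f"cell {cell_id}: region has {n_px} px, need >= 20")
    props = regionprops(mask.astype(np.uint8))[0]
    area = n_px * pixel_size ** 2
    perimeter = props.perimeter * pixel_size

    rr, cc = np.nonzero(mask)
    x, y = pixels_to_um(rr, cc, labels.shape[0], pixel_size)
    cov = np.cov(np.vstack([x, y]), bias=True)
    # pixels are unit squares, not points: add the square's own variance
    cov += np.eye(2) * (pixel_size ** 2 / 12.0)
    eigvals, eigvecs = np.linalg.eigh(cov)
    lam_minor, lam_major = np.maximum(eigvals, 1e-15)
    v = eigvecs[:, 1]  # principal (major) axis
    major = 4.0 * np.sqrt(lam_major)
    minor = 4.0 * np.sqrt(lam_minor)
    orientation = float(wrap180(np.degrees(np.arctan2(v[1], v[0])) - ap_angle))

    touches = bool(rr.min() == 0 or cc.min() == 0
                   or rr.max() == labels.shape[0] - 1
                   or cc.max() == labels.shape[1] - 1)
    return {
        "cell_id": int(cell_id), "frame": int(frame),
        "area_um2": float(area), "perimeter_um": float(perimeter),
        "major_axis_um": float(major), "minor_axis_um": float(minor),
        "orientation_deg": orientation,
        "roundness": float(4.0 * area / (np.pi * major ** 2)),
        "circularity": float(4.0 * np.pi * area / perimeter ** 2)
        if perimeter > 0 else float("nan"),
        "touches_border": touches,
    }


def measure_all_shapes(label_stack: np.ndarray, pixel_size: float,
                       ap_angle: float = 0.0,
                       min_pixels: int = 20) -> pd.DataFrame:
    """Shape table for every cell in every frame of a label stack."""
    rows = []
    for f in range(label_stack.shape[0]):
        frame_labels = label_stack[f]
        for cid in np.unique(frame_labels):
            if cid == 0:
                continue
            if (frame_labels == cid).sum() < min_pixels:
                continue
            rows.append(measure_shape(frame_labels, int(cid), pixel_size,
                                      ap_angle, frame=f))
    return pd.DataFrame(rows, columns=SHAPE_COLUMNS)


# ---------------------------------------------------------------------------
# Orientation statistics
# ---------------------------------------------------------------------------

def orientation_histogram(orientations, bin_width: float = 20.0) -> pd.Series:
    """Axial orientation histogram: fractions over [0,20), ..., [160,180)."""
    a = np.asarray(orientations, dtype=float)
    if a.size == 0:
        raise ConfigurationError("orientation histogram needs >= 1 angle")
    if np.any((a < 0) | (a >= 180)):
        raise ConfigurationError(
            "orientations must be axial angles in [0, 180); reduce directed "
            "0-360 angles mod 180 first")
    if not (bin_width > 0 and abs(180.0 / bin_width - round(180.0 / bin_width))
            < 1e-9):
        raise ConfigurationError(f"bin_width must divide 180, got {bin_width}")
    n_bins = int(round(180.0 / bin_width))
    counts = np.bincount((a // bin_width).astype(int), minlength=n_bins)
    edges = np.arange(n_bins) * bin_width
    out = pd.Series(counts / a.size,
                    index=[f"[{lo:g},{lo + bin_width:g})" for lo in edges])
    out.attrs["n"] = int(a.size)
    return out


def relative_angle(elongation_orientation: float, myo_axis: float,
                   in_plane_threshold: float = 20.0) -> tuple[float, bool]:
    """Minimal axial angle (degrees, [0, 90]) between a cell's elongation
    axis and its local Myo-II axis, and whether they are "in plane"
    (within the threshold)."""
    if not (np.isfinite(elongation_orientation) and np.isfinite(myo_axis)):
        raise ConfigurationError("both axial angles must be defined")
    d = float(axial_difference(elongation_orientation, myo_axis))
    return d, d <= in_plane_threshold


def myosin_axis_per_cell(steps: pd.DataFrame) -> pd.Series:
    """Local Myo-II pattern axis per cell: axial circular mean of the cell's
    step angles reduced mod 180. NaN for cells with a degenerate
    (uniform-axis) step set."""
    return steps.groupby("cell_id")["angle_deg"].apply(
        lambda a: axial_mean(np.asarray(a, float) % 180.0))


# ---------------------------------------------------------------------------
# Planar cell chirality
# ---------------------------------------------------------------------------

def measure_pcc(segments: pd.DataFrame, tilt_window: float = 45.0,
                ap_angle: float = 0.0) -> pd.DataFrame:
    """Clockwise / anti-clockwise membrane tilt fractions per chamber.

    ``segments`` has one membrane edge segment per row with endpoint columns
    x0_um, y0_um, x1_um, y1_um and chamber_id. Segments whose axial angle
    lies within ``tilt_window`` of the circumferential (Up-Down, 90 degree)
    axis qualify; exact 0-degree tilts are excluded. The tilt sign convention
    is: axial angle < 90 (tilted toward the anterior going up) = CW,
    > 90 = ACW.
    """
    seg = segments.copy()
    dx = seg["x1_um"] - seg["x0_um"]
    dy = seg["y1_um"] - seg["y0_um"]
    axial = wrap180(np.degrees(np.arctan2(dy, dx)) - ap_angle)
    tilt = 90.0 - axial  # >0: CW, <0: ACW
    qualifies = (np.abs(tilt) <= tilt_window) & (np.abs(tilt) > 1e-12)
    seg = seg.assign(tilt_deg=tilt)[qualifies]
    if seg.empty:
        raise ConfigurationError(
            "insufficient membranes: no segments within the tilt window")
    per = seg.groupby("chamber_id")["tilt_deg"].agg(
        cw_fraction=lambda t: float((t > 0).mean()),
        acw_fraction=lambda t: float((t < 0).mean()),
        n_segments="size")
    return per.reset_index()


# ---------------------------------------------------------------------------
# Rotation speed
# ---------------------------------------------------------------------------

def rotation_speed(label_stack: np.ndarray, pixel_size: float,
                   frame_interval: float, ap_angle: float = 0.0) -> dict:
    """Tissue rotation speed from per-frame cell centroid displacement.

    Mean per-frame displacement of matched cell centroids along the
    circumferential (Up-Down) axis, converted to µm/min; positive = Up.
    Cells touching the image border in either frame of a pair are excluded
    (their clipped centroids do not move with the tissue).
    """
    n_frames = label_stack.shape[0]
    if n_frames < 2:
        raise ConfigurationError("rotation_speed needs >= 2 frames")
    up = np.radians(ap_angle + 90.0)
    u_vec = np.array([np.cos(up), np.sin(up)])

    def centroids(frame_labels):
        out = {}
        for p in regionprops(frame_labels.astype(np.int32)):
            rr, cc = p.coords[:, 0], p.coords[:, 1]
            x, y = pixels_to_um(rr, cc, frame_labels.shape[0], pixel_size)
            border = (rr.min() == 0 or cc.min() == 0
                      or rr.max() == frame_labels.shape[0] - 1
                      or cc.max() == frame_labels.shape[1] - 1)
            out[p.label] = (x.mean(), y.mean(), border)
        return out

    disps = []
    prev = centroids(label_stack[0])
    for f in range(1, n_frames):
        cur = centroids(label_stack[f])
        for cid, (x1, y1, b1) in cur.items():
            if cid not in prev:
                continue
            x0, y0, b0 = prev[cid]
            if b0 or b1:
                continue
            disps.append((x1 - x0) * u_vec[0] + (y1 - y0) * u_vec[1])
        prev = cur
    if not disps:
        raise ConfigurationError(
            "no interior cells matched across frames; cannot estimate speed")
    mean_disp = float(np.mean(disps))
    speed = mean_disp / frame_interval * 60.0
    return {"speed_um_per_min": speed,
            "direction": "Up" if speed >= 0 else "Down",
            "n_displacements": len(disps)}
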