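"""Synthetic ground-truth generator for rotating-epithelium movies.

Emulates the imaging regime of basal-surface Myo-II in the fly follicle
epithelium: dot-like puncta (~0.36 µm FWHM, with a sparse ~1 µm population)
moving at ~2-2.5 µm/min with configurable directional structure, imaged at a
6 s frame interval for 300-600 s; polygonal cells tiling the field, optionally
translating collectively ("rotating") in the Up or Down direction at
~0.2-0.65 µm/min; and per-cell pulsatile intensity/area dynamics with a
configurable intensity -> area-reduction lag.

All randomness flows from one seed. Stream order (via
``numpy.random.SeedSequence.spawn``): 0 = tracks, 1 = cell sheet,
2 = movie noise, 3 = pulse series. Identical seeds give bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigurationError
from .geometry import um_to_pixels, wrap360

# Quadrant boundaries (degrees, AP convention): Down = [225, 315) is the
# retrograde quadrant once rotation is unified to Up.
_DOWN_LO, _DOWN_HI = 225.0, 315.0


# ---------------------------------------------------------------------------
# Configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneConfig:
    """Imaging-scene parameters (calibration, duration, noise).

    Defaults follow the live-imaging regime the pipeline targets: 6 s frame
    interval and a 300 s movie (51 frames), 0.1 µm/pixel (63x/1.45 confocal
    regime).
    """

    image_shape: tuple[int, int] = (256, 256)  # (rows, cols) pixels
    pixel_size: float = 0.1                    # µm / pixel
    frame_interval: float = 6.0                # s
    n_frames: int = 51                         # 300 s at 6 s
    ap_angle: float = 0.0                      # anterior direction, degrees
    background_level: float = 100.0            # A.U.
    noise_sd: float = 4.0                      # A.U.
    seed: int = 0

    def __post_init__(self):
        rows, cols = self.image_shape
        if rows <= 0 or cols <= 0:
            raise ConfigurationError(
                f"image_shape must be positive, got {self.image_shape}")
        if self.pixel_size <= 0:
            raise ConfigurationError(
                f"pixel_size must be > 0 µm, got {self.pixel_size}")
        if self.frame_interval <= 0:
            raise ConfigurationError(
                f"frame_interval must be > 0 s, got {self.frame_interval}")
        if self.n_frames < 2:
            raise ConfigurationError(
                f"n_frames must be >= 2, got {self.n_frames}")

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the field in µm."""
        rows, cols = self.image_shape
        return cols * self.pixel_size, rows * self.pixel_size

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) * self.frame_interval

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


class FixedDirection:
    """Every step moves at one angle (degrees, AP convention)."""

    def __init__(self, angle: float):
        self.angle = float(wrap360(angle))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return np.full(n, self.angle)

    def sample_bias(self, rng: np.random.Generator) -> "FixedDirection":
        return self


class VonMisesDirection:
    """Step angles ~ von Mises(mu, kappa) (degrees; kappa >= 0)."""

    def __init__(self, mu: float, kappa: float):
        if kappa < 0:
            raise ConfigurationError(f"kappa must be >= 0, got {kappa}")
        self.mu = float(wrap360(mu))
        self.kappa = float(kappa)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kappa == 0:
            return rng.uniform(0.0, 360.0, n)
        draws = rng.vonmises(np.radians(self.mu), self.kappa, n)
        return wrap360(np.degrees(draws))

    def sample_bias(self, rng: np.random.Generator) -> "VonMisesDirection":
        """Per-cell bias: a new mean direction drawn from this distribution."""
        mu_i = self.sample(1, rng)[0]
        return VonMisesDirection(mu_i, self.kappa)


class QuadrantMixture:
    """With probability ``p_retro`` a step falls uniformly in the Down
    (retrograde) quadrant [225, 315); otherwise uniformly over the remaining
    270 degrees."""

    def __init__(self, p_retro: float):
        if not 0.0 <= p_retro <= 1.0:
            raise ConfigurationError(
                f"p_retro must be in [0, 1], got {p_retro}")
        self.p_retro = float(p_retro)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        retro = rng.random(n) < self.p_retro
        angles = np.where(
            retro,
            rng.uniform(_DOWN_LO, _DOWN_HI, n),
            wrap360(_DOWN_HI + rng.uniform(0.0, 270.0, n)),
        )
        return angles

    def sample_bias(self, rng: np.random.Generator) -> "_QuadrantBias":
        return _QuadrantBias(bool(rng.random() < self.p_retro))


class _QuadrantBias:
    """A cell committed to one quadrant (Down if retro, Up otherwise)."""

    def __init__(self, retro: bool):
        self.retro = retro

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        lo, hi = (_DOWN_LO, _DOWN_HI) if self.retro else (45.0, 135.0)
        return rng.uniform(lo, hi, n)


@dataclass(frozen=True)
class DotPopulationSpec:
    """A population of dot-like puncta sharing size/speed statistics."""

    n_dots: int = 105
    diameter_fwhm: float = 0.363      # µm
    diameter_sd: float = 0.05         # µm; dot-to-dot dispersion
    intensity: float = 400.0          # A.U., peak above background
    speed: float = 2.44               # µm/min
    direction_model: object = field(default_factory=lambda: VonMisesDirection(270.0, 4.0))
    per_cell_direction: bool = False
    min_separation: float = 0.0       # µm between initial positions (0 = off)

    def __post_init__(self):
        if self.n_dots < 0:
            raise ConfigurationError(f"n_dots must be >= 0, got {self.n_dots}")
        if self.diameter_fwhm <= 0:
            raise ConfigurationError(
                f"diameter_fwhm must be > 0 µm, got {self.diameter_fwhm}")
        if self.speed < 0:
            raise ConfigurationError(f"speed must be >= 0, got {self.speed}")


@dataclass(frozen=True)
class CellSheetSpec:
    """A polygonal cell sheet with collective translation and pulsing."""

    n_cells: int = 25
    mean_cell_area: float = 25.0          # µm²
    elongation_ratio: float = 1.0         # major/minor >= 1
    elongation_angle: float = 90.0        # degrees, axial (AP convention)
    tissue_translation_speed: float = 0.5  # µm/min
    translation_direction: str = "Up"     # Up | Down
    pulse_amplitude: float = 0.3          # fraction of baseline
    pulse_period: float = 60.0            # s, population mean
    pulse_period_cv: float = 0.15         # cell-to-cell period variability
    intensity_to_area_lag: int = 1        # frames
    pulse_noise_sd: float = 0.05          # fraction of baseline

    def __post_init__(self):
        if self.n_cells < 1:
            raise ConfigurationError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.mean_cell_area <= 0:
            raise ConfigurationError(
                f"mean_cell_area must be > 0 µm², got {self.mean_cell_area}")
        if self.elongation_ratio < 1.0:
            raise ConfigurationError(
                f"elongation_ratio must be >= 1, got {self.elongation_ratio}")
        if not 0.0 <= self.pulse_amplitude < 1.0:
            raise ConfigurationError(
                f"pulse_amplitude must be in [0, 1), got {self.pulse_amplitude}")
        if self.translation_direction not in ("Up", "Down"):
            raise ConfigurationError(
                "translation_direction must be 'Up' or 'Down', "
                f"got {self.translation_direction!r}")
        if int(self.intensity_to_area_lag) != self.intensity_to_area_lag:
            raise ConfigurationError("intensity_to_area_lag must be an integer "
                                     f"number of frames, got {self.intensity_to_area_lag}")


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

_STREAMS = {"tracks": 0, "cells": 1, "noise": 2, "pulses": 3}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic child generator for one named stream of a scene seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[stream]])


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# Track generation
# ---------------------------------------------------------------------------

TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um", "diameter_um",
                 "intensity", "cell_id", "chamber_id", "reflected"]


def generate_tracks(scene: SceneConfig, dots: DotPopulationSpec,
                    rng=None, labels: np.ndarray | None = None,
                    chamber_id: int = 0,
                    track_id_offset: int = 0,
                    avoid=None) -> pd.DataFrame:
    """Simulate ground-truth dot tracks.

    One row per dot per frame. Per-step displacement magnitude is exactly
    ``speed * frame_interval`` (before boundary reflection); step directions
    are drawn from ``dots.direction_model``. Dots reflect at the field edges;
    the ``reflected`` flag marks the arrival row of a reflected step so such
    steps can be excluded from ground-truth speed summaries.

    ``labels`` (optional per-frame label stack) assigns each row a cell id
    by lookup at the dot position; otherwise ``cell_id`` is 0. ``avoid``
    (an (n, 2) array of µm positions) extends ``min_separation`` to
    previously placed populations, for mixtures of resolvable puncta.
    """
    rng = _as_rng(stream_rng(scene.seed, "tracks") if rng is None else rng)
    width, height = scene.extent_um
    step_len = dots.speed * scene.frame_interval / 60.0  # µm per frame
    margin = min(dots.diameter_fwhm, width / 4, height / 4)

    diameters = np.maximum(
        rng.normal(dots.diameter_fwhm, dots.diameter_sd, dots.n_dots),
        0.2 * dots.diameter_fwhm)

    placed: list[tuple[float, float]] = [] if avoid is None else \
        [tuple(p) for p in np.asarray(avoid, dtype=float)]
    records = []
    for i in range(dots.n_dots):
        model = dots.direction_model
        if dots.per_cell_direction:
            model = model.sample_bias(rng)
        # rejection-sample initial positions to keep puncta resolvable
        for _ in range(200):
            x = rng.uniform(margin, width - margin)
            y = rng.uniform(margin, height - margin)
            if dots.min_separation <= 0 or not placed or \
                    min(np.hypot(x - px_, y - py_)
                        for px_, py_ in placed) >= dots.min_separation:
                break
        else:
            raise ConfigurationError(
                f"could not place {dots.n_dots} dots with "
                f"min_separation={dots.min_separation} µm in a "
                f"{width:.0f}x{height:.0f} µm field")
        placed.append((x, y))
        angles = model.sample(scene.n_frames - 1, rng)
        phys = np.radians(angles + scene.ap_angle)
        dx = step_len * np.cos(phys)
        dy = step_len * np.sin(phys)
        xs, ys, refl = [x], [y], [False]
        for k in range(scene.n_frames - 1):
            nx, ny = xs[-1] + dx[k], ys[-1] + dy[k]
            bounced = False
            # reflect at the field boundary (at most a few bounces)
            for _ in range(4):
                moved = False
                if nx < 0:
                    nx, moved = -nx, True
                elif nx > width:
                    nx, moved = 2 * width - nx, True
                if ny < 0:
                    ny, moved = -ny, True
                elif ny > height:
                    ny, moved = 2 * height - ny, True
                bounced = bounced or moved
                if not moved:
                    break
            xs.append(nx)
            ys.append(ny)
            refl.append(bounced)
        track = pd.DataFrame({
            "track_id": track_id_offset + i,
            "frame": np.arange(scene.n_frames),
            "x_um": xs,
            "y_um": ys,
            "diameter_um": diameters[i],
            "intensity": dots.intensity,
            "cell_id": 0,
            "chamber_id": chamber_id,
            "reflected": refl,
        })
        records.append(track)

    if not records:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    table = pd.concat(records, ignore_index=True)
    if labels is not None:
        table["cell_id"] = lookup_cell_ids(table, labels, scene)
    return table


def lookup_cell_ids(tracks: pd.DataFrame, labels: np.ndarray,
                    scene: SceneConfig) -> np.ndarray:
    """Cell id at each (frame, position) of a track table, from a label stack."""
    n_rows = labels.shape[1]
    row, col = um_to_pixels(tracks["x_um"].to_numpy(),
                            tracks["y_um"].to_numpy(),
                            n_rows, scene.pixel_size)
    r = np.clip(np.rint(row).astype(int), 0, labels.shape[1] - 1)
    c = np.clip(np.rint(col).astype(int), 0, labels.shape[2] - 1)
    f = tracks["frame"].to_numpy(int)
    return labels[f, r, c]


# ---------------------------------------------------------------------------
# Cell sheet generation
# ---------------------------------------------------------------------------

def generate_cell_sheet(cells: CellSheetSpec, scene: SceneConfig,
                        rng=None) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-frame label masks for a translating sheet of polygonal cells.

    Cells are the Voronoi regions of jittered grid centroids under an
    anisotropic metric (shrunk along the elongation axis), which yields
    convex polygonal cells elongated by ``elongation_ratio`` along
    ``elongation_angle``. The whole sheet translates rigidly along the
    Up (or Down) direction at ``tissue_translation_speed``.

    Returns ``(labels, truth)``: a ``(n_frames, rows, cols)`` uint16 stack
    (labels 1..n_cells tile the frame; no overlaps by construction) and a
    ground-truth table of per-frame centroid positions.
    """
    rng = _as_rng(stream_rng(scene.seed, "cells") if rng is None else rng)
    n_r, n_c = scene.image_shape
    width, height = scene.extent_um

    spacing = float(np.sqrt(cells.mean_cell_area))
    nx = max(1, int(np.ceil(width / spacing)) + 2)
    ny = max(1, int(np.ceil(height / spacing)) + 2)
    gx, gy = np.meshgrid(
        (np.arange(nx) - (nx - 1) / 2) * spacing + width / 2,
        (np.arange(ny) - (ny - 1) / 2) * spacing + height / 2)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    pts += rng.uniform(-0.25 * spacing, 0.25 * spacing, pts.shape)
    # keep the n_cells centroids closest to the field centre
    order = np.argsort(np.hypot(pts[:, 0] - width / 2, pts[:, 1] - height / 2))
    n_cells = min(cells.n_cells, len(pts))
    pts = pts[order[:n_cells]]

    # anisotropic metric: distances shrink along the elongation axis
    theta = np.radians(cells.elongation_angle + scene.ap_angle)
    rot = np.array([[np.cos(theta), np.sin(theta)],
                    [-np.sin(theta), np.cos(theta)]])
    s = np.sqrt(cells.elongation_ratio)
    metric = np.diag([1.0 / s, s]) @ rot

    sign = 1.0 if cells.translation_direction == "Up" else -1.0
    up = np.radians(scene.ap_angle + 90.0)
    u_vec = np.array([np.cos(up), np.sin(up)])
    shift_per_frame = sign * cells.tissue_translation_speed * \
        scene.frame_interval / 60.0 * u_vec

    cc, rr = np.meshgrid(np.arange(n_c), np.arange(n_r))
    px = cc.ravel() * scene.pixel_size
    py = (n_r - 1 - rr.ravel()) * scene.pixel_size
    pix = np.column_stack([px, py]) @ metric.T

    labels = np.empty((scene.n_frames, n_r, n_c), dtype=np.uint16)
    truth = []
    for f in range(scene.n_frames):
        cent = pts + f * shift_per_frame
        tree = cKDTree(cent @ metric.T)
        _, idx = tree.query(pix)
        labels[f] = (idx + 1).astype(np.uint16).reshape(n_r, n_c)
        truth.append(pd.DataFrame({
            "cell_id": np.arange(1, n_cells + 1),
            "frame": f,
            "x_um": cent[:, 0],
            "y_um": cent[:, 1],
        }))
    return labels, pd.concat(truth, ignore_index=True)


# ---------------------------------------------------------------------------
# Movie rendering
# ---------------------------------------------------------------------------

def render_movie(tracks: pd.DataFrame, scene: SceneConfig,
                 rng=None) -> np.ndarray:
    """Render a track table to a 16-bit movie stack.

    Each punctum is an isotropic 2D Gaussian with FWHM = its
    ``diameter_um`` and peak amplitude = its ``intensity`` above background;
    Gaussian read noise of ``scene.noise_sd`` is added per pixel. An empty
    track table yields a background-plus-noise-only stack.
    """
    rng = _as_rng(stream_rng(scene.seed, "noise") if rng is None else rng)
    n_r, n_c = scene.image_shape
    movie = np.full((scene.n_frames, n_r, n_c), float(scene.background_level))

    if len(tracks):
        small = tracks["diameter_um"].min() < 2.0 * scene.pixel_size
        if small:
            warnings.warn("puncta smaller than 2 pixels FWHM are "
                          "sub-resolution at this pixel size", stacklevel=2)
        for row in tracks.itertuples(index=False):
            _add_gaussian(movie[int(row.frame)], row.x_um, row.y_um,
                          row.diameter_um, row.intensity, scene)
    if scene.noise_sd > 0:
        movie += rng.normal(0.0, scene.noise_sd, movie.shape)
    return np.clip(np.rint(movie), 0, 65535).astype(np.uint16)


def _add_gaussian(frame: np.ndarray, x_um: float, y_um: float,
                  fwhm_um: float, amplitude: float, scene: SceneConfig):
    n_r, n_c = frame.shape
    sigma = fwhm_um / scene.pixel_size / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    r0, c0 = um_to_pixels(x_um, y_um, n_r, scene.pixel_size)
    half = int(np.ceil(5 * sigma)) + 1
    rlo, rhi = max(0, int(r0) - half), min(n_r, int(r0) + half + 1)
    clo, chi = max(0, int(c0) - half), min(n_c, int(c0) + half + 1)
    if rlo >= rhi or clo >= chi:
        return
    rr, cc = np.meshgrid(np.arange(rlo, rhi), np.arange(clo, chi),
                         indexing="ij")
    frame[rlo:rhi, clo:chi] += amplitude * np.exp(
        -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma ** 2))


# ---------------------------------------------------------------------------
# Pulse series
# ---------------------------------------------------------------------------

def generate_pulse_series(cells: CellSheetSpec, scene: SceneConfig,
                          rng=None) -> pd.DataFrame:
    """Per-cell pulsatile intensity and basal-area series.

    Intensity is a noisy oscillation around baseline 1.0; the area deviation
    is the (sign-flipped) intensity deviation delayed by
    ``intensity_to_area_lag`` frames plus independent noise, so the
    area-reduction *rate* equals the intensity rate delayed by the lag.
    Pulses are not clock-like: each cell's period is drawn around
    ``pulse_period`` with coefficient of variation ``pulse_period_cv``
    (and a random phase), so cross-cell averages carry no common-period
    alias. Returns a tidy table (cell_id, frame, time_s, intensity,
    area_um2).
    """
    lag = int(cells.intensity_to_area_lag)
    if lag >= scene.n_frames:
        raise ConfigurationError(
            f"intensity_to_area_lag ({lag} frames) must be < n_frames "
            f"({scene.n_frames})")
    rng = _as_rng(stream_rng(scene.seed, "pulses") if rng is None else rng)
    t = scene.times_s
    out = []
    for cell in range(1, cells.n_cells + 1):
        phase = rng.uniform(0.0, 2 * np.pi)
        period = max(0.5 * cells.pulse_period,
                     rng.normal(cells.pulse_period,
                                cells.pulse_period_cv * cells.pulse_period))
        dev = cells.pulse_amplitude * np.sin(
            2 * np.pi * t / period + phase)
        dev_lagged = cells.pulse_amplitude * np.sin(
            2 * np.pi * (t - lag * scene.frame_interval)
            / period + phase)
        intensity = 1.0 + dev + rng.normal(0, cells.pulse_noise_sd, t.size)
        area = cells.mean_cell_area * (
            1.0 - dev_lagged + rng.normal(0, cells.pulse_noise_sd, t.size))
        area = np.maximum(area, 0.05 * cells.mean_cell_area)
        out.append(pd.DataFrame({
            "cell_id": cell,
            "frame": np.arange(scene.n_frames),
            "time_s": t,
            "intensity": intensity,
            "area_um2": area,
        }))
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Angular event datasets (movement angles without imaging)
# ---------------------------------------------------------------------------

def generate_angular_events(n_chambers: int, events_per_chamber: int,
                            direction_model, rng,
                            cells_per_chamber: int = 10,
                            rotation_directions=None) -> pd.DataFrame:
    """Movement-angle events for several egg chambers, bypassing imaging.

    Angles are drawn from ``direction_model`` in the *unified* frame (rotation
    Up, retrograde = Down quadrant); chambers assigned a Down rotation have
    their angles mirrored back (theta -> 360 - theta) so that the raw table
    requires unification, exactly as real data would. Events are spread
    round-robin over ``cells_per_chamber`` cells.

    Returns a table (angle_deg, cell_id, chamber_id, rotation_direction).
    """
    rng = _as_rng(rng)
    if rotation_directions is None:
        rotation_directions = np.where(rng.random(n_chambers) < 0.5,
                                       "Up", "Down")
    frames = []
    for ch in range(n_chambers):
        unified = direction_model.sample(events_per_chamber, rng)
        rot = rotation_directions[ch]
        raw = unified if rot == "Up" else wrap360(360.0 - unified)
        frames.append(pd.DataFrame({
            "angle_deg": raw,
            "cell_id": np.arange(events_per_chamber) % cells_per_chamber + 1,
            "chamber_id": ch,
            "rotation_direction": rot,
        }))
    return pd.concat(frames, ignore_index=True)
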