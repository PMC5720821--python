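"""Config-driven orchestration: simulate -> track -> angles -> shape -> pulses.

Every run writes a frozen copy of its configuration into the output
directory, and every output CSV opens with a comment line carrying the
config hash and seed, so any stage can be re-run from the on-disk
intermediates and two runs with the same config are byte-identical.

Stream order for the single run seed follows :mod:`myoflow.synth`
(tracks, cells, noise, pulses).
"""

from __future__ import annotations

import copy
import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import angular, pulses, shape, synth, tracking
from .errors import ConfigurationError
from .io import (Movie, MovieMetadata, read_movie, write_labels, write_movie,
                 write_tracks)

log = logging.getLogger("myoflow")

STAGES = ("simulate", "track", "angles", "shape", "pulses")

DEFAULT_CONFIG = {
    "seed": 0,
    "stages": list(STAGES),
    "scene": {},        # synth.SceneConfig fields
    "dots": {},         # synth.DotPopulationSpec fields
    "cells": {},        # synth.CellSheetSpec fields
    "rotation_direction": "Up",
    "detection": {"expected_diameter": 0.363, "snr_threshold": 5.0,
                  "estimate_size": True},
    "linking": {"max_step": None, "min_track_length": 3},
    "angles": {"bin_width": 20.0, "min_events_correction": 5},
    "pulses": {"max_offset_frames": 10, "smooth": False},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def build_config(overrides: dict | None = None) -> dict:
    config = _merge(DEFAULT_CONFIG, overrides or {})
    unknown = [s for s in config["stages"] if s not in STAGES]
    if unknown:
        raise ConfigurationError(f"unknown stage(s): {unknown}; "
                                 f"valid stages are {list(STAGES)}")
    return config


def config_hash(config: dict) -> str:
    text = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, chash: str, seed: int,
               extra: str = "") -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# config_hash={chash} seed={seed}"
                 + (f" {extra}" if extra else "") + "\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _direction_model(spec: dict):
    kind = spec.get("kind", "von_mises")
    if kind == "fixed":
        return synth.FixedDirection(spec.get("angle", 270.0))
    if kind == "von_mises":
        return synth.VonMisesDirection(spec.get("mu", 270.0),
                                       spec.get("kappa", 4.0))
    if kind == "quadrant_mixture":
        return synth.QuadrantMixture(spec.get("p_retro", 0.77))
    raise ConfigurationError(f"unknown direction model kind {kind!r}")


def _specs_from_config(config: dict):
    scene = synth.SceneConfig(seed=config["seed"],
                              **{k: tuple(v) if k == "image_shape" else v
                                 for k, v in config["scene"].items()})
    dot_cfg = dict(config["dots"])
    model = _direction_model(dot_cfg.pop("direction_model", {}))
    dots = synth.DotPopulationSpec(direction_model=model, **dot_cfg)
    cells = synth.CellSheetSpec(**config["cells"])
    return scene, dots, cells


def stage_simulate(config: dict, outdir: Path, chash: str) -> Movie:
    scene, dots, cells = _specs_from_config(config)
    seed = config["seed"]
    labels, cell_truth = synth.generate_cell_sheet(
        cells, scene, rng=synth.stream_rng(seed, "cells"))
    tracks = synth.generate_tracks(scene, dots,
                                   rng=synth.stream_rng(seed, "tracks"),
                                   labels=labels)
    movie_data = synth.render_movie(tracks, scene,
                                    rng=synth.stream_rng(seed, "noise"))
    pulse_truth = synth.generate_pulse_series(
        cells, scene, rng=synth.stream_rng(seed, "pulses"))
    meta = MovieMetadata(pixel_size=scene.pixel_size,
                         frame_interval=scene.frame_interval,
                         ap_angle=scene.ap_angle,
                         rotation_direction=config["rotation_direction"])
    movie = Movie(data=movie_data, metadata=meta, labels=labels)
    write_movie(movie, outdir / "movie.tif")
    write_labels(labels, outdir / "labels.tif")
    _write_csv(tracks, outdir / "truth_tracks.csv", chash, seed)
    _write_csv(cell_truth, outdir / "truth_cells.csv", chash, seed)
    _write_csv(pulse_truth, outdir / "pulse_series.csv", chash, seed)
    log.info("simulate: %d tracks, %d cells, %d frames",
             tracks["track_id"].nunique(), cells.n_cells, scene.n_frames)
    return movie


def stage_track(config: dict, outdir: Path, chash: str,
                movie: Movie) -> pd.DataFrame:
    det = config["detection"]
    spots = tracking.detect_movie(movie, det["expected_diameter"],
                                  det["snr_threshold"],
                                  det["estimate_size"])
    max_step = config["linking"]["max_step"]
    if max_step is None:
        speed = config["dots"].get("speed",
                                   synth.DotPopulationSpec().speed)
        max_step = 3.0 * speed * movie.metadata.frame_interval / 60.0
    linked = tracking.link_tracks(spots, max_step=max_step,
                                  min_track_length=config["linking"]
                                  ["min_track_length"])
    linked["chamber_id"] = 0
    out = linked[["track_id", "frame", "x_um", "y_um", "diameter_um",
                  "intensity", "cell_id", "chamber_id", "snr"]]
    path = outdir / "tracks.csv"
    write_tracks(out, path)  # schema check
    _write_csv(out, path, chash, config["seed"])
    log.info("track: %d spots -> %d tracks (max_step=%.3f µm)",
             len(spots), out["track_id"].nunique(), max_step)
    return out


def stage_angles(config: dict, outdir: Path, chash: str,
                 tracks: pd.DataFrame, metadata: MovieMetadata) -> dict:
    seed = config["seed"]
    steps = tracking.steps_table(tracks, metadata)
    _write_csv(steps, outdir / "steps.csv", chash, seed,
               extra=f"n_zero_steps={steps.attrs['n_zero_steps']}")
    dataset = angular.AngularDataset.from_steps(
        steps, rotation_direction=metadata.rotation_direction)

    rose = angular.rose_histogram(dataset.events["angle_deg"],
                                  config["angles"]["bin_width"])
    quad = angular.quadrant_fractions(dataset.events["angle_deg"])
    _write_csv(rose.rename("fraction").rename_axis("bin").reset_index(),
               outdir / "rose.csv", chash, seed)
    _write_csv(quad.rename("fraction").rename_axis("quadrant").reset_index(),
               outdir / "quadrants.csv", chash, seed)

    results = {"rose": rose, "quadrants": quad, "n_steps": len(dataset)}
    if metadata.rotation_direction in ("Up", "Down"):
        unified = angular.unify_to_up(dataset)
        per_chamber, pooled = angular.retrograde_fraction(unified)
        ratios = angular.weighted_ratio(unified)
        _write_csv(ratios, outdir / "ratios.csv", chash, seed,
                   extra=ratios.attrs["weighting"])
        results.update(retrograde_per_chamber=per_chamber,
                       retrograde_pooled=pooled, ratios=ratios)
        log.info("angles: %d steps, pooled retrograde fraction %.3f",
                 len(dataset), pooled)
    else:
        corrected, corr_log = angular.angular_correction(
            dataset, config["angles"]["min_events_correction"])
        ratios = angular.dominant_direction_ratio(dataset)
        _write_csv(corr_log, outdir / "correction_log.csv", chash, seed)
        _write_csv(ratios, outdir / "ratios.csv", chash, seed)
        results.update(corrected=corrected, correction_log=corr_log,
                       ratios=ratios)
        log.info("angles: %d steps, %d cells angularly corrected",
                 len(dataset), int(corr_log["corrected"].sum()))
    return results


def stage_shape(config: dict, outdir: Path, chash: str,
                movie: Movie) -> pd.DataFrame:
    if movie.labels is None:
        raise ConfigurationError("shape stage requires a label mask")
    shapes = shape.measure_all_shapes(movie.labels,
                                      movie.metadata.pixel_size,
                                      movie.metadata.ap_angle)
    _write_csv(shapes, outdir / "shapes.csv", chash, config["seed"])
    speed = shape.rotation_speed(movie.labels, movie.metadata.pixel_size,
                                 movie.metadata.frame_interval,
                                 movie.metadata.ap_angle)
    _write_csv(pd.DataFrame([speed]), outdir / "rotation_speed.csv",
               chash, config["seed"])
    log.info("shape: %d cell-frames, rotation speed %.3f µm/min",
             len(shapes), speed["speed_um_per_min"])
    return shapes


def stage_pulses(config: dict, outdir: Path, chash: str,
                 series: list[pulses.PulseSeries]) -> pulses.Correlogram:
    cfg = config["pulses"]
    # clamp the offset window to what the series length supports
    # (>= 10 overlapping points at every offset)
    n_rate = min(s.times.size for s in series) - 1
    max_off = min(cfg["max_offset_frames"], n_rate - 10)
    if max_off < 1:
        raise ConfigurationError(
            f"series too short for a correlogram: {n_rate + 1} frames")
    if max_off < cfg["max_offset_frames"]:
        log.info("pulses: offset window clamped to ±%d frames", max_off)
    cg = pulses.cell_averaged_correlogram(series, max_off, cfg["smooth"])
    table = pd.DataFrame({"offset_s": cg.offsets_s, "R_mean": cg.R,
                          "R_sem": cg.R_sem, "n_cells": cg.n_cells})
    _write_csv(table, outdir / "correlogram.csv", chash, config["seed"],
               extra=f"smooth={cfg['smooth']}")
    log.info("pulses: %d cells, peak R=%.3f at %+.0f s",
             cg.n_cells, cg.peak_R, cg.peak_offset_s)
    return cg


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run(config: dict | None = None, outdir="myoflow_run") -> dict:
    """Execute the enabled stages in order; returns in-memory results.

    A frozen config copy, every intermediate CSV and the movie/labels are
    written to ``outdir``; all CSVs carry the config hash and seed.
    """
    config = build_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    with open(outdir / "config_frozen.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    results: dict = {"config_hash": chash}
    stages = config["stages"]
    movie = None
    if "simulate" in stages:
        movie = stage_simulate(config, outdir, chash)
    elif any(s in stages for s in ("track", "shape", "pulses")):
        movie_path = config.get("movie")
        if not movie_path:
            raise ConfigurationError(
                "stage 'track'/'shape'/'pulses' without 'simulate' requires "
                "a 'movie' input path in the config")
        movie = read_movie(movie_path, labels_path=config.get("labels"))
    results["movie"] = movie

    tracks = None
    if "track" in stages:
        tracks = stage_track(config, outdir, chash, movie)
        results["tracks"] = tracks
    if "angles" in stages:
        if tracks is None:
            raise ConfigurationError("angles stage requires the track stage")
        results["angles"] = stage_angles(config, outdir, chash, tracks,
                                         movie.metadata)
    if "shape" in stages:
        results["shape"] = stage_shape(config, outdir, chash, movie)
    if "pulses" in stages:
        truth = outdir / "pulse_series.csv"
        if truth.exists():
            table = pd.read_csv(truth, comment="#")
            series = pulses.series_from_table(table)
        else:
            series = pulses.extract_pulse_series(movie)
        results["pulses"] = stage_pulses(config, outdir, chash, series)

    summary = pd.DataFrame([{
        "config_hash": chash, "seed": config["seed"],
        "stages": "|".join(stages),
        "n_tracks": tracks["track_id"].nunique() if tracks is not None
        else np.nan,
        "retrograde_pooled": results.get("angles", {}).get(
            "retrograde_pooled", np.nan),
        "peak_offset_s": results["pulses"].peak_offset_s
        if "pulses" in results else np.nan,
    }])
    _write_csv(summary, outdir / "summary.csv", chash, config["seed"])
    return results


# ---------------------------------------------------------------------------
# Fixture profiles
# ---------------------------------------------------------------------------

FIXTURE_PROFILES = ("fast-rotation", "slow-rotation", "static-pulsing",
                    "clone-mosaic")


def make_fixtures(profile: str, seed: int = 0) -> dict:
    """Small, fully parameterized synthetic datasets for each regime.

    All profiles use a 6 s frame interval and <= 64 cells / <= 100 frames.
    fast-rotation: stage-7-like (2.44 µm/min dots, 77% retrograde,
    0.5 µm/min tissue translation). slow-rotation: stage-4-like (2.11,
    59%, 0.2). static-pulsing: non-rotating chambers with per-cell opposing
    direction biases and a 1-frame intensity->area lag. clone-mosaic: a
    retrograde-biased control population mixed with an unbiased clone
    population.
    """
    if profile not in FIXTURE_PROFILES:
        raise ConfigurationError(
            f"unknown profile {profile!r}; valid profiles: "
            f"{list(FIXTURE_PROFILES)}")
    scene = synth.SceneConfig(image_shape=(160, 160), n_frames=26, seed=seed)
    if profile == "fast-rotation":
        return {"scene": scene,
                "dots": synth.DotPopulationSpec(
                    n_dots=40, speed=2.44,
                    direction_model=synth.QuadrantMixture(0.77)),
                "cells": synth.CellSheetSpec(
                    n_cells=16, tissue_translation_speed=0.5,
                    elongation_ratio=2.0, pulse_amplitude=0.05),
                "rotation_direction": "Up"}
    if profile == "slow-rotation":
        return {"scene": scene,
                "dots": synth.DotPopulationSpec(
                    n_dots=40, speed=2.11,
                    direction_model=synth.QuadrantMixture(0.59)),
                "cells": synth.CellSheetSpec(
                    n_cells=16, tissue_translation_speed=0.2,
                    elongation_ratio=1.3, pulse_amplitude=0.05),
                "rotation_direction": "Up"}
    if profile == "static-pulsing":
        return {"scene": scene,
                "dots": synth.DotPopulationSpec(
                    n_dots=40, speed=2.0,
                    direction_model=synth.QuadrantMixture(0.5),
                    per_cell_direction=True),
                "cells": synth.CellSheetSpec(
                    n_cells=16, tissue_translation_speed=0.0,
                    elongation_ratio=1.0, pulse_amplitude=0.3,
                    intensity_to_area_lag=1),
                "rotation_direction": "unknown"}
    # clone-mosaic
    return {"scene": scene,
            "dots": [synth.DotPopulationSpec(
                         n_dots=25, speed=2.44,
                         direction_model=synth.QuadrantMixture(0.77)),
                     synth.DotPopulationSpec(
                         n_dots=15, speed=2.0,
                         direction_model=synth.QuadrantMixture(0.5),
                         per_cell_direction=True)],
            "cells": synth.CellSheetSpec(
                n_cells=16, tissue_translation_speed=0.5,
                elongation_ratio=1.5, pulse_amplitude=0.15,
                intensity_to_area_lag=1),
            "rotation_direction": "Up"}


def write_fixture(profile: str, outdir, seed: int = 0) -> Path:
    """Generate a fixture bundle on disk (movie, labels, truth CSVs)."""
    bundle = make_fixtures(profile, seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scene = bundle["scene"]
    dot_specs = bundle["dots"]
    if not isinstance(dot_specs, list):
        dot_specs = [dot_specs]
    labels, cell_truth = synth.generate_cell_sheet(
        bundle["cells"], scene, rng=synth.stream_rng(seed, "cells"))
    rng = synth.stream_rng(seed, "tracks")
    parts, offset = [], 0
    for i, spec in enumerate(dot_specs):
        t = synth.generate_tracks(scene, spec, rng=rng, labels=labels,
                                  chamber_id=i, track_id_offset=offset)
        offset += spec.n_dots
        parts.append(t)
    tracks = pd.concat(parts, ignore_index=True)
    movie_data = synth.render_movie(tracks, scene,
                                    rng=synth.stream_rng(seed, "noise"))
    pulse_truth = synth.generate_pulse_series(
        bundle["cells"], scene, rng=synth.stream_rng(seed, "pulses"))
    meta = MovieMetadata(pixel_size=scene.pixel_size,
                         frame_interval=scene.frame_interval,
                         ap_angle=scene.ap_angle,
                         rotation_direction=bundle["rotation_direction"])
    write_movie(Movie(movie_data, meta, labels), outdir / "movie.tif")
    write_labels(labels, outdir / "labels.tif")
    tracks.to_csv(outdir / "truth_tracks.csv", index=False)
    cell_truth.to_csv(outdir / "truth_cells.csv", index=False)
    pulse_truth.to_csv(outdir / "pulse_series.csv", index=False)
    return outdir
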