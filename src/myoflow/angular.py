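"""Planar-direction statistics for Myo-II movement events.

Movement directions are degrees in [0, 360), 0 = anterior, 90 = "Up".
Events are assigned to four 90-degree quadrants — Anterior [315, 360) u
[0, 45), Up [45, 135), Posterior [135, 225), Down [225, 315) — with
half-open boundaries (a boundary angle belongs to the quadrant it opens).

Chambers rotating Down are unified to Up by the mirror theta -> 360 - theta,
so "retrograde" (against rotation) is always the Down quadrant after
unification. Per-cell retrograde/anterograde ratios use a Haldane-Anscombe
pseudocount of 1/2 only when a count is zero; "weighted" chamber summaries
weight each cell by its event count (raw counts are always retained).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .geometry import circular_mean, signed_delta, wrap360

QUADRANTS = ("Anterior", "Up", "Posterior", "Down")

EVENT_COLUMNS = ["angle_deg", "cell_id", "chamber_id", "rotation_direction"]


@dataclass
class AngularDataset:
    """Movement-angle events tagged with cell, chamber and rotation sense.

    ``events`` columns: angle_deg in [0, 360), cell_id, chamber_id,
    rotation_direction ('Up' | 'Down' | 'unknown', constant per chamber).
    """

    events: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise ConfigurationError(
                f"angular dataset missing column(s): {', '.join(missing)}")
        a = self.events["angle_deg"].to_numpy(float)
        if len(a) and (a.min() < 0 or a.max() >= 360):
            raise ConfigurationError("angles must lie in [0, 360)")
        per = self.events.groupby("chamber_id")["rotation_direction"].nunique()
        bad = per.index[per > 1].tolist()
        if bad:
            raise ConfigurationError(
                "rotation_direction must be constant within a chamber; "
                f"violated by chamber(s) {bad}")

    def __len__(self):
        return len(self.events)

    @classmethod
    def from_steps(cls, steps: pd.DataFrame,
                   rotation_direction: str = "unknown",
                   chamber_id=None) -> "AngularDataset":
        """Build from a :func:`myoflow.tracking.steps_table` output."""
        ev = pd.DataFrame({
            "angle_deg": steps["angle_deg"].to_numpy(float),
            "cell_id": steps.get("cell_id", 0),
            "chamber_id": steps["chamber_id"] if chamber_id is None
            else chamber_id,
            "rotation_direction": rotation_direction,
        })
        return cls(ev)


# ---------------------------------------------------------------------------
# Quadrants and rose histograms
# ---------------------------------------------------------------------------

def assign_quadrant(angle):
    """Quadrant label(s) for angle(s) in [0, 360)."""
    a = np.asarray(angle, dtype=float)
    if np.any((a < 0) | (a >= 360)):
        raise ConfigurationError("angle out of range [0, 360)")
    out = np.empty(a.shape, dtype=object)
    out[(a >= 315) | (a < 45)] = "Anterior"
    out[(a >= 45) & (a < 135)] = "Up"
    out[(a >= 135) & (a < 225)] = "Posterior"
    out[(a >= 225) & (a < 315)] = "Down"
    if np.isscalar(angle):
        return out.item()
    return out


def quadrant_fractions(angles) -> pd.Series:
    """Fractions of events per quadrant; sums to 1. ``n`` in ``.attrs``."""
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ConfigurationError("quadrant fractions need >= 1 event")
    labels = assign_quadrant(a)
    counts = pd.Series(labels).value_counts()
    frac = pd.Series({q: counts.get(q, 0) / a.size for q in QUADRANTS})
    frac.attrs["n"] = int(a.size)
    return frac


def rose_histogram(angles, bin_width: float = 20.0) -> pd.Series:
    """Fractions over [0, bin), [bin, 2 bin), ... bins covering 0-360."""
    if not (bin_width > 0 and abs(360.0 / bin_width - round(360.0 / bin_width))
            < 1e-9):
        raise ConfigurationError(
            f"bin_width must divide 360, got {bin_width}")
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ConfigurationError("rose histogram needs >= 1 angle")
    if np.any((a < 0) | (a >= 360)):
        raise ConfigurationError("angle out of range [0, 360)")
    n_bins = int(round(360.0 / bin_width))
    counts = np.bincount((a // bin_width).astype(int), minlength=n_bins)
    edges = np.arange(n_bins) * bin_width
    out = pd.Series(counts / a.size,
                    index=[f"[{lo:g},{lo + bin_width:g})" for lo in edges])
    out.attrs["n"] = int(a.size)
    out.attrs["bin_width"] = float(bin_width)
    return out


# ---------------------------------------------------------------------------
# Unification and retrograde fractions
# ---------------------------------------------------------------------------

def unify_to_up(dataset: AngularDataset) -> AngularDataset:
    """Mirror Down-rotating chambers (theta -> 360 - theta) so every chamber
    rotates Up; an involution on the mirrored chambers, applied once."""
    ev = dataset.events
    unknown = ev.loc[~ev["rotation_direction"].isin(["Up", "Down"]),
                     "chamber_id"].unique().tolist()
    if unknown:
        raise ConfigurationError(
            "rotation direction unknown for chamber(s) "
            f"{unknown}; cannot unify")
    ev = ev.copy()
    down = ev["rotation_direction"] == "Down"
    ev.loc[down, "angle_deg"] = wrap360(360.0 - ev.loc[down, "angle_deg"])
    ev["rotation_direction"] = "Up"
    return AngularDataset(ev)


def retrograde_fraction(dataset: AngularDataset) -> tuple[pd.Series, float]:
    """Fraction of events in the Down quadrant per chamber + pooled mean.

    The dataset must already be unified to Up (every chamber's rotation is
    Up, so retrograde = Down). The pooled mean is the unweighted mean over
    chambers.
    """
    ev = dataset.events
    if not (ev["rotation_direction"] == "Up").all():
        raise ConfigurationError(
            "retrograde_fraction requires a dataset unified to Up")
    down = assign_quadrant(ev["angle_deg"].to_numpy(float)) == "Down"
    per = pd.Series(down).groupby(ev["chamber_id"].to_numpy()).mean()
    per.name = "retrograde_fraction"
    return per, float(per.mean())


# ---------------------------------------------------------------------------
# Per-cell retrograde/anterograde ratios
# ---------------------------------------------------------------------------

RATIO_BINS = ("<1", "1-2", "2-3", ">3")


def ratio_bin(ratio: float) -> str:
    """Half-open ratio bins: [0,1) '<1', [1,2) '1-2', [2,3) '2-3',
    [3, inf) '>3'."""
    if ratio < 1:
        return "<1"
    if ratio < 2:
        return "1-2"
    if ratio < 3:
        return "2-3"
    return ">3"


def _pseudocounted_ratio(retro: int, antero: int) -> float:
    """(retro + 1/2) / (antero + 1/2) when either count is zero, else the
    raw quotient (Haldane-Anscombe, applied only when needed)."""
    if retro == 0 or antero == 0:
        return (retro + 0.5) / (antero + 0.5)
    return retro / antero


def weighted_ratio(dataset: AngularDataset) -> pd.DataFrame:
    """Per-cell retrograde/anterograde ratio records (unified dataset).

    retro = events in the Down quadrant, antero = events in Up;
    Anterior/Posterior events are excluded from the ratio but counted.
    Cells with zero Up+Down events are flagged ``excluded``. The chamber
    summary (``out.attrs['chamber_summary']``) is the event-count-weighted
    mean log2 ratio per chamber.
    """
    ev = dataset.events.reset_index(drop=True)
    if not (ev["rotation_direction"] == "Up").all():
        raise ConfigurationError(
            "weighted_ratio requires a dataset unified to Up")
    quad = assign_quadrant(ev["angle_deg"].to_numpy(float))
    records = []
    for (chamber, cell), grp_idx in ev.groupby(
            ["chamber_id", "cell_id"]).groups.items():
        q = quad[np.asarray(grp_idx)]
        retro = int((q == "Down").sum())
        antero = int((q == "Up").sum())
        other = int(len(grp_idx) - retro - antero)
        excluded = (retro + antero) == 0
        ratio = np.nan if excluded else _pseudocounted_ratio(retro, antero)
        records.append({
            "chamber_id": chamber, "cell_id": cell,
            "retro_count": retro, "antero_count": antero,
            "other_count": other,
            "ratio": ratio,
            "log2_ratio": np.nan if excluded else float(np.log2(ratio)),
            "bin": None if excluded else ratio_bin(ratio),
            "excluded": excluded,
        })
    out = pd.DataFrame.from_records(records)
    ok = out[~out["excluded"]].copy()
    if len(ok):
        w = ok["retro_count"] + ok["antero_count"]
        summary = ok.assign(_w=w).groupby("chamber_id").apply(
            lambda g: float(np.average(g["log2_ratio"], weights=g["_w"])),
            include_groups=False)
    else:
        summary = pd.Series(dtype=float)
    out.attrs["chamber_summary"] = summary
    out.attrs["weighting"] = "event-count weighting of per-cell log2 ratios"
    return out


def dominant_direction_ratio(dataset: AngularDataset) -> pd.DataFrame:
    """Per-cell dominant/opposite ratios for static (non-rotating) chambers.

    Per chamber, the dominant of {Up, Down} is chosen from pooled counts
    (exact tie -> Up, flagged); per-cell ratios are then
    dominant-quadrant / opposite-quadrant counts, pseudocounted as in
    :func:`weighted_ratio`.
    """
    ev = dataset.events.reset_index(drop=True)
    quad = assign_quadrant(ev["angle_deg"].to_numpy(float))
    records = []
    ties = []
    for chamber, grp_idx in ev.groupby("chamber_id").groups.items():
        q = quad[np.asarray(grp_idx)]
        up_total = int((q == "Up").sum())
        down_total = int((q == "Down").sum())
        tie = up_total == down_total
        dominant = "Up" if up_total >= down_total else "Down"
        if tie:
            ties.append(chamber)
        sub = ev.loc[grp_idx]
        for cell, cell_idx in sub.groupby("cell_id").groups.items():
            qc = quad[np.asarray(cell_idx)]
            dom = int((qc == dominant).sum())
            opp = int((qc == ("Down" if dominant == "Up" else "Up")).sum())
            excluded = (dom + opp) == 0
            ratio = np.nan if excluded else _pseudocounted_ratio(dom, opp)
            records.append({
                "chamber_id": chamber, "cell_id": cell,
                "dominant": dominant, "tie": tie,
                "retro_count": dom, "antero_count": opp,
                "ratio": ratio,
                "log2_ratio": np.nan if excluded else float(np.log2(ratio)),
                "bin": None if excluded else ratio_bin(ratio),
                "excluded": excluded,
            })
    out = pd.DataFrame.from_records(records)
    out.attrs["tied_chambers"] = ties
    return out


# ---------------------------------------------------------------------------
# Symmetry classification
# ---------------------------------------------------------------------------

def classify_symmetry(up_count: int, down_count: int,
                      strong_fraction: float = 0.70, strong_p: float = 0.01,
                      weak_fraction: float = 0.60, weak_p: float = 0.05,
                      min_events: int = 20) -> dict:
    """Three-way symmetry call for one chamber's Up/Down counts.

    Dominant fraction f and an exact two-sided binomial test against 0.5:
    'strong asymmetry' if f >= strong_fraction and p < strong_p;
    'weak asymmetry' if f >= weak_fraction and p < weak_p (and not strong);
    otherwise 'symmetric'. Thresholds are configurable.
    """
    n = up_count + down_count
    if n < min_events:
        raise ConfigurationError(
            f"insufficient events: need >= {min_events} Up+Down events, "
            f"got {n}")
    dominant = max(up_count, down_count)
    f = dominant / n
    p = stats.binomtest(dominant, n, 0.5, alternative="two-sided").pvalue
    if f >= strong_fraction and p < strong_p:
        label = "strong asymmetry"
    elif f >= weak_fraction and p < weak_p:
        label = "weak asymmetry"
    else:
        label = "symmetric"
    return {"label": label, "dominant_fraction": float(f),
            "p_value": float(p), "n": int(n),
            "dominant": "Up" if up_count >= down_count else "Down"}


# ---------------------------------------------------------------------------
# Angular correction
# ---------------------------------------------------------------------------

def angular_correction(dataset: AngularDataset,
                       min_events: int = 5) -> tuple[AngularDataset,
                                                     pd.DataFrame]:
    """Rigidly rotate each cell's angles so its predominant direction lies
    perpendicular to the AP axis.

    Per cell, the predominant direction mu is the circular (vector-sum)
    mean of its event angles; the applied rotation delta is the signed
    smallest angle taking mu to the nearer of 90 or 270 degrees, so
    |delta| < 90 (an exact tie at mu = 0/180 is broken toward 90 and
    flagged). Being a rigid rotation, within-cell angular dispersion is
    unchanged. Cells with fewer than ``min_events`` events, or with zero
    mean resultant length, are left uncorrected and flagged.

    Returns (corrected dataset, correction log).
    """
    ev = dataset.events.copy()
    log = []
    for (chamber, cell), idx in ev.groupby(
            ["chamber_id", "cell_id"]).groups.items():
        angles = ev.loc[idx, "angle_deg"].to_numpy(float)
        entry = {"chamber_id": chamber, "cell_id": cell,
                 "n_events": len(angles), "mu_deg": np.nan,
                 "delta_deg": 0.0, "corrected": False, "flag": ""}
        if len(angles) < min_events:
            entry["flag"] = "too_few_events"
            log.append(entry)
            continue
        mu, r = circular_mean(angles)
        if not np.isfinite(mu):
            entry["flag"] = "zero_resultant"
            log.append(entry)
            continue
        d90 = float(signed_delta(mu, 90.0))
        d270 = float(signed_delta(mu, 270.0))
        if abs(d90) < abs(d270):
            delta = d90
        elif abs(d270) < abs(d90):
            delta = d270
        else:  # exact tie (mu = 0 or 180): break toward 90
            delta = d90
            entry["flag"] = "tie_broken_toward_90"
        ev.loc[idx, "angle_deg"] = wrap360(angles + delta)
        entry.update(mu_deg=mu, delta_deg=delta, corrected=True)
        log.append(entry)
    return AngularDataset(ev), pd.DataFrame.from_records(log)


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(values_a, values_b) -> dict:
    """Classical two-sample two-sided Student t-test with per-group SEM.

    Zero variance in both groups with equal means is reported as p = 1
    (flagged) rather than undefined.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigurationError("each group needs n >= 2")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ConfigurationError("non-finite values in input")
    flag = ""
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            t, p, flag = 0.0, 1.0, "degenerate: zero variance, equal means"
        else:
            t, p, flag = np.inf, 0.0, "degenerate: zero variance"
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
    return {
        "t": float(t), "p": float(p), "stars": significance_stars(float(p)),
        "mean_a": float(a.mean()), "sem_a": float(stats.sem(a)),
        "mean_b": float(b.mean()), "sem_b": float(stats.sem(b)),
        "n_a": int(a.size), "n_b": int(b.size), "flag": flag,
    }
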