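"""Per-frame contact and load metrics: force, contact area, CoP and CoC.

Conventions:

* a sensor is "active" when its pressure strictly exceeds the
  ``ActivationRule`` threshold (default: any positive pressure),
* total force is expressed as percent body mass with g = 9.81 m/s^2,
* frames with force under 5% body mass are excluded from summary
  statistics (insole noise while the foot is off the ground); frames at
  exactly 5% are retained,
* the centre of pressure (CoP) is the pressure-weighted centroid of
  active cell centres, the centre of contact (CoC) the unweighted one;
  both live in normalized foot coordinates, so AP distances are fractions
  of foot length and ML distances fractions of foot width.

The CoP can leave the contact area entirely (e.g. heel + forefoot
loading puts it over the unloaded arch); ``cop_contact_stats``
quantifies how often, and at what local pressure percentile, the CoP sits
on an active cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .foot_model import FootOutline, PressureRecording, cell_centres, region_of
from .foot_model import AP_REGION_ORDER

__all__ = [
    "ActivationRule",
    "total_force",
    "exclude_low_force",
    "contact_area",
    "contact_probability_map",
    "centre_of_pressure",
    "centre_of_contact",
    "compute_frame_metrics",
    "cop_contact_stats",
    "cop_coc_relationship",
    "force_area_relationship",
    "CopContactStats",
    "GRAVITY",
]

GRAVITY = 9.81
UNDEFINED = float("nan")


@dataclass(frozen=True)
class ActivationRule:
    """Pressure above which a sensor counts as in contact (kPa)."""

    active_threshold_kpa: float = 0.0

    def __post_init__(self) -> None:
        if self.active_threshold_kpa < 0:
            raise ValueError("activation threshold must be >= 0")

    def active(self, frame: np.ndarray) -> np.ndarray:
        return frame > self.active_threshold_kpa


def total_force(
    frame: np.ndarray, cell_area_cm2: float, body_mass_kg: float
) -> float:
    """Summed force on the foot as percent body mass.

    force_N = sum(p_kPa) * area_m2 * 1000 = sum(p_kPa) * area_cm2 * 0.1.
    """
    if body_mass_kg <= 0:
        raise ValueError("body mass must be positive")
    frame = np.asarray(frame, dtype=float)
    force_n = frame.sum() * cell_area_cm2 * 0.1
    return 100.0 * force_n / (body_mass_kg * GRAVITY)


def exclude_low_force(
    frames_metrics: pd.DataFrame, floor_pct: float = 5.0
) -> pd.DataFrame:
    """Drop frames with force strictly below ``floor_pct`` body mass."""
    keep = frames_metrics["force_pct_bm"] >= floor_pct
    return frames_metrics.loc[keep]


def contact_area(
    frame: np.ndarray, outline: FootOutline, rule: ActivationRule | None = None
) -> float:
    """Active in-outline sensors as percent of all in-outline sensors."""
    rule = rule or ActivationRule()
    mask = outline.in_outline_mask
    n_in = int(mask.sum())
    active = rule.active(np.asarray(frame)) & mask
    return 100.0 * active.sum() / n_in


def contact_probability_map(
    recording: PressureRecording,
    rule: ActivationRule | None = None,
    floor_pct: float = 5.0,
) -> np.ndarray:
    """Per-cell fraction of retained frames in which the cell is active."""
    rule = rule or ActivationRule()
    forces = np.array([
        total_force(f, recording.grid.cell_area_cm2, recording.body_mass_kg)
        for f in recording.frames
    ])
    retained = recording.frames[forces >= floor_pct]
    if retained.shape[0] == 0:
        raise ValueError("no frames remain after low-force exclusion")
    return rule.active(retained).mean(axis=0)


def centre_of_pressure(
    frame: np.ndarray, rule: ActivationRule | None = None
) -> tuple[float, float]:
    """Pressure-weighted centroid of active cell centres, (AP, ML)."""
    rule = rule or ActivationRule()
    frame = np.asarray(frame, dtype=float)
    active = rule.active(frame)
    if not active.any():
        return (UNDEFINED, UNDEFINED)
    ap, ml = cell_centres(*frame.shape)
    w = np.where(active, frame, 0.0)
    total = w.sum()
    return (float((w.sum(axis=1) @ ap) / total), float((w.sum(axis=0) @ ml) / total))


def centre_of_contact(
    frame: np.ndarray, rule: ActivationRule | None = None
) -> tuple[float, float]:
    """Unweighted centroid of active cell centres, (AP, ML)."""
    rule = rule or ActivationRule()
    frame = np.asarray(frame, dtype=float)
    active = rule.active(frame)
    if not active.any():
        return (UNDEFINED, UNDEFINED)
    ap, ml = cell_centres(*frame.shape)
    n = active.sum()
    return (
        float((active.sum(axis=1) @ ap) / n),
        float((active.sum(axis=0) @ ml) / n),
    )


def compute_frame_metrics(
    recording: PressureRecording,
    outline: FootOutline,
    rule: ActivationRule | None = None,
) -> pd.DataFrame:
    """Tidy per-frame metrics table (one row per frame, unfiltered).

    Columns: frame, force_pct_bm, contact_area_pct, cop_ap, cop_ml,
    coc_ap, coc_ml, cop_in_contact, cop_pressure_percentile, cop_region,
    cop_clamped.
    """
    rule = rule or ActivationRule()
    rows = []
    for t, frame in enumerate(recording.frames):
        force = total_force(
            frame, recording.grid.cell_area_cm2, recording.body_mass_kg
        )
        area = contact_area(frame, outline, rule)
        cop = centre_of_pressure(frame, rule)
        coc = centre_of_contact(frame, rule)
        in_contact = False
        percentile = UNDEFINED
        region = "undefined"
        clamped = False
        if np.isfinite(cop[0]):
            i, j = outline._cell_of(cop)
            active = rule.active(frame)
            in_contact = bool(active[i, j])
            if in_contact:
                # weak percentile: share of active cells at or below the
                # CoP cell's pressure
                percentile = float(stats.percentileofscore(
                    frame[active], frame[i, j], kind="weak"
                ))
            clamped = not outline.contains(cop)
            region = region_of(cop, outline)
        rows.append({
            "frame": t,
            "force_pct_bm": force,
            "contact_area_pct": area,
            "cop_ap": cop[0], "cop_ml": cop[1],
            "coc_ap": coc[0], "coc_ml": coc[1],
            "cop_in_contact": in_contact,
            "cop_pressure_percentile": percentile,
            "cop_region": region,
            "cop_clamped": clamped,
        })
    return pd.DataFrame(rows)


@dataclass
class CopContactStats:
    fraction_in_contact: float
    mean_pressure_percentile: float
    region_occupancy_pct: dict[str, float]
    n_frames: int
    n_clamped_outside: int


def cop_contact_stats(
    recording: PressureRecording,
    outline: FootOutline,
    rule: ActivationRule | None = None,
    floor_pct: float = 5.0,
) -> CopContactStats:
    """How often the CoP sits in the contact area, at what local pressure
    percentile, and which foot region it occupies (percent of frames)."""
    metrics = compute_frame_metrics(recording, outline, rule)
    metrics = exclude_low_force(metrics, floor_pct)
    metrics = metrics[np.isfinite(metrics["cop_ap"])]
    n = len(metrics)
    if n == 0:
        raise ValueError("no frames remain after exclusion")
    frac = float(metrics["cop_in_contact"].mean())
    pct = metrics.loc[metrics["cop_in_contact"], "cop_pressure_percentile"]
    mean_pct = float(pct.mean()) if len(pct) else UNDEFINED
    occupancy = {
        r: 100.0 * float((metrics["cop_region"] == r).mean())
        for r in AP_REGION_ORDER
    }
    return CopContactStats(
        fraction_in_contact=frac,
        mean_pressure_percentile=mean_pct,
        region_occupancy_pct=occupancy,
        n_frames=n,
        n_clamped_outside=int(metrics["cop_clamped"].sum()),
    )


def cop_coc_relationship(
    metrics: pd.DataFrame | list[pd.DataFrame],
) -> dict:
    """Shared variance (squared Pearson r) between CoP and CoC per axis,
    plus per-frame CoP-CoC distances as percent foot length/width.

    Accepts one or several per-frame metrics tables (pooled over frames).
    Axes with zero variance yield a NaN sentinel.
    """
    if isinstance(metrics, list):
        metrics = pd.concat(metrics, ignore_index=True)
    m = metrics[np.isfinite(metrics["cop_ap"]) & np.isfinite(metrics["coc_ap"])]
    if len(m) < 10:
        raise ValueError("need at least 10 frames with defined CoP and CoC")

    def r2(x: np.ndarray, y: np.ndarray) -> float:
        if np.std(x) == 0 or np.std(y) == 0:
            return UNDEFINED
        r, _ = stats.pearsonr(x, y)
        return float(r**2)

    dist_ap = 100.0 * np.abs(m["cop_ap"].to_numpy() - m["coc_ap"].to_numpy())
    dist_ml = 100.0 * np.abs(m["cop_ml"].to_numpy() - m["coc_ml"].to_numpy())
    return {
        "r2_ap": r2(m["cop_ap"].to_numpy(), m["coc_ap"].to_numpy()),
        "r2_ml": r2(m["cop_ml"].to_numpy(), m["coc_ml"].to_numpy()),
        "dist_ap_pct_length": dist_ap,
        "dist_ml_pct_width": dist_ml,
    }


def force_area_relationship(
    metrics: pd.DataFrame, n_bins: int = 40
) -> dict:
    """Spearman rank correlation between force and contact area, its
    square as shared variance, and a 2-D histogram on [0, 100]^2
    (force axis clipped at 100% body mass for binning)."""
    force = metrics["force_pct_bm"].to_numpy()
    area = metrics["contact_area_pct"].to_numpy()
    if len(force) < 10:
        raise ValueError("need at least 10 frames")
    if np.all(force == force[0]) or np.all(area == area[0]):
        return {"spearman_rho": UNDEFINED, "r2": UNDEFINED, "hist": None}
    rho, p = stats.spearmanr(force, area)
    hist, xedges, yedges = np.histogram2d(
        np.clip(force, 0, 100), np.clip(area, 0, 100),
        bins=n_bins, range=[[0, 100], [0, 100]],
    )
    return {
        "spearman_rho": float(rho),
        "r2": float(rho**2),
        "p_value": float(p),
        "hist": hist,
        "force_edges": xedges,
        "area_edges": yedges,
    }
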