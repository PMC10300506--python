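"""Standardized foot coordinate system and sensor-grid mapping.

All analyses run in a common, foot-aligned frame: the anterior--posterior
(AP) axis runs heel -> toes and maps to the row index, the medial--lateral
(ML) axis runs lateral -> medial and maps to the column index.  Normalized
coordinates live in [0, 1]^2 with cell centres at ``(i + 0.5) / n_rows``.
A standardized foot outline partitions the in-outline cells into four
coarse anatomical regions (heel, arch, metatarsals, toes) whose AP extents
are configurable proportions of foot length.

Raw insole matrices are mapped onto this outline by trimming empty border
rows/columns, rescaling the remaining block onto the outline's bounding
box, and zeroing anything that falls outside the outline.  Recordings from
different insole sizes are brought onto a common 56 x 20 grid by exact
area-overlap rebinning, which conserves the per-frame load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DEFAULT_N_ROWS",
    "DEFAULT_N_COLS",
    "DEFAULT_CELL_AREA_CM2",
    "DEFAULT_AP_PROPORTIONS",
    "AP_REGION_ORDER",
    "SensorGrid",
    "FootOutline",
    "PressureRecording",
    "build_standard_outline",
    "map_raw_to_outline",
    "rescale_to_common_grid",
    "region_of",
    "cell_centres",
]

DEFAULT_N_ROWS = 56
DEFAULT_N_COLS = 20
DEFAULT_CELL_AREA_CM2 = 0.258

#: Fraction of foot length occupied by each coarse region, heel -> toes.
DEFAULT_AP_PROPORTIONS: dict[str, float] = {
    "heel": 0.25,
    "arch": 0.25,
    "metatarsals": 0.30,
    "toes": 0.20,
}
AP_REGION_ORDER: tuple[str, ...] = ("heel", "arch", "metatarsals", "toes")


class InvalidConfigError(ValueError):
    """Raised for configuration that violates a structural precondition."""


@dataclass(frozen=True)
class SensorGrid:
    """Rectangular sensor lattice in foot-aligned coordinates."""

    n_rows: int = DEFAULT_N_ROWS
    n_cols: int = DEFAULT_N_COLS
    cell_area_cm2: float = DEFAULT_CELL_AREA_CM2
    in_outline_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_rows <= self.n_cols:
            raise InvalidConfigError(
                f"feet are longer than wide: need n_rows > n_cols, got "
                f"{self.n_rows} x {self.n_cols}"
            )
        if self.cell_area_cm2 <= 0:
            raise InvalidConfigError("cell_area_cm2 must be positive")
        if self.in_outline_mask is not None:
            m = np.asarray(self.in_outline_mask, dtype=bool)
            if m.shape != (self.n_rows, self.n_cols):
                raise InvalidConfigError("in_outline_mask shape mismatch")
            object.__setattr__(self, "in_outline_mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols


def cell_centres(n_rows: int, n_cols: int) -> tuple[np.ndarray, np.ndarray]:
    """AP and ML coordinates of cell centres as broadcastable vectors."""
    ap = (np.arange(n_rows) + 0.5) / n_rows
    ml = (np.arange(n_cols) + 0.5) / n_cols
    return ap, ml


def _halfwidth_profile(ap: np.ndarray) -> np.ndarray:
    """Foot half-width (as a fraction of grid half-width) along the AP axis.

    Piecewise-linear plan form: rounded heel, arch waist, metatarsal flare
    to full width, tapering toes.  The profile touches full width so that
    the outline's bounding box equals the whole grid.
    """
    knots_ap = np.array([0.0, 0.08, 0.25, 0.45, 0.62, 0.75, 0.92, 1.0])
    knots_w = np.array([0.55, 0.80, 0.78, 0.62, 0.95, 1.00, 0.80, 0.40])
    return np.interp(ap, knots_ap, knots_w)


def _build_in_outline_mask(n_rows: int, n_cols: int) -> np.ndarray:
    ap, ml = cell_centres(n_rows, n_cols)
    hw = 0.5 * _halfwidth_profile(ap)  # in ML units
    return np.abs(ml[None, :] - 0.5) <= hw[:, None] + 1e-12


def _boundary_polygon(n_samples: int = 64) -> np.ndarray:
    """Simple closed polygon (ap, ml) tracing the standard outline."""
    ap = np.linspace(0.0, 1.0, n_samples)
    hw = 0.5 * _halfwidth_profile(ap)
    medial = np.column_stack([ap, 0.5 + hw])
    lateral = np.column_stack([ap[::-1], 0.5 - hw[::-1]])
    return np.vstack([medial, lateral])


@dataclass
class FootOutline:
    """Standardized foot boundary with named region masks.

    ``region_masks`` maps region name -> boolean mask on the working grid.
    The four coarse regions partition the in-outline cells; optional
    sub-regions (great_toe, medial_arch, lateral_arch) overlap their parent
    coarse region and are excluded from the partition invariant.
    """

    boundary: np.ndarray
    region_masks: dict[str, np.ndarray]
    grid: SensorGrid
    foot_length_cm: float = 28.0
    foot_width_cm: float = 10.0
    region_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AP_PROPORTIONS)
    )

    @property
    def in_outline_mask(self) -> np.ndarray:
        return self.grid.in_outline_mask

    def coarse_masks(self) -> dict[str, np.ndarray]:
        return {r: self.region_masks[r] for r in AP_REGION_ORDER}

    def ap_boundaries(self) -> np.ndarray:
        """Cumulative AP positions of region upper edges, heel -> toes."""
        props = [self.region_proportions[r] for r in AP_REGION_ORDER]
        return np.cumsum(props)

    def contains(self, coordinate: Sequence[float]) -> bool:
        i, j = self._cell_of(coordinate)
        return bool(self.in_outline_mask[i, j])

    def _cell_of(self, coordinate: Sequence[float]) -> tuple[int, int]:
        ap, ml = float(coordinate[0]), float(coordinate[1])
        i = min(max(int(ap * self.grid.n_rows), 0), self.grid.n_rows - 1)
        j = min(max(int(ml * self.grid.n_cols), 0), self.grid.n_cols - 1)
        return i, j

    def nearest_in_outline_cell(self, coordinate: Sequence[float]) -> tuple[int, int]:
        i, j = self._cell_of(coordinate)
        if self.in_outline_mask[i, j]:
            return i, j
        rows, cols = np.nonzero(self.in_outline_mask)
        d2 = (rows - i) ** 2 + (cols - j) ** 2
        k = int(np.argmin(d2))
        return int(rows[k]), int(cols[k])

    def to_json(self) -> str:
        """Serialize masks to a JSON sidecar (region -> [[row, col], ...])."""
        payload = {
            "n_rows": self.grid.n_rows,
            "n_cols": self.grid.n_cols,
            "cell_area_cm2": self.grid.cell_area_cm2,
            "foot_length_cm": self.foot_length_cm,
            "foot_width_cm": self.foot_width_cm,
            "region_proportions": self.region_proportions,
            "boundary": np.asarray(self.boundary).tolist(),
            "regions": {
                name: np.argwhere(mask).tolist()
                for name, mask in self.region_masks.items()
            },
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FootOutline":
        payload = json.loads(text)
        n_rows, n_cols = payload["n_rows"], payload["n_cols"]
        masks = {}
        for name, cells in payload["regions"].items():
            m = np.zeros((n_rows, n_cols), dtype=bool)
            for r, c in cells:
                m[r, c] = True
            masks[name] = m
        union = np.zeros((n_rows, n_cols), dtype=bool)
        for r in AP_REGION_ORDER:
            union |= masks[r]
        grid = SensorGrid(n_rows, n_cols, payload["cell_area_cm2"], union)
        return cls(
            boundary=np.asarray(payload["boundary"], dtype=float),
            region_masks=masks,
            grid=grid,
            foot_length_cm=payload["foot_length_cm"],
            foot_width_cm=payload["foot_width_cm"],
            region_proportions=payload["region_proportions"],
        )


@dataclass
class PressureRecording:
    """Frame-major stack of per-sensor pressures on a foot-aligned grid."""

    frames: np.ndarray  # (T, n_rows, n_cols), kPa, >= 0
    grid: SensorGrid
    sample_rate_hz: float = 100.0
    body_mass_kg: float = 70.0
    side: str = "right"
    task_label: str = "unknown"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise InvalidConfigError("frames must be (T, n_rows, n_cols)")
        if self.frames.shape[1:] != self.grid.shape:
            raise InvalidConfigError(
                f"frame shape {self.frames.shape[1:]} does not match grid "
                f"{self.grid.shape}"
            )
        if self.sample_rate_hz <= 0:
            raise InvalidConfigError("sample_rate_hz must be positive")
        if np.any(self.frames < 0):
            raise InvalidConfigError("pressures must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.sample_rate_hz

    def flattened(self) -> np.ndarray:
        """Frames as a (T, n_cells) matrix for factorization."""
        return self.frames.reshape(self.n_frames, -1)

    def with_frames(self, frames: np.ndarray) -> "PressureRecording":
        return replace(self, frames=frames)


def _region_index_of_ap(ap: float, boundaries: np.ndarray) -> int:
    # ties on a boundary break toward the posterior region
    for k, b in enumerate(boundaries):
        if ap <= b + 1e-12:
            return k
    return len(boundaries) - 1


def build_standard_outline(
    region_proportions: Mapping[str, float] | None = None,
    n_rows: int = DEFAULT_N_ROWS,
    n_cols: int = DEFAULT_N_COLS,
    cell_area_cm2: float = DEFAULT_CELL_AREA_CM2,
    foot_length_cm: float = 28.0,
    foot_width_cm: float = 10.0,
    include_subregions: bool = True,
) -> FootOutline:
    """Construct the standardized outline and its region partition.

    Parameters
    ----------
    region_proportions
        Fraction of foot length per coarse region (heel, arch,
        metatarsals, toes); must sum to 1 within 1e-6.
    n_rows, n_cols
        Working grid dimensions; each must be at least the number of
        coarse regions (4).
    """
    props = dict(DEFAULT_AP_PROPORTIONS if region_proportions is None else region_proportions)
    missing = set(AP_REGION_ORDER) - set(props)
    if missing:
        raise InvalidConfigError(f"missing region proportions: {sorted(missing)}")
    total = sum(props[r] for r in AP_REGION_ORDER)
    if abs(total - 1.0) > 1e-6:
        raise InvalidConfigError(f"AP region proportions sum to {total}, expected 1")
    if any(props[r] < 0 for r in AP_REGION_ORDER):
        raise InvalidConfigError("region proportions must be non-negative")
    if n_rows < len(AP_REGION_ORDER) or n_cols < len(AP_REGION_ORDER):
        raise InvalidConfigError(
            f"grid {n_rows} x {n_cols} degenerate: each dimension must be >= "
            f"{len(AP_REGION_ORDER)}"
        )

    mask = _build_in_outline_mask(n_rows, n_cols)
    grid = SensorGrid(n_rows, n_cols, cell_area_cm2, mask)
    boundaries = np.cumsum([props[r] for r in AP_REGION_ORDER])
    boundaries[-1] = 1.0  # guard against rounding

    ap, ml = cell_centres(n_rows, n_cols)
    region_idx = np.array([_region_index_of_ap(a, boundaries) for a in ap])
    masks: dict[str, np.ndarray] = {}
    for k, name in enumerate(AP_REGION_ORDER):
        m = np.zeros((n_rows, n_cols), dtype=bool)
        m[region_idx == k, :] = True
        masks[name] = m & mask

    if include_subregions:
        medial = ml[None, :] > 0.5  # ties toward lateral
        masks["medial_arch"] = masks["arch"] & medial
        masks["lateral_arch"] = masks["arch"] & ~medial
        great_toe = ml[None, :] > 0.65
        masks["great_toe"] = masks["toes"] & great_toe

    return FootOutline(
        boundary=_boundary_polygon(),
        region_masks=masks,
        grid=grid,
        foot_length_cm=foot_length_cm,
        foot_width_cm=foot_width_cm,
        region_proportions=props,
    )


def region_of(
    coordinate: Sequence[float],
    outline: FootOutline,
    clamp: bool = True,
) -> str:
    """Coarse region containing a normalized (AP, ML) coordinate.

    Coordinates that fall outside the outline (e.g. a centre of pressure
    between two disjoint contact regions that leaves the plan form) are
    clamped to the nearest in-outline cell; pass ``clamp=False`` to get the
    sentinel label ``"outside"`` instead.
    """
    ap, ml = float(coordinate[0]), float(coordinate[1])
    if not (0.0 <= ap <= 1.0 and 0.0 <= ml <= 1.0):
        raise ValueError(f"coordinate {coordinate} outside [0, 1]^2")
    if not outline.contains(coordinate):
        if not clamp:
            return "outside"
        i, _ = outline.nearest_in_outline_cell(coordinate)
        ap = (i + 0.5) / outline.grid.n_rows
    k = _region_index_of_ap(ap, outline.ap_boundaries())
    return AP_REGION_ORDER[k]


def _overlap_matrix(n_src: int, n_dst: int) -> np.ndarray:
    """F[I, i] = fraction of source cell i overlapping destination cell I.

    Cells partition [0, 1] uniformly on both sides, so each column sums
    to 1 and a matrix product redistributes cell masses exactly.
    """
    F = np.zeros((n_dst, n_src))
    src_edges = np.arange(n_src + 1) / n_src
    dst_edges = np.arange(n_dst + 1) / n_dst
    for i in range(n_src):
        lo, hi = src_edges[i], src_edges[i + 1]
        I0 = int(np.searchsorted(dst_edges, lo, side="right")) - 1
        I1 = int(np.searchsorted(dst_edges, hi, side="left"))
        for I in range(max(I0, 0), min(I1, n_dst)):
            overlap = min(hi, dst_edges[I + 1]) - max(lo, dst_edges[I])
            if overlap > 0:
                F[I, i] = overlap / (hi - lo)
    return F


def _resize_frames(frames: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Area-overlap rebinning of every frame onto the target lattice.

    Each source cell's pressure mass is split among the destination
    cells it geometrically overlaps, so the per-frame summed load is
    conserved exactly, a uniform field stays uniform, and an impulse
    never leaks beyond the image of its source cell.
    """
    T, r, c = frames.shape
    R, C = target_shape
    if (r, c) == (R, C):
        return frames.copy()
    F_row = _overlap_matrix(r, R)
    F_col = _overlap_matrix(c, C)
    return np.einsum("Ri,tic,Cc->tRC", F_row, frames, F_col, optimize=True)


def map_raw_to_outline(
    raw_frames: np.ndarray,
    outline: FootOutline,
    sample_rate_hz: float = 100.0,
    body_mass_kg: float = 70.0,
    side: str = "right",
    task_label: str = "unknown",
) -> tuple[PressureRecording, dict]:
    """Map raw sensor matrices onto the standardized outline.

    Border rows/columns that are empty across *all* frames are trimmed,
    the remaining block is rescaled onto the outline's bounding box, and
    cells outside the outline are zeroed.  The mapping report states the
    fraction of the total raw pressure captured inside the outline.
    """
    raw = np.asarray(raw_frames, dtype=float)
    if raw.ndim != 3:
        raise InvalidConfigError("raw_frames must be (T, rows, cols)")
    if np.any(raw < 0):
        raise InvalidConfigError("raw pressures must be non-negative")
    total_raw = raw.sum()
    if total_raw <= 0:
        raise ValueError("all-zero recording: cannot locate foot boundary")

    occupied = raw.sum(axis=0) > 0
    rows = np.nonzero(occupied.any(axis=1))[0]
    cols = np.nonzero(occupied.any(axis=0))[0]
    trimmed = raw[:, rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]

    mask = outline.in_outline_mask
    out_rows = np.nonzero(mask.any(axis=1))[0]
    out_cols = np.nonzero(mask.any(axis=0))[0]
    bbox_shape = (out_rows[-1] - out_rows[0] + 1, out_cols[-1] - out_cols[0] + 1)

    resized = _resize_frames(trimmed, bbox_shape)
    frames = np.zeros((raw.shape[0], outline.grid.n_rows, outline.grid.n_cols))
    frames[:, out_rows[0] : out_rows[-1] + 1, out_cols[0] : out_cols[-1] + 1] = resized
    mapped_total = frames.sum()
    frames *= mask[None, :, :]
    captured = frames.sum() / mapped_total if mapped_total > 0 else 0.0

    report = {
        "captured_pressure_fraction": float(captured),
        "trimmed_rows": int(raw.shape[1] - trimmed.shape[1]),
        "trimmed_cols": int(raw.shape[2] - trimmed.shape[2]),
        "source_shape": list(raw.shape[1:]),
        "mapped_shape": list(outline.grid.shape),
    }
    rec = PressureRecording(
        frames=frames,
        grid=outline.grid,
        sample_rate_hz=sample_rate_hz,
        body_mass_kg=body_mass_kg,
        side=side,
        task_label=task_label,
    )
    return rec, report


def rescale_to_common_grid(
    recording: PressureRecording,
    target_grid: SensorGrid | tuple[int, int] | None = None,
) -> PressureRecording:
    """Rebin a recording onto the common analysis grid.

    Area-overlap rebinning conserves the per-frame total load (pressure
    times cell area) exactly.
    """
    if target_grid is None:
        target_grid = SensorGrid(in_outline_mask=_build_in_outline_mask(
            DEFAULT_N_ROWS, DEFAULT_N_COLS))
    elif isinstance(target_grid, tuple):
        n_rows, n_cols = target_grid
        target_grid = SensorGrid(
            n_rows, n_cols,
            in_outline_mask=_build_in_outline_mask(n_rows, n_cols),
        )
    if target_grid.n_rows < 2 or target_grid.n_cols < 2:
        raise InvalidConfigError("target grid must be at least 2 x 2")
    if recording.grid.shape == target_grid.shape:
        return recording
    frames = _resize_frames(recording.frames, target_grid.shape)
    # conserve per-frame summed force (sum(p) * cell_area) across cell sizes
    frames *= recording.grid.cell_area_cm2 / target_grid.cell_area_cm2
    return PressureRecording(
        frames=frames,
        grid=target_grid,
        sample_rate_hz=recording.sample_rate_hz,
        body_mass_kg=recording.body_mass_kg,
        side=recording.side,
        task_label=recording.task_label,
    )
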