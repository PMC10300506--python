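"""Synthetic plantar-pressure generator with ground truth.

Emulates the statistical structure the analysis pipeline assumes, without
requiring real insole recordings:

* two-foot quiet standing with low-frequency postural sway sharing body
  weight between feet (heel + metatarsal load),
* gait as a rolling heel->toe pressure wave with a stance duty factor,
  near-zero swing phases, and a double-humped (heel-strike / push-off)
  vertical force profile whose per-stride impulse equals
  body weight x stride duration / 2 per foot,
* gravel walking as plain walking plus Poisson-placed localized hotspots
  (a stepped-on stone multiplies local pressure),
* recordings planted from K non-negative spatial components with
  non-negative activations, for factorization-recovery tests,
* a stomp + yaw-turn scenario for synchronization and turn exclusion.

Every generator is fully determined by its seed.  Pressures are in kPa;
force bookkeeping uses force_N = sum(p_kPa) * cell_area_cm2 * 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .foot_model import (
    FootOutline,
    PressureRecording,
    build_standard_outline,
    cell_centres,
)

__all__ = [
    "SyntheticTaskConfig",
    "GroundTruth",
    "gen_standing",
    "gen_walking",
    "gen_from_components",
    "gen_stomp_and_turns",
    "gen_jump",
    "GRAVITY",
]

GRAVITY = 9.81  # m s^-2

TASK_KINDS = ("standing", "wobble", "walking", "gravel", "jump", "planted")


@dataclass
class SyntheticTaskConfig:
    """Parameters of one synthetic task recording.

    duty_factor is the stance fraction of each gait cycle; step_rate_hz is
    strides per second per foot.  noise_sigma is the per-cell truncated
    Gaussian noise level in kPa.  hotspot_rate is the expected number of
    gravel stones contacted per stance.
    """

    task_kind: str = "standing"
    duration_s: float = 45.0
    sample_rate_hz: float = 100.0
    body_mass_kg: float = 70.0
    seed: int = 0
    duty_factor: float = 0.6
    step_rate_hz: float = 0.9
    sway_amplitude: float = 0.03
    hotspot_rate: float = 4.0
    hotspot_factor: float = 3.0
    noise_sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.task_kind not in TASK_KINDS:
            raise ValueError(f"unknown task_kind {self.task_kind!r}")
        if not 0.0 < self.duty_factor < 1.0:
            raise ValueError("duty_factor must be in (0, 1)")
        if self.step_rate_hz <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("rates must be positive")
        if self.body_mass_kg <= 0:
            raise ValueError("body mass must be positive")


@dataclass
class GroundTruth:
    """Generative ground truth accompanying a synthetic recording."""

    cop_trace: np.ndarray | None = None  # (T, 2) true weighted centroid
    step_windows: list[tuple[int, int]] = field(default_factory=list)
    planted_components: np.ndarray | None = None  # (K, n_cells), unit sum
    planted_activations: np.ndarray | None = None  # (T, K)
    turn_windows: list[tuple[int, int]] = field(default_factory=list)
    turn_angles_deg: list[float] = field(default_factory=list)
    stomp_frame: int | None = None

    def __post_init__(self) -> None:
        sw = sorted(self.step_windows)
        for (a0, a1), (b0, b1) in zip(sw, sw[1:]):
            if a1 > b0:
                raise ValueError("step windows must be non-overlapping")
        self.step_windows = [(int(a), int(b)) for a, b in sw]


def _body_weight_newton(mass_kg: float) -> float:
    return mass_kg * GRAVITY


def _pressure_scale(outline: FootOutline) -> float:
    """kPa per Newton on a unit-sum spatial template."""
    return 1.0 / (outline.grid.cell_area_cm2 * 0.1)


def _gaussian_template(
    outline: FootOutline,
    centre_ap: float,
    centre_ml: float,
    sigma_ap: float,
    sigma_ml: float,
) -> np.ndarray:
    """Unit-sum in-outline Gaussian pressure blob."""
    ap, ml = cell_centres(outline.grid.n_rows, outline.grid.n_cols)
    g = np.exp(
        -0.5 * ((ap[:, None] - centre_ap) / sigma_ap) ** 2
        - 0.5 * ((ml[None, :] - centre_ml) / sigma_ml) ** 2
    )
    g *= outline.in_outline_mask
    s = g.sum()
    if s <= 0:
        raise ValueError("template centre falls outside the outline")
    return g / s


def _truncated_noise(rng: np.random.Generator, shape, sigma: float,
                     mask: np.ndarray | None = None) -> np.ndarray:
    if sigma <= 0:
        return np.zeros(shape)
    noise = np.clip(rng.normal(0.0, sigma, size=shape), 0.0, None)
    if mask is not None:
        noise = noise * mask
    return noise


def _add_measurement_noise(
    frames: np.ndarray,
    rng: np.random.Generator,
    sigma: float,
    mask: np.ndarray,
) -> np.ndarray:
    """Additive zero-mean sensor noise, clipped at zero pressure."""
    if sigma <= 0:
        return frames
    frames = frames + rng.normal(0.0, sigma, size=frames.shape) * mask
    return np.clip(frames, 0.0, None)


def _apply_sensor_floor(frames: np.ndarray, noise_sigma: float) -> np.ndarray:
    """Zero out sub-threshold sensor readings.

    Resistive insole sensors only respond above an individual activation
    threshold, so pressure spread thinly across many sensors is slightly
    under-read (most visible in two-foot standing).  The floor is tied to
    the noise level (2 sigma): readings indistinguishable from noise are
    reported as zero.  With noise_sigma = 0 the floor vanishes and load
    is conserved exactly.
    """
    floor = 2.0 * noise_sigma
    if floor <= 0:
        return frames
    frames[frames < floor] = 0.0
    return frames


def _cop_of_frames(frames: np.ndarray) -> np.ndarray:
    """True pressure-weighted centroid per frame (nan when empty)."""
    T, n_rows, n_cols = frames.shape
    ap, ml = cell_centres(n_rows, n_cols)
    total = frames.sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        cop_ap = (frames.sum(axis=2) @ ap) / total
        cop_ml = (frames.sum(axis=1) @ ml) / total
    return np.column_stack([cop_ap, cop_ml])


def gen_standing(
    config: SyntheticTaskConfig,
    outline: FootOutline | None = None,
) -> tuple[dict[str, PressureRecording], GroundTruth]:
    """Two-foot quiet standing (or wobble-board) with postural sway.

    Returns one recording per foot ({"left", "right"}).  The summed force
    over both feet equals body weight each frame (before additive sensor
    noise); slow (<1 Hz) sway shifts load between feet and, on the wobble
    board, more strongly between heel and metatarsals.
    """
    if config.task_kind not in ("standing", "wobble"):
        raise ValueError("gen_standing requires task_kind standing|wobble")
    if config.duration_s < 1.0:
        raise ValueError("standing recordings must last at least 1 s")
    outline = outline or build_standard_outline()
    fs = config.sample_rate_hz
    T = int(round(config.duration_s * fs))
    t = np.arange(T) / fs
    rng = np.random.default_rng(config.seed)

    heel = _gaussian_template(outline, 0.14, 0.50, 0.07, 0.12)
    mets = _gaussian_template(outline, 0.68, 0.52, 0.07, 0.16)

    # low-frequency sway: sum of slow sinusoids with random phase
    def slow_wave() -> np.ndarray:
        f1, f2 = rng.uniform(0.15, 0.45), rng.uniform(0.5, 0.9)
        p1, p2 = rng.uniform(0, 2 * np.pi, 2)
        return np.sin(2 * np.pi * f1 * t + p1) + 0.4 * np.sin(2 * np.pi * f2 * t + p2)

    ml_sway = config.sway_amplitude * slow_wave()  # left/right load share
    ap_sway = config.sway_amplitude * slow_wave()  # heel/metatarsal share
    if config.task_kind == "wobble":
        ap_sway = ap_sway * 4.0
        ml_sway = ml_sway * 2.0
    share_left = np.clip(0.5 + ml_sway, 0.05, 0.95)
    w_heel = np.clip(0.55 + ap_sway, 0.05, 0.95)

    bw = _body_weight_newton(config.body_mass_kg)
    scale = _pressure_scale(outline)
    recs: dict[str, PressureRecording] = {}
    for side, share in (("left", share_left), ("right", 1.0 - share_left)):
        template = (
            w_heel[:, None, None] * heel[None]
            + (1.0 - w_heel)[:, None, None] * mets[None]
        )
        frames = (share * bw * scale)[:, None, None] * template
        frames = _add_measurement_noise(
            frames, rng, config.noise_sigma, outline.in_outline_mask
        )
        frames = _apply_sensor_floor(frames, config.noise_sigma)
        recs[side] = PressureRecording(
            frames=frames,
            grid=outline.grid,
            sample_rate_hz=fs,
            body_mass_kg=config.body_mass_kg,
            side=side,
            task_label=config.task_kind,
        )
    truth = GroundTruth(cop_trace=_cop_of_frames(recs["right"].frames))
    return recs, truth


def _stance_profile(s: np.ndarray) -> np.ndarray:
    """Double-humped vertical force profile over normalized stance time."""
    return np.sin(np.pi * s) ** 0.7 * (1.0 + 0.35 * np.cos(2.0 * np.pi * s))


def gen_walking(
    config: SyntheticTaskConfig,
    outline: FootOutline | None = None,
) -> tuple[PressureRecording, GroundTruth]:
    """Single-foot gait: a heel->toe pressure wave per stance.

    Each stride lasts 1/step_rate_hz; the stance occupies duty_factor of
    it.  Per-frame stance force follows a double-humped profile scaled so
    that the per-stride vertical impulse equals body weight x stride
    duration / 2 (two feet share the gait cycle).  task_kind "gravel"
    additionally multiplies local <=3x3 patches by hotspot_factor at
    Poisson-placed stone locations, redrawn each stance.
    """
    if config.task_kind not in ("walking", "gravel"):
        raise ValueError("gen_walking requires task_kind walking|gravel")
    outline = outline or build_standard_outline()
    fs = config.sample_rate_hz
    stride_frames = int(round(fs / config.step_rate_hz))
    stance_frames = int(round(config.duty_factor * stride_frames))
    n_strides = int(config.duration_s * fs) // stride_frames
    if n_strides < 3:
        raise ValueError(
            f"duration {config.duration_s} s gives {n_strides} strides; "
            "need at least 3"
        )
    T = n_strides * stride_frames
    rng = np.random.default_rng(config.seed)
    gravel_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))

    bw = _body_weight_newton(config.body_mass_kg)
    scale = _pressure_scale(outline)
    n_rows, n_cols = outline.grid.shape

    s = (np.arange(stance_frames) + 0.5) / stance_frames
    profile = _stance_profile(s)
    # per-stride impulse: sum(force) over stance = bw * stride_frames / 2
    base_force = profile * (bw * stride_frames / 2.0 / profile.sum())
    ap_path = 0.12 + (0.85 - 0.12) * (3 * s**2 - 2 * s**3)  # smoothstep
    ml_path = 0.44 + 0.14 * s

    frames = np.zeros((T, n_rows, n_cols))
    step_windows: list[tuple[int, int]] = []
    for k in range(n_strides):
        start = k * stride_frames
        step_windows.append((start, start + stance_frames))
        jitter = 1.0 + rng.normal(0.0, 0.02)  # per-stride amplitude jitter
        hotspots: list[tuple[int, int]] = []
        if config.task_kind == "gravel" and config.hotspot_rate > 0:
            n_spots = gravel_rng.poisson(config.hotspot_rate)
            for _ in range(n_spots):
                i = int(gravel_rng.uniform(0.10, 0.90) * n_rows)
                j = int(gravel_rng.uniform(0.30, 0.75) * n_cols)
                hotspots.append((i, j))
        for f in range(stance_frames):
            blob = _gaussian_template(
                outline, ap_path[f], ml_path[f], 0.055, 0.10
            )
            frame = base_force[f] * jitter * scale * blob
            for (i, j) in hotspots:
                frame[max(i - 1, 0) : i + 2, max(j - 1, 0) : j + 2] *= (
                    config.hotspot_factor
                )
            frames[start + f] = frame
    frames = _add_measurement_noise(
        frames, rng, config.noise_sigma, outline.in_outline_mask
    )
    frames = _apply_sensor_floor(frames, config.noise_sigma)

    rec = PressureRecording(
        frames=frames,
        grid=outline.grid,
        sample_rate_hz=fs,
        body_mass_kg=config.body_mass_kg,
        side="right",
        task_label=config.task_kind,
    )
    truth = GroundTruth(
        cop_trace=_cop_of_frames(frames), step_windows=step_windows
    )
    return rec, truth


def gen_jump(
    config: SyntheticTaskConfig,
    outline: FootOutline | None = None,
) -> tuple[PressureRecording, GroundTruth]:
    """Single impact transient peaking at 3x body weight, then standing."""
    if config.task_kind != "jump":
        raise ValueError("gen_jump requires task_kind jump")
    outline = outline or build_standard_outline()
    fs = config.sample_rate_hz
    T = int(round(config.duration_s * fs))
    t = np.arange(T) / fs
    rng = np.random.default_rng(config.seed)
    bw = _body_weight_newton(config.body_mass_kg)
    impact = 3.0 * bw * np.exp(-0.5 * ((t - 0.3) / 0.05) ** 2)
    settle = 0.5 * bw / (1.0 + np.exp(-(t - 0.6) * 20.0))
    force = impact + settle
    heel = _gaussian_template(outline, 0.16, 0.50, 0.08, 0.13)
    mets = _gaussian_template(outline, 0.68, 0.52, 0.07, 0.16)
    template = 0.5 * (heel + mets)
    frames = force[:, None, None] * template[None] * _pressure_scale(outline)
    frames = _add_measurement_noise(
        frames, rng, config.noise_sigma, outline.in_outline_mask
    )
    frames = _apply_sensor_floor(frames, config.noise_sigma)
    rec = PressureRecording(
        frames=frames, grid=outline.grid, sample_rate_hz=fs,
        body_mass_kg=config.body_mass_kg, side="right", task_label="jump",
    )
    return rec, GroundTruth(cop_trace=_cop_of_frames(frames))


def default_blob_centres(k: int) -> list[tuple[float, float]]:
    """K well-separated blob centres along the loaded axis of the foot."""
    anchors = [
        (0.14, 0.50), (0.66, 0.42), (0.70, 0.76), (0.38, 0.42),
        (0.90, 0.58), (0.14, 0.24), (0.40, 0.66), (0.14, 0.76),
        (0.90, 0.30), (0.54, 0.55),
    ]
    if k <= len(anchors):
        return anchors[:k]
    extra_needed = k - len(anchors)
    extra = [
        (0.08 + 0.84 * (i + 0.5) / extra_needed, 0.42 + 0.16 * (i % 2))
        for i in range(extra_needed)
    ]
    return anchors + extra


def gen_from_components(
    k: int,
    T: int = 300,
    noise_sigma: float = 0.5,
    seed: int = 0,
    spatial_layout: Sequence[tuple[float, float]] | None = None,
    outline: FootOutline | None = None,
    sigma_cells: float = 2.0,
    activation_scale: float = 400.0,
) -> tuple[PressureRecording, GroundTruth]:
    """Plant K non-negative spatial components with smooth activations.

    frames = activations @ components + truncated Gaussian noise, clipped
    at zero.  Components are unit-sum Gaussian blobs whose centres must be
    at least 2 cells apart (identifiability).
    """
    if not 1 <= k <= 30:
        raise ValueError("k must be in 1..30")
    outline = outline or build_standard_outline()
    n_rows, n_cols = outline.grid.shape
    centres = list(spatial_layout) if spatial_layout is not None else default_blob_centres(k)
    if len(centres) != k:
        raise ValueError(f"need {k} blob centres, got {len(centres)}")
    cells = [(ap * n_rows, ml * n_cols) for ap, ml in centres]
    for a in range(k):
        for b in range(a + 1, k):
            d = np.hypot(cells[a][0] - cells[b][0], cells[a][1] - cells[b][1])
            if d < 2.0:
                raise ValueError(
                    f"blob centres {a} and {b} closer than 2 cells ({d:.2f})"
                )
    rng = np.random.default_rng(seed)
    comps = np.stack([
        _gaussian_template(
            outline, ap, ml, sigma_cells / n_rows, sigma_cells / n_cols
        ).ravel()
        for ap, ml in centres
    ])
    # rectified smooth random series, unit variance before scaling
    smooth = ndimage.gaussian_filter1d(
        rng.normal(0.0, 1.0, size=(T, k)), sigma=5.0, axis=0
    )
    smooth /= smooth.std(axis=0, keepdims=True) + 1e-12
    # components take turns dominating (distinct contact events), so each
    # contributes a comparable, separable share of the variance
    block = max(10, T // (4 * k))
    n_blocks = -(-T // block)
    owner = np.resize(np.arange(k), n_blocks)
    rng.shuffle(owner)
    envelope = np.zeros((T, k))
    for b in range(n_blocks):
        envelope[b * block : (b + 1) * block, owner[b]] = 1.0
    envelope = ndimage.gaussian_filter1d(envelope, sigma=2.0, axis=0)
    envelope = 0.02 + 0.98 * envelope
    acts = np.abs(smooth) * envelope
    # equal energy per component: each contributes the same variance share
    acts *= activation_scale * np.sqrt(T / k) / (
        np.linalg.norm(acts, axis=0, keepdims=True) + 1e-12
    )
    flat = acts @ comps
    flat += _truncated_noise(rng, flat.shape, noise_sigma,
                             outline.in_outline_mask.ravel()[None, :])
    frames = np.clip(flat, 0.0, None).reshape(T, n_rows, n_cols)
    rec = PressureRecording(
        frames=frames, grid=outline.grid, sample_rate_hz=100.0,
        body_mass_kg=70.0, side="right", task_label="planted",
    )
    truth = GroundTruth(
        cop_trace=_cop_of_frames(frames),
        planted_components=comps,
        planted_activations=acts,
    )
    return rec, truth


def gen_stomp_and_turns(
    duration_s: float = 30.0,
    sample_rate_hz: float = 100.0,
    stomp_frame: int = 250,
    gyro_lag_frames: int = 0,
    turns: Sequence[tuple[float, float, float]] = ((12.0, 3.0, 180.0),),
    noise_sigma: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """1-D summed-pressure and yaw-rate traces with a stomp and yaw turns.

    ``turns`` is a sequence of (start_s, duration_s, angle_deg); each turn
    is a constant yaw-rate segment integrating to the requested angle.
    The gyro stomp spike appears ``gyro_lag_frames`` after the pressure
    spike, emulating unsynchronized stream starts.
    """
    fs = sample_rate_hz
    T = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    baseline = 2000.0  # kPa summed over the foot while standing
    pressure = baseline + rng.normal(0.0, noise_sigma * 10, size=T)
    pressure = np.clip(pressure, 0.0, None)
    pressure[stomp_frame] += baseline * 10.0

    gyro = rng.normal(0.0, noise_sigma, size=T)
    g_spike = stomp_frame + gyro_lag_frames
    if not 0 <= g_spike < T:
        raise ValueError("gyro spike outside trace")
    gyro[g_spike] += 500.0  # deg/s transient

    turn_windows: list[tuple[int, int]] = []
    turn_angles: list[float] = []
    for start_s, dur_s, angle_deg in turns:
        a = int(round(start_s * fs))
        b = int(round((start_s + dur_s) * fs))
        if b > T:
            raise ValueError("turn extends past end of trace")
        gyro[a:b] += angle_deg / dur_s  # deg/s, integrates to angle_deg
        turn_windows.append((a, b))
        turn_angles.append(float(angle_deg))

    truth = GroundTruth(
        stomp_frame=stomp_frame,
        turn_windows=turn_windows,
        turn_angles_deg=turn_angles,
    )
    return pressure, gyro, truth
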