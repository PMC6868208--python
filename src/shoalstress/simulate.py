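"""Synthetic shoal study generator.

Produces a complete synthetic study — fish trajectories, clip-level
behaviour tables, body lengths and whole-body cortisol — with the
statistical structure the analysis pipeline assumes: 23 groups of 7 fish
observed in a 45 x 25 cm tank (20 cm water depth) in two conditions
(``immediate`` exposure to a novel-tank stressor, and ``after_24h``), 180
position frames per session taken 10 s apart, and 180 ten-second behaviour
clips per session.

The motion model is a deliberately simple zonal collective-motion scheme:
each fish is attracted to the centroid of its shoal-mates, repelled at
short range, attracted to the nearest wall (thigmotaxis), biased towards
the tank bottom, and perturbed by Gaussian noise, with occasional large
random velocity impulses ("erratic bursts"). A single stress parameter
theta in [0, 1] scales cohesion, wall attraction, bottom bias, burst rate
and (inversely) locomotor noise, so that a stressed shoal (theta = 1) is
denser, more regular, closer to the walls and the bottom, and more erratic
than a recovered one (theta = 0.2). The parameters are configuration
choices that reproduce those qualitative contrasts, not claims about real
zebrafish kinematics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd

from .geometry import TankGeometry

CONDITIONS = ("immediate", "after_24h")


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and motion-model parameters.

    Design defaults (groups, fish, frames, tank, body lengths, cortisol
    targets) mirror the empirical study the pipeline is built for; the
    motion-model weights are synthetic-dynamics tuning constants.
    """

    # --- design ---
    n_groups: int = 23
    n_fish: int = 7
    n_frames: int = 180
    frame_interval_s: float = 10.0
    subframe_rate_hz: float = 10.0
    tank: TankGeometry = field(default_factory=TankGeometry)
    body_length_mean_mm: float = 36.98
    body_length_sd_mm: float = 2.24
    # --- stress level per condition ---
    theta_immediate: float = 1.0
    theta_24h: float = 0.2
    # --- motion model (cm, s) ---
    w_attraction: float = 0.05       # 1/s, baseline centroid attraction
    kappa_theta: float = 25.0        # extra attraction factor: w*(1+kappa*theta)
    w_repulsion: float = 20.0        # cm/s at zero distance, linearly decaying
    repulsion_radius_cm: float = 2.5
    w_wall: float = 2.5              # cm/s towards nearest wall at theta=1
    #: condition-independent share of wall attraction; keeps the centroid's
    #: wall-distance dynamics mixing faster than the 10 s frame spacing so
    #: frames behave as near-independent observations in both conditions
    wall_attraction_floor: float = 0.15
    noise_sd_cm: float = 3.5         # per sqrt(s) horizontal diffusion, at theta=0
    noise_theta_damping: float = 0.6  # noise scaled by (1 - damping*theta)
    depth_relaxation_per_s: float = 0.8
    depth_noise_sd_cm: float = 1.5   # per sqrt(s)
    depth_pref_frac0: float = 0.375  # preferred depth = depth*(frac0 - slope*theta)
    depth_pref_slope: float = 0.075
    group_theta_sd: float = 0.06     # per-group latent trait: theta shifted by N(0, sd)
    # --- erratic bursts ---
    burst_rate_base: float = 1.0e-4  # per fish per subframe, at theta=0
    burst_rate_theta_mult: float = 27.0  # p = p0*(1 + mult*theta)
    burst_speed_cm_s: float = 120.0
    # --- cortisol (ng/g; SD on the per-fish scale) ---
    cortisol_mean_immediate: float = 40.2
    cortisol_mean_24h: float = 19.9
    cortisol_sd_immediate: float = 28.8   # = 6.0 SE * sqrt(23)
    cortisol_sd_24h: float = 20.6         # = 4.3 SE * sqrt(23)
    cortisol_group_rho: float = 0.3       # share of log-scale variance between groups

    def theta(self, condition: str) -> float:
        if condition == "immediate":
            return self.theta_immediate
        if condition == "after_24h":
            return self.theta_24h
        raise ValueError(f"unknown condition: {condition}")

    @property
    def n_subframes(self) -> int:
        total_s = self.n_frames * self.frame_interval_s
        return int(round(total_s * self.subframe_rate_hz))

    @property
    def subframes_per_frame(self) -> int:
        return int(round(self.frame_interval_s * self.subframe_rate_hz))

    def validate(self) -> None:
        if not 0 <= self.theta_24h <= 1 or not 0 <= self.theta_immediate <= 1:
            raise ValueError("theta must lie in [0, 1]")
        for name in ("burst_rate_base", "w_repulsion", "w_wall", "noise_sd_cm",
                     "depth_noise_sd_cm", "w_attraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_fish < 2 or self.n_groups < 1 or self.n_frames < 1:
            raise ValueError("design counts must be positive (>=2 fish)")


@dataclass
class SimulatedStudy:
    """All tables of one synthetic study plus provenance."""

    positions: pd.DataFrame     # group_id, condition, frame_index, time_s, fish_id, x_cm, y_cm, z_cm
    behaviours: pd.DataFrame    # group_id, condition, clip_index, behaviour, present
    body_lengths: pd.DataFrame  # group_id, fish_id, standard_length_mm
    cortisol: pd.DataFrame      # group_id, condition, fish_id, cortisol_ng_per_g
    config: SimulationConfig
    seed: int


@numba.njit(cache=False)
def _motion_kernel(pos0, n_steps, dt, L, W, D,
                   w_att, w_rep, r_rep, w_wall, k_z, z_pref,
                   sigma_xy, sigma_z, p_burst, burst_step,
                   normals, burst_u, burst_angle):  # pragma: no cover - jitted
    n_fish = pos0.shape[0]
    traj = np.empty((n_steps + 1, n_fish, 3))
    traj[0] = pos0
    pos = pos0.copy()
    sq_dt = np.sqrt(dt)
    for t in range(n_steps):
        sx = 0.0
        sy = 0.0
        for i in range(n_fish):
            sx += pos[i, 0]
            sy += pos[i, 1]
        for i in range(n_fish):
            x = pos[i, 0]
            y = pos[i, 1]
            z = pos[i, 2]
            # attraction to centroid of the others
            cx = (sx - x) / (n_fish - 1)
            cy = (sy - y) / (n_fish - 1)
            vx = w_att * (cx - x)
            vy = w_att * (cy - y)
            # short-range repulsion
            for j in range(n_fish):
                if j == i:
                    continue
                ddx = x - pos[j, 0]
                ddy = y - pos[j, 1]
                d = np.sqrt(ddx * ddx + ddy * ddy)
                if 1e-12 < d < r_rep:
                    f = w_rep * (r_rep - d) / (r_rep * d)
                    vx += f * ddx
                    vy += f * ddy
            # attraction towards the nearest wall
            dx0 = x
            dx1 = L - x
            dy0 = y
            dy1 = W - y
            m = dx0
            wx, wy = -1.0, 0.0
            if dx1 < m:
                m = dx1
                wx, wy = 1.0, 0.0
            if dy0 < m:
                m = dy0
                wx, wy = 0.0, -1.0
            if dy1 < m:
                m = dy1
                wx, wy = 0.0, 1.0
            vx += w_wall * wx
            vy += w_wall * wy
            # erratic burst impulse
            if burst_u[t, i] < p_burst:
                vx += burst_step * np.cos(burst_angle[t, i]) / dt
                vy += burst_step * np.sin(burst_angle[t, i]) / dt
            nx = x + vx * dt + sigma_xy * sq_dt * normals[t, i, 0]
            ny = y + vy * dt + sigma_xy * sq_dt * normals[t, i, 1]
            nz = (
                z
                + k_z * (z_pref - z) * dt
                + sigma_z * sq_dt * normals[t, i, 2]
            )
            # reflect at the walls / surface / bottom
            for _ in range(8):
                if nx < 0.0:
                    nx = -nx
                elif nx > L:
                    nx = 2.0 * L - nx
                else:
                    break
            for _ in range(8):
                if ny < 0.0:
                    ny = -ny
                elif ny > W:
                    ny = 2.0 * W - ny
                else:
                    break
            for _ in range(8):
                if nz < 0.0:
                    nz = -nz
                elif nz > D:
                    nz = 2.0 * D - nz
                else:
                    break
            pos[i, 0] = min(max(nx, 0.0), L)
            pos[i, 1] = min(max(ny, 0.0), W)
            pos[i, 2] = min(max(nz, 0.0), D)
        traj[t + 1] = pos
    return traj


def simulate_shoal(
    config: SimulationConfig, condition: str, seed, theta: float | None = None
) -> np.ndarray:
    """One group-session trajectory at subframe resolution.

    Returns an ``(n_subframes + 1, n_fish, 3)`` array of (x, y, z)
    positions in cm, deterministic for a given seed. Fish start at random
    positions near the tank centre (release point). ``theta`` overrides the
    condition's stress level, e.g. to apply a group-specific trait shift.
    """
    config.validate()
    if theta is None:
        theta = config.theta(condition)
    theta = float(np.clip(theta, 0.0, 1.0))
    tank = config.tank
    rng = np.random.default_rng(seed)
    n_steps = config.n_subframes
    dt = 1.0 / config.subframe_rate_hz

    pos0 = np.empty((config.n_fish, 3))
    pos0[:, 0] = tank.length_cm / 2 + rng.uniform(-4, 4, config.n_fish)
    pos0[:, 1] = tank.width_cm / 2 + rng.uniform(-4, 4, config.n_fish)
    pos0[:, 2] = tank.water_depth_cm / 2 + rng.uniform(-2, 2, config.n_fish)

    normals = rng.standard_normal((n_steps, config.n_fish, 3))
    burst_u = rng.random((n_steps, config.n_fish))
    burst_angle = rng.uniform(0, 2 * np.pi, (n_steps, config.n_fish))

    w_att = config.w_attraction * (1.0 + config.kappa_theta * theta)
    sigma_xy = config.noise_sd_cm * (1.0 - config.noise_theta_damping * theta)
    z_pref = tank.water_depth_cm * (
        config.depth_pref_frac0 - config.depth_pref_slope * theta
    )
    p_burst = config.burst_rate_base * (1.0 + config.burst_rate_theta_mult * theta)
    burst_step = config.burst_speed_cm_s * dt

    floor = config.wall_attraction_floor
    w_wall = config.w_wall * (floor + (1.0 - floor) * theta)
    traj = _motion_kernel(
        pos0, n_steps, dt,
        tank.length_cm, tank.width_cm, tank.water_depth_cm,
        w_att, config.w_repulsion, config.repulsion_radius_cm,
        w_wall, config.depth_relaxation_per_s, z_pref,
        sigma_xy, config.depth_noise_sd_cm, p_burst, burst_step,
        normals, burst_u, burst_angle,
    )
    if not np.all(np.isfinite(traj)):
        raise RuntimeError(
            f"unstable simulation produced non-finite positions; config: {config}"
        )
    return traj


def downsample_frames(
    traj: np.ndarray, config: SimulationConfig, group_id: str, condition: str
) -> pd.DataFrame:
    """Retain one position frame every ``frame_interval_s`` (long format)."""
    step = config.subframes_per_frame
    idx = np.arange(1, config.n_frames + 1) * step
    frames = traj[idx]  # (n_frames, n_fish, 3)
    n_frames, n_fish, _ = frames.shape
    return pd.DataFrame(
        {
            "group_id": group_id,
            "condition": condition,
            "frame_index": np.repeat(np.arange(n_frames), n_fish),
            "time_s": np.repeat(idx / config.subframe_rate_hz, n_fish),
            "fish_id": np.tile([f"f{i}" for i in range(n_fish)], n_frames),
            "x_cm": frames[:, :, 0].ravel(),
            "y_cm": frames[:, :, 1].ravel(),
            "z_cm": frames[:, :, 2].ravel(),
        }
    )


def derive_behaviour_table(
    traj: np.ndarray,
    config: SimulationConfig,
    group_id: str,
    condition: str,
    speed_threshold_cm_s: float = 60.0,
    turn_threshold_deg: float = 120.0,
    turn_min_speed_cm_s: float = 30.0,
) -> pd.DataFrame:
    """Clip-level behaviour presence/absence from a subframe trajectory.

    Per 10 s clip: ``erratic_movement`` is present iff any fish exceeds the
    speed threshold — or turns by more than ``turn_threshold_deg`` between
    consecutive subframes while moving faster than ``turn_min_speed_cm_s`` —
    at any subframe of the clip; ``top_half`` is present iff any fish is
    above half the water depth at any subframe.
    """
    if traj.shape[2] < 3:
        raise ValueError("top_half unavailable: trajectory has no z coordinate")
    dt = 1.0 / config.subframe_rate_hz
    disp = np.diff(traj[:, :, :2], axis=0)          # (n_steps, n_fish, 2)
    speed = np.linalg.norm(disp, axis=2) / dt       # cm/s
    fast = speed > speed_threshold_cm_s

    # turning angle between consecutive displacement vectors
    a, b = disp[:-1], disp[1:]
    dot = (a * b).sum(axis=2)
    norm = np.linalg.norm(a, axis=2) * np.linalg.norm(b, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.clip(np.where(norm > 0, dot / norm, 1.0), -1.0, 1.0)
    angle = np.degrees(np.arccos(cosang))
    sharp_turn = (angle > turn_threshold_deg) & (
        np.minimum(speed[:-1], speed[1:]) > turn_min_speed_cm_s
    )
    erratic_step = fast.copy()
    erratic_step[1:] |= sharp_turn

    top_step = traj[1:, :, 2] > config.tank.water_depth_cm / 2.0

    spc = config.subframes_per_frame
    n_clips = config.n_frames
    erratic = erratic_step[: n_clips * spc].reshape(n_clips, spc, -1).any(axis=(1, 2))
    top = top_step[: n_clips * spc].reshape(n_clips, spc, -1).any(axis=(1, 2))
    rows = []
    for name, col in (("erratic_movement", erratic), ("top_half", top)):
        rows.append(
            pd.DataFrame(
                {
                    "group_id": group_id,
                    "condition": condition,
                    "clip_index": np.arange(n_clips),
                    "behaviour": name,
                    "present": col.astype(int),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_body_lengths(config: SimulationConfig, seed) -> pd.DataFrame:
    """Per-fish standard lengths (mm), normal around the population mean."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(config.n_groups):
        lengths = rng.normal(
            config.body_length_mean_mm, config.body_length_sd_mm, config.n_fish
        )
        lengths = np.clip(lengths, 5.0, None)  # biological floor
        rows.append(
            pd.DataFrame(
                {
                    "group_id": f"g{g:02d}",
                    "fish_id": [f"f{i}" for i in range(config.n_fish)],
                    "standard_length_mm": lengths,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def simulate_cortisol(config: SimulationConfig, seed) -> pd.DataFrame:
    """Whole-body cortisol, one sampled fish per group per condition (ng/g).

    Values are lognormal with condition-specific parameters calibrated so
    that the per-condition sample mean and SE approximate the configured
    targets at n = ``n_groups``. A fraction ``cortisol_group_rho`` of the
    log-scale variance is a group effect shared by a group's two samples
    (the repeated-measures correlation a group random intercept models);
    the marginal distribution per condition is unchanged. A zero-variance
    config returns the condition mean for every fish.
    """
    rng = np.random.default_rng(seed)
    z_group = rng.standard_normal(config.n_groups)  # shared latent group effect
    rho = config.cortisol_group_rho
    rows = []
    for condition, mean, sd in (
        ("immediate", config.cortisol_mean_immediate, config.cortisol_sd_immediate),
        ("after_24h", config.cortisol_mean_24h, config.cortisol_sd_24h),
    ):
        if sd == 0:
            vals = np.full(config.n_groups, mean)
        else:
            mu, sigma = _lognormal_params(mean, sd)
            logv = (
                mu
                + sigma * np.sqrt(rho) * z_group
                + sigma * np.sqrt(1 - rho) * rng.standard_normal(config.n_groups)
            )
            vals = np.exp(logv)
        rows.append(
            pd.DataFrame(
                {
                    "group_id": [f"g{g:02d}" for g in range(config.n_groups)],
                    "condition": condition,
                    "fish_id": "sampled",
                    "cortisol_ng_per_g": vals,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def child_seeds(master_seed: int, config: SimulationConfig) -> dict:
    """Deterministic per-table / per-session seeds from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    n_sessions = config.n_groups * len(CONDITIONS)
    children = ss.spawn(n_sessions + 3)
    seeds = {
        "body_lengths": children[0],
        "cortisol": children[1],
        "group_traits": children[2],
    }
    i = 3
    for g in range(config.n_groups):
        for condition in CONDITIONS:
            seeds[(f"g{g:02d}", condition)] = children[i]
            i += 1
    return seeds


def simulate_study(
    config: SimulationConfig | None = None, seed: int = 0
) -> SimulatedStudy:
    """Full synthetic study: positions, behaviours, body lengths, cortisol."""
    config = config or SimulationConfig()
    config.validate()
    seeds = child_seeds(seed, config)
    trait_rng = np.random.default_rng(seeds["group_traits"])
    traits = trait_rng.normal(0.0, config.group_theta_sd, config.n_groups)
    pos_tables, beh_tables = [], []
    for g in range(config.n_groups):
        gid = f"g{g:02d}"
        for condition in CONDITIONS:
            theta = config.theta(condition) + traits[g]
            traj = simulate_shoal(config, condition, seeds[(gid, condition)], theta=theta)
            pos_tables.append(downsample_frames(traj, config, gid, condition))
            beh_tables.append(derive_behaviour_table(traj, config, gid, condition))
    return SimulatedStudy(
        positions=pd.concat(pos_tables, ignore_index=True),
        behaviours=pd.concat(beh_tables, ignore_index=True),
        body_lengths=simulate_body_lengths(config, seeds["body_lengths"]),
        cortisol=simulate_cortisol(config, seeds["cortisol"]),
        config=config,
        seed=seed,
    )


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["tank"] = dataclasses.asdict(config.tank)
    return d
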