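"""Synthetic mating-swarm generator.

Produces labelled multi-trial datasets that mimic the *structure* of field
recordings of Anopheles mating swarms: swarming males fly long, smooth,
quasi-circular orbits above a fixed marker with little vertical movement;
couples (a mating pair tracked as one entity) and incoming females produce
short, erratic tracks with large, heavy-tailed accelerations.  Sampling is
nominally 25 Hz and tracks are grouped into trials (one swarm recording
each), so the whole pipeline — windowing, features, selection, one-class
fitting, trial-wise cross-validation and QC — can be exercised end to end.

The generator makes no claim of aerodynamic fidelity; its purpose is to
reproduce the qualitative class contrasts (orbital stability vs erratic
high-acceleration flight, long vs short durations, segment-count imbalance)
at realistic magnitudes (orbit radii ~0.3 m, speeds ~1 m/s).

All classes share the same orbital backbone; the non-male classes add an
Ornstein-Uhlenbeck velocity perturbation with occasional heavy-tailed kicks
and direction reversals, scaled by an ``erraticity`` knob.  At erraticity 0
the classes are statistically indistinguishable, which provides a null
control for the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .tracks import Dataset, Track, Trial


@dataclass
class ClassParams:
    """Per-class generation parameters."""

    n_trials: int
    tracks_per_trial: int
    duration_mean_s: float
    duration_sd_s: float
    duration_min_s: float
    erraticity: float  # 0 = pure orbit, 1 = default non-male perturbation


@dataclass
class SimConfig:
    """Simulation parameters; `seed` fixes the entire dataset.

    Default sizes mirror the segment imbalance of the field data
    (roughly 3000 male vs 1100 non-male segments at a 1.6 s / 0.8 s
    windowing).
    """

    seed: int = 0
    fs_hz: float = 25.0
    # swarm / orbit geometry
    orbit_radius_m: float = 0.30
    orbit_radius_sd_m: float = 0.05
    angular_rate_rad_s: float = 3.5
    angular_rate_sd: float = 0.7
    swarm_height_m: float = 2.0
    vertical_jitter_sd_m: float = 0.02
    radial_jitter_sd_m: float = 0.03
    measurement_noise_m: float = 0.002
    # erratic (non-male) perturbation at erraticity 1
    erratic_speed_sd_ms: float = 0.8
    erratic_tau_s: float = 0.2
    heavy_tail_prob: float = 0.05
    heavy_tail_scale: float = 4.0
    reversal_rate_hz: float = 1.0
    # class composition
    male: ClassParams = field(
        default_factory=lambda: ClassParams(8, 14, 22.0, 6.0, 8.0, 0.0)
    )
    couple: ClassParams = field(
        default_factory=lambda: ClassParams(6, 20, 7.0, 2.0, 4.0, 1.0)
    )
    female: ClassParams = field(
        default_factory=lambda: ClassParams(2, 6, 6.0, 1.5, 4.0, 1.2)
    )
    # focal males (males pursuing a female) fly male-like: same orbital
    # model as males (erraticity 0), distinguished only by shorter tracks
    focal_male: ClassParams = field(
        default_factory=lambda: ClassParams(1, 5, 8.0, 2.0, 5.0, 0.0)
    )
    # optional QC scenario: extra male trials recorded in high wind
    n_anomalous_male_trials: int = 0
    anomalous_velocity_multiplier: float = 5.0

    def with_erraticity_scale(self, scale: float) -> "SimConfig":
        """Scale every non-reference class's erraticity (gap control)."""
        return replace(
            self,
            couple=replace(self.couple, erraticity=self.couple.erraticity * scale),
            female=replace(self.female, erraticity=self.female.erraticity * scale),
            focal_male=replace(
                self.focal_male, erraticity=self.focal_male.erraticity * scale
            ),
        )


def _ou_series(
    rng: np.random.Generator, n: int, dt: float, tau: float, sd: float
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path of length n (marginal SD = sd)."""
    if sd == 0:
        return np.zeros(n)
    a = np.exp(-dt / tau)
    innov_sd = sd * np.sqrt(1.0 - a * a)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    shocks = rng.normal(0.0, innov_sd, size=n - 1)
    for k in range(1, n):
        x[k] = a * x[k - 1] + shocks[k - 1]
    return x


def _simulate_track(
    rng: np.random.Generator,
    cfg: SimConfig,
    duration: float,
    erraticity: float,
    centre: np.ndarray,
    velocity_multiplier: float = 1.0,
    wind_ms: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    dt = 1.0 / cfg.fs_hz
    n = max(int(round(duration * cfg.fs_hz)) + 1, 5)
    t = np.arange(n) * dt

    radius = max(rng.normal(cfg.orbit_radius_m, cfg.orbit_radius_sd_m), 0.1)
    omega = max(rng.normal(cfg.angular_rate_rad_s, cfg.angular_rate_sd), 1.0)
    omega *= rng.choice([-1.0, 1.0]) * velocity_multiplier
    phase = rng.uniform(0, 2 * np.pi)

    # direction reversals of the orbital sense (non-males only)
    sign = np.ones(n)
    if erraticity > 0 and cfg.reversal_rate_hz > 0:
        flips = rng.random(n) < erraticity * cfg.reversal_rate_hz * dt
        sign = np.cumprod(np.where(flips, -1.0, 1.0))
    theta = phase + np.cumsum(np.concatenate([[0.0], omega * sign[1:] * dt]))

    dr = _ou_series(rng, n, dt, 1.0, cfg.radial_jitter_sd_m)
    dz = _ou_series(rng, n, dt, 0.5, cfg.vertical_jitter_sd_m)
    pos = np.empty((n, 3))
    pos[:, 0] = centre[0] + (radius + dr) * np.cos(theta)
    pos[:, 1] = centre[1] + (radius + dr) * np.sin(theta)
    pos[:, 2] = centre[2] + dz

    if erraticity > 0:
        # OU velocity perturbation with heavy-tailed kicks, all three axes
        sd = erraticity * cfg.erratic_speed_sd_ms
        vel = np.column_stack(
            [_ou_series(rng, n, dt, cfg.erratic_tau_s, sd) for _ in range(3)]
        )
        kicks = rng.random((n, 3)) < cfg.heavy_tail_prob
        vel = np.where(kicks, vel * cfg.heavy_tail_scale, vel)
        pos += np.cumsum(vel * dt, axis=0)

    if wind_ms:
        pos[:, 0] += wind_ms * t
    pos += rng.normal(0.0, cfg.measurement_noise_m, size=pos.shape)
    return pos, t


def _make_trial(
    rng: np.random.Generator,
    cfg: SimConfig,
    trial_id: str,
    label: str,
    params: ClassParams,
    velocity_multiplier: float = 1.0,
    wind_ms: float = 0.0,
) -> Trial:
    centre = np.array(
        [rng.normal(0, 0.5), rng.normal(0, 0.5), cfg.swarm_height_m + rng.normal(0, 0.2)]
    )
    tracks = []
    for i in range(params.tracks_per_trial):
        duration = max(
            rng.normal(params.duration_mean_s, params.duration_sd_s),
            params.duration_min_s,
        )
        pos, t = _simulate_track(
            rng, cfg, duration, params.erraticity, centre, velocity_multiplier, wind_ms
        )
        tracks.append(
            Track(
                track_id=f"{trial_id}_t{i:03d}",
                trial_id=trial_id,
                label=label,
                positions=pos,
                times=t,
            )
        )
    return Trial(trial_id, tracks)


def simulate(config: SimConfig | None = None) -> Dataset:
    """Generate a labelled multi-trial dataset; deterministic given the seed."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    trials: list[Trial] = []
    for k in range(cfg.male.n_trials):
        trials.append(_make_trial(rng, cfg, f"m{k:02d}", "male", cfg.male))
    for k in range(cfg.couple.n_trials):
        trials.append(_make_trial(rng, cfg, f"c{k:02d}", "couple", cfg.couple))
    for k in range(cfg.female.n_trials):
        trials.append(_make_trial(rng, cfg, f"f{k:02d}", "female", cfg.female))
    for k in range(cfg.focal_male.n_trials):
        trials.append(
            _make_trial(rng, cfg, f"fm{k:02d}", "focal_male", cfg.focal_male)
        )
    for k in range(cfg.n_anomalous_male_trials):
        trials.append(
            _make_trial(
                rng,
                cfg,
                f"w{k:02d}",
                "male",
                cfg.male,
                velocity_multiplier=cfg.anomalous_velocity_multiplier,
                wind_ms=2.0,
            )
        )
    return Dataset(trials)


def shuffle_labels(dataset: Dataset, seed: int) -> Dataset:
    """Permute class labels across tracks (null control for the pipeline)."""
    rng = np.random.default_rng(seed)
    tracks = list(dataset)
    labels = [t.label for t in tracks]
    perm = rng.permutation(len(labels))
    trials: dict[str, Trial] = {}
    for track, j in zip(tracks, perm):
        shuffled = Track(
            track_id=track.track_id,
            trial_id=track.trial_id,
            label=labels[j],
            positions=track.positions.copy(),
            times=track.times.copy(),
        )
        trials.setdefault(track.trial_id, Trial(track.trial_id)).tracks.append(shuffled)
    return Dataset([trials[k] for k in sorted(trials)])
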