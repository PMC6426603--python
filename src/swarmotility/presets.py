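"""Condition presets shared by the simulator and the analysis pipeline.

Each preset bundles the generative parameters for one growth/assay
condition.  The calibration table maps the three experimental conditions
(growth in liquid broth, cells lifted from the edge of a swarm colony on
0.5% agar, and cells grown on hard 1.5% agar which does not support
swarming) onto motility, motor, protein-decay, and fluorescence-scene
parameters.  Hard-agar cells behave like liquid-grown cells: the swarm
response requires swarmable agar.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "MotilityPreset",
    "MotorPreset",
    "DecayPreset",
    "FluorScenePreset",
    "CONDITIONS",
    "make_preset",
    "make_motor_preset",
    "make_decay_preset",
    "make_fluor_preset",
]


@dataclass(frozen=True)
class MotilityPreset:
    """Generative parameters for pseudo-2D run-and-tumble swimming.

    Parameters
    ----------
    run_speed : float
        Asymptotic swimming speed during runs, μm/s.
    tumble_bias_true : float
        Fraction of time spent tumbling, in [0, 1].
    mean_tumble_duration : float
        Mean duration of a tumble, s.  The mean run duration follows as
        ``mean_tumble_duration * (1 - TB) / TB``.
    rotational_diffusion : float
        Rotational diffusion coefficient of the heading during runs,
        rad²/s.
    speed_recovery_tau : float
        Exponential time constant of speed recovery after a tumble, s.
        The default 0.17 s gives ~95% recovery by 0.5 s.
    nonmotile_fraction : float
        Fraction of cells that are non-motile (Brownian only).
    brownian_D : float
        Translational diffusion coefficient of non-motile cells, μm²/s.
    localization_sigma : float
        Isotropic localization noise added to reported positions, μm.
    """

    run_speed: float = 21.0
    tumble_bias_true: float = 0.12
    mean_tumble_duration: float = 0.2
    rotational_diffusion: float = 0.06
    speed_recovery_tau: float = 0.17
    nonmotile_fraction: float = 0.0
    brownian_D: float = 0.4
    localization_sigma: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumble_bias_true <= 1.0:
            raise ValueError(
                f"tumble_bias_true must be in [0, 1], got {self.tumble_bias_true}"
            )
        if self.run_speed < 0:
            raise ValueError(f"run_speed must be >= 0, got {self.run_speed}")
        if not 0.0 <= self.nonmotile_fraction <= 1.0:
            raise ValueError("nonmotile_fraction must be in [0, 1]")
        if self.tumble_bias_true > 0 and self.mean_tumble_duration <= 0:
            raise ValueError("mean_tumble_duration must be > 0 when cells tumble")

    @property
    def mean_run_duration(self) -> float:
        """Mean run duration implied by the tumble bias, s (inf if TB=0)."""
        if self.tumble_bias_true == 0:
            return float("inf")
        return (
            self.mean_tumble_duration
            * (1.0 - self.tumble_bias_true)
            / self.tumble_bias_true
        )


@dataclass(frozen=True)
class MotorPreset:
    """Generative parameters for a two-state CW/CCW flagellar-motor trace.

    The motor is a telegraph process between counter-clockwise (CCW, the
    run-promoting direction) and clockwise (CW) rotation.  Switching rates
    are set so that the expected number of direction changes per minute is
    ``reversal_rate`` and the stationary fraction of time spent CW is
    ``cw_bias``:  k(CCW→CW) = R/(2(1−b)), k(CW→CCW) = R/(2b).
    """

    ccw_frequency: float = 68.0  # Hz
    cw_frequency: float = 68.0  # Hz
    reversal_rate: float = 38.0  # reversals per minute
    cw_bias: float = 0.12
    orbit_radius: float = 0.2  # μm, eccentricity of the bead orbit
    center_jitter_sigma: float = 0.02  # μm
    fps: float = 1250.0

    def __post_init__(self) -> None:
        if self.ccw_frequency <= 0 or self.cw_frequency <= 0:
            raise ValueError("rotation frequencies must be > 0")
        if not 0.0 <= self.cw_bias <= 1.0:
            raise ValueError(f"cw_bias must be in [0, 1], got {self.cw_bias}")
        if self.reversal_rate < 0:
            raise ValueError("reversal_rate must be >= 0")
        if self.reversal_rate > 0 and not 0.0 < self.cw_bias < 1.0:
            raise ValueError(
                "a switching motor (reversal_rate > 0) requires cw_bias in (0, 1); "
                f"got reversal_rate={self.reversal_rate}, cw_bias={self.cw_bias}"
            )

    @property
    def switching_rates(self) -> tuple[float, float]:
        """(k_ccw_to_cw, k_cw_to_ccw) in 1/s; (0, 0) for a non-switching motor."""
        if self.reversal_rate == 0:
            return 0.0, 0.0
        rate_per_s = self.reversal_rate / 60.0
        return (
            rate_per_s / (2.0 * (1.0 - self.cw_bias)),
            rate_per_s / (2.0 * self.cw_bias),
        )


@dataclass(frozen=True)
class DecayPreset:
    """First-order protein-decay time course with multiplicative noise."""

    initial_intensity: float = 1000.0
    decay_rate: float = 2.7e-3  # min^-1
    lognormal_sigma: float = 0.1
    sample_times: Sequence[float] = (0.0, 60.0, 120.0, 180.0, 240.0, 300.0, 360.0)

    def __post_init__(self) -> None:
        if self.decay_rate < 0:
            raise ValueError("decay_rate must be >= 0")
        if self.initial_intensity <= 0:
            raise ValueError("initial_intensity must be > 0")
        times = tuple(float(t) for t in self.sample_times)
        if len(times) == 0:
            raise ValueError("sample_times must be nonempty")
        if any(t < 0 for t in times):
            raise ValueError("sample_times must be nonnegative")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sample_times must be strictly increasing")
        object.__setattr__(self, "sample_times", times)


@dataclass(frozen=True)
class FluorScenePreset:
    """Two-channel fluorescence scene with per-cell expression variability."""

    n_cells: int = 50
    mean_area: float = 120.0  # px
    area_sd: float = 15.0  # px
    yfp_mean: float = 20000.0  # total a.u. per cell
    cherry_mean: float = 20000.0
    expression_cv: float = 0.25
    background_level: float = 100.0  # a.u. per px
    autofluorescence: float = 500.0  # total a.u. per cell

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("yfp_mean", "cherry_mean", "background_level", "autofluorescence"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.expression_cv < 0:
            raise ValueError("expression_cv must be >= 0")


# Calibration table: published condition-level values used as generator
# parameters.  Hard agar reuses the liquid behavioral parameters (hard agar
# abolishes the swarm response).
_MOTILITY_TABLE: dict[str, dict] = {
    "liquid": dict(run_speed=21.0, tumble_bias_true=0.12),
    "swarm": dict(run_speed=25.0, tumble_bias_true=0.04),
    "hard": dict(run_speed=21.0, tumble_bias_true=0.12),
}

_MOTOR_TABLE: dict[str, dict] = {
    "liquid": dict(ccw_frequency=68.0, cw_frequency=68.0, reversal_rate=38.0, cw_bias=0.12),
    "swarm": dict(ccw_frequency=78.0, cw_frequency=78.0, reversal_rate=9.0, cw_bias=0.03),
    "hard": dict(ccw_frequency=68.0, cw_frequency=68.0, reversal_rate=38.0, cw_bias=0.12),
}

_DECAY_TABLE: dict[str, dict] = {
    "liquid": dict(decay_rate=2.7e-3),
    "swarm": dict(decay_rate=1.5e-4),
    "hard": dict(decay_rate=2.7e-3),
}

# Swarmers raise CheZ ~1.5x relative to CheY; liquid ratio defined as 1.
_FLUOR_TABLE: dict[str, dict] = {
    "liquid": dict(yfp_mean=20000.0, cherry_mean=20000.0),
    "swarm": dict(yfp_mean=24000.0, cherry_mean=30000.0),
    "hard": dict(yfp_mean=20000.0, cherry_mean=20000.0),
}

CONDITIONS = ("liquid", "swarm", "hard")

# Relative CheZ level in swarmers vs liquid (western-blot calibration).
CHEZ_LEVEL_RATIO_SWARM = 1.5


def _lookup(table: dict[str, dict], condition: str) -> dict:
    key = condition.lower()
    if key not in table:
        raise ValueError(
            f"unknown condition {condition!r}; valid labels: {sorted(table)}"
        )
    return dict(table[key])


def make_preset(condition: str = "liquid", **overrides) -> MotilityPreset:
    """Build a :class:`MotilityPreset` for a named condition.

    Parameters
    ----------
    condition : {'liquid', 'swarm', 'hard'}
        Condition label.  Keyword overrides replace individual fields.
    """
    params = _lookup(_MOTILITY_TABLE, condition)
    params.update(overrides)
    return MotilityPreset(**params)


def make_motor_preset(condition: str = "liquid", **overrides) -> MotorPreset:
    """Build a :class:`MotorPreset` for a named condition."""
    params = _lookup(_MOTOR_TABLE, condition)
    params.update(overrides)
    return MotorPreset(**params)


def make_decay_preset(condition: str = "liquid", **overrides) -> DecayPreset:
    """Build a :class:`DecayPreset` for a named condition."""
    params = _lookup(_DECAY_TABLE, condition)
    params.update(overrides)
    return DecayPreset(**params)


def make_fluor_preset(condition: str = "liquid", **overrides) -> FluorScenePreset:
    """Build a :class:`FluorScenePreset` for a named condition."""
    params = _lookup(_FLUOR_TABLE, condition)
    params.update(overrides)
    return FluorScenePreset(**params)


def preset_to_json(preset) -> str:
    """Serialize any preset dataclass to a JSON string."""
    d = dataclasses.asdict(preset)
    d["__preset__"] = type(preset).__name__
    return json.dumps(d, indent=2, sort_keys=True)


def preset_from_json(text: str):
    """Inverse of :func:`preset_to_json`."""
    d = json.loads(text)
    name = d.pop("__preset__")
    cls = {
        "MotilityPreset": MotilityPreset,
        "MotorPreset": MotorPreset,
        "DecayPreset": DecayPreset,
        "FluorScenePreset": FluorScenePreset,
    }[name]
    if "sample_times" in d and isinstance(d["sample_times"], list):
        d["sample_times"] = tuple(d["sample_times"])
    return cls(**d)
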