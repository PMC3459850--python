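"""Model parameters, configuration loading, and the seeded random-number contract.

All lengths are in micrometres, times in minutes, angles in radians.  The
parameter record collects every symbol of the rod-agent rippling model:

* cell geometry (length ``L``, width ``w``),
* motility (mean speed ``v``, positional diffusion ``D``),
* the internal reversal phase clock (native inter-reversal period ``T``,
  phase diffusion ``D_phi``),
* refractory gating (mean refractory time ``T0``, derived phase sector
  ``phi0``),
* side-to-side contact signaling (probability ``p0``, antiparallel angular
  tolerance ``dtheta0``, minimal long-axis overlap fraction ``overlap_frac``),
* local nematic alignment (correlation time ``tau_theta``, orientation noise
  ``D_theta``, square neighborhood side ``neighbor_box``),
* discretisation and domain (``dt``, ``domain_x``, ``domain_y``, boundary
  condition, population size, seed).

Default values are reconstructions from the published description of the
model (cell length 7 µm, speed 6 µm/min, native period 8 min, refractory
2.7 min, signaling probability 0.10 on prey / 0.03 off prey, 15° angular
tolerance, 50% minimal overlap, 500×100 µm domain); the population size
default corresponds to the near-confluent packing at which side-to-side
contacts are frequent enough for ripples (area coverage n·L·w/A ≈ 0.84).
Every default can be overridden through a YAML/JSON config file.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

__all__ = [
    "ModelParams",
    "ConfigError",
    "RandomSource",
    "load_config",
    "save_config",
    "BOUNDARIES",
    "SIGNALING_RULES",
    "REVERSAL_CONVENTIONS",
]

BOUNDARIES = ("periodic", "open-x")
SIGNALING_RULES = (
    "counter_asymmetric",  # only counter-moving pairs; directions independent
    "counter_symmetric",   # only counter-moving pairs; one event reverses both
    "any_direction",       # co- and counter-moving pairs signal alike
    "same_direction",      # only co-moving pairs signal
)
REVERSAL_CONVENTIONS = ("half_cycle_interval", "full_cycle")


class ConfigError(ValueError):
    """Invalid or inconsistent model configuration; message names the field."""


@dataclass(frozen=True)
class ModelParams:
    # geometry
    L: float = 7.0
    w: float = 0.5
    # motility
    v: float = 6.0
    D: float = 0.3
    # reversal clock
    T: float = 8.0
    D_phi: float = 0.014
    T0: float = 2.7
    # signaling
    p0: float = 0.10
    dtheta0: float = math.radians(15.0)
    overlap_frac: float = 0.5
    # alignment
    tau_theta: float = 0.5
    D_theta: float = 0.01
    neighbor_box: float = 7.0
    # discretisation / domain
    dt: float = 0.1
    domain_x: float = 500.0
    domain_y: float = 100.0
    boundary: str = "periodic"
    n_agents: int = 12000
    seed: int = 0
    # conventions and switches
    reversal_convention: str = "half_cycle_interval"
    signaling_rule: str = "counter_asymmetric"
    rate_normalized_p0: bool = False
    p0_reference_dt: float = 0.1
    init_angle_spread: float = 0.15

    def __post_init__(self) -> None:
        self.validate()

    # ---- derived clock quantities -------------------------------------
    @property
    def omega(self) -> float:
        """Mean phase speed (rad/min).

        Orientation flips at every half-cycle crossing (π and 2π), so under
        the default ``half_cycle_interval`` convention the configured native
        reversal period ``T`` is the inter-reversal interval and the full
        clock cycle lasts 2·T, giving ω = π/T.  Under ``full_cycle`` the
        clock period itself is ``T`` (ω = 2π/T) and the inter-reversal
        interval is T/2.
        """
        if self.reversal_convention == "half_cycle_interval":
            return math.pi / self.T
        return 2.0 * math.pi / self.T

    @property
    def clock_period(self) -> float:
        """Duration of one full 2π phase cycle (min)."""
        return 2.0 * math.pi / self.omega

    @property
    def phi0(self) -> float:
        """Refractory phase sector, φ0 = ω·T0 (rad)."""
        return self.omega * self.T0

    @property
    def step_p0(self) -> float:
        """Per-ordered-pair, per-step signaling probability actually applied.

        ``p0`` is defined per time step at the reference dt (0.1 min).  With
        ``rate_normalized_p0`` the probability is rescaled so the signaling
        *rate* is invariant under changes of dt:
        p_eff = 1 − (1 − p0)^(dt/dt_ref).
        """
        if not self.rate_normalized_p0:
            return self.p0
        return 1.0 - (1.0 - self.p0) ** (self.dt / self.p0_reference_dt)

    # ---- validation ----------------------------------------------------
    def validate(self) -> None:
        def req(cond: bool, msg: str) -> None:
            if not cond:
                raise ConfigError(msg)

        for name in ("L", "w", "v", "D", "T", "D_phi", "T0", "p0", "dtheta0",
                     "overlap_frac", "tau_theta", "D_theta", "neighbor_box",
                     "dt", "domain_x", "domain_y", "p0_reference_dt",
                     "init_angle_spread"):
            val = getattr(self, name)
            req(isinstance(val, (int, float)) and math.isfinite(float(val)),
                f"{name}: must be a finite number, got {val!r}")
        req(isinstance(self.n_agents, (int, np.integer)),
            f"n_agents: must be an integer, got {self.n_agents!r}")
        req(isinstance(self.seed, (int, np.integer)),
            f"seed: must be an integer, got {self.seed!r}")

        req(self.L > 0, f"L: cell length must be > 0, got {self.L}")
        req(self.w > 0, f"w: cell width must be > 0, got {self.w}")
        req(self.w < self.L, f"w: cell width must be < length L, got w={self.w}, L={self.L}")
        req(self.v >= 0, f"v: speed must be >= 0, got {self.v}")
        req(self.T > 0, f"T: native reversal period must be > 0, got {self.T}")
        req(self.T0 > 0, f"T0: refractory time must be > 0, got {self.T0}")
        req(self.dt > 0, f"dt: time step must be > 0, got {self.dt}")
        req(self.dt < self.T0 / 5.0,
            f"dt: time step must resolve the refractory clock (dt < T0/5 = "
            f"{self.T0 / 5.0:g}), got {self.dt}")
        req(0.0 <= self.p0 <= 1.0, f"p0: probability must be in [0, 1], got {self.p0}")
        req(0.0 < self.overlap_frac <= 1.0,
            f"overlap_frac: must be in (0, 1], got {self.overlap_frac}")
        req(0.0 < self.dtheta0 < math.pi / 2,
            f"dtheta0: angular tolerance must be in (0, pi/2), got {self.dtheta0}")
        for name in ("D", "D_phi", "D_theta"):
            req(getattr(self, name) >= 0, f"{name}: noise coefficient must be >= 0")
        req(self.tau_theta > 0, f"tau_theta: must be > 0, got {self.tau_theta}")
        req(self.neighbor_box > 0, f"neighbor_box: must be > 0, got {self.neighbor_box}")
        req(self.domain_x >= 4 * self.L,
            f"domain_x: must be >= 4 L = {4 * self.L:g}, got {self.domain_x}")
        req(self.domain_y >= 4 * self.L,
            f"domain_y: must be >= 4 L = {4 * self.L:g}, got {self.domain_y}")
        req(self.n_agents >= 1, f"n_agents: must be >= 1, got {self.n_agents}")
        req(self.boundary in BOUNDARIES,
            f"boundary: must be one of {BOUNDARIES}, got {self.boundary!r}")
        req(self.signaling_rule in SIGNALING_RULES,
            f"signaling_rule: must be one of {SIGNALING_RULES}, got {self.signaling_rule!r}")
        req(self.reversal_convention in REVERSAL_CONVENTIONS,
            f"reversal_convention: must be one of {REVERSAL_CONVENTIONS}, "
            f"got {self.reversal_convention!r}")
        req(self.init_angle_spread >= 0, "init_angle_spread: must be >= 0")

    # ---- (de)serialisation ---------------------------------------------
    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_agents"] = int(d["n_agents"])
        d["seed"] = int(d["seed"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        clean = {}
        for key, val in data.items():
            if key in ("boundary", "signaling_rule", "reversal_convention"):
                if not isinstance(val, str):
                    raise ConfigError(f"{key}: must be a string, got {val!r}")
                clean[key] = val
            elif key == "rate_normalized_p0":
                if not isinstance(val, bool):
                    raise ConfigError(f"{key}: must be a boolean, got {val!r}")
                clean[key] = val
            elif key in ("n_agents", "seed"):
                if isinstance(val, bool) or not isinstance(val, (int, np.integer)):
                    raise ConfigError(f"{key}: must be an integer, got {val!r}")
                clean[key] = int(val)
            else:
                if isinstance(val, bool) or not isinstance(val, (int, float, np.floating, np.integer)):
                    raise ConfigError(f"{key}: must be numeric, got {val!r}")
                clean[key] = float(val)
        return cls(**clean)


def load_config(path: str | Path) -> ModelParams:
    """Load and validate a model configuration from YAML or JSON.

    Flat keys match :class:`ModelParams` field names; missing keys fall back
    to the documented defaults.  The derived quantities ``omega`` and ``phi0``
    are computed from ``T`` and ``T0`` and are not configurable directly.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    text = path.read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse configuration file {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(data).__name__}")
    return ModelParams.from_dict(data)


def save_config(params: ModelParams, path: str | Path) -> None:
    """Write a configuration file (YAML or, for ``.json`` paths, JSON)."""
    path = Path(path)
    d = params.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


class RandomSource:
    """Seeded random stream: same seed + same call sequence ⇒ same numbers.

    Thin wrapper over :class:`numpy.random.Generator` (PCG64).  Child streams
    produced by :meth:`spawn` are independent and reproducible.
    """

    def __init__(self, seed: int | np.random.SeedSequence):
        if isinstance(seed, np.random.SeedSequence):
            self.seed_sequence = seed
            self.seed = int(seed.entropy) if isinstance(seed.entropy, int) else -1
        else:
            self.seed = int(seed)
            self.seed_sequence = np.random.SeedSequence(self.seed)
        self.generator = np.random.Generator(np.random.PCG64(self.seed_sequence))

    def uniform(self, a: float = 0.0, b: float = 1.0, size=None):
        """U(a, b) deviates."""
        return self.generator.uniform(a, b, size=size)

    def normal(self, size=None, scale: float = 1.0):
        """Standard normal deviates, optionally scaled."""
        return self.generator.normal(0.0, scale, size=size)

    def integers(self, low: int, high: int, size=None):
        return self.generator.integers(low, high, size=size)

    def choice(self, a, size=None, replace=True):
        return self.generator.choice(a, size=size, replace=replace)

    def spawn(self, n: int) -> list["RandomSource"]:
        """Derive ``n`` independent child streams."""
        return [RandomSource(ss) for ss in self.seed_sequence.spawn(n)]
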