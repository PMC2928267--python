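"""Configuration objects: lattice/chain setup, looping parameters, run plans.

All configuration round-trips losslessly through plain dictionaries (and
hence YAML), and every production output embeds the resolved
configuration together with the seed that produced it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import numpy as np

#: squared co-localization radius: "distance less than 3 lattice units"
#: on an integer lattice means squared distance <= 8 (strict inequality).
COLOCALIZATION_RADIUS = 3.0
COLOCALIZATION_R2 = 8

#: contacts between beads closer than min_contour_separation along the
#: chain are trivial (bonded / next-nearest) and are excluded everywhere.
MIN_CONTOUR_SEPARATION = 3


@dataclass
class LoopParams:
    """Parameters of the diffusion-driven looping mechanism.

    P is the probability that a co-localized pair actually forms a loop
    when probed; mean_lifetime is the mean of the Poisson lifetime
    distribution in MCS.  Lifetimes are conventionally chosen as a
    multiplier of the relaxation time (integrated autocorrelation time
    of Rg^2) of the corresponding self-avoiding-walk system.
    """

    P: float = 0.0
    mean_lifetime: float = 0.0
    colocalization_radius: float = COLOCALIZATION_RADIUS
    min_contour_separation: int = MIN_CONTOUR_SEPARATION
    lifetime_multipliers: tuple[float, ...] = (0.1, 1.0, 10.0)

    def __post_init__(self):
        if not 0.0 <= self.P <= 1.0:
            raise ValueError(f"looping probability P must be in [0, 1], got {self.P}")
        if self.mean_lifetime < 0:
            raise ValueError("mean_lifetime must be >= 0")
        if self.colocalization_radius <= 0:
            raise ValueError("colocalization_radius must be positive")

    @property
    def radius_sq(self) -> int:
        """Largest integer squared distance strictly below the radius."""
        r2 = self.colocalization_radius**2
        r2i = int(np.floor(r2))
        if r2i == r2:  # strict inequality on the Euclidean distance
            r2i -= 1
        return r2i


@dataclass
class SystemConfig:
    """A single dilute chain on a periodic lattice."""

    N: int = 128
    L: tuple[int, int, int] = (128, 128, 128)
    periodic: bool = True
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.L, int):
            self.L = (self.L, self.L, self.L)
        self.L = tuple(int(x) for x in self.L)
        if self.N < 2:
            raise ValueError("chain length N must be >= 2")

    @property
    def chain_lengths(self) -> list[int]:
        return [self.N]

    @property
    def density(self) -> float:
        """Fraction of lattice sites covered by monomer cubes."""
        return 8.0 * self.N / float(np.prod(self.L))


@dataclass
class MeltConfig:
    """A dense multi-chain system (model nucleus)."""

    n_chains: int = 32
    N: int = 128
    box: tuple[int, int, int] = (64, 64, 64)
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.box, int):
            self.box = (self.box, self.box, self.box)
        self.box = tuple(int(x) for x in self.box)
        if self.density >= 0.6:
            raise ValueError(
                f"site occupancy {self.density:.3f} >= 0.6 is not feasible "
                "for the bond-fluctuation model"
            )

    @property
    def total_monomers(self) -> int:
        return self.n_chains * self.N

    @property
    def chain_lengths(self) -> list[int]:
        return [self.N] * self.n_chains

    @property
    def density(self) -> float:
        return 8.0 * self.total_monomers / float(np.prod(self.box))


@dataclass
class SamplingConfig:
    """Equilibration / decorrelation constants.

    sokal_c is the window constant of the Sokal windowing procedure;
    tau_multiplier k sets the sample spacing max(k*tau_int, t_cm);
    burn-in lasts burnin_multiplier*tau_int before the first sample.
    """

    sokal_c: float = 6.0
    tau_multiplier: float = 2.0
    burnin_multiplier: float = 10.0
    n_samples: int = 100
    #: explicit sampling interval (MCS); skips the pilot when set
    interval: int | None = None


@dataclass
class ObservablesConfig:
    """Analysis windows and physical calibration constants."""

    contact_radius: float = COLOCALIZATION_RADIUS
    min_contour_separation: int = MIN_CONTOUR_SEPARATION
    # power-law fit windows as fractions of the chain length
    hl_fit_window: tuple[float, float] = (0.05, 0.5)
    pc_short_window: tuple[float, float] = (None, 0.15)  # lower bound 4 beads
    pc_short_min_s: int = 4
    pc_long_window: tuple[float, float] = (0.15, 0.9)
    log_bins_above: int = 16
    kb_per_bead: float = 400.0
    nm_per_bead: float = 480.0


@dataclass
class RunConfig:
    """Complete, serializable description of one production run."""

    engine: SystemConfig | MeltConfig = field(default_factory=SystemConfig)
    looping: LoopParams = field(default_factory=LoopParams)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    observables: ObservablesConfig = field(default_factory=ObservablesConfig)
    seed: int = 0
    out: str = "run"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["engine"]["kind"] = "melt" if isinstance(self.engine, MeltConfig) else "chain"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        eng = dict(d.get("engine", {}))
        kind = eng.pop("kind", "chain")
        engine = (MeltConfig if kind == "melt" else SystemConfig)(**_coerce(eng))
        looping = LoopParams(**_coerce(d.get("looping", {})))
        sampling = SamplingConfig(**d.get("sampling", {}))
        observables = ObservablesConfig(**_coerce(d.get("observables", {})))
        return cls(
            engine=engine,
            looping=looping,
            sampling=sampling,
            observables=observables,
            seed=int(d.get("seed", 0)),
            out=str(d.get("out", "run")),
        )


def _coerce(d: dict) -> dict:
    """YAML gives lists where dataclasses expect tuples."""
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def load_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: RunConfig, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def config_fields(cls) -> list[str]:
    return [f.name for f in fields(cls)]
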