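"""Run configuration: every tunable of the pipeline in one validated record."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class BNConfig:
    """Knobs of the Bayesian-network stage."""

    R: int = 500                     # bootstrap replicates per model
    top_fraction: float = 1.0 / 3.0  # fraction of networks averaged
    strength_threshold: float = 0.5  # minimum consensus arc strength
    iss: float = 1.0                 # imaginary sample size of the BDeu prior
    levels: int = 3                  # discretization levels
    ibreaks: int = 20                # initial quantile bins for Hartemink
    tol: float = 1e-8                # minimum hill-climb improvement
    restarts: int = 0                # random restarts per hill climb
    n_particles: int = 500           # likelihood-weighting particles

    def validate(self) -> None:
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if not 0 <= self.strength_threshold <= 1:
            raise ValueError("strength_threshold must be in [0, 1]")
        if self.iss <= 0:
            raise ValueError("iss must be positive")
        if self.levels < 2 or self.ibreaks < self.levels:
            raise ValueError("need ibreaks >= levels >= 2")


@dataclass
class RunConfig:
    """Full pipeline configuration with the package defaults."""

    fraction: float = 1.0 / 3.0      # top fraction of probes kept
    test: str = "moderated"          # differential test: moderated | welch
    adjust: str = "bh"               # p-value adjustment
    network_class: int = 1           # class used to build the network
    powers: tuple[int, ...] = tuple(range(1, 21))
    rsq_cut: float = 0.85
    n_bins: int = 10
    fallback_beta: int = 6           # power used when the scale-free scan fails
    min_module_size: int = 20
    cut_height: float = 0.99
    merge_cut: float = 0.15
    f_ref: int = 9                   # oversampling factor of the largest class
    k: int = 5                       # ensemble size / CV folds
    seed: int = 0
    bn: BNConfig = field(default_factory=BNConfig)

    def validate(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if self.k != 1 and self.k % 2 == 0:
            raise ValueError("k must be odd")
        if self.f_ref < 1:
            raise ValueError("f_ref must be >= 1")
        self.bn.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["powers"] = list(self.powers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        bn = BNConfig(**d.pop("bn", {}))
        if "powers" in d:
            d["powers"] = tuple(int(p) for p in d["powers"])
        cfg = cls(bn=bn, **d)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))
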