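"""Simulation parameter configuration.

All constants of the generative model live in :class:`SimulationParams`:
library composition (essential / null genes, guides per gene, negative
controls), the essential-gene effect-size distribution (a truncated
normal on the log2 fold-change scale), the per-guide effect variance,
the Bernoulli guide binding efficiency, the mean sequencing depth, the
number of biological replicates per arm, and the RNG seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

__all__ = ["SimulationParams", "InvalidParameterError"]


class InvalidParameterError(ValueError):
    """Raised when a simulation parameter violates its constraints."""


@dataclass(frozen=True)
class SimulationParams:
    """Configuration of one simulated pooled CRISPR essentiality screen.

    Parameters
    ----------
    n_essential
        Number of true-positive (essential) genes.
    n_null
        Number of non-essential genes (gene effect exactly 0).
    guides_per_gene
        Guides targeting each gene.
    n_controls
        Number of negative-control guides (no gene label).
    effect_mean, effect_variance, effect_upper_bound
        Location, variance and upper truncation bound of the parent
        normal from which baseline essential-gene effects are drawn
        (log2 fold-change units; the bound keeps all effects negative).
    effect_multiplier
        Scalar in [0, 1] applied to baseline gene effects to emulate
        lower-signal screens (scales location, spread and bound alike).
    guide_effect_variance
        Variance of individual guide effects around their gene effect.
    guide_efficiency
        Probability in (0, 1] that a guide binds and exerts its effect;
        non-binding guides behave like null guides.
    depth
        Mean sequencing reads per guide per sample.
    n_replicates
        Biological replicates per arm (initial and treated).
    seed
        Root RNG seed; all randomness derives from it.
    """

    n_essential: int = 600
    n_null: int = 18000
    guides_per_gene: int = 5
    n_controls: int = 500
    effect_mean: float = -1.2
    effect_variance: float = 5.0
    effect_upper_bound: float = -0.7
    effect_multiplier: float = 0.8
    guide_effect_variance: float = 0.1
    guide_efficiency: float = 1.0
    depth: float = 100.0
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_essential < 0 or self.n_null < 0 or self.n_controls < 0:
            raise InvalidParameterError("gene and control counts must be >= 0")
        if self.guides_per_gene <= 0:
            raise InvalidParameterError("guides_per_gene must be a positive integer")
        if self.effect_variance <= 0:
            raise InvalidParameterError("effect_variance must be > 0")
        if self.effect_upper_bound >= 0:
            raise InvalidParameterError("effect_upper_bound must be < 0")
        if not 0.0 <= self.effect_multiplier:
            raise InvalidParameterError("effect_multiplier must be >= 0")
        if not 0.0 < self.guide_efficiency <= 1.0:
            raise InvalidParameterError("guide_efficiency must be in (0, 1]")
        if self.guide_effect_variance <= 0:
            raise InvalidParameterError("guide_effect_variance must be > 0")
        if self.depth < 0:
            raise InvalidParameterError("depth must be >= 0")
        if self.n_replicates <= 0:
            raise InvalidParameterError("n_replicates must be a positive integer")

    # -- derived quantities -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.n_essential + self.n_null

    @property
    def n_guides(self) -> int:
        return self.n_genes * self.guides_per_gene + self.n_controls

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(
                f"unknown parameter(s): {sorted(unknown)}; valid fields are {sorted(known)}"
            )
        return cls(**d)

    def replace(self, **changes: Any) -> "SimulationParams":
        return dataclasses.replace(self, **changes)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationParams":
        """Load parameters from a YAML or JSON config file."""
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))
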