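"""Generative model for pooled CRISPR essentiality screen counts.

The model, stage by stage:

1. *Gene effects.* Null genes have effect exactly 0. Essential-gene
   baseline effects are drawn from a normal with mean ``effect_mean``
   and variance ``effect_variance``, truncated above at
   ``effect_upper_bound`` (all on the log2 fold-change scale), then
   scaled by ``effect_multiplier``. The truncation yields the long
   negative tail typical of essentiality screens while excluding
   weak-effect genes from the positive class.
2. *Guide effects.* Each targeting guide binds with probability
   ``guide_efficiency`` (i.i.d. Bernoulli). A binding guide draws its
   effect from Normal(gene effect, ``guide_effect_variance``); a
   non-binding guide — and every negative control — draws from the
   null distribution Normal(0, ``guide_effect_variance``).
3. *Abundance.* Each guide gets a latent relative abundance
   ~ Gamma(shape 1, scale 1) (mean 1). This vector is shared by every
   sample of the screen: it is guide-specific technical variation
   (cloning / library representation), constant across arms and
   replicates.
4. *Counts.* Initial-arm counts are Poisson(abundance x depth x eps)
   with eps ~ Gamma(1, 1) drawn independently per guide x sample; the
   gamma mixing overdisperses the counts relative to pure Poisson.
   Treated-arm abundance is abundance x 2**(guide effect), renormalized
   to mean 1, then counts are drawn the same way.

Randomness is organised as one root seed spawning independent child
streams per stage (effects, binding masks, abundance, one per count
sample), so e.g. changing ``n_replicates`` does not perturb the drawn
effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .library import GuideLibrary, build_library
from .params import InvalidParameterError, SimulationParams

__all__ = [
    "EffectProfile",
    "SimulatedScreen",
    "sample_gene_effects",
    "sample_guide_effects",
    "sample_initial_abundance",
    "compute_treated_abundance",
    "sample_counts",
    "simulate_screen",
]


@dataclass(frozen=True)
class EffectProfile:
    """Latent effects of one simulated screen.

    ``gene_effect`` is indexed by gene id (log2 fold change; 0 for null
    genes), ``guide_effect`` and ``binding_mask`` by guide id. Controls
    carry ``binding_mask`` True by convention — their effect is always a
    null-distribution draw regardless.
    """

    gene_effect: pd.Series
    guide_effect: pd.Series
    binding_mask: pd.Series


@dataclass(frozen=True)
class SimulatedScreen:
    """A simulated screen: counts plus every latent quantity behind them.

    ``counts`` is a guides x samples integer matrix; ``sample_names``
    label its columns as ``<arm>_rep<k>`` with arm in
    {``initial``, ``treated``}. ``abundance`` is the single latent
    abundance vector shared by all samples.
    """

    library: GuideLibrary
    params: SimulationParams
    abundance: np.ndarray
    effects: EffectProfile
    counts: np.ndarray
    sample_names: list[str]
    child_seeds: dict[str, int] = field(default_factory=dict)

    def counts_frame(self) -> pd.DataFrame:
        """Counts as a MAGeCK-style table (sgRNA, gene, one column per sample)."""
        df = pd.DataFrame(self.counts, columns=self.sample_names)
        df.insert(0, "gene", self.library.guides["gene"].to_numpy())
        df.insert(0, "sgRNA", self.library.guides["guide"].to_numpy())
        return df


def sample_gene_effects(
    params: SimulationParams, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-gene effects; essential genes first, then null genes.

    Essential effects are ``s * X`` with ``X`` from the truncated normal
    parent and ``s = effect_multiplier``; null genes get exactly 0.
    """
    if params.effect_multiplier < 0:
        raise InvalidParameterError("effect_multiplier must be >= 0")
    sd = float(np.sqrt(params.effect_variance))
    b = (params.effect_upper_bound - params.effect_mean) / sd
    baseline = stats.truncnorm.rvs(
        -np.inf, b, loc=params.effect_mean, scale=sd,
        size=params.n_essential, random_state=rng,
    )
    effects = np.zeros(params.n_genes)
    effects[: params.n_essential] = params.effect_multiplier * baseline
    return effects


def sample_guide_effects(
    gene_effects: np.ndarray,
    library: GuideLibrary,
    params: SimulationParams,
    rng: np.random.Generator,
) -> EffectProfile:
    """Draw the Bernoulli binding mask and per-guide effects.

    Binding guides draw Normal(gene effect, guide_effect_variance);
    non-binding guides and controls draw Normal(0, same variance).
    """
    if not 0.0 < params.guide_efficiency <= 1.0:
        raise InvalidParameterError("guide_efficiency must be in (0, 1]")
    gene_effect = pd.Series(gene_effects, index=library.genes["gene"].to_numpy())

    is_control = library.control_mask
    n_guides = library.n_guides
    mask = np.ones(n_guides, dtype=bool)
    targeting = ~is_control
    mask[targeting] = rng.random(targeting.sum()) < params.guide_efficiency

    per_guide_mean = np.zeros(n_guides)
    effective = targeting & mask
    gene_of_guide = library.guides["gene"].to_numpy()
    per_guide_mean[effective] = gene_effect.loc[gene_of_guide[effective]].to_numpy()

    sd = float(np.sqrt(params.guide_effect_variance))
    guide_effect = rng.normal(per_guide_mean, sd)

    guide_index = library.guides["guide"].to_numpy()
    return EffectProfile(
        gene_effect=gene_effect,
        guide_effect=pd.Series(guide_effect, index=guide_index),
        binding_mask=pd.Series(mask, index=guide_index),
    )


def sample_initial_abundance(n_guides: int, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. Gamma(shape 1, scale 1) latent abundances (mean 1, strictly > 0)."""
    if n_guides < 0:
        raise InvalidParameterError("n_guides must be >= 0")
    a = rng.gamma(shape=1.0, scale=1.0, size=n_guides)
    # Gamma(1,1) puts no mass at 0 but floating-point draws can hit it.
    return np.maximum(a, np.finfo(float).tiny)


def compute_treated_abundance(
    abundance: np.ndarray, guide_effects: np.ndarray
) -> np.ndarray:
    """Apply guide effects on the linear scale and renormalize to mean 1.

    Raw treated abundance is ``abundance * 2**effect`` (effects are log2
    fold changes), rescaled so the mean is exactly 1.
    """
    abundance = np.asarray(abundance, dtype=float)
    if abundance.size == 0:
        raise ValueError("cannot normalize an empty abundance vector")
    if np.any(abundance <= 0):
        raise ValueError("abundance must be strictly positive")
    raw = abundance * np.exp2(np.asarray(guide_effects, dtype=float))
    return raw / raw.mean()


def sample_counts(
    abundance: np.ndarray, depth: float, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw a guides x samples count matrix from the gamma-mixed Poisson.

    Each entry is Poisson(abundance_i * depth * eps) with
    eps ~ Gamma(1, 1) independent per entry; marginally
    E[count] = abundance_i * depth and the counts are overdispersed.
    """
    if depth < 0:
        raise InvalidParameterError("depth must be >= 0")
    abundance = np.asarray(abundance, dtype=float)
    noise = rng.gamma(shape=1.0, scale=1.0, size=(abundance.size, n_samples))
    lam = abundance[:, None] * depth * noise
    return rng.poisson(lam)


def simulate_screen(params: SimulationParams) -> SimulatedScreen:
    """Run the full generative model for one screen, reproducibly from the seed.

    Composes library construction, gene- and guide-effect sampling, the
    shared latent abundance, and per-replicate count draws for the
    initial and treated arms. Child RNG streams are spawned per stage
    from the root seed.
    """
    library = build_library(params)

    root = np.random.SeedSequence(params.seed)
    ss_effects, ss_guides, ss_abund, ss_counts = root.spawn(4)
    gene_effects = sample_gene_effects(params, np.random.default_rng(ss_effects))
    effects = sample_guide_effects(
        gene_effects, library, params, np.random.default_rng(ss_guides)
    )
    abundance = sample_initial_abundance(
        library.n_guides, np.random.default_rng(ss_abund)
    )
    treated_abundance = compute_treated_abundance(
        abundance, effects.guide_effect.to_numpy()
    )

    r = params.n_replicates
    sample_names = [f"initial_rep{k}" for k in range(1, r + 1)] + [
        f"treated_rep{k}" for k in range(1, r + 1)
    ]
    sample_streams = ss_counts.spawn(2 * r)
    cols = []
    for k in range(r):
        cols.append(
            sample_counts(abundance, params.depth, 1, np.random.default_rng(sample_streams[k]))
        )
    for k in range(r):
        cols.append(
            sample_counts(
                treated_abundance, params.depth, 1, np.random.default_rng(sample_streams[r + k])
            )
        )
    counts = np.hstack(cols)

    child_seeds = {
        "effects": int(ss_effects.generate_state(1)[0]),
        "guides": int(ss_guides.generate_state(1)[0]),
        "abundance": int(ss_abund.generate_state(1)[0]),
        "counts": int(ss_counts.generate_state(1)[0]),
    }
    return SimulatedScreen(
        library=library,
        params=params,
        abundance=abundance,
        effects=effects,
        counts=counts,
        sample_names=sample_names,
        child_seeds=child_seeds,
    )
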