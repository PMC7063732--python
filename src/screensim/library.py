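"""Guide library construction: the guide->gene map with truth labels.

A :class:`GuideLibrary` carries one row per guide (guide id, gene id,
control flag) and one row per gene (gene id, essentiality truth label).
Negative-control guides carry the sentinel gene label ``CONTROL`` and
never contribute to gene-level results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import InvalidParameterError, SimulationParams

__all__ = ["GuideLibrary", "build_library", "CONTROL_GENE"]

#: Sentinel gene label carried by negative-control guides in count tables.
CONTROL_GENE = "CONTROL"


@dataclass(frozen=True)
class GuideLibrary:
    """Guide-to-gene map with control flags and per-gene truth labels.

    Attributes
    ----------
    guides
        DataFrame with columns ``guide`` (unique id), ``gene`` (gene id,
        or ``CONTROL`` for negative controls) and ``is_control`` (bool).
    genes
        DataFrame with columns ``gene`` and ``is_essential`` (bool);
        excludes the control sentinel.
    """

    guides: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        if self.guides["guide"].duplicated().any():
            raise ValueError("guide ids must be unique")
        targeting = self.guides.loc[~self.guides["is_control"], "gene"]
        known = set(self.genes["gene"])
        missing = set(targeting) - known
        if missing:
            raise ValueError(f"guides target genes absent from the gene table: {sorted(missing)[:5]}")
        orphan = known - set(targeting)
        if orphan:
            raise ValueError(f"genes without any guide: {sorted(orphan)[:5]}")

    @property
    def n_guides(self) -> int:
        return len(self.guides)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def control_mask(self) -> np.ndarray:
        return self.guides["is_control"].to_numpy()

    def essential_genes(self) -> pd.Index:
        return pd.Index(self.genes.loc[self.genes["is_essential"], "gene"])

    def truth_labels(self) -> pd.Series:
        """Boolean essentiality labels indexed by gene id."""
        return self.genes.set_index("gene")["is_essential"]


def build_library(params: SimulationParams) -> GuideLibrary:
    """Construct the truth-labeled guide library for a parameter setting.

    The library has ``n_essential + n_null`` genes with
    ``guides_per_gene`` guides each, plus ``n_controls`` negative-control
    guides. Construction is deterministic: essential genes are named
    ``ess_<i>``, null genes ``null_<i>``, guides ``<gene>_g<k>`` and
    controls ``ctrl_<k>``.
    """
    if params.guides_per_gene <= 0:
        raise InvalidParameterError("guides_per_gene must be positive")

    ess = [f"ess_{i:05d}" for i in range(1, params.n_essential + 1)]
    null = [f"null_{i:05d}" for i in range(1, params.n_null + 1)]
    gene_ids = ess + null

    genes = pd.DataFrame(
        {
            "gene": gene_ids,
            "is_essential": np.r_[
                np.ones(params.n_essential, dtype=bool),
                np.zeros(params.n_null, dtype=bool),
            ],
        }
    )

    g = params.guides_per_gene
    gene_rep = np.repeat(gene_ids, g)
    k = np.tile(np.arange(1, g + 1), len(gene_ids))
    guide_ids = [f"{gene}_g{i}" for gene, i in zip(gene_rep, k)]
    ctrl_ids = [f"ctrl_{i:04d}" for i in range(1, params.n_controls + 1)]

    guides = pd.DataFrame(
        {
            "guide": guide_ids + ctrl_ids,
            "gene": list(gene_rep) + [CONTROL_GENE] * params.n_controls,
            "is_control": np.r_[
                np.zeros(len(guide_ids), dtype=bool),
                np.ones(params.n_controls, dtype=bool),
            ],
        }
    )
    return GuideLibrary(guides=guides, genes=genes)
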