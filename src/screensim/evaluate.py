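"""Benchmarking against ground truth: metrics, thinning, parameter sweeps.

Rankings are scored by PR-AUC (average precision; baseline equals
prevalence), ROC-AUC (Mann-Whitney with tie correction), and the
empirical FDR among genes called at an estimated-FDR cutoff (default
0.1). When a method makes no calls at the cutoff the empirical FDR is
*undefined* (NaN / "NA"), never 0 or 1, so aggregation can drop the
point rather than bias it.

Binomial count thinning and per-gene guide subsampling together emulate
the depth-vs-guides design tradeoff at constant total sequencing.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import fields as dataclass_fields

import numpy as np
import pandas as pd
from sklearn import metrics as sk_metrics

from .analyze import analyze_screen
from .library import GuideLibrary
from .params import InvalidParameterError, SimulationParams
from .simulate import simulate_screen

__all__ = [
    "MetricError",
    "precision_recall_auc",
    "roc_auc",
    "empirical_fdr",
    "thin_counts",
    "subsample_guides",
    "sweep_child_seed",
    "run_sweep",
    "aggregate_sweep",
    "evaluate_results",
]

logger = logging.getLogger(__name__)


class MetricError(ValueError):
    """Raised when a metric is undefined for the given labels."""


def _check_labels(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise MetricError("scores and labels must have matching shape")
    return scores, labels


def precision_recall_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average precision of a ranking: step integral of the PR curve.

    Higher scores rank first; tied scores are treated as one block. The
    no-skill baseline equals the label prevalence.
    """
    scores, labels = _check_labels(scores, labels)
    if not labels.any():
        raise MetricError("PR-AUC undefined without positive labels")
    if labels.all():
        raise MetricError("PR-AUC undefined without negative labels")
    return float(sk_metrics.average_precision_score(labels, scores))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC-AUC (Mann-Whitney with tie correction); 0.5 random, 1 perfect."""
    scores, labels = _check_labels(scores, labels)
    if labels.all() or not labels.any():
        raise MetricError("ROC-AUC undefined with single-class labels")
    return float(sk_metrics.roc_auc_score(labels, scores))


def empirical_fdr(
    results: pd.DataFrame, labels: pd.Series, cutoff: float = 0.1
) -> tuple[float, int]:
    """Realized false-discovery fraction at an estimated-FDR cutoff.

    Returns ``(fdr, n_discoveries)`` where ``fdr`` is the fraction of
    genes with ``fdr <= cutoff`` whose truth label is null, or NaN when
    there are no discoveries (the point is undefined, not zero).
    """
    if not 0.0 < cutoff < 1.0:
        raise MetricError("cutoff must lie in (0, 1)")
    called = results.loc[results["fdr"] <= cutoff, "gene"]
    n = len(called)
    if n == 0:
        return float("nan"), 0
    truth = labels.reindex(called)
    if truth.isna().any():
        raise MetricError("truth labels missing for some discovered genes")
    return float((~truth.astype(bool)).mean()), n


def thin_counts(
    counts: np.ndarray, keep_probability: float, rng: np.random.Generator
) -> np.ndarray:
    """Binomially thin a count table: each entry -> Binomial(count, p).

    Emulates reduced sequencing depth; thinning by p then q equals
    thinning once by p*q in distribution.
    """
    if not 0.0 < keep_probability <= 1.0:
        raise InvalidParameterError("keep_probability must be in (0, 1]")
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise InvalidParameterError("counts must be non-negative")
    if keep_probability == 1.0:
        return counts.copy()
    return rng.binomial(counts, keep_probability)


def subsample_guides(
    library: GuideLibrary,
    counts: np.ndarray,
    guides_per_gene_target: int,
    rng: np.random.Generator,
) -> tuple[GuideLibrary, np.ndarray]:
    """Uniformly keep a fixed number of guides per gene (controls kept).

    Genes with fewer guides than the target are dropped with a warning.
    Combined with :func:`thin_counts` at a compensating probability this
    reproduces the constant-total-depth guides-vs-depth tradeoff.
    """
    if guides_per_gene_target <= 0:
        raise InvalidParameterError("guides_per_gene_target must be positive")
    guides = library.guides.reset_index(drop=True)
    keep = np.zeros(len(guides), dtype=bool)
    keep[guides["is_control"].to_numpy()] = True

    dropped = []
    for gene, idx in guides.loc[~guides["is_control"]].groupby("gene").groups.items():
        idx = np.asarray(idx)
        if idx.size < guides_per_gene_target:
            dropped.append(gene)
            continue
        chosen = rng.choice(idx, size=guides_per_gene_target, replace=False)
        keep[chosen] = True
    if dropped:
        logger.warning(
            "dropped %d genes with fewer than %d guides", len(dropped), guides_per_gene_target
        )
    new_guides = guides.loc[keep].reset_index(drop=True)
    kept_genes = set(new_guides.loc[~new_guides["is_control"], "gene"])
    new_genes = library.genes.loc[library.genes["gene"].isin(kept_genes)].reset_index(drop=True)
    return (
        GuideLibrary(guides=new_guides, genes=new_genes),
        np.asarray(counts)[keep],
    )


def sweep_child_seed(root_seed: int, param_name: str, value, replicate: int) -> int:
    """Deterministic per-cell seed: hash of (root seed, parameter, value, replicate).

    Insertion-order free, so any sweep cell is reproducible in isolation.
    """
    key = f"{root_seed}|{param_name}|{value!r}|{replicate}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


_PARAM_FIELDS = {f.name for f in dataclass_fields(SimulationParams)}


def run_sweep(
    base_params: SimulationParams,
    param_name: str,
    grid: list,
    methods: list[str],
    n_sim: int = 3,
    cutoff: float = 0.1,
    root_seed: int | None = None,
) -> pd.DataFrame:
    """Simulate/analyze/score each grid value x replicate simulation x method.

    Returns a long-format table with one row per benchmark record:
    ``sweep_param, sweep_value, method, sim_replicate, pr_auc, roc_auc,
    empirical_fdr, n_discoveries``. Rankings for the AUCs use each
    method's significance order (negated rank).
    """
    if param_name not in _PARAM_FIELDS:
        raise InvalidParameterError(
            f"unknown sweep parameter {param_name!r}; valid fields: {sorted(_PARAM_FIELDS)}"
        )
    if n_sim < 1:
        raise InvalidParameterError("n_sim must be >= 1")
    if root_seed is None:
        root_seed = base_params.seed

    records = []
    for value in grid:
        for rep in range(n_sim):
            seed = sweep_child_seed(root_seed, param_name, value, rep)
            params = base_params.replace(**{param_name: value, "seed": seed})
            screen = simulate_screen(params)
            labels = screen.library.truth_labels()
            for method in methods:
                results = analyze_screen(
                    screen.counts, screen.sample_names, screen.library, method
                )
                ranking = -results["rank"].to_numpy(dtype=float)
                y = labels.reindex(results["gene"]).to_numpy(dtype=bool)
                fdr, n_disc = empirical_fdr(results, labels, cutoff)
                records.append(
                    {
                        "sweep_param": param_name,
                        "sweep_value": value,
                        "method": method,
                        "sim_replicate": rep,
                        "pr_auc": precision_recall_auc(ranking, y),
                        "roc_auc": roc_auc(ranking, y),
                        "empirical_fdr": fdr,
                        "n_discoveries": n_disc,
                    }
                )
    return pd.DataFrame.from_records(records)


def aggregate_sweep(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd over replicate simulations per sweep cell x method.

    Undefined empirical FDRs (no discoveries) are dropped from the FDR
    aggregation exactly as undefined points are dropped from plots.
    """
    grp = records.groupby(["sweep_param", "sweep_value", "method"], sort=True)
    agg = grp.agg(
        pr_auc_mean=("pr_auc", "mean"),
        pr_auc_sd=("pr_auc", "std"),
        roc_auc_mean=("roc_auc", "mean"),
        roc_auc_sd=("roc_auc", "std"),
        empirical_fdr_mean=("empirical_fdr", "mean"),
        empirical_fdr_sd=("empirical_fdr", "std"),
        n_discoveries_mean=("n_discoveries", "mean"),
        n_replicates=("pr_auc", "size"),
    )
    return agg.reset_index()


def evaluate_results(
    results: pd.DataFrame, labels: pd.Series, cutoff: float = 0.1
) -> dict:
    """Score one gene-result table against truth labels."""
    ranking = -results["rank"].to_numpy(dtype=float)
    y = labels.reindex(results["gene"]).to_numpy(dtype=bool)
    fdr, n_disc = empirical_fdr(results, labels, cutoff)
    return {
        "pr_auc": precision_recall_auc(ranking, y),
        "roc_auc": roc_auc(ranking, y),
        "empirical_fdr": fdr,
        "n_discoveries": n_disc,
        "cutoff": cutoff,
    }
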