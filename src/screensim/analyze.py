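"""Gene-level analysis of paired screen count tables.

Three baseline gene-ranking methods operate on normalized guide-level
log2 fold changes (treated vs initial):

``t_test``
    Pooled-variance two-sided t-test of each gene's guides against the
    negative-control guides. Pooling the variance keeps the test defined
    even with a single guide per gene and is conservative when the
    control spread exceeds the gene's. Requires control guides.
``rsa``
    Redundant activity ranking: guides are ranked by depletion and each
    gene gets the minimum iterative-hypergeometric tail probability of
    its guides' ranks. Only ranks enter, never LFC magnitudes, so a
    single outlier guide cannot carry a gene.
``stouffer``
    Per-guide z-scores against the null LFC distribution, combined per
    gene as z = sum(z_i)/sqrt(n); rewards consistent signal across a
    majority of guides (unlike Fisher's method, which rewards one
    strong guide).

All methods report Benjamini-Hochberg estimated FDRs over genes.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .library import GuideLibrary

__all__ = [
    "AnalysisError",
    "size_factors",
    "guide_log_fold_changes",
    "pooled_t_test",
    "bh_adjust",
    "rsa_rank_pvalue",
    "stouffer_combine",
    "analyze_screen",
    "METHODS",
]

logger = logging.getLogger(__name__)

METHODS = ("t_test", "rsa", "stouffer")

_P_FLOOR = 1e-300


class AnalysisError(ValueError):
    """Raised for degenerate inputs or unsupported analysis configurations."""


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios per-sample scaling factors, geometric mean 1.

    The reference is the per-guide geometric mean across samples,
    computed over guides with nonzero counts in every sample; each
    sample's factor is the median ratio of its counts to the reference.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise AnalysisError("counts must be a guides x samples matrix")
    if np.any(counts.sum(axis=0) == 0):
        raise AnalysisError("a sample has all-zero counts; size factors undefined")
    positive = np.all(counts > 0, axis=1)
    if not positive.any():
        raise AnalysisError("no guide has nonzero counts in every sample")
    ref = np.exp(np.log(counts[positive]).mean(axis=1))
    factors = np.median(counts[positive] / ref[:, None], axis=0)
    return factors / np.exp(np.log(factors).mean())


def guide_log_fold_changes(
    counts: np.ndarray,
    sample_names: list[str],
    *,
    guide_ids: np.ndarray | list[str] | None = None,
    control_mask: np.ndarray | None = None,
    pseudocount: float = 0.5,
    centering: str = "controls",
) -> pd.DataFrame:
    """Normalized, centered per-guide log2 fold changes (treated vs initial).

    Counts are scaled by median-of-ratios size factors and averaged per
    arm; the LFC is ``log2((mean treated + pc) / (mean initial + pc))``,
    then shifted so the median LFC of the centering reference set
    (negative controls, or all guides) is 0 — the standard assumption
    that the bulk of guides have no effect.

    Returns a DataFrame with columns ``guide``, ``lfc``,
    ``mean_initial``, ``mean_treated``.
    """
    counts = np.asarray(counts)
    if pseudocount <= 0:
        raise AnalysisError("pseudocount must be > 0")
    if centering not in ("controls", "all"):
        raise AnalysisError("centering must be 'controls' or 'all'")
    initial = [i for i, s in enumerate(sample_names) if s.startswith("initial")]
    treated = [i for i, s in enumerate(sample_names) if s.startswith("treated")]
    if not initial or not treated:
        raise AnalysisError(
            "sample names must include both arms ('initial*' and 'treated*')"
        )

    factors = size_factors(counts)
    norm = counts / factors[None, :]
    mean_initial = norm[:, initial].mean(axis=1)
    mean_treated = norm[:, treated].mean(axis=1)
    lfc = np.log2(mean_treated + pseudocount) - np.log2(mean_initial + pseudocount)

    if centering == "controls":
        if control_mask is None or not np.asarray(control_mask).any():
            logger.warning(
                "no control guides available for centering; falling back to all guides"
            )
            offset = np.median(lfc)
        else:
            offset = np.median(lfc[np.asarray(control_mask)])
    else:
        offset = np.median(lfc)
    lfc = lfc - offset

    if guide_ids is None:
        guide_ids = [f"guide_{i}" for i in range(counts.shape[0])]
    return pd.DataFrame(
        {
            "guide": np.asarray(guide_ids),
            "lfc": lfc,
            "mean_initial": mean_initial,
            "mean_treated": mean_treated,
        }
    )


def _pooled_t(
    mean1: np.ndarray,
    ss1: np.ndarray,
    n1: np.ndarray,
    mean2: float,
    ss2: float,
    n2: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pooled-variance two-sample t; ss = sums of squared deviations."""
    df = n1 + n2 - 2
    sp2 = (ss1 + ss2) / df
    floored = sp2 < 1e-12
    if np.any(floored):
        warnings.warn("pooled variance below 1e-12 floored", RuntimeWarning, stacklevel=3)
        sp2 = np.maximum(sp2, 1e-12)
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def pooled_t_test(
    gene_lfcs: np.ndarray, control_lfcs: np.ndarray
) -> tuple[float, float]:
    """Two-sided pooled-variance t-test of gene guides vs control guides.

    Degrees of freedom are ``n1 + n2 - 2``; the pooled variance keeps
    the test defined for a single gene guide.
    """
    x = np.asarray(gene_lfcs, dtype=float)
    c = np.asarray(control_lfcs, dtype=float)
    if x.size < 1:
        raise AnalysisError("need at least one gene guide")
    if c.size < 2:
        raise AnalysisError("need at least two control guides")
    t, p = _pooled_t(
        np.array([x.mean()]),
        np.array([((x - x.mean()) ** 2).sum()]),
        np.array([x.size]),
        c.mean(),
        ((c - c.mean()) ** 2).sum(),
        c.size,
    )
    return float(t[0]), float(p[0])


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (estimated FDRs)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise AnalysisError("p-values must lie in [0, 1] and contain no NaN")
    return multipletests(p, method="fdr_bh")[1]


def rsa_rank_pvalue(guide_ranks: np.ndarray, n_total_guides: int) -> float:
    """Iterative hypergeometric rank p-value for one gene.

    Given the (distinct, sorted ascending) ranks of a gene's guides
    among all ``n_total_guides`` targeting guides, returns
    ``min_i P(X >= i)`` with X ~ Hypergeometric(population n_total,
    successes n_gene, draws rank_i): the most significant enrichment of
    the gene's guides in any top-of-list prefix. Uses ranks only.
    """
    ranks = np.asarray(guide_ranks, dtype=int)
    if ranks.size == 0:
        raise AnalysisError("need at least one guide rank")
    if len(np.unique(ranks)) != ranks.size:
        raise AnalysisError("guide ranks must be distinct")
    if ranks.min() < 1 or ranks.max() > n_total_guides:
        raise AnalysisError("ranks must lie in [1, n_total_guides]")
    ranks = np.sort(ranks)
    k = ranks.size
    i = np.arange(1, k + 1)
    tail = stats.hypergeom.sf(i - 1, n_total_guides, k, ranks)
    return float(tail.min())


def stouffer_combine(
    guide_p_values: np.ndarray, direction_signs: np.ndarray
) -> float:
    """Combine two-sided guide p-values with direction signs (Stouffer).

    Each guide contributes a signed z-score ``sign * isf(p / 2)``
    (recovering its signed z from the two-sided p); the combined
    statistic is ``sum(z) / sqrt(n)`` and the returned value is its
    two-sided p. With one guide this is the identity.
    """
    p = np.asarray(guide_p_values, dtype=float)
    signs = np.asarray(direction_signs, dtype=float)
    if p.size < 1:
        raise AnalysisError("need at least one p-value")
    if p.shape != signs.shape:
        raise AnalysisError("p-values and signs must have matching shape")
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn(
            "p-values at 0 or 1 clipped to [1e-300, 1 - 1e-300]",
            RuntimeWarning,
            stacklevel=2,
        )
        p = np.clip(p, _P_FLOOR, 1 - 1e-16)
    z = signs * stats.norm.isf(p / 2.0)
    combined = z.sum() / np.sqrt(p.size)
    return float(2.0 * stats.norm.sf(abs(combined)))


# ---------------------------------------------------------------------------
# per-method gene tables


def _gene_groups(lfc: pd.DataFrame, library: GuideLibrary) -> pd.DataFrame:
    """Targeting-guide LFC table joined with gene labels."""
    guides = library.guides
    merged = lfc.merge(guides[["guide", "gene", "is_control"]], on="guide", how="inner")
    if len(merged) != len(guides):
        raise AnalysisError("count table and library guide ids do not match")
    return merged


def _t_test_table(merged: pd.DataFrame) -> pd.DataFrame:
    ctrl = merged.loc[merged["is_control"], "lfc"].to_numpy()
    if ctrl.size < 2:
        raise AnalysisError(
            "the t-test requires at least two negative-control guides"
        )
    targ = merged.loc[~merged["is_control"]]
    grp = targ.groupby("gene", sort=True)["lfc"]
    n = grp.count().to_numpy()
    mean = grp.mean().to_numpy()
    # sum of squared deviations via the shifted-moment identity
    sumsq = targ.assign(sq=targ["lfc"] ** 2).groupby("gene", sort=True)["sq"].sum().to_numpy()
    ss = np.maximum(sumsq - n * mean**2, 0.0)
    t, p = _pooled_t(mean, ss, n, ctrl.mean(), ((ctrl - ctrl.mean()) ** 2).sum(), ctrl.size)
    return pd.DataFrame(
        {"gene": grp.count().index, "statistic": t, "p_value": p, "mean_lfc": mean, "n_guides": n}
    )


def _hypergeom_sf(i: np.ndarray, M: int, K: np.ndarray, N: np.ndarray) -> np.ndarray:
    """P(X >= i) for X ~ Hypergeom(M, K, N), vectorized over i, K, N.

    Sums the at-most-max(K) pmf terms in log space; efficient when the
    number of successes per draw (guides per gene) is small.
    """
    from scipy.special import gammaln

    i = np.asarray(i, dtype=int)
    K = np.asarray(K, dtype=int)
    N = np.asarray(N, dtype=int)
    out = np.zeros(np.broadcast(i, K, N).shape)
    log_denom = gammaln(M + 1) - gammaln(N + 1) - gammaln(M - N + 1)
    for j in range(1, int(K.max()) + 1):
        valid = (j >= i) & (j <= K) & (j <= N) & (N - j <= M - K)
        if not valid.any():
            continue
        Kv, Nv = K[valid] if K.ndim else K, N[valid]
        logp = (
            gammaln(Kv + 1)
            - gammaln(j + 1)
            - gammaln(Kv - j + 1)
            + gammaln(M - Kv + 1)
            - gammaln(Nv - j + 1)
            - gammaln(M - Kv - Nv + j + 1)
            - (log_denom[valid] if np.ndim(log_denom) else log_denom)
        )
        out[valid] += np.exp(logp)
    # include j = 0 when i == 0 (tail probability is then 1)
    out[i <= 0] = 1.0
    return np.clip(out, 0.0, 1.0)


def _rsa_table(merged: pd.DataFrame) -> pd.DataFrame:
    targ = merged.loc[~merged["is_control"]].copy()
    # most-depleted first; ties broken by guide id for determinism
    targ = targ.sort_values(["lfc", "guide"], kind="mergesort").reset_index(drop=True)
    targ["rank"] = np.arange(1, len(targ) + 1)
    m = len(targ)
    sizes = targ.groupby("gene")["gene"].transform("size").to_numpy()
    order_in_gene = targ.groupby("gene").cumcount().to_numpy() + 1
    tail = _hypergeom_sf(order_in_gene, m, sizes, targ["rank"].to_numpy())
    targ["tail"] = tail
    grp = targ.groupby("gene", sort=True)
    out = grp.agg(p_value=("tail", "min"), mean_lfc=("lfc", "mean"), n_guides=("lfc", "size"))
    out = out.reset_index()
    out["statistic"] = -np.log10(np.maximum(out["p_value"], _P_FLOOR))
    return out[["gene", "statistic", "p_value", "mean_lfc", "n_guides"]]


def _stouffer_table(merged: pd.DataFrame) -> pd.DataFrame:
    ctrl = merged.loc[merged["is_control"], "lfc"].to_numpy()
    targ = merged.loc[~merged["is_control"]].copy()
    if ctrl.size >= 2:
        mu, sd = ctrl.mean(), ctrl.std(ddof=1)
    else:
        logger.warning(
            "fewer than two control guides; z-scoring guides against all targeting guides"
        )
        mu, sd = targ["lfc"].mean(), targ["lfc"].std(ddof=1)
    if sd < 1e-12:
        raise AnalysisError("null LFC spread is degenerate (sd ~ 0)")
    targ["z"] = (targ["lfc"] - mu) / sd
    grp = targ.groupby("gene", sort=True)
    n = grp.size().to_numpy()
    zsum = grp["z"].sum().to_numpy()
    combined = zsum / np.sqrt(n)
    p = 2.0 * stats.norm.sf(np.abs(combined))
    return pd.DataFrame(
        {
            "gene": grp.size().index,
            "statistic": combined,
            "p_value": p,
            "mean_lfc": grp["lfc"].mean().to_numpy(),
            "n_guides": n,
        }
    )


def analyze_screen(
    counts: np.ndarray,
    sample_names: list[str],
    library: GuideLibrary,
    method: str = "t_test",
    *,
    pseudocount: float = 0.5,
    centering: str = "controls",
) -> pd.DataFrame:
    """Score every gene of a screen with one baseline method.

    Returns one row per (non-control) gene with columns ``gene``,
    ``score`` (-log10 p signed by the mean LFC direction), ``p_value``,
    ``fdr`` (Benjamini-Hochberg), ``rank`` (1 = most significant; ties
    broken by gene id) and ``n_guides``. Deterministic in the inputs and
    invariant to guide row order.
    """
    if method not in METHODS:
        raise AnalysisError(f"unknown method {method!r}; choose from {METHODS}")
    lfc = guide_log_fold_changes(
        counts,
        sample_names,
        guide_ids=library.guides["guide"].to_numpy(),
        control_mask=library.control_mask,
        pseudocount=pseudocount,
        centering=centering,
    )
    merged = _gene_groups(lfc, library)
    if method == "t_test":
        table = _t_test_table(merged)
    elif method == "rsa":
        table = _rsa_table(merged)
    else:
        table = _stouffer_table(merged)

    table = table.sort_values("gene", kind="mergesort").reset_index(drop=True)
    p = np.clip(table["p_value"].to_numpy(), _P_FLOOR, 1.0)
    table["fdr"] = bh_adjust(p)
    table["score"] = -np.log10(p) * np.sign(table["mean_lfc"].to_numpy())
    order = table.sort_values(["p_value", "gene"], kind="mergesort").index
    rank = np.empty(len(table), dtype=int)
    rank[order] = np.arange(1, len(table) + 1)
    table["rank"] = rank
    return table[["gene", "score", "p_value", "fdr", "rank", "n_guides"]]
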