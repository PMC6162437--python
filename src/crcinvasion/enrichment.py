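"""Single-sample and two-group gene-set enrichment scoring.

The single-sample score (ssGSEA) is a rank-weighted running-sum statistic: for
one sample, genes are ordered by descending expression rank and the score is
the sum over all positions of (cumulative weighted fraction of gene-set hits −
cumulative uniform fraction of misses).  Hit weights are rank^alpha normalised
over the in-set genes; every out-of-set gene contributes 1/(number of misses).
A positive score means the set's genes concentrate at the top of the sample's
expression profile.

The two-group test ranks genes by a signal-to-noise metric between phenotype
groups, computes the classic weighted Kolmogorov-Smirnov running-sum statistic
(maximum deviation, signed) for a gene set, and calibrates it against a
permutation null — phenotype (label) permutation when both groups have at
least MIN_PHENOTYPE_GROUP samples, gene-set permutation otherwise.  P-values
use the add-one estimator, so p = 0 is impossible and the granularity is
1/(n_perm + 1).

Scores are rank-based, hence invariant to any strictly increasing per-sample
transform of expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signatures import MIN_USABLE_GENES, SignatureCollection

logger = logging.getLogger(__name__)

DEFAULT_WEIGHT = 0.25
MIN_PHENOTYPE_GROUP = 7

__all__ = [
    "rank_transform",
    "ssgsea_score",
    "ssgsea_matrix",
    "gsea_two_group",
    "GseaResult",
]


def _validate_matrix(matrix: pd.DataFrame) -> None:
    if matrix.shape[0] < 2 or matrix.shape[1] < 1:
        raise ValueError("expression matrix must have >= 2 genes and >= 1 sample")
    if matrix.index.has_duplicates:
        raise ValueError("duplicate gene identifiers in expression matrix")
    if matrix.columns.has_duplicates:
        raise ValueError("duplicate sample identifiers in expression matrix")
    if matrix.isna().to_numpy().any():
        raise ValueError("expression matrix contains missing values")


def rank_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Within-sample ranks, 1 = lowest expression.

    Ties are resolved deterministically: among equal values the
    lexicographically smaller gene identifier receives the lower rank, so every
    gene gets a distinct integer rank on every platform.
    """
    _validate_matrix(matrix)
    gene_order = np.argsort(matrix.index.astype(str))
    # tie-break key: position of each gene in lexicographic order
    tie_key = np.empty(len(gene_order), dtype=np.int64)
    tie_key[gene_order] = np.arange(len(gene_order))

    values = matrix.to_numpy()
    ranks = np.empty_like(values, dtype=np.int64)
    for j in range(values.shape[1]):
        order = np.lexsort((tie_key, values[:, j]))
        ranks[order, j] = np.arange(1, values.shape[0] + 1)
    return pd.DataFrame(ranks, index=matrix.index, columns=matrix.columns)


def _running_sum_score(ranks: np.ndarray, hit: np.ndarray, weight: float) -> float:
    """Sum over descending-rank positions of (cum hit fraction − cum miss fraction)."""
    order = np.argsort(-ranks, kind="stable")
    hit_ord = hit[order]
    n_miss = int((~hit_ord).sum())
    weights = np.where(hit_ord, ranks[order].astype(float) ** weight, 0.0)
    denom = weights.sum()
    cum_hit = np.cumsum(weights) / denom
    cum_miss = np.cumsum(~hit_ord) / n_miss
    return float(np.sum(cum_hit - cum_miss))


def ssgsea_score(
    sample_ranks: pd.Series, gene_set, weight_exponent: float = DEFAULT_WEIGHT
) -> float:
    """ssGSEA enrichment score of one gene set in one sample.

    ``sample_ranks`` are within-sample ranks (from :func:`rank_transform`);
    ``gene_set`` is a GeneSet or any iterable of gene ids.  The set must have
    at least MIN_USABLE_GENES members in the ranked universe and must not cover
    it entirely (the miss term would be undefined).
    """
    genes = getattr(gene_set, "genes", gene_set)
    members = {str(g).upper() for g in genes}
    universe = sample_ranks.index.astype(str).str.upper()
    hit = np.asarray(universe.isin(members))
    n_hit = int(hit.sum())
    if n_hit < MIN_USABLE_GENES:
        raise ValueError(
            f"gene set has {n_hit} gene(s) in the matrix; >= {MIN_USABLE_GENES} required"
        )
    if n_hit == len(sample_ranks):
        raise ValueError("gene set covers the entire gene universe")
    return _running_sum_score(sample_ranks.to_numpy(), hit, weight_exponent)


def ssgsea_matrix(
    matrix: pd.DataFrame,
    collection: SignatureCollection,
    weight_exponent: float = DEFAULT_WEIGHT,
    normalize: bool = False,
) -> pd.DataFrame:
    """Score every usable set in every sample.

    Unusable sets (fewer than MIN_USABLE_GENES genes in the matrix, or covering
    the whole universe) are omitted with a logged warning.  With ``normalize``
    all scores are divided by the global (max − min) range across the matrix.
    """
    ranks = rank_transform(matrix)
    rank_values = ranks.to_numpy()
    universe = ranks.index.astype(str).str.upper()

    rows = []
    names = []
    for gs in collection:
        hit = np.asarray(universe.isin(set(gs.genes)))
        n_hit = int(hit.sum())
        if n_hit < MIN_USABLE_GENES or n_hit == len(universe):
            logger.warning("omitting unusable gene set %r (%d usable genes)", gs.name, n_hit)
            continue
        scores = [
            _running_sum_score(rank_values[:, j], hit, weight_exponent)
            for j in range(rank_values.shape[1])
        ]
        rows.append(scores)
        names.append(gs.name)
    if not rows:
        raise ValueError("no usable gene sets for this matrix")

    esm = pd.DataFrame(rows, index=pd.Index(names, name="set"), columns=matrix.columns)
    if normalize:
        span = float(esm.to_numpy().max() - esm.to_numpy().min())
        if span > 0:
            esm = esm / span
    return esm


# ---------------------------------------------------------------------------
# two-group GSEA with a permutation null
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    n_perm: int
    ranking_metric: str
    permutation_scheme: str
    seed: int

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value must lie in (0, 1]")


def _signal_to_noise(values: np.ndarray, group1: np.ndarray) -> np.ndarray:
    """Per-gene signal-to-noise ratio with the standard GSEA variance floor."""
    x1, x2 = values[:, group1], values[:, ~group1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    s1, s2 = x1.std(axis=1, ddof=1), x2.std(axis=1, ddof=1)
    s1 = np.maximum(s1, 0.2 * np.abs(m1) + 1e-8)
    s2 = np.maximum(s2, 0.2 * np.abs(m2) + 1e-8)
    return (m1 - m2) / (s1 + s2)


def _ks_statistic(metric: np.ndarray, hit: np.ndarray, weight: float = 1.0) -> float:
    """Signed maximum deviation of the weighted KS running sum."""
    order = np.argsort(-metric, kind="stable")
    hit_ord = hit[order]
    w = np.where(hit_ord, np.abs(metric[order]) ** weight, 0.0)
    denom = w.sum()
    if denom <= 0:
        # all in-set metrics are exactly zero: uniform hit weights
        w = hit_ord.astype(float)
        denom = w.sum()
    n_miss = int((~hit_ord).sum())
    running = np.cumsum(w) / denom - np.cumsum(~hit_ord) / n_miss
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def gsea_two_group(
    matrix: pd.DataFrame,
    labels: pd.Series,
    gene_set,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> GseaResult:
    """Two-group GSEA of one gene set with a permutation p-value.

    ``labels`` maps the matrix's sample ids onto exactly two groups; genes are
    ranked by signal-to-noise (first group label in sorted order = group 1).
    The permutation scheme is phenotype permutation when both groups have at
    least MIN_PHENOTYPE_GROUP samples, gene-set permutation otherwise.
    """
    _validate_matrix(matrix)
    labels = labels.reindex(matrix.columns)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    group1 = (labels == groups[0]).to_numpy()
    if group1.sum() == 0 or (~group1).sum() == 0:
        raise ValueError("both groups must be non-empty")

    genes = getattr(gene_set, "genes", gene_set)
    members = {str(g).upper() for g in genes}
    universe = matrix.index.astype(str).str.upper()
    hit = np.asarray(universe.isin(members))
    n_hit = int(hit.sum())
    if n_hit < MIN_USABLE_GENES or n_hit == len(universe):
        raise ValueError("gene set unusable for this matrix")

    values = matrix.to_numpy(dtype=float)
    metric = _signal_to_noise(values, group1)
    observed = _ks_statistic(metric, hit, weight)

    rng = np.random.default_rng(seed)
    phenotype = min(int(group1.sum()), int((~group1).sum())) >= MIN_PHENOTYPE_GROUP
    null = np.empty(n_perm)
    if phenotype:
        scheme = "phenotype"
        for b in range(n_perm):
            perm = rng.permutation(group1)
            null[b] = _ks_statistic(_signal_to_noise(values, perm), hit, weight)
    else:
        scheme = "gene_set"
        idx = np.arange(len(universe))
        for b in range(n_perm):
            random_hit = np.zeros(len(universe), dtype=bool)
            random_hit[rng.choice(idx, size=n_hit, replace=False)] = True
            null[b] = _ks_statistic(metric, random_hit, weight)

    p = (1 + int(np.sum(np.abs(null) >= abs(observed)))) / (n_perm + 1)
    mean_abs_null = float(np.mean(np.abs(null)))
    nes = observed / mean_abs_null if mean_abs_null > 0 else 0.0
    name = getattr(gene_set, "name", "gene_set")
    return GseaResult(
        set_name=name,
        es=observed,
        nes=nes,
        p_value=p,
        n_perm=n_perm,
        ranking_metric="signal_to_noise",
        permutation_scheme=scheme,
        seed=seed,
    )
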