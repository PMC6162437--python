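"""Unsupervised structure discovery in tumor expression matrices.

Three complementary views, mirroring how bulk tumor cohorts are routinely
dissected:

* **NMF metagene factorization** with restarts and consensus clustering.
  V ≈ W·H is fitted by Lee-Seung multiplicative updates minimising squared
  Frobenius error (the reference algorithm for metagene extraction; the update
  rule is provably monotone, which we assert on every run).  Samples are
  assigned to the metagene with the largest coefficient; stability across
  restarts is summarised in a consensus (co-assignment) matrix whose cophenetic
  correlation drives rank selection.
* **Hierarchical clustering** of samples on 1 − Pearson correlation distance
  over the top most-variable genes, average linkage.
* **PCA** of the full transcriptome (genes centered across samples).

Expression is expected on a log2(FPKM+1)-like scale, i.e. non-negative up to
noise; residual negative entries are clipped at zero with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

EXPRESSION_FLOOR = 0.0  # "expressed" means value > this on the log2 scale
COPHENETIC_THRESHOLD = 0.95
MIN_RANK_IMPROVEMENT = 0.05  # relative error gain an extra metagene must bring

__all__ = [
    "filter_expressed",
    "nmf_factorize",
    "select_rank",
    "top_variable_hclust",
    "pca_embed",
    "NmfResult",
    "top_loading_genes",
    "linkage_to_newick",
]


def filter_expressed(
    matrix: pd.DataFrame, min_expressed_samples: int = 1, floor: float = EXPRESSION_FLOOR
) -> pd.DataFrame:
    """Keep genes expressed (value > ``floor``) in at least ``min_expressed_samples`` samples."""
    keep = (matrix > floor).sum(axis=1) >= min_expressed_samples
    if not keep.any():
        raise ValueError("no genes pass the expression filter")
    return matrix.loc[keep]


@dataclass
class NmfResult:
    """Best-of-restarts NMF factorization plus restart-consensus summary."""

    W: pd.DataFrame  # genes x rank, non-negative
    H: pd.DataFrame  # rank x samples, non-negative
    assignments: pd.Series  # sample -> component in {1..rank}
    reconstruction_error: float
    consensus: pd.DataFrame  # samples x samples co-assignment frequency
    n_restarts: int
    seed: int
    rank: int
    loss_history: np.ndarray = field(repr=False, default=None)


def _mu_nmf(
    V: np.ndarray, rank: int, max_iter: int, tol: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Multiplicative-update NMF for squared Frobenius loss.

    Returns (W, H, per-check loss history).  The loss is asserted non-increasing
    (up to floating-point slack) — a violation would indicate a broken update.
    """
    eps = 1e-12
    n, m = V.shape
    scale = np.sqrt(max(V.mean(), eps) / rank)
    W = rng.uniform(eps, 1.0, size=(n, rank)) * scale
    H = rng.uniform(eps, 1.0, size=(rank, m)) * scale

    losses = [np.linalg.norm(V - W @ H)]
    for it in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + eps)
        W *= (V @ H.T) / (W @ (H @ H.T) + eps)
        loss = np.linalg.norm(V - W @ H)
        prev = losses[-1]
        assert loss <= prev * (1 + 1e-9) + 1e-12, (
            f"NMF objective increased at iteration {it}: {prev} -> {loss}"
        )
        losses.append(loss)
        if prev > 0 and (prev - loss) / prev < tol:
            break
    return W, H, np.asarray(losses)


def nmf_factorize(
    matrix: pd.DataFrame,
    rank: int,
    n_restarts: int = 30,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
) -> NmfResult:
    """Factorize a non-negative expression matrix into ``rank`` metagenes.

    The best of ``n_restarts`` random initialisations (lowest reconstruction
    error) provides W, H and the argmax-coefficient sample assignments; the
    consensus matrix records, over restarts, how often each sample pair was
    co-assigned.  Ties in the argmax go to the lowest component index.
    """
    if rank >= min(matrix.shape):
        raise ValueError(f"rank {rank} must be < min(genes, samples) = {min(matrix.shape)}")
    V = matrix.to_numpy(dtype=float)
    n_neg = int((V < 0).sum())
    if n_neg:
        logger.warning("clipping %d negative entries at 0 before NMF", n_neg)
        V = np.clip(V, 0, None)

    rng = np.random.default_rng(seed)
    best = None
    co = np.zeros((V.shape[1], V.shape[1]))
    for _ in range(n_restarts):
        W, H, losses = _mu_nmf(V, rank, max_iter, tol, rng)
        # resolve the W/H scale ambiguity before the argmax: a component's
        # coefficient only means as much as its basis vector is long
        scaled = H * np.linalg.norm(W, axis=0)[:, None]
        assign = np.argmax(scaled, axis=0)  # first (lowest) index wins ties
        co += assign[None, :] == assign[:, None]
        if best is None or losses[-1] < best[2][-1]:
            best = (W, H, losses)

    W, H, losses = best
    assignments = pd.Series(
        np.argmax(H * np.linalg.norm(W, axis=0)[:, None], axis=0) + 1,
        index=matrix.columns,
        name="component",
    )
    comp_index = pd.Index(range(1, rank + 1), name="component")
    return NmfResult(
        W=pd.DataFrame(W, index=matrix.index, columns=comp_index),
        H=pd.DataFrame(H, index=comp_index, columns=matrix.columns),
        assignments=assignments,
        reconstruction_error=float(losses[-1]),
        consensus=pd.DataFrame(
            co / n_restarts, index=matrix.columns, columns=matrix.columns
        ),
        n_restarts=n_restarts,
        seed=seed,
        rank=rank,
        loss_history=losses,
    )


def top_loading_genes(result: NmfResult, component: int, n: int = 25) -> pd.Series:
    """Top-loading genes of one metagene (W column), descending."""
    return result.W[component].sort_values(ascending=False).head(n)


def consensus_cophenetic(consensus: pd.DataFrame) -> float:
    """Cophenetic correlation of average-linkage clustering of 1 − consensus."""
    dist = 1.0 - consensus.to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if np.allclose(condensed, condensed[0]):
        # all pairs equally (dis)similar: hierarchy is degenerate but perfectly
        # represented by any ultrametric -> treat as fully stable
        return 1.0
    Z = hierarchy.linkage(condensed, method="average")
    c, _ = hierarchy.cophenet(Z, condensed)
    return float(c)


def select_rank(
    matrix: pd.DataFrame,
    candidate_ranks,
    n_restarts: int = 20,
    seed: int = 0,
    threshold: float = COPHENETIC_THRESHOLD,
    min_improvement: float = MIN_RANK_IMPROVEMENT,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[int, pd.DataFrame]:
    """Choose the factorization rank by consensus stability plus an error elbow.

    Every candidate rank is factorized with ``n_restarts`` restarts (plus one
    auxiliary rank below the lowest candidate, to anchor its improvement).  A
    candidate *passes* when (a) the cophenetic correlation of its consensus
    matrix reaches ``threshold`` — the clustering is stable across restarts —
    and (b) its reconstruction error improves on the next-lower rank's by at
    least ``min_improvement`` (relative) — the extra metagene explains real
    structure, not noise.  The chosen rank is the largest passing candidate;
    if none passes (pure noise), the lowest candidate is returned with a
    logged warning.  The full profile is returned alongside.
    """
    candidates = sorted(candidate_ranks)
    if len(candidates) < 2:
        raise ValueError("at least two candidate ranks required")
    if candidates[-1] >= min(matrix.shape):
        raise ValueError(f"candidate rank {candidates[-1]} infeasible for shape {matrix.shape}")

    fit_ranks = candidates if candidates[0] <= 1 else [candidates[0] - 1, *candidates]
    errors: dict[int, float] = {}
    records = []
    for i, rank in enumerate(fit_ranks):
        res = nmf_factorize(
            matrix, rank, n_restarts=n_restarts, max_iter=max_iter, tol=tol,
            seed=seed + 1000 * i,
        )
        errors[rank] = res.reconstruction_error
        if rank in candidates:
            records.append(
                {
                    "rank": rank,
                    "cophenetic": consensus_cophenetic(res.consensus),
                    "reconstruction_error": res.reconstruction_error,
                }
            )
    profile = pd.DataFrame(records).set_index("rank")
    improvements = []
    for rank in profile.index:
        prev = errors.get(rank - 1)
        if prev is None or prev <= 0:
            improvements.append(np.nan)  # no anchor: improvement not assessable
        else:
            improvements.append((prev - errors[rank]) / prev)
    profile["improvement"] = improvements

    passes = (profile["cophenetic"] >= threshold) & (
        profile["improvement"].fillna(np.inf) >= min_improvement
    )
    if passes.any():
        return int(profile.index[passes].max()), profile
    logger.warning(
        "no candidate rank is both stable (cophenetic >= %.2f) and informative "
        "(improvement >= %.0f%%); returning lowest candidate",
        threshold,
        100 * min_improvement,
    )
    return candidates[0], profile


def top_variable_hclust(
    matrix: pd.DataFrame, n_top_genes: int, k_clusters: int
) -> tuple[pd.Series, np.ndarray]:
    """Cluster samples on the top most-variable genes.

    Genes are ranked by variance (log scale); samples are clustered on
    1 − Pearson correlation distance with average linkage and the tree is cut
    at ``k_clusters``.  Returns (labels, scipy linkage matrix).
    """
    if n_top_genes > matrix.shape[0]:
        raise ValueError("n_top_genes exceeds the gene count")
    variances = matrix.var(axis=1)
    top = variances.sort_values(ascending=False).index[:n_top_genes]
    sub = matrix.loc[top]

    sds = sub.std(axis=0)
    constant = sds.index[sds == 0]
    if len(constant):
        raise ValueError(
            f"constant expression profile (undefined correlation) for sample(s): "
            f"{list(constant)}"
        )
    corr = np.corrcoef(sub.to_numpy().T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=k_clusters, criterion="maxclust")
    return pd.Series(labels, index=matrix.columns, name="cluster"), Z


def linkage_to_newick(Z: np.ndarray, leaf_names) -> str:
    """Serialise a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(Z)
    names = list(leaf_names)

    def render(node) -> str:
        if node.is_leaf():
            return names[node.id]
        left, right = node.get_left(), node.get_right()
        ld = node.dist - left.dist
        rd = node.dist - right.dist
        return f"({render(left)}:{ld:.6g},{render(right)}:{rd:.6g})"

    return render(tree) + ";"


def pca_embed(matrix: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples over genes centered across samples.

    Returns (samples × components coordinate frame, variance-explained
    fractions, which are non-increasing and sum to ≤ 1).
    """
    if n_components > min(matrix.shape):
        raise ValueError("n_components exceeds min(genes, samples)")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(matrix.to_numpy().T)
    frame = pd.DataFrame(
        coords,
        index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return frame, pca.explained_variance_ratio_
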