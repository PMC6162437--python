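"""Microbiome profiling from taxon × sample read-count tables.

The input is the product of host-read depletion and database mapping: for each
sample, the number of shotgun reads assigned to each microbial taxon, together
with the taxon's lineage (phylum / family / species).  The module aggregates
counts up the taxonomy, expresses per-taxon enrichment as a log2 fold-change of
reads-per-million against the cohort median, and computes two community
diversity indices per sample:

* Simpson's diversity, in the unbiased pairwise-draw form
  ``D = 1 − Σ n_i(n_i − 1) / (N(N − 1))`` — the probability that two reads
  drawn without replacement map to different species;
* Shannon-Wiener diversity ``D = −Σ p_i ln p_i`` with ``p_i = n_i / N``
  (natural log; zero-count taxa contribute 0 by the 0·ln 0 → 0 convention).

Both indices are 0 for a monoculture and maximal for the uniform composition
(Shannon = ln k for k taxa).
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

LINEAGE_LEVELS = ("phylum", "family", "species")
DEFAULT_PSEUDOCOUNT = 0.5

__all__ = [
    "split_taxon_table",
    "aggregate_taxonomy",
    "relative_abundance",
    "enrichment_log2fc",
    "simpson_diversity",
    "shannon_diversity",
    "diversity_table",
    "compare_groups",
]


def split_taxon_table(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a taxon table into (lineage frame, integer count frame)."""
    lineage_cols = [c for c in LINEAGE_LEVELS if c in table.columns]
    counts = table.drop(columns=lineage_cols)
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.allclose(values, np.round(values)):
            raise ValueError("read counts must be integers")
        counts = counts.round().astype(np.int64)
    if (counts.to_numpy() < 0).any():
        raise ValueError("read counts must be non-negative")
    return table[lineage_cols], counts


def aggregate_taxonomy(table: pd.DataFrame, level: str) -> pd.DataFrame:
    """Sum counts within each lineage value at ``level``.

    Per-sample totals are conserved.  The returned table keeps the lineage
    columns above the requested level (their first value per group) and is
    indexed by the level's values.
    """
    if level not in LINEAGE_LEVELS:
        raise ValueError(f"unknown taxonomy level {level!r}; expected one of {LINEAGE_LEVELS}")
    lineage, counts = split_taxon_table(table)
    if level not in lineage.columns or lineage[level].isna().any() or (lineage[level] == "").any():
        raise ValueError(f"lineage not populated at level {level!r}")

    keep = LINEAGE_LEVELS[: LINEAGE_LEVELS.index(level)]
    grouped = counts.groupby(lineage[level], sort=True).sum()
    upper = lineage.groupby(lineage[level], sort=True)[list(keep)].first() if keep else None
    out = grouped if upper is None else pd.concat([upper, grouped], axis=1)
    out.index.name = level
    return out


def relative_abundance(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample proportions p_i = n_i / N.

    Samples with zero total are flagged (returned as the second element) and
    their proportions reported as missing rather than raising.
    """
    _, counts = split_taxon_table(table)
    totals = counts.sum(axis=0)
    empty = list(totals.index[totals == 0])
    props = counts.astype(float).div(totals.replace(0, np.nan), axis=1)
    return props, empty


def enrichment_log2fc(
    table: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """Per-taxon per-sample log2 fold-change against the cohort median.

    Proportions are scaled to reads-per-million and each cell is
    ``log2((rpm + pseudocount) / (median rpm of that taxon + pseudocount))``:
    positive = enriched relative to the cohort, negative = depleted.
    """
    props, empty = relative_abundance(table)
    if props.shape[1] < 2:
        raise ValueError("enrichment requires >= 2 samples")
    rpm = props * 1e6
    baseline = rpm.median(axis=1, skipna=True)
    return np.log2(rpm.add(pseudocount).div(baseline + pseudocount, axis=0))


def simpson_diversity(counts) -> float:
    """Unbiased Simpson diversity D = 1 − Σ n_i(n_i−1) / (N(N−1)); requires N ≥ 2."""
    n = np.asarray(counts, dtype=np.int64)
    if (n < 0).any():
        raise ValueError("counts must be non-negative")
    total = int(n.sum())
    if total < 2:
        raise ValueError(f"Simpson diversity undefined for N = {total} (< 2 reads)")
    return 1.0 - float((n * (n - 1)).sum()) / (total * (total - 1))


def shannon_diversity(counts) -> float:
    """Shannon-Wiener diversity D = −Σ p_i ln p_i (natural log); requires N ≥ 1."""
    n = np.asarray(counts, dtype=np.int64)
    if (n < 0).any():
        raise ValueError("counts must be non-negative")
    total = int(n.sum())
    if total == 0:
        raise ValueError("Shannon diversity undefined for an empty sample")
    p = n[n > 0] / total
    return float(-(p * np.log(p)).sum())


def diversity_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Simpson and Shannon diversity, read total and observed taxa."""
    _, counts = split_taxon_table(table)
    records = []
    for sample in counts.columns:
        col = counts[sample].to_numpy()
        records.append(
            {
                "sample": sample,
                "simpson": simpson_diversity(col),
                "shannon": shannon_diversity(col),
                "N": int(col.sum()),
                "taxa_observed": int((col > 0).sum()),
            }
        )
    return pd.DataFrame(records).set_index("sample")


def compare_groups(diversity: pd.DataFrame, groups: pd.Series) -> dict:
    """Group summaries and pairwise rank tests of the diversity indices.

    Returns per-group median/IQR of each index and a two-sided Mann-Whitney U
    p-value for every group pair (exact tie handling via the normal
    approximation with tie correction; identical groups give p = 1).
    """
    groups = groups.reindex(diversity.index)
    if groups.isna().any():
        raise ValueError("group labels missing for some samples")
    names = sorted(groups.unique())
    if len(names) < 2:
        raise ValueError(">= 2 groups required")
    for g in names:
        if (groups == g).sum() == 0:
            raise ValueError(f"group {g!r} has no samples")

    summary_rows = []
    for g in names:
        sub = diversity.loc[groups == g]
        for index_name in ("simpson", "shannon"):
            q1, med, q3 = sub[index_name].quantile([0.25, 0.5, 0.75])
            summary_rows.append(
                {
                    "group": g,
                    "index": index_name,
                    "n": len(sub),
                    "median": med,
                    "iqr": q3 - q1,
                }
            )

    tests = []
    for a, b in itertools.combinations(names, 2):
        for index_name in ("simpson", "shannon"):
            x = diversity.loc[groups == a, index_name]
            y = diversity.loc[groups == b, index_name]
            if np.array_equal(np.sort(x), np.sort(y)):
                p = 1.0  # identical samples: no evidence of a shift by convention
            else:
                p = float(mannwhitneyu(x, y, alternative="two-sided").pvalue)
                p = min(p, 1.0)
            tests.append({"group_a": a, "group_b": b, "index": index_name, "p_value": p})

    return {
        "summary": pd.DataFrame(summary_rows).set_index(["group", "index"]),
        "tests": pd.DataFrame(tests),
    }


def uniform_shannon(k: int) -> float:
    """Closed form: Shannon diversity of a uniform k-taxon community (= ln k)."""
    return math.log(k)
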