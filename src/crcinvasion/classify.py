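"""Invasion-subtype classification from signature-enrichment profiles.

Colorectal tumors are assigned to one of four subtypes — ``proliferative``,
``collective`` (invasion by cohesive epithelial groups), ``crypt-like``
(monolayer MYC-positive crypt structures in a dense fibroblast stroma) or
``EMT`` (epithelial-mesenchymal transition) — from their single-sample
enrichment scores of proliferation, EMT, CAF/stromal and tumor-region
signatures.  Each subtype is encoded as an *archetype*: a ±1/0 pattern over
the signatures saying which are expected activated (+1), suppressed (−1) or
irrelevant (0).

Scores are first z-scaled per signature across the cohort (population SD, so
small hand checks are exact).  A sample's similarity to an archetype is the
uncentered correlation (cosine) between its z-scored signature vector and the
±1 pattern, restricted to the archetype's nonzero entries; the sample takes
the best archetype's label when the best similarity reaches ``tau`` and the
margin over the runner-up reaches ``delta``, and is ``unclassified``
otherwise.  The cosine is used rather than a second Pearson centering because
archetype support patterns may be one-sided (all +1), which has zero variance;
the scores themselves are already cohort-centered by the z-scaling.

Cross-tabulation against an external label set (e.g. the four consensus
molecular subtypes, CMS1-4) reports per-cell one-sided hypergeometric
over-representation p-values.
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

SUBTYPE_ORDER = ("proliferative", "collective", "crypt-like", "EMT")
UNCLASSIFIED = "unclassified"
# Calibrated so that roughly a fifth of a 1-SD-effect archetype cohort falls
# below threshold (matching the ~21% unclassified rate typical of cohort-scale
# CRC subtyping); see docs/methods.md for the calibration conditions.
DEFAULT_TAU = 0.5
DEFAULT_DELTA = 0.12

__all__ = [
    "SUBTYPE_ORDER",
    "UNCLASSIFIED",
    "default_archetypes",
    "zscale_scores",
    "classify_samples",
    "crosstab_enrichment",
    "summarize_subtypes",
]


def default_archetypes() -> pd.DataFrame:
    """The shipped 4-subtype archetype matrix (subtypes × signatures, ±1/0).

    Qualitatively: proliferative tumors differ from all invasive tumors in
    every signature except the epithelial one; collective invasion suppresses
    the stroma-related block; crypt-like and EMT invasion share an activated
    stroma but differ in proliferation and central-tumor activation.  Shipped
    as an editable TSV (``data/archetypes.tsv``) so users can swap in their
    own patterns.
    """
    path = resources.files("crcinvasion.data").joinpath("archetypes.tsv")
    with resources.as_file(path) as p:
        frame = pd.read_csv(p, sep="\t", index_col=0)
    return frame.astype(int)


def _validate_archetypes(archetypes: pd.DataFrame) -> None:
    values = archetypes.to_numpy()
    if not ((values == -1) | (values == 0) | (values == 1)).all():
        raise ValueError("archetype entries must be -1, 0 or +1")
    zero_rows = archetypes.index[(values == 0).all(axis=1)]
    if len(zero_rows):
        raise ValueError(f"archetype row(s) with no nonzero entries: {list(zero_rows)}")


def zscale_scores(esm: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each signature row to unit population SD across samples.

    Constant rows become all-zero with a logged warning.  A single-sample
    matrix is an error: the method is cohort-relative.
    """
    if esm.shape[1] < 2:
        raise ValueError("z-scaling requires >= 2 samples (cohort-relative scores)")
    values = esm.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population SD (divide by n)
    constant = sd[:, 0] == 0
    if constant.any():
        for name in esm.index[constant]:
            logger.warning("signature %r is constant across samples; z-scores set to 0", name)
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (values - mean) / sd_safe
    z[constant, :] = 0.0
    return pd.DataFrame(z, index=esm.index, columns=esm.columns)


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def classify_samples(
    scaled_scores: pd.DataFrame,
    archetypes: pd.DataFrame | None = None,
    tau: float = DEFAULT_TAU,
    delta: float = DEFAULT_DELTA,
) -> pd.DataFrame:
    """Assign every sample to its nearest archetype, or ``unclassified``.

    ``scaled_scores`` is the z-scaled signatures × samples matrix;
    ``archetypes`` is subtypes × signatures with entries in {−1, 0, +1}.  A
    sample whose z-vector is constant (e.g. all-zero) over an archetype's
    support gets similarity 0 for that archetype.  Ties in the best similarity
    are broken by archetype row order (logged when invoked).

    Returns a frame indexed by sample with ``label``, ``confidence`` (best
    similarity), ``margin`` (best − second best) and one ``sim_<subtype>``
    column per archetype.
    """
    if archetypes is None:
        archetypes = default_archetypes()
    _validate_archetypes(archetypes)
    missing = [
        sig
        for sig in archetypes.columns
        if (archetypes[sig] != 0).any() and sig not in scaled_scores.index
    ]
    if missing:
        raise ValueError(f"archetypes reference signatures absent from scores: {missing}")

    supports = {
        subtype: archetypes.columns[archetypes.loc[subtype] != 0]
        for subtype in archetypes.index
    }
    sims = pd.DataFrame(
        0.0, index=scaled_scores.columns, columns=archetypes.index
    )
    for subtype, support in supports.items():
        pattern = archetypes.loc[subtype, support].to_numpy(dtype=float)
        block = scaled_scores.loc[support].to_numpy()
        for j, sample in enumerate(scaled_scores.columns):
            # zero-norm vectors carry no direction: similarity 0 (cosine handles it)
            sims.loc[sample, subtype] = _cosine(block[:, j], pattern)

    records = []
    order = list(archetypes.index)
    for sample in scaled_scores.columns:
        row = sims.loc[sample]
        ranked = sorted(order, key=lambda s: (-row[s], order.index(s)))
        best, second = ranked[0], ranked[1] if len(ranked) > 1 else None
        if second is not None and row[best] == row[second]:
            logger.info("similarity tie for sample %r broken by archetype order", sample)
        confidence = float(row[best])
        margin = confidence - (float(row[second]) if second is not None else 0.0)
        label = best if (confidence >= tau and margin >= delta) else UNCLASSIFIED
        records.append(
            {"sample": sample, "label": label, "confidence": confidence, "margin": margin}
        )
    result = pd.DataFrame(records).set_index("sample")
    for subtype in order:
        result[f"sim_{subtype}"] = sims[subtype]
    return result


def crosstab_enrichment(
    assignments: pd.Series | pd.DataFrame, external_labels: pd.Series
) -> dict:
    """Cross-tabulate subtype calls against an external labelling.

    Only samples carrying both labels enter the table.  For each cell the
    one-sided hypergeometric over-representation p-value is reported (drawing
    the column total from the population, counting hits in the row), plus a
    Bonferroni-adjusted column.

    Returns a dict with ``counts``, ``row_fractions``, ``col_fractions``,
    ``p_values``, ``p_bonferroni`` DataFrames and ``n`` (samples tabulated).
    """
    if isinstance(assignments, pd.DataFrame):
        assignments = assignments["label"]
    common = assignments.index.intersection(external_labels.index)
    if len(common) == 0:
        raise ValueError("no samples carry both label sets")
    ours = assignments.loc[common]
    theirs = external_labels.loc[common]

    counts = pd.crosstab(ours, theirs)
    counts.index.name = "subtype"
    counts.columns.name = "external"
    n = int(counts.to_numpy().sum())
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)

    p = pd.DataFrame(1.0, index=counts.index, columns=counts.columns)
    for r in counts.index:
        for c in counts.columns:
            k = int(counts.loc[r, c])
            # P(X >= k) with K=row total successes, n=column total draws
            p.loc[r, c] = float(hypergeom.sf(k - 1, n, int(row_tot[r]), int(col_tot[c])))
    n_cells = counts.size
    return {
        "counts": counts,
        "row_fractions": counts.div(row_tot, axis=0),
        "col_fractions": counts.div(col_tot, axis=1),
        "p_values": p,
        "p_bonferroni": (p * n_cells).clip(upper=1.0),
        "n": n,
    }


def summarize_subtypes(assignments: pd.Series | pd.DataFrame) -> dict:
    """Per-label counts plus the classified total and fraction of all samples."""
    if isinstance(assignments, pd.DataFrame):
        assignments = assignments["label"]
    counts = assignments.value_counts().to_dict()
    n_total = int(len(assignments))
    n_classified = int(sum(v for k, v in counts.items() if k != UNCLASSIFIED))
    return {
        "counts": counts,
        "n_total": n_total,
        "n_classified": n_classified,
        "fraction_classified": (n_classified / n_total) if n_total else 0.0,
    }
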