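"""Classify tumors into the four invasion subtypes and cross-tabulate vs CMS.

Generates a 200-tumor cohort from the shipped archetype patterns
(proliferative / collective / crypt-like / EMT), scores the nine signatures,
z-scales across the cohort and assigns each tumor to its nearest archetype.
An external CMS-like labelling is then cross-tabulated with hypergeometric
enrichment — the workflow that splits the mesenchymal subtype (CMS4-like)
into crypt-like and EMT invasion.
"""

import numpy as np
import pandas as pd

from crcinvasion import (
    classify_samples,
    crosstab_enrichment,
    default_archetypes,
    generate_expression_cohort,
    ssgsea_matrix,
    summarize_subtypes,
    zscale_scores,
)
from crcinvasion.synthetic import archetype_cohort_config, signature_collection

archetypes = default_archetypes()
config = archetype_cohort_config(archetypes, seed=3)
matrix, truth = generate_expression_cohort(config)

scores = ssgsea_matrix(matrix, signature_collection(config))
assignments = classify_samples(zscale_scores(scores), archetypes)

summary = summarize_subtypes(assignments)
print("subtype counts:", summary["counts"])
print(f"classified {summary['n_classified']}/{summary['n_total']} tumors "
      f"({100 * summary['fraction_classified']:.0f}%); the rest fall below the "
      f"confidence/margin thresholds")

# an external CMS-like labelling: mesenchymal lumps crypt-like + EMT together
cms_like = truth.to_series().map(
    {"proliferative": "CMS3-like", "collective": "CMS1-like",
     "crypt-like": "CMS4-like", "EMT": "CMS4-like"}
)
ct = crosstab_enrichment(assignments, cms_like)
print("\ncontingency counts (our labels x external):")
print(ct["counts"])
print("\nhypergeometric over-representation p-values:")
print(ct["p_values"].map(lambda p: f"{p:.2g}"))
print("\nboth crypt-like and EMT concentrate in the mesenchymal-like column: "
      "the classifier decomposes that subtype into two invasion modes")
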