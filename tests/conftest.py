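import numpy as np
import pandas as pd
import pytest

from crcinvasion import (
    classify_samples,
    default_archetypes,
    ssgsea_matrix,
    zscale_scores,
)
from crcinvasion.synthetic import (
    archetype_cohort_config,
    generate_expression_cohort,
    signature_collection,
)


@pytest.fixture
def small_matrix() -> pd.DataFrame:
    """A tiny deterministic 6-gene x 4-sample expression matrix."""
    rng = np.random.default_rng(42)
    return pd.DataFrame(
        rng.normal(5, 1, size=(6, 4)),
        index=[f"G{i}" for i in range(6)],
        columns=[f"S{j}" for j in range(4)],
    )


def run_archetype_pipeline(seed: int, tau=None, delta=None, **cohort_kwargs):
    """Generate an archetype cohort, score it and classify it; returns
    (assignment frame with a 'truth' column, archetype matrix)."""
    archetypes = default_archetypes()
    config = archetype_cohort_config(archetypes, seed=seed, **cohort_kwargs)
    matrix, truth = generate_expression_cohort(config)
    scores = ssgsea_matrix(matrix, signature_collection(config))
    kwargs = {}
    if tau is not None:
        kwargs["tau"] = tau
    if delta is not None:
        kwargs["delta"] = delta
    result = classify_samples(zscale_scores(scores), archetypes, **kwargs)
    result["truth"] = truth.to_series()
    return result, archetypes
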