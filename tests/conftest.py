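import numpy as np
import pandas as pd
import pytest

from teaterroir import CohortSpec, FeatureTable, MatchedDesign, generate_cohort


@pytest.fixture(scope="session")
def design4() -> MatchedDesign:
    pairs = tuple((f"p{i}", f"p{i}_A", f"p{i}_B") for i in range(4))
    return MatchedDesign(pairs, ("A", "B"))


@pytest.fixture(scope="session")
def design8() -> MatchedDesign:
    pairs = tuple((f"p{i}", f"p{i}_A", f"p{i}_B") for i in range(8))
    return MatchedDesign(pairs, ("A", "B"))


@pytest.fixture(scope="session")
def cohort() -> "CohortBundle":
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def null_spec_kwargs() -> dict:
    """Spec overrides that switch every simulated region effect off.

    The hurdle detection probability is equalized across regions (not
    zeroed) so the sesquiterpene keeps nonzero variance for z-scoring.
    """
    return dict(
        volatile_effect=0.0,
        microbe_effect=0.0,
        stable_nonvolatile_effect=0.0,
        soil_effect=0.0,
        contingent_sd=0.0,
        hurdle_prob_a=7 / 8,
        hurdle_prob_b=7 / 8,
    )


def toy_table(values, feature_ids, sample_ids, kind="generic") -> FeatureTable:
    return FeatureTable(
        pd.DataFrame(np.asarray(values, float), index=feature_ids, columns=sample_ids),
        kind,
    )
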