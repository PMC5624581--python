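import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from uvcover import CohortModel, PhantomSpec, ScoringConfig, generate_cohort, score_image

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

COHORT_SEED = 20


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free uncovered phantom with exactly two intensity levels."""
    from uvcover import generate_phantom

    spec = PhantomSpec(noise_sd=0.0, skin_intensity=200)
    return generate_phantom(spec, seed=1)


@pytest.fixture(scope="session")
def cohort_bundles():
    """Rendered 57-participant two-visit cohort, no artifacts."""
    model = CohortModel(seed=COHORT_SEED)
    return generate_cohort(model)


@pytest.fixture(scope="session")
def scored_cohort(cohort_bundles):
    """Cohort table with scored percentages joined to ground truth."""
    bundles, table = cohort_bundles
    cfg = ScoringConfig()
    rows = []
    for b in bundles:
        res = score_image(b.image, b.landmarks, cfg, image_id=b.metadata["image_id"])
        row = res.as_row()
        row.update(
            {
                k: b.metadata[k]
                for k in (
                    "participant_id",
                    "visit",
                    "gender",
                    "skin_type",
                    "formulation",
                    "truth_pct_face",
                    "truth_pct_letterbox",
                    "truth_pct_rest",
                    "truth_canthus_missed_left",
                    "truth_canthus_missed_right",
                )
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
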