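import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from phasemod import phase_model as pm
from phasemod import synthgen

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def study_cohort() -> pd.DataFrame:
    """One synthetic cohort at study scale (18 subjects, 130 keywords)."""
    return synthgen.generate_cohort(synthgen.CohortParams(seed=11))


@pytest.fixture(scope="session")
def centered_target(study_cohort) -> pd.DataFrame:
    return pm.center_scores(study_cohort, "target")


def make_cohort_from_deltas(deltas, cs_mean: float = 50.0) -> pd.DataFrame:
    """Build a noiseless score table whose per-subject dCS at the four
    phases equals `deltas` (one 4-vector per subject).

    Scores are written through fractional keyword counts so the table's
    derived CS reproduces cs_mean + delta exactly.
    """
    rows = []
    for s, d in enumerate(deltas):
        d = np.asarray(d, dtype=float)
        assert d.shape == (4,)
        for phase, delta in zip((0.0, 90.0, 180.0, 270.0), d):
            cs = cs_mean + delta
            rows.append({
                "subject_id": f"S{s + 1:02d}",
                "source": "target",
                "phase_deg": phase,
                "n_keywords": 100,
                "n_correct": cs,  # fractional counts: exact CS by design
            })
    return pd.DataFrame(rows)
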