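import numpy as np
import pytest

from natisc.isc import BoldRun
from natisc.synthetic import CohortSpec, EffectRegion, weight_for_isc


def make_run(data, subject=0, condition="genetic", session=0, tr=2.0):
    data = np.asarray(data, dtype=float)
    mask = np.ones((data.shape[0], 1, 1), dtype=bool)
    return BoldRun(subject_id=subject, condition=condition,
                   session_index=session, data=data, mask=mask, tr_seconds=tr)


@pytest.fixture
def planted_spec():
    """Small cohort with one genetic-only effect region (true ISC 0.5)."""
    return CohortSpec(
        n_subjects=6, sessions_per_condition=2, n_trs=150,
        grid_shape=(6, 6, 3), noise_sd=0.8,
        effect_regions=[EffectRegion(box=((0, 3), (0, 3), (0, 2)),
                                     condition="genetic",
                                     weight=weight_for_isc(0.5, 0.8))],
        seed=7)
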