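import numpy as np
import pandas as pd
import pytest

from emsig.schema import ScaleDefinition, SurveyDataset, reverse_score
from emsig.simulate import generate_dataset, study_like_config


@pytest.fixture(scope="session")
def study_dataset():
    """One study-like synthetic cohort (n=1020, 85 items, 16 planted clusters)."""
    return generate_dataset(study_like_config(seed=1))


@pytest.fixture(scope="session")
def study_scored(study_dataset):
    """Reverse-scored study dataset with factor solutions and scores."""
    from emsig.factors import compute_factor_scores, pcc_matrix, select_k

    dataset, truth = study_dataset
    dataset = reverse_score(dataset)
    solutions = {}
    for scale in dataset.scales:
        corr = pcc_matrix(dataset, scale.scale_id)
        solutions[scale.scale_id] = select_k(
            corr, pcc_floor=0.55, scale_id=scale.scale_id, prefix=scale.prefix
        )
    scores = compute_factor_scores(dataset, solutions)
    return dataset, truth, solutions, scores


def tiny_dataset(responses: dict, likert_max: int = 5, dose=None, reverse=()):
    """Hand-built one-scale dataset for unit tests."""
    frame = pd.DataFrame(responses)
    n = len(frame)
    scale = ScaleDefinition(
        scale_id="S",
        item_ids=tuple(frame.columns),
        likert_min=1,
        likert_max=likert_max,
        reverse_items=frozenset(reverse),
    )
    return SurveyDataset(
        responses=frame,
        dose=pd.Series(dose if dose is not None else np.zeros(n, dtype=int)),
        demographics=pd.DataFrame(index=frame.index),
        scales=(scale,),
    )
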