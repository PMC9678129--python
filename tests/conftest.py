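"""Shared fixtures: one moderately sized synthetic study, generated once.

The study follows the emulated design (10 lame + 11 control cows, two
extraction days, pooled QCs, two polarities) at a reduced feature count
so the whole suite stays fast; feature-count-sensitive tests build their
own designs.
"""

from __future__ import annotations

import numpy as np
import pytest

from milkspot.feature_extraction import FeatureMatrix
from milkspot.pipeline import PipelineConfig, _first_day_cows, _stage_extract
from milkspot.synthetic_data import (
    EffectSpec,
    StudyDesign,
    generate_study,
    map_truth_to_matrix,
    pick_robust_features,
)


@pytest.fixture(scope="session")
def study_small():
    """Generated + extracted study: 50 features/polarity, 10 planted
    effects (|log2 FC| = 1.5) on robustly observed features."""
    design = StudyDesign(n_features_per_polarity=50, seed=2)
    idx = pick_robust_features(design, 10)
    effects = [
        EffectSpec(int(j), "up" if i % 2 == 0 else "down", 1.5)
        for i, j in enumerate(idx)
    ]
    peak_lists, metadata, truth = generate_study(design, effects)
    fm = _stage_extract(PipelineConfig(), peak_lists, metadata)
    planted_cols = map_truth_to_matrix(truth, fm)[idx]
    assert (planted_cols >= 0).all(), "planted features must survive extraction"
    return {
        "design": design,
        "effects": effects,
        "peak_lists": peak_lists,
        "metadata": metadata,
        "truth": truth,
        "fm": fm,
        "planted_cols": planted_cols,
    }


@pytest.fixture(scope="session")
def day8(study_small):
    """First-day cow samples only: (FeatureMatrix, y) with y=1 for lame."""
    cow_ids, y = _first_day_cows(study_small["metadata"])
    fm: FeatureMatrix = study_small["fm"].subset_samples(cow_ids)
    return fm, np.asarray(y)
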