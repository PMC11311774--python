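"""Shared fixtures: tiny hand-built cohorts and one default simulated cohort."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mdxmet import PeakAreaMatrix, RankedEntry, RankedList, simulate_cohort
from mdxmet.synthetic_data import SimulationConfig


def make_matrix(values: pd.DataFrame, tissue: str | list = "brain",
                timepoint: str | list = "baseline",
                treatment: str | list = "none",
                animal_id: list | None = None) -> PeakAreaMatrix:
    """Wrap a values frame in a PeakAreaMatrix with minimal metadata."""
    cols = list(values.columns)
    def expand(x):
        return list(x) if isinstance(x, (list, tuple)) else [x] * len(cols)
    meta = pd.DataFrame({
        "animal_id": animal_id if animal_id is not None else [f"A{i}" for i in range(len(cols))],
        "tissue": expand(tissue),
        "timepoint": expand(timepoint),
        "treatment": expand(treatment),
    }, index=pd.Index(cols, name="sample_id"))
    return PeakAreaMatrix(values=values.astype(float), samples=meta)


def make_paired_matrix(baseline: dict[str, float | None],
                       h72: dict[str, float | None],
                       animal: str = "A1") -> PeakAreaMatrix:
    """One animal, two samples; None encodes not-detected."""
    mets = list(baseline)
    assert list(h72) == mets
    values = pd.DataFrame(
        {f"{animal}_b": [baseline[m] for m in mets],
         f"{animal}_t": [h72[m] for m in mets]},
        index=mets, dtype=float)
    return make_matrix(values, tissue="brain",
                       timepoint=["baseline", "h72"],
                       treatment="vehicle", animal_id=[animal, animal])


def ranked_from_scores(scores: dict[str, float], rank_only: bool = False) -> RankedList:
    """RankedList ordered by descending score, ties lexicographic."""
    items = sorted(scores.items(), key=lambda t: (-t[1], t[0]))
    return RankedList(
        entries=[RankedEntry(metabolite=m, score=float(s), rank=i + 1)
                 for i, (m, s) in enumerate(items)],
        rank_only=rank_only)


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(SimulationConfig(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
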