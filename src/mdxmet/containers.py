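"""Core in-memory containers shared across the pipeline.

A cohort is a metabolite × sample peak-area matrix with explicit
missingness (NaN = not detected, i.e. below the detection limit — never
zero abundance) plus a sample metadata table. Ranked lists and metabolite
sets are the currency of the downstream enrichment analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

TISSUES = ("tumor", "brain")
TIMEPOINTS = ("baseline", "h72")
TREATMENTS = ("vehicle", "TMZ", "none")

METADATA_COLUMNS = ("animal_id", "tissue", "timepoint", "treatment")


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


def validate_sample_metadata(samples: pd.DataFrame) -> None:
    """Check a metadata table: unique sample ids, known enum levels,
    unique (animal_id, timepoint) pairs."""
    if samples.index.has_duplicates:
        dups = sorted(samples.index[samples.index.duplicated()].unique())
        raise ValidationError(f"duplicate sample id(s): {dups}")
    missing_cols = [c for c in METADATA_COLUMNS if c not in samples.columns]
    if missing_cols:
        raise ValidationError(f"metadata missing column(s): {missing_cols}")
    for col, levels in (("tissue", TISSUES), ("timepoint", TIMEPOINTS),
                        ("treatment", TREATMENTS)):
        bad = set(samples[col].unique()) - set(levels)
        if bad:
            raise ValidationError(f"unknown {col} level(s): {sorted(bad)}")
    pairs = samples[["animal_id", "timepoint"]]
    if pairs.duplicated().any():
        bad = pairs[pairs.duplicated()].values.tolist()
        raise ValidationError(f"duplicate (animal_id, timepoint) pair(s): {bad}")


@dataclass
class PeakAreaMatrix:
    """Metabolite × sample peak areas with attached sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by metabolite id, columns are sample ids.
        NaN encodes "not detected"; all present values must be > 0.
    samples
        Metadata indexed by sample id with columns ``animal_id``,
        ``tissue`` (tumor/brain), ``timepoint`` (baseline/h72) and
        ``treatment`` (vehicle/TMZ/none).
    scale
        ``"raw"`` or ``"normalized"``.
    raw
        When ``scale == "normalized"``, the pre-normalization raw values
        (same shape); the magnitude rule for metabolites undetected at
        baseline ranks by raw peak area, so they must travel together.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scale: str = "raw"
    raw: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dups = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise ValidationError(f"duplicate metabolite id(s): {dups}")
        if self.values.columns.has_duplicates:
            dups = sorted(self.values.columns[self.values.columns.duplicated()].unique())
            raise ValidationError(f"duplicate sample id(s) in matrix: {dups}")
        validate_sample_metadata(self.samples)
        absent = [s for s in self.values.columns if s not in self.samples.index]
        if absent:
            raise ValidationError(
                f"sample(s) in matrix absent from metadata: {absent}")
        arr = self.values.to_numpy(dtype=float)
        present = ~np.isnan(arr)
        if (arr[present] <= 0).any():
            raise ValidationError(
                "peak areas must be positive; zero/negative values must be "
                "encoded as missing (NaN) on read")
        if self.scale not in ("raw", "normalized"):
            raise ValidationError(f"unknown scale {self.scale!r}")

    # -- convenience --------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def detected(self) -> pd.DataFrame:
        """Boolean mask of detected entries."""
        return self.values.notna()

    def raw_values(self) -> pd.DataFrame:
        """Raw peak areas regardless of the matrix's current scale."""
        return self.raw if self.raw is not None else self.values

    def select_samples(self, **criteria: str) -> list[str]:
        """Sample ids whose metadata match all ``criteria``
        (e.g. ``tissue="tumor", timepoint="baseline"``)."""
        meta = self.samples.loc[list(self.values.columns)]
        mask = pd.Series(True, index=meta.index)
        for key, value in criteria.items():
            if key not in meta.columns:
                raise KeyError(f"unknown metadata field {key!r}")
            mask &= meta[key] == value
        return list(meta.index[mask])

    def subset(self, metabolites: Iterable[str] | None = None,
               sample_ids: Iterable[str] | None = None) -> "PeakAreaMatrix":
        values = self.values
        raw = self.raw
        if metabolites is not None:
            metabolites = list(metabolites)
            values = values.loc[metabolites]
            raw = raw.loc[metabolites] if raw is not None else None
        if sample_ids is not None:
            sample_ids = list(sample_ids)
            values = values[sample_ids]
            raw = raw[sample_ids] if raw is not None else None
        return PeakAreaMatrix(values=values,
                              samples=self.samples.loc[list(values.columns)],
                              scale=self.scale, raw=raw)


@dataclass
class RankedEntry:
    """One metabolite in a ranked list.

    ``score`` is the ordering statistic (fold change for group lists); NaN
    marks a non-finite score (metabolite undetected in the denominator, so
    no true fold change exists). ``fc`` carries the fold change where one
    was computable.
    """

    metabolite: str
    score: float
    rank: int
    fc: float | None = None
    block: str | None = None  # for longitudinal lists: "t1_only"/"both"/"t0_only"


@dataclass
class RankedList:
    """An ordered metabolite list for one comparison.

    ``rank_only`` flags lists whose scores are ranks rather than fold
    changes (per-animal longitudinal lists and mean-rank aggregates);
    downstream scoring then uses reversed ranks ``N + 1 - rank``.
    """

    entries: list[RankedEntry]
    provenance: dict = field(default_factory=dict)
    universe_size: int | None = None
    rank_only: bool = False

    def __post_init__(self) -> None:
        if self.universe_size is None:
            self.universe_size = len(self.entries)
        names = [e.metabolite for e in self.entries]
        if len(set(names)) != len(names):
            raise ValidationError("ranked list has duplicate metabolites")
        ranks = [e.rank for e in self.entries]
        if sorted(ranks) != list(range(1, len(self.entries) + 1)):
            raise ValidationError("ranks must be a permutation of 1..N")
        if len(self.entries) > self.universe_size:
            raise ValidationError("list longer than its universe")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def metabolites(self) -> list[str]:
        return [e.metabolite for e in sorted(self.entries, key=lambda e: e.rank)]

    def scores(self) -> np.ndarray:
        """Ordering-statistic scores in rank order."""
        ordered = sorted(self.entries, key=lambda e: e.rank)
        return np.array([e.score for e in ordered], dtype=float)

    def effective_scores(self) -> np.ndarray:
        """Scores used for enrichment weighting, in rank order.

        Rank-only lists score each entry as ``N + 1 - rank``; fold-change
        lists use the fold change, with any non-finite entry (top block of
        denominator-undetected metabolites) weighted at the largest finite
        score so it cannot silently vanish from the running sum.
        """
        n = len(self.entries)
        if self.rank_only:
            return np.arange(n, 0, -1, dtype=float)
        s = self.scores()
        finite = np.isfinite(s)
        if not finite.all():
            fill = np.abs(s[finite]).max() if finite.any() else 1.0
            s = np.where(finite, s, fill)
        return s

    def rank_of(self, metabolite: str) -> int:
        for e in self.entries:
            if e.metabolite == metabolite:
                return e.rank
        raise KeyError(metabolite)


@dataclass
class MetaboliteSet:
    """A named set of metabolite ids (a "feature set" for enrichment)."""

    name: str
    members: frozenset[str]
    description: str = "na"

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ValidationError(f"metabolite set {self.name!r} is empty")

    @property
    def k(self) -> int:
        return len(self.members)


@dataclass
class MetaboliteSetLibrary:
    """A named collection of metabolite sets (GMT/GMX-compatible)."""

    sets: dict[str, MetaboliteSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, s in self.sets.items():
            if name != s.name:
                raise ValidationError(f"library key {name!r} != set name {s.name!r}")

    def add(self, s: MetaboliteSet) -> None:
        if s.name in self.sets:
            raise ValidationError(f"duplicate set name {s.name!r}")
        self.sets[s.name] = s

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> MetaboliteSet:
        return self.sets[name]
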