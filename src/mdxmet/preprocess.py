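"""Normalization and the detection filter that defines the analysis universe.

Peak areas are made comparable across samples by median scaling: each
sample's values are divided by its median over *detected* metabolites, so
afterwards every sample has median 1. Metabolites detected in fewer than a
fraction (default 90%) of samples are dropped before any downstream
statistics — with 33 samples and the default threshold the required count
is ceil(0.9 × 33) = 30.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import PeakAreaMatrix, ValidationError


@dataclass
class NormalizationReport:
    per_sample_scale: dict[str, float] = field(default_factory=dict)
    n_metabolites_in: int = 0
    n_metabolites_out: int = 0
    detection_threshold: float | None = None
    required_count: int | None = None
    mode: str = "per_sample_median"
    notes: list[str] = field(default_factory=list)


def median_normalize(matrix: PeakAreaMatrix,
                     mode: str = "per_sample_median",
                     ) -> tuple[PeakAreaMatrix, NormalizationReport]:
    """Scale peak areas so each sample's median over detected metabolites is 1.

    MISSING entries are preserved (below-detection, not zero abundance) and
    never enter the median. The raw values are retained on the result: the
    rank rule for metabolites undetected at baseline orders them by raw
    peak area, not by any normalized quantity.

    ``mode="per_metabolite_median"`` instead divides each metabolite row by
    its median across detected samples (the alternative reading of
    "median = 1" scaling); ``mode="none"`` is the identity.
    """
    values = matrix.values
    report = NormalizationReport(n_metabolites_in=values.shape[0],
                                 n_metabolites_out=values.shape[0], mode=mode)
    if mode == "none":
        report.per_sample_scale = {s: 1.0 for s in values.columns}
        return matrix, report
    if mode == "per_sample_median":
        medians = values.median(axis=0, skipna=True)
        empty = medians.index[medians.isna()]
        if len(empty):
            raise ValidationError(
                f"sample(s) with zero detected metabolites: {list(empty)}")
        normalized = values.div(medians, axis=1)
        report.per_sample_scale = {s: float(m) for s, m in medians.items()}
    elif mode == "per_metabolite_median":
        medians = values.median(axis=1, skipna=True)
        empty = medians.index[medians.isna()]
        if len(empty):
            raise ValidationError(
                f"metabolite(s) with zero detected samples: {list(empty)}")
        normalized = values.div(medians, axis=0)
        report.per_sample_scale = {s: float("nan") for s in values.columns}
        report.notes.append("per-metabolite scaling: per-sample scales not defined")
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    out = PeakAreaMatrix(values=normalized, samples=matrix.samples,
                         scale="normalized", raw=matrix.raw_values())
    return out, report


def detection_filter(matrix: PeakAreaMatrix, threshold: float = 0.90,
                     ) -> tuple[PeakAreaMatrix, NormalizationReport]:
    """Keep metabolites detected in at least ceil(threshold × n_samples)
    samples ("present in at least 90% of samples"); row order is preserved."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    n = matrix.n_samples
    required = math.ceil(threshold * n)
    counts = matrix.detected().sum(axis=1)
    keep = counts[counts >= required].index
    out = matrix.subset(metabolites=list(keep))
    report = NormalizationReport(
        n_metabolites_in=matrix.values.shape[0],
        n_metabolites_out=out.values.shape[0],
        detection_threshold=threshold, required_count=required,
        mode="detection_filter")
    return out, report


def preprocess(matrix: PeakAreaMatrix, threshold: float = 0.90,
               mode: str = "per_sample_median",
               filter_before_normalization: bool = True,
               ) -> tuple[PeakAreaMatrix, NormalizationReport]:
    """Detection filter + median normalization in the configured order.

    Filtering first defines the analysis universe before any scaling; a
    flag reverses the order (the filter itself only looks at detection
    status, which normalization preserves, but the median scale does depend
    on which metabolites are present, so the order is recorded)."""
    if filter_before_normalization:
        filtered, frep = detection_filter(matrix, threshold)
        normalized, nrep = median_normalize(filtered, mode=mode)
    else:
        normalized, nrep = median_normalize(matrix, mode=mode)
        normalized, frep = detection_filter(normalized, threshold)
    report = NormalizationReport(
        per_sample_scale=nrep.per_sample_scale,
        n_metabolites_in=matrix.values.shape[0],
        n_metabolites_out=normalized.values.shape[0],
        detection_threshold=threshold, required_count=frep.required_count,
        mode=mode,
        notes=[f"order={'filter_then_normalize' if filter_before_normalization else 'normalize_then_filter'}"]
        + nrep.notes)
    return normalized, report
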