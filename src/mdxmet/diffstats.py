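"""Nonparametric differential-abundance statistics and NES comparisons.

Group sizes in a microdialysis cohort are small (9 vs 12 baseline samples,
3 animals per 72 h arm), so everything here is exact where feasible:
Mann–Whitney U for unpaired and Wilcoxon signed-rank for paired
comparisons use the exact permutation null whenever both sizes are ≤ 25
and ties do not prevent it, falling back to the tie-corrected normal
approximation otherwise. With complete separation at n = 9 vs 12 the
smallest attainable two-sided p is 2/C(21,9) ≈ 6.8 × 10⁻⁶; with n = 3
pairs it is 2/2³ = 0.25, which is why per-metabolite significance is
unreachable in a three-animal arm no matter the effect size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PeakAreaMatrix, ValidationError

_EXACT_MAX_N = 25


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str  # "exact" or "normal_approx"
    n1: int
    n2: int
    test: str = ""
    degenerate: bool = False
    notes: list[str] = field(default_factory=list)


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_exact(a, b) -> TestResult:
    """Two-sided Mann–Whitney U test.

    Exact p by full enumeration of the U null when both groups have ≤ 25
    observations and the pooled sample is tie-free; tie-corrected normal
    approximation otherwise. Identical constant groups give p = 1 with a
    degenerate flag instead of an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=a.size * b.size / 2.0, p_value=1.0,
                          method="exact", n1=a.size, n2=b.size,
                          test="mann_whitney", degenerate=True,
                          notes=["all values identical"])
    exact_ok = (a.size <= _EXACT_MAX_N and b.size <= _EXACT_MAX_N
                and not _has_ties(pooled))
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact_ok else "asymptotic")
    return TestResult(statistic=float(res.statistic),
                      p_value=float(min(res.pvalue, 1.0)),
                      method="exact" if exact_ok else "normal_approx",
                      n1=a.size, n2=b.size, test="mann_whitney")


def wilcoxon_signed_rank_exact(paired_diffs) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (standard convention, noted on the
    result); exact p by enumeration of the 2ⁿ sign assignments when the
    remaining n ≤ 25 with no tied |differences|, normal approximation with
    mid-ranks otherwise. All-zero differences give p = 1, degenerate.
    """
    d = np.asarray(paired_diffs, dtype=float)
    if d.size == 0:
        raise ValidationError("need at least one difference")
    nonzero = d[d != 0]
    notes = []
    if nonzero.size < d.size:
        notes.append(f"dropped {d.size - nonzero.size} zero difference(s)")
    if nonzero.size == 0:
        return TestResult(statistic=0.0, p_value=1.0, method="exact",
                          n1=d.size, n2=d.size, test="wilcoxon",
                          degenerate=True, notes=notes + ["all differences zero"])
    exact_ok = nonzero.size <= _EXACT_MAX_N and not _has_ties(np.abs(nonzero))
    res = stats.wilcoxon(nonzero, zero_method="wilcox",
                         alternative="two-sided",
                         method="exact" if exact_ok else "approx")
    return TestResult(statistic=float(res.statistic),
                      p_value=float(min(res.pvalue, 1.0)),
                      method="exact" if exact_ok else "normal_approx",
                      n1=nonzero.size, n2=nonzero.size, test="wilcoxon",
                      notes=notes)


@dataclass
class VolcanoRow:
    metabolite: str
    fc: float
    p_value: float
    cls: str  # up / down / ns
    degenerate: bool = False


def volcano_table(matrix: PeakAreaMatrix, group_a, group_b,
                  paired: bool = False, fc_cut: float = 1.5,
                  p_cut: float = 0.05,
                  ) -> tuple[list[VolcanoRow], dict[str, int]]:
    """Per-metabolite fold change + nonparametric p with up/down/ns calls.

    FC is the ratio of group means (MISSING contributing 0, the ranking
    convention); p is Mann–Whitney for unpaired groups, Wilcoxon
    signed-rank on animal-matched differences for paired ones. A
    metabolite is "up" iff fc > fc_cut and p < p_cut, "down" iff
    fc < 1/fc_cut and p < p_cut (strict inequalities on both sides, with
    the down threshold the reciprocal of the up threshold). Degenerate
    tests classify as ns with a flag.
    """
    ids_a = matrix.select_samples(**group_a) if isinstance(group_a, dict) else list(group_a)
    ids_b = matrix.select_samples(**group_b) if isinstance(group_b, dict) else list(group_b)
    if not ids_a or not ids_b:
        raise ValidationError("both groups must be non-empty")
    va = matrix.values[ids_a].fillna(0.0)
    vb = matrix.values[ids_b].fillna(0.0)
    if paired:
        animals_a = matrix.samples.loc[ids_a, "animal_id"]
        animals_b = matrix.samples.loc[ids_b, "animal_id"]
        common = [an for an in animals_a if an in set(animals_b)]
        if not common:
            raise ValidationError("paired mode: no matching animals")
        a_by_animal = {an: sid for sid, an in animals_a.items()}
        b_by_animal = {an: sid for sid, an in animals_b.items()}
        cols_a = [a_by_animal[an] for an in common]
        cols_b = [b_by_animal[an] for an in common]

    rows: list[VolcanoRow] = []
    counts = {"up": 0, "down": 0, "ns": 0}
    for m in matrix.metabolite_ids:
        mean_a, mean_b = float(va.loc[m].mean()), float(vb.loc[m].mean())
        fc = mean_a / mean_b if mean_b > 0 else float("inf") if mean_a > 0 else float("nan")
        if paired:
            diffs = va.loc[m, cols_a].to_numpy() - vb.loc[m, cols_b].to_numpy()
            tr = wilcoxon_signed_rank_exact(diffs) if np.any(diffs != 0) else \
                TestResult(0.0, 1.0, "exact", len(diffs), len(diffs),
                           "wilcoxon", degenerate=True)
        else:
            tr = mann_whitney_exact(va.loc[m].to_numpy(), vb.loc[m].to_numpy())
        if tr.degenerate:
            cls = "ns"
        elif np.isfinite(fc) and fc > fc_cut and tr.p_value < p_cut:
            cls = "up"
        elif fc == float("inf") and tr.p_value < p_cut:
            cls = "up"
        elif np.isfinite(fc) and fc < 1.0 / fc_cut and tr.p_value < p_cut:
            cls = "down"
        else:
            cls = "ns"
        counts[cls] += 1
        rows.append(VolcanoRow(metabolite=m, fc=fc, p_value=tr.p_value,
                               cls=cls, degenerate=tr.degenerate))
    return rows, counts


def volcano_frame(rows: list[VolcanoRow]) -> pd.DataFrame:
    return pd.DataFrame([{"metabolite": r.metabolite, "fc": r.fc,
                          "p_value": r.p_value, "class": r.cls,
                          "degenerate": r.degenerate} for r in rows])


@dataclass
class NormalityRow:
    metabolite: str
    group: str
    n: int
    statistic: float
    p_value: float
    testable: bool


def normality_screen(matrix: PeakAreaMatrix, grouping: str | None = None,
                     ) -> pd.DataFrame:
    """D'Agostino–Pearson omnibus normality screen per metabolite (and
    optionally per metadata group). Groups of n < 8 are flagged untestable
    (the omnibus test's minimum); results justify the nonparametric tests
    above but never gate them."""
    if grouping is None:
        groups = {"all": list(matrix.values.columns)}
    else:
        meta = matrix.samples.loc[list(matrix.values.columns)]
        groups = {str(level): list(meta.index[meta[grouping] == level])
                  for level in meta[grouping].unique()}
    out: list[NormalityRow] = []
    for gname, ids in groups.items():
        sub = matrix.values[ids]
        for m in matrix.metabolite_ids:
            x = sub.loc[m].dropna().to_numpy()
            if x.size < 8:
                out.append(NormalityRow(m, gname, x.size, float("nan"),
                                        float("nan"), False))
                continue
            k2, p = stats.normaltest(x)
            out.append(NormalityRow(m, gname, x.size, float(k2), float(p), True))
    return pd.DataFrame([r.__dict__ for r in out])


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame
    degenerate: bool = False


def nes_anova(nes_groups: dict[str, np.ndarray | list]) -> AnovaResult:
    """One-way ANOVA across named groups of NES values plus Tukey-HSD
    pairwise comparisons (the post-hoc for comparing, e.g., per-patient
    enrichment for several candidate signatures)."""
    if len(nes_groups) < 2:
        raise ValidationError("need ≥2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in nes_groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValidationError(f"group {k!r} has <2 values")
    pooled = np.concatenate(list(arrays.values()))
    if np.allclose(pooled, pooled[0]):
        empty = pd.DataFrame(columns=["group_a", "group_b", "p_value"])
        return AnovaResult(float("nan"), 1.0, empty, degenerate=True)
    f, p = stats.f_oneway(*arrays.values())
    tukey = stats.tukey_hsd(*arrays.values())
    names = list(arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append({"group_a": names[i], "group_b": names[j],
                         "p_value": float(tukey.pvalue[i, j])})
    return AnovaResult(float(f), float(p), pd.DataFrame(rows))
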