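"""Ranked-list construction.

Three list types feed the enrichment engine:

* group fold-change lists — mean(numerator group) / mean(denominator
  group) per metabolite, ranked highest to lowest (e.g. tumor/brain at
  baseline);
* per-animal longitudinal lists — 72 h vs baseline fold changes for one
  animal, with the special rule for metabolites that have no finite fold
  change because they were undetected at one timepoint;
* mean-rank aggregates — each metabolite's ranks averaged across animals
  to give one consensus list per arm.

The longitudinal rule: a metabolite detected only at the later timepoint
has an infinite fold change, so such metabolites form a top block ordered
by the magnitude of their *raw* peak area at 72 h (the worked case: two
newly-appearing metabolites with raw peaks 585,283 and 90,433 take ranks 1
and 2). Symmetrically, metabolites detected only at baseline form a bottom
block under the finite-fold-change block.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    MetaboliteSet,
    MetaboliteSetLibrary,
    PeakAreaMatrix,
    RankedEntry,
    RankedList,
    ValidationError,
)


def _group_means(matrix: PeakAreaMatrix, sample_ids: list[str],
                 missing_as_zero: bool = True) -> pd.Series:
    sub = matrix.values[sample_ids]
    if missing_as_zero:
        return sub.fillna(0.0).mean(axis=1)
    return sub.mean(axis=1).fillna(0.0)


def _resolve_selector(matrix: PeakAreaMatrix, selector) -> list[str]:
    if isinstance(selector, dict):
        ids = matrix.select_samples(**selector)
    else:
        ids = list(selector)
    if not ids:
        raise ValidationError(f"selector {selector!r} matched no samples")
    return ids


def group_fc_ranked_list(matrix: PeakAreaMatrix, numerator, denominator,
                         missing_as_zero: bool = True) -> RankedList:
    """Rank metabolites by the ratio of group means (numerator/denominator).

    Selectors are metadata dicts (``{"tissue": "tumor", "timepoint":
    "baseline"}``) or explicit sample-id lists; they must be disjoint.
    MISSING contributes 0 to the group means by default (group means then
    stay monotone in detection); ``missing_as_zero=False`` averages over
    detected samples only.

    Metabolites whose denominator mean is 0 but numerator mean > 0 have no
    finite fold change and form a top block ordered by descending
    numerator mean; metabolites absent from both groups are excluded. Ties
    break lexicographically by metabolite id.
    """
    num_ids = _resolve_selector(matrix, numerator)
    den_ids = _resolve_selector(matrix, denominator)
    if set(num_ids) & set(den_ids):
        raise ValidationError("numerator and denominator samples overlap")
    num_mean = _group_means(matrix, num_ids, missing_as_zero)
    den_mean = _group_means(matrix, den_ids, missing_as_zero)

    top_block, finite = [], []
    for m in matrix.metabolite_ids:
        nm, dm = float(num_mean[m]), float(den_mean[m])
        if dm == 0 and nm == 0:
            continue
        if dm == 0:
            top_block.append((m, nm))
        else:
            finite.append((m, nm / dm))
    top_block.sort(key=lambda t: (-t[1], t[0]))
    finite.sort(key=lambda t: (-t[1], t[0]))

    entries = [RankedEntry(metabolite=m, score=float("nan"), rank=0, fc=None,
                           block="denominator_undetected")
               for m, _ in top_block]
    entries += [RankedEntry(metabolite=m, score=fc, rank=0, fc=fc, block="finite")
                for m, fc in finite]
    for i, e in enumerate(entries):
        e.rank = i + 1
    return RankedList(
        entries=entries, universe_size=len(matrix.metabolite_ids),
        provenance={"comparison": "group_fc", "numerator": numerator,
                    "denominator": denominator,
                    "missing_as_zero": missing_as_zero,
                    "n_numerator": len(num_ids), "n_denominator": len(den_ids)})


def paired_fc_ranked_list(matrix: PeakAreaMatrix, animal: str,
                          t0: str = "baseline", t1: str = "h72") -> RankedList:
    """Per-animal longitudinal ranked list (t1 vs t0), in three blocks.

    Top block: metabolites detected at t1 only, by descending raw t1 peak
    area (no finite fold change exists — the magnitude rule). Middle:
    detected at both timepoints, by descending fold change
    normalized(t1)/normalized(t0). Bottom block: detected at t0 only, by
    descending raw t0 peak area. Metabolites detected at neither timepoint
    are excluded; ranks run 1..N over the concatenation. The list is
    rank-only: downstream scoring uses reversed ranks.
    """
    s0 = matrix.select_samples(animal_id=animal, timepoint=t0)
    s1 = matrix.select_samples(animal_id=animal, timepoint=t1)
    if len(s0) != 1 or len(s1) != 1:
        raise ValidationError(
            f"animal {animal!r} needs exactly one sample at {t0!r} and {t1!r} "
            f"(found {len(s0)} and {len(s1)})")
    v0, v1 = matrix.values[s0[0]], matrix.values[s1[0]]
    raw = matrix.raw_values()
    r0, r1 = raw[s0[0]], raw[s1[0]]

    appeared, both, disappeared = [], [], []
    for m in matrix.metabolite_ids:
        d0, d1 = not pd.isna(v0[m]), not pd.isna(v1[m])
        if d1 and not d0:
            appeared.append((m, float(r1[m])))
        elif d0 and d1:
            both.append((m, float(v1[m]) / float(v0[m])))
        elif d0:
            disappeared.append((m, float(r0[m])))
    appeared.sort(key=lambda t: (-t[1], t[0]))
    both.sort(key=lambda t: (-t[1], t[0]))
    disappeared.sort(key=lambda t: (-t[1], t[0]))

    entries = [RankedEntry(metabolite=m, score=float("nan"), rank=0, fc=None,
                           block="t1_only") for m, _ in appeared]
    entries += [RankedEntry(metabolite=m, score=fc, rank=0, fc=fc, block="both")
                for m, fc in both]
    entries += [RankedEntry(metabolite=m, score=float("nan"), rank=0, fc=None,
                            block="t0_only") for m, _ in disappeared]
    for i, e in enumerate(entries):
        e.rank = i + 1
    return RankedList(
        entries=entries, universe_size=len(matrix.metabolite_ids),
        rank_only=True,
        provenance={"comparison": "paired_fc", "animal": animal,
                    "t0": t0, "t1": t1,
                    "blocks": {"t1_only": len(appeared), "both": len(both),
                               "t0_only": len(disappeared)},
                    "rules": ["t1-only block ranked by raw t1 peak area",
                              "t0-only block mirrored at the bottom by raw t0 peak area"]})


def mean_rank_aggregate(lists: list[RankedList]) -> RankedList:
    """Average each metabolite's rank across per-animal lists.

    A metabolite missing from some lists is averaged over the lists that
    contain it (available-case averaging, flagged in provenance). The
    output is ordered by ascending mean rank — best average rank first —
    and is rank-only for downstream scoring. Ties break lexicographically.
    """
    if not lists:
        raise ValidationError("mean_rank_aggregate needs at least one list")
    if len(lists) < 2:
        raise ValidationError("mean_rank_aggregate needs ≥2 lists")
    ranks: dict[str, list[int]] = {}
    for rl in lists:
        for e in rl.entries:
            ranks.setdefault(e.metabolite, []).append(e.rank)
    items = [(m, float(np.mean(rs)), len(rs)) for m, rs in ranks.items()]
    items.sort(key=lambda t: (t[1], t[0]))
    entries = [RankedEntry(metabolite=m, score=mean_rank, rank=i + 1, fc=None)
               for i, (m, mean_rank, _) in enumerate(items)]
    partial = [m for m, _, c in items if c < len(lists)]
    return RankedList(
        entries=entries, universe_size=max(rl.universe_size for rl in lists),
        rank_only=True,
        provenance={"comparison": "mean_rank_aggregate",
                    "n_lists": len(lists),
                    "inputs": [rl.provenance.get("comparison") for rl in lists],
                    "available_case_metabolites": sorted(partial)})


def build_set_library(lists: dict[str, RankedList], k: int = 35,
                      ) -> MetaboliteSetLibrary:
    """Top-k and bottom-k sets for each named ranked list.

    For a list of length N the sets are ``<name>_top{k}`` (ranks 1..k) and
    ``<name>_bottom{k}`` (ranks N-k+1..N); each list must have ≥ 2k entries
    so the two sets cannot overlap.
    """
    lib = MetaboliteSetLibrary()
    for name, rl in lists.items():
        n = len(rl)
        if n < 2 * k:
            raise ValidationError(
                f"list {name!r} has {n} entries; need ≥ {2 * k} for "
                f"disjoint top/bottom {k}")
        ordered = rl.metabolites
        lib.add(MetaboliteSet(name=f"{name}_top{k}",
                              members=frozenset(ordered[:k]),
                              description=f"ranks 1..{k} of {name}"))
        lib.add(MetaboliteSet(name=f"{name}_bottom{k}",
                              members=frozenset(ordered[-k:]),
                              description=f"ranks {n - k + 1}..{n} of {name}"))
    return lib
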