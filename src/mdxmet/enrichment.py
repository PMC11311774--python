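"""Preranked metabolite-set enrichment: running-sum ES, permutation NES/p/FDR.

The statistic is the weighted Kolmogorov–Smirnov running sum. Walking a
ranked list of N metabolites from top to bottom, encountering a set member
("hit") with score s_i increments the sum by |s_i|^w / Σ_hits|s_j|^w and a
non-member decrements it by 1/(N − k); the enrichment score ES is the
running sum's maximum-magnitude deviation from zero, in [−1, 1]. Positive
ES means the set concentrates at the top of the list.

Significance comes from a size-matched random-set null (the only
permutation scheme available to a preranked list, where sample labels no
longer exist): NES = ES / mean(same-sign null ES), nominal p is the
same-sign null tail fraction with add-one smoothing, and FDR q follows the
tail-ratio recipe over pooled sign-matched null and observed NES values,
clipped to [0, 1] and made monotone within each sign.

Rank-only lists (per-animal longitudinal lists, mean-rank aggregates) are
scored with reversed ranks s_i = N + 1 − rank_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MetaboliteSet, MetaboliteSetLibrary, RankedList

# relative slack for tail counts: ES values from different evaluation orders
# differ in the last few ulps, and a true tie must stay inside the tail
_TIE_TOL = 1e-9


@dataclass
class EnrichmentParams:
    """Knobs for the enrichment engine.

    weight_exponent
        w in |s_i|^w; 1 (weighted, the preranked default) or 0 (classic KS).
    n_permutations
        Random size-matched sets per null; ≥100 required for FDR reporting.
    seed
        Mandatory; null draws are reproducible given (seed, N, set size).
    min_overlap
        Sets overlapping the list in fewer members are flagged NOT_TESTED.
    log2_scores
        Score fold-change lists by |log2 FC| instead of raw FC, preventing a
        single extreme fold change from dominating the weighted sum.
    """

    weight_exponent: float = 1.0
    n_permutations: int = 1000
    seed: int = 0
    min_overlap: int = 1
    log2_scores: bool = False

    def __post_init__(self) -> None:
        if self.weight_exponent < 0:
            raise ValueError("weight_exponent must be ≥ 0")
        if self.n_permutations < 100:
            raise ValueError("need ≥100 permutations for FDR reporting")


@dataclass
class ESResult:
    set_name: str
    es: float
    running_sum: np.ndarray | None = None
    leading_edge: list[str] = field(default_factory=list)
    overlap: int = 0
    not_tested: bool = False


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    leading_edge: list[str] = field(default_factory=list)
    direction: str = "positive"
    overlap: int = 0
    not_tested: bool = False

    def p_text(self, n_perm: int) -> str:
        floor = 2.0 / (n_perm + 1)
        if self.p_nominal <= floor:
            return f"< {1.0 / (n_perm + 1):.2g}"
        return f"{self.p_nominal:.4g}"


def _weights(ranked_list: RankedList, params: EnrichmentParams) -> np.ndarray:
    s = ranked_list.effective_scores()
    if params.log2_scores and not ranked_list.rank_only:
        s = np.log2(np.clip(np.abs(s), 1e-300, None))
    return np.abs(s) ** params.weight_exponent


def _es_of_steps(cumsum: np.ndarray) -> tuple[float, int]:
    j = int(np.argmax(np.abs(cumsum)))
    return float(cumsum[j]), j


def enrichment_score(ranked_list: RankedList, met_set: MetaboliteSet,
                     params: EnrichmentParams) -> ESResult:
    """Running-sum ES of one set against one ranked list.

    Returns the ES, the full running sum (for enrichment plots) and the
    leading edge: hits at or before the extremum for positive ES, at or
    after it for negative ES. A set overlapping the list in fewer than
    ``min_overlap`` members is flagged NOT_TESTED rather than raising.
    """
    names = ranked_list.metabolites
    n = len(names)
    hit = np.fromiter((m in met_set.members for m in names), dtype=bool, count=n)
    k = int(hit.sum())
    if k < params.min_overlap:
        return ESResult(set_name=met_set.name, es=float("nan"),
                        overlap=k, not_tested=True)
    w = _weights(ranked_list, params)
    steps = np.empty(n)
    steps[~hit] = -1.0 / (n - k) if k < n else 0.0
    sw = w[hit].sum()
    steps[hit] = w[hit] / sw if sw > 0 else 1.0 / k
    cs = np.cumsum(steps)
    es, j = _es_of_steps(cs)
    if es >= 0:
        leading = [names[i] for i in range(j + 1) if hit[i]]
    else:
        leading = [names[i] for i in range(j, n) if hit[i]]
    return ESResult(set_name=met_set.name, es=es, running_sum=cs,
                    leading_edge=leading, overlap=k)


def permutation_null(ranked_list: RankedList, set_size: int,
                     params: EnrichmentParams,
                     n_permutations: int | None = None) -> np.ndarray:
    """Sample the ES null for uniformly random size-matched sets.

    Draws are reproducible given (seed, N, set_size): the generator is
    derived from those three values only, so identical lists queried with
    the same seed share identical nulls regardless of naming.
    """
    n = len(ranked_list)
    if not (1 <= set_size <= n):
        raise ValueError(f"set_size must be in 1..{n}")
    n_perm = n_permutations or params.n_permutations
    if set_size == n:
        return np.ones(n_perm)
    rng = np.random.default_rng([abs(int(params.seed)), n, set_size])
    w = _weights(ranked_list, params)

    out = np.empty(n_perm)
    # batch to bound memory at ~30 MB regardless of n_perm
    batch = max(1, min(n_perm, 20000 * 152 // max(n, 1)))
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        # sorted so hit weights accumulate in list order, bit-identical to
        # the scalar path (matters when |peak| and |trough| tie exactly)
        idx = np.sort(np.argpartition(rng.random((b, n)), set_size - 1,
                                      axis=1)[:, :set_size], axis=1)
        steps = np.full((b, n), -1.0 / (n - set_size))
        hw = w[idx]
        sw = hw.sum(axis=1, keepdims=True)
        rows = np.arange(b)[:, None]
        steps[rows, idx] = np.where(sw > 0, hw / np.where(sw > 0, sw, 1.0),
                                    1.0 / set_size)
        cs = np.cumsum(steps, axis=1)
        j = np.argmax(np.abs(cs), axis=1)
        out[done:done + b] = cs[np.arange(b), j]
        done += b
    return out


def nes_p_fdr(observed: dict[str, ESResult],
              nulls: dict[str, np.ndarray]) -> dict[str, EnrichmentResult]:
    """Turn raw ES values plus per-set nulls into NES, nominal p and FDR q.

    NES divides each ES (observed or null) by the mean of the same-sign
    null ES for its set; nominal p is the add-one-smoothed same-sign tail
    fraction. FDR q for a set with normalized score NES* is the ratio of
    the sign-matched pooled-null tail fraction at |NES*| to the observed
    tail fraction at |NES*|, clipped to [0, 1] and made monotone (a
    stronger |NES| never gets a larger q) within each sign.
    """
    results: dict[str, EnrichmentResult] = {}
    norm_obs: dict[str, float] = {}
    pooled_null: list[np.ndarray] = []

    for name, obs in observed.items():
        if obs.not_tested or not np.isfinite(obs.es):
            results[name] = EnrichmentResult(
                set_name=name, es=obs.es, nes=float("nan"), p_nominal=1.0,
                fdr_q=1.0, leading_edge=obs.leading_edge,
                direction="positive", overlap=obs.overlap, not_tested=True)
            continue
        null = np.asarray(nulls[name], dtype=float)
        pos, neg = null[null > 0], null[null < 0]
        mean_pos = pos.mean() if pos.size else float("nan")
        mean_neg_abs = np.abs(neg).mean() if neg.size else float("nan")

        null_nes_parts = []
        if pos.size:
            null_nes_parts.append(pos / mean_pos)
        if neg.size:
            null_nes_parts.append(neg / mean_neg_abs)
        if null_nes_parts:
            pooled_null.append(np.concatenate(null_nes_parts))

        es = obs.es
        if es == 0:
            nes, p, direction = 0.0, 1.0, "positive"
        elif es > 0:
            direction = "positive"
            nes = es / mean_pos if pos.size else float("nan")
            p = (1.0 + (pos >= es - _TIE_TOL * abs(es)).sum()) / \
                (1.0 + pos.size) if pos.size else 1.0
        else:
            direction = "negative"
            nes = es / mean_neg_abs if neg.size else float("nan")
            p = (1.0 + (neg <= es + _TIE_TOL * abs(es)).sum()) / \
                (1.0 + neg.size) if neg.size else 1.0
        results[name] = EnrichmentResult(
            set_name=name, es=es, nes=nes, p_nominal=float(p), fdr_q=1.0,
            leading_edge=obs.leading_edge, direction=direction,
            overlap=obs.overlap, not_tested=not np.isfinite(nes))
        if np.isfinite(nes):
            norm_obs[name] = nes

    if not norm_obs:
        return results
    all_null = np.concatenate(pooled_null) if pooled_null else np.array([])
    obs_arr = np.array(list(norm_obs.values()))

    for sign in (1, -1):
        names = [n for n, v in norm_obs.items() if np.sign(v) == sign
                 or (v == 0 and sign == 1)]
        if not names:
            continue
        null_side = all_null[np.sign(all_null) == sign]
        obs_side = obs_arr[np.sign(obs_arr) == sign]
        raw_q = []
        for n_ in names:
            nes = norm_obs[n_]
            if null_side.size:
                num = (np.abs(null_side) >=
                       abs(nes) * (1 - _TIE_TOL)).sum() / null_side.size
            else:
                num = 0.0
            den = (np.abs(obs_side) >=
                   abs(nes) * (1 - _TIE_TOL)).sum() / max(obs_side.size, 1)
            raw_q.append(min(1.0, num / den) if den > 0 else 1.0)
        # monotone step-up within the sign: q = min over itself and all weaker
        order = np.argsort([-abs(norm_obs[n_]) for n_ in names], kind="stable")
        q_sorted = np.array(raw_q)[order]
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        for pos_i, idx in enumerate(order):
            results[names[idx]].fdr_q = float(q_sorted[pos_i])
    return results


def enrich(ranked_list: RankedList, library: MetaboliteSetLibrary,
           params: EnrichmentParams) -> dict[str, EnrichmentResult]:
    """Query a whole library against one ranked list.

    Nulls are computed once per distinct overlap size and shared across
    sets of that size; FDR is estimated within this query, matching how a
    preranked run handles one .rnk file against one library.
    """
    observed: dict[str, ESResult] = {}
    nulls: dict[str, np.ndarray] = {}
    cache: dict[int, np.ndarray] = {}
    for met_set in library:
        res = enrichment_score(ranked_list, met_set, params)
        observed[met_set.name] = res
        if not res.not_tested:
            if res.overlap not in cache:
                cache[res.overlap] = permutation_null(
                    ranked_list, res.overlap, params)
            nulls[met_set.name] = cache[res.overlap]
    return nes_p_fdr(observed, nulls)


@dataclass
class CrossEnrichment:
    """All-vs-all query results: lists are rows, sets are columns."""

    nes: pd.DataFrame
    fdr: pd.DataFrame
    es: pd.DataFrame
    p: pd.DataFrame
    results: dict[str, dict[str, EnrichmentResult]]

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return (self.fdr <= alpha) & self.nes.notna()


def cross_enrichment_matrix(lists: dict[str, RankedList],
                            library: MetaboliteSetLibrary,
                            params: EnrichmentParams) -> CrossEnrichment:
    """One enrichment query per (ranked list, set) pair.

    Each row of the matrices is an independent library query (its own FDR
    denominator); NOT_TESTED pairs propagate as NaN."""
    results = {name: enrich(rl, library, params) for name, rl in lists.items()}
    set_names = [s.name for s in library]
    def grid(attr):
        return pd.DataFrame(
            {sn: [getattr(results[ln][sn], attr) if not results[ln][sn].not_tested
                  else float("nan") for ln in lists] for sn in set_names},
            index=list(lists))
    return CrossEnrichment(nes=grid("nes"), fdr=grid("fdr_q"),
                           es=grid("es"), p=grid("p_nominal"), results=results)


def results_table(results: dict[str, EnrichmentResult],
                  n_perm: int | None = None) -> pd.DataFrame:
    """Flatten one query's results to a tidy table (one row per set)."""
    rows = []
    for r in results.values():
        rows.append({
            "set_name": r.set_name, "es": r.es, "nes": r.nes,
            "p_nominal": r.p_nominal, "fdr_q": r.fdr_q,
            "direction": r.direction, "overlap": r.overlap,
            "not_tested": r.not_tested,
            "leading_edge": "|".join(r.leading_edge),
        })
    return pd.DataFrame(rows)
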