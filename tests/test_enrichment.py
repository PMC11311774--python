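"""The running-sum enrichment engine against independent oracles:
hand-derived running sums, exhaustive set enumeration, a symmetry
argument for the unweighted statistic, and gseapy's preranked ES."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from mdxmet import (
    EnrichmentParams,
    MetaboliteSet,
    MetaboliteSetLibrary,
    cross_enrichment_matrix,
    enrich,
    enrichment_score,
    nes_p_fdr,
    permutation_null,
)
from mdxmet.enrichment import ESResult

from conftest import ranked_from_scores


def exhaustive_es(scores: np.ndarray, hit_idx: tuple[int, ...],
                  w: float = 1.0) -> float:
    """Straight-line re-derivation of the running-sum ES for one hit set."""
    n = len(scores)
    hits = set(hit_idx)
    nr = sum(abs(scores[i]) ** w for i in hits)
    miss_step = 1.0 / (n - len(hits)) if len(hits) < n else 0.0
    run, best = 0.0, 0.0
    for i in range(n):
        if i in hits:
            run += abs(scores[i]) ** w / nr
        else:
            run -= miss_step
        if abs(run) > abs(best):
            best = run
    return best


def _params(**kw):
    kw.setdefault("seed", 11)
    return EnrichmentParams(**kw)


def _list(n, rng=None, rank_only=False):
    rng = rng or np.random.default_rng(3)
    scores = np.sort(rng.uniform(0.2, 10, n))[::-1]
    return ranked_from_scores(
        {f"m{i:02d}": float(scores[i]) for i in range(n)}, rank_only=rank_only)


class TestEnrichmentScore:
    def test_hand_derived_running_sum_five_metabolites(self):
        rl = ranked_from_scores({f"m{i + 1}": float(5 - i) for i in range(5)})
        res = enrichment_score(rl, MetaboliteSet("s", {"m1", "m3"}), _params())
        np.testing.assert_allclose(
            res.running_sum, [0.625, 0.625 - 1 / 3, 2 / 3, 1 / 3, 0.0],
            atol=1e-12)
        assert res.es == pytest.approx(2 / 3)
        assert res.leading_edge == ["m1", "m3"]

    @pytest.mark.parametrize("w", [0.0, 1.0])
    def test_own_top_k_scores_plus_one_and_bottom_k_minus_one(self, w, rng):
        rl = _list(40, rng)
        ordered = rl.metabolites
        top = MetaboliteSet("top", set(ordered[:8]))
        bottom = MetaboliteSet("bottom", set(ordered[-8:]))
        p = _params(weight_exponent=w)
        assert enrichment_score(rl, top, p).es == pytest.approx(1.0)
        assert enrichment_score(rl, bottom, p).es == pytest.approx(-1.0)

    def test_matches_straight_line_oracle_on_random_sets(self, rng):
        rl = _list(25, rng)
        scores = rl.scores()
        names = rl.metabolites
        for _ in range(25):
            idx = tuple(rng.choice(25, size=rng.integers(1, 10), replace=False))
            met_set = MetaboliteSet("s", {names[i] for i in idx})
            mine = enrichment_score(rl, met_set, _params()).es
            assert mine == pytest.approx(exhaustive_es(scores, idx))

    def test_negative_es_leading_edge_is_at_or_after_the_extremum(self):
        rl = ranked_from_scores({f"m{i}": float(10 - i) for i in range(10)})
        met_set = MetaboliteSet("s", {"m8", "m9"})
        res = enrichment_score(rl, met_set, _params())
        assert res.es < 0
        assert res.leading_edge == ["m8", "m9"]

    def test_zero_overlap_is_flagged_not_tested(self):
        rl = _list(10)
        res = enrichment_score(rl, MetaboliteSet("s", {"absent"}), _params())
        assert res.not_tested and np.isnan(res.es)

    def test_reversing_the_list_flips_the_sign_unweighted(self, rng):
        rl = _list(30, rng)
        flipped = ranked_from_scores(
            {e.metabolite: -e.score for e in rl.entries})
        p = _params(weight_exponent=0.0)
        for _ in range(10):
            members = set(rng.choice(rl.metabolites, 6, replace=False))
            s = MetaboliteSet("s", members)
            assert enrichment_score(rl, s, p).es == pytest.approx(
                -enrichment_score(flipped, s, p).es)

    def test_es_always_within_unit_interval(self, rng):
        rl = _list(50, rng)
        for _ in range(50):
            members = set(rng.choice(rl.metabolites,
                                     rng.integers(1, 50), replace=False))
            es = enrichment_score(rl, MetaboliteSet("s", members), _params()).es
            assert -1.0 <= es <= 1.0

    def test_agrees_with_gseapy_prerank_es(self, rng):
        gp = pytest.importorskip("gseapy")
        import pandas as pd
        rl = _list(60, rng)
        sets = {f"s{j}": set(rng.choice(rl.metabolites, 10, replace=False))
                for j in range(3)}
        rnk = pd.DataFrame({"gene": rl.metabolites, "score": rl.scores()})
        res = gp.prerank(rnk=rnk, gene_sets={k: sorted(v) for k, v in sets.items()},
                         permutation_num=10, seed=1, min_size=1, max_size=100,
                         outdir=None, no_plot=True, weight=1.0, threads=1)
        theirs = dict(zip(res.res2d["Term"], res.res2d["ES"].astype(float)))
        for name, members in sets.items():
            mine = enrichment_score(rl, MetaboliteSet(name, members),
                                    _params()).es
            assert mine == pytest.approx(theirs[name], abs=1e-9)


class TestPermutationNull:
    def test_fixed_seed_reproduces_draws(self):
        rl = _list(20)
        a = permutation_null(rl, 5, _params(seed=42), n_permutations=500)
        b = permutation_null(rl, 5, _params(seed=42), n_permutations=500)
        np.testing.assert_array_equal(a, b)

    def test_unweighted_null_is_centred_at_zero(self):
        rl = _list(10)
        draws = permutation_null(rl, 5, _params(weight_exponent=0.0),
                                 n_permutations=10_000)
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert abs(draws.mean()) < 3 * se

    def test_full_size_set_degenerates_to_all_ones(self):
        rl = _list(8)
        draws = permutation_null(rl, 8, _params(), n_permutations=200)
        np.testing.assert_array_equal(draws, np.ones(200))


class TestNesPFdr:
    def test_observed_equal_to_largest_null_gets_add_one_p(self):
        null = np.concatenate([np.linspace(0.05, 0.5, 100),
                               -np.linspace(0.05, 0.5, 100)])
        obs = {"s": ESResult(set_name="s", es=0.5, leading_edge=[], overlap=3)}
        res = nes_p_fdr(obs, {"s": null})["s"]
        assert res.p_nominal == pytest.approx(2 / 101)
        assert res.nes == pytest.approx(0.5 / null[null > 0].mean())

    def test_single_set_fdr_matches_direct_tail_ratio(self):
        rng = np.random.default_rng(5)
        null = rng.normal(0, 0.2, 1000)
        es = 0.45
        res = nes_p_fdr({"s": ESResult("s", es=es, overlap=4)}, {"s": null})["s"]
        pos = null[null > 0]
        null_nes = pos / pos.mean()
        obs_nes = es / pos.mean()
        # with one observed set the denominator tail fraction is 1
        expected = min(1.0, (null_nes >= obs_nes).mean() / 1.0)
        # pooled null also contains the normalized negative side
        neg = null[null < 0]
        pooled = np.concatenate([null_nes, neg / np.abs(neg).mean()])
        expected = min(1.0, (pooled[pooled > 0] >= obs_nes).mean())
        assert res.fdr_q == pytest.approx(expected)

    def test_zero_es_maps_to_zero_nes(self):
        res = nes_p_fdr({"s": ESResult("s", es=0.0, overlap=2)},
                        {"s": np.array([0.3, -0.2, 0.1])})["s"]
        assert res.nes == 0.0 and res.p_nominal == 1.0

    def test_fdr_is_monotone_within_sign(self, rng):
        rl = _list(60, rng)
        lib = MetaboliteSetLibrary()
        for j in range(8):
            lib.add(MetaboliteSet(
                f"s{j}", set(rng.choice(rl.metabolites, 10, replace=False))))
        results = enrich(rl, lib, _params(n_permutations=300))
        rows = [(r.nes, r.fdr_q) for r in results.values()
                if np.isfinite(r.nes)]
        for sign in (1, -1):
            side = sorted(((abs(n), q) for n, q in rows if np.sign(n) == sign),
                          reverse=True)
            qs = [q for _, q in side]
            assert qs == sorted(qs)
            assert all(0 <= q <= 1 for q in qs)


class TestCrossEnrichment:
    def test_diagonal_self_enrichment_is_maximal_and_significant(self, rng):
        lists = {f"l{j}": _list(80, np.random.default_rng(j)) for j in range(3)}
        lib = MetaboliteSetLibrary()
        for name, rl in lists.items():
            lib.add(MetaboliteSet(f"{name}_top", set(rl.metabolites[:15])))
        cross = cross_enrichment_matrix(lists, lib, _params())
        for name in lists:
            assert cross.es.loc[name, f"{name}_top"] == pytest.approx(1.0)
            assert cross.nes.loc[name, f"{name}_top"] > 0
            assert cross.fdr.loc[name, f"{name}_top"] <= 0.05

    def test_identical_lists_give_identical_rows(self, rng):
        rl = _list(50, rng)
        twin = ranked_from_scores(
            {e.metabolite: e.score for e in rl.entries})
        lib = MetaboliteSetLibrary()
        lib.add(MetaboliteSet("top", set(rl.metabolites[:10])))
        lib.add(MetaboliteSet("mid", set(rl.metabolites[20:30])))
        cross = cross_enrichment_matrix({"a": rl, "b": twin}, lib, _params())
        np.testing.assert_array_equal(cross.nes.loc["a"].to_numpy(),
                                      cross.nes.loc["b"].to_numpy())
        np.testing.assert_array_equal(cross.fdr.loc["a"].to_numpy(),
                                      cross.fdr.loc["b"].to_numpy())


class TestNullCalibration:
    def test_nominal_p_is_uniform_under_random_sets(self):
        """KS check of p against uniform over replicate random queries."""
        rng = np.random.default_rng(99)
        n, k, n_perm, reps = 40, 5, 499, 1000
        pvals = []
        for r in range(reps):
            scores = np.sort(rng.uniform(0.2, 5, n))[::-1]
            rl = ranked_from_scores(
                {f"m{i:02d}": float(scores[i]) for i in range(n)})
            members = set(rng.choice(rl.metabolites, k, replace=False))
            p = _params(seed=int(rng.integers(2 ** 31)), n_permutations=n_perm)
            obs = enrichment_score(rl, MetaboliteSet("s", members), p)
            null = permutation_null(rl, k, p)
            res = nes_p_fdr({"s": obs}, {"s": null})["s"]
            pvals.append(res.p_nominal)
        stat = stats.kstest(pvals, "uniform").statistic
        assert stat < 1.63 / math.sqrt(reps)  # alpha = 0.01 critical value

    def test_small_null_library_fdr_rate_is_controlled(self, rng):
        """Light version of the global-null FDR calibration (the full 500
        library run lives in the acceptance suite)."""
        hits = 0
        total = 0
        for lib_i in range(60):
            r = np.random.default_rng(1000 + lib_i)
            rl = _list(60, r)
            lib = MetaboliteSetLibrary()
            for j in range(12):
                size = int(r.integers(5, 15))
                lib.add(MetaboliteSet(
                    f"s{j}", set(r.choice(rl.metabolites, size, replace=False))))
            results = enrich(rl, lib, _params(seed=lib_i, n_permutations=200))
            hits += sum(res.fdr_q <= 0.05 for res in results.values())
            total += len(results)
        assert hits / total <= 0.10
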