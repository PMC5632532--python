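import itertools
import math

import numpy as np
import pytest
from scipy import stats

from clonepop.clonal import (
    allele_distance,
    assign_mlg,
    clonal_indices,
    clonal_partition,
    clonal_richness,
    collapse_mll,
    estimate_allele_freqs,
    evenness_v,
    fit_pareto_beta,
    p_gen,
    p_sex,
    pairwise_allele_distances,
    simpson_complement,
)
from clonepop.simulate import SimConfig, simulate_dataset

from conftest import make_table, random_table


# ---------------------------------------------------------------------------
# oracles


def multiset_distance_oracle(ga, gb):
    """Brute-force allele distance: per locus, 2 - |multiset intersection|."""
    total = 0
    for (a1, a2), (b1, b2) in zip(ga, gb):
        if a1 == 0 and b1 == 0:
            continue
        if a1 == 0 or b1 == 0:
            total += 2
            continue
        a, b = [a1, a2], [b1, b2]
        inter = 0
        for x in a:
            if x in b:
                b.remove(x)
                inter += 1
        total += 2 - inter
    return total


def components_oracle(dist, threshold):
    """Connected components by BFS over the <=threshold graph."""
    n = dist.shape[0]
    seen, comps = set(), []
    for s in range(n):
        if s in seen:
            continue
        comp, stack = set(), [s]
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(u for u in range(n) if dist[v, u] <= threshold and u not in comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


def simpson_pair_oracle(counts):
    """P(two distinct sampled ramets are different genets), all pairs."""
    labels = [g for g, c in enumerate(counts) for _ in range(c)]
    pairs = list(itertools.combinations(range(len(labels)), 2))
    diff = sum(1 for i, j in pairs if labels[i] != labels[j])
    return diff / len(pairs)


def partitions(n, maxpart=None):
    """All integer partitions of n (descending)."""
    maxpart = maxpart or n
    if n == 0:
        yield []
        return
    for k in range(min(n, maxpart), 0, -1):
        for rest in partitions(n - k, k):
            yield [k] + rest


# ---------------------------------------------------------------------------
# MLG assignment


class TestAssignMlg:
    def test_identical_genotypes_share_mlg(self):
        t = make_table([[(101, 105), (200, 203)], [(105, 101), (203, 200)]])
        mlg = assign_mlg(t)
        assert mlg[0] == mlg[1]

    def test_missing_blocks_identity(self):
        t = make_table([[(101, 105), (200, 203)], [(101, 105), (0, 0)]])
        assert assign_mlg(t)[0] != assign_mlg(t)[1]

    def test_shared_missing_still_distinct_mlgs(self):
        # missing matches nothing, not even another missing call
        t = make_table([[(101, 105), (0, 0)], [(101, 105), (0, 0)]])
        mlg = assign_mlg(t)
        assert mlg[0] != mlg[1]

    def test_error_free_clone_is_one_mlg(self):
        cfg = SimConfig(seed=9, n_pops=1, genets_per_pop=6, ramets_per_pop=24,
                        clone_size_law=("dominant", 19))
        t, truth = simulate_dataset(cfg)
        mlg = assign_mlg(t)
        genet = np.array(truth.genet_of)
        dominant = genet == genet[0]
        assert len(np.unique(mlg[dominant])) == 1
        assert dominant.sum() == 19

    def test_first_appearance_order(self):
        t = make_table([[(105, 105)], [(101, 101)], [(105, 105)]])
        assert assign_mlg(t).tolist() == [0, 1, 0]


# ---------------------------------------------------------------------------
# distances


class TestAlleleDistance:
    @pytest.mark.parametrize(
        "ga, gb, expected",
        [
            ([(101, 105)], [(101, 105)], 0),
            ([(101, 105)], [(101, 107)], 1),
            ([(101, 105)], [(107, 109)], 2),
            ([(101, 101)], [(101, 105)], 1),
            ([(101, 101)], [(105, 105)], 2),
            ([(101, 105), (200, 200)], [(101, 107), (200, 203)], 2),
            ([(0, 0)], [(101, 105)], 2),
            ([(0, 0)], [(0, 0)], 0),
        ],
    )
    def test_known_cases(self, ga, gb, expected):
        assert allele_distance(ga, gb) == expected

    def test_matches_multiset_oracle_on_random_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(300):
            ga = np.sort(rng.integers(0, 4, size=(5, 2)), axis=1) * 2 + 100
            gb = np.sort(rng.integers(0, 4, size=(5, 2)), axis=1) * 2 + 100
            if rng.random() < 0.3:
                ga[rng.integers(5)] = 0
            if rng.random() < 0.3:
                gb[rng.integers(5)] = 0
            assert allele_distance(ga, gb) == multiset_distance_oracle(ga, gb)

    def test_pairwise_matrix_matches_scalar(self):
        rng = np.random.default_rng(5)
        g = np.sort(rng.integers(1, 5, size=(8, 4, 2)), axis=2) * 3 + 100
        g[2, 1] = 0
        d = pairwise_allele_distances(g)
        for i in range(8):
            for j in range(8):
                assert d[i, j] == allele_distance(g[i], g[j])

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            allele_distance([(101, 105)], [(101, 105), (200, 200)])


class TestCollapseMll:
    def test_transitive_chain_merges(self):
        # d(A,B)=1, d(B,C)=1, d(A,C)=2 -> single MLL by chaining
        t = make_table(
            [[(101, 105), (200, 200)],
             [(101, 107), (200, 200)],
             [(107, 107), (200, 200)]],
        )
        d = pairwise_allele_distances(t.alleles)
        assert (d[0, 1], d[1, 2], d[0, 2]) == (1, 1, 2)
        mll = collapse_mll(t, assign_mlg(t))
        assert len(set(mll.values())) == 1

    def test_all_distances_over_threshold_no_merge(self):
        t = make_table([[(101, 101), (200, 200)], [(105, 105), (206, 206)]])
        mll = collapse_mll(t, assign_mlg(t))
        assert len(set(mll.values())) == 2

    def test_matches_components_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(40):
            t = random_table(rng, n=10, n_loci=3, n_alleles=3)
            mlg = assign_mlg(t)
            mll = collapse_mll(t, mlg)
            # oracle over MLG representatives
            ids = np.unique(mlg)
            reps = [int(np.nonzero(mlg == g)[0][0]) for g in ids]
            d = pairwise_allele_distances(t.alleles[reps])
            expected = components_oracle(d, 1)
            got = {}
            for k, g in enumerate(ids):
                got.setdefault(mll[int(g)], set()).add(k)
            assert {frozenset(v) for v in got.values()} == expected

    def test_recovers_simulated_genets_with_injected_errors(self, paper_bundle):
        for name, (t, truth) in paper_bundle.items():
            part = clonal_partition(t)
            assert part.n_mll == truth.n_genets(), name
            # MLLs must coincide with the true genet partition
            mll = part.mll_per_individual
            genet = np.array(truth.genet_of)
            assert len(np.unique(mll)) == len(np.unique(genet))
            for m in np.unique(mll):
                assert len(np.unique(genet[mll == m])) == 1


# ---------------------------------------------------------------------------
# allele frequencies, p_gen, p_sex


class TestAlleleFreqs:
    def test_per_genet_counts(self):
        t = make_table([[(101, 101)], [(101, 105)]])
        f = estimate_allele_freqs(t, "per_genet")
        assert f["L1"] == {101: 0.75, 105: 0.25}

    def test_round_robin_matches_hand_enumeration(self):
        # A and C identical everywhere; B distinct.  Excluding any one locus
        # leaves two unique genotypes {A,C} and {B}, so frequencies at each
        # locus count A and B once: 3/4 vs 1/4.
        t = make_table(
            [[(101, 103), (203, 203), (305, 307)],
             [(101, 101), (203, 205), (305, 305)],
             [(101, 103), (203, 203), (305, 307)]],
        )
        f = estimate_allele_freqs(t, "round_robin")
        assert f["L1"] == {101: 0.75, 103: 0.25}
        assert f["L2"] == {203: 0.75, 205: 0.25}
        assert f["L3"] == {305: 0.75, 307: 0.25}

    def test_per_ramet_differs_under_dominant_clone(self):
        calls = [[(101, 101)]] * 5 + [[(105, 105)]]
        t = make_table(calls)
        ramet = estimate_allele_freqs(t, "per_ramet")
        genet = estimate_allele_freqs(t, "per_genet")
        assert ramet["L1"][101] == pytest.approx(10 / 12)
        assert genet["L1"][101] == pytest.approx(0.5)

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(8)
        t = random_table(rng, n=20, missing_rate=0.1)
        for scheme in ("per_genet", "round_robin", "per_ramet"):
            for locus, f in estimate_allele_freqs(t, scheme).items():
                if f:
                    assert sum(f.values()) == pytest.approx(1.0)


class TestPGen:
    def test_homozygote_fixed_allele(self):
        assert p_gen(np.array([[101, 101]]), {"L1": {101: 1.0}}, ("L1",)) == 1.0

    def test_heterozygote_closed_forms(self):
        freqs = {"L1": {101: 0.5, 105: 0.5}}
        g = np.array([[101, 105]])
        assert p_gen(g, freqs, ("L1",), f_is=0.0) == pytest.approx(0.5)
        assert p_gen(g, freqs, ("L1",), f_is=1.0) == 0.0

    def test_inbreeding_raises_homozygote_probability(self):
        freqs = {"L1": {101: 0.25, 105: 0.75}}
        g = np.array([[101, 101]])
        assert p_gen(g, freqs, ("L1",), f_is=0.5) == pytest.approx(
            0.25**2 + 0.25 * 0.75 * 0.5
        )

    def test_three_locus_product_matches_hand_enumeration(self):
        freqs = {
            "L1": {101: 0.5, 103: 0.5},
            "L2": {203: 0.25, 205: 0.75},
            "L3": {305: 1.0},
        }
        g = np.array([[101, 103], [205, 205], [305, 305]])
        expected = (2 * 0.5 * 0.5) * (0.75**2) * 1.0
        assert p_gen(g, freqs, ("L1", "L2", "L3")) == pytest.approx(expected)

    def test_missing_locus_skipped(self):
        freqs = {"L1": {101: 0.5, 103: 0.5}, "L2": {205: 1.0}}
        g = np.array([[101, 103], [0, 0]])
        assert p_gen(g, freqs, ("L1", "L2")) == pytest.approx(0.5)

    def test_unknown_allele_raises(self):
        with pytest.raises(KeyError):
            p_gen(np.array([[101, 101]]), {"L1": {105: 1.0}}, ("L1",))


class TestPSex:
    def test_degenerate_pgen(self):
        assert p_sex(0.0, 2, 24) == 0.0
        assert p_sex(1.0, 2, 24) == 1.0

    def test_monotone_in_pgen_and_repeats(self):
        grid = np.linspace(0.001, 0.999, 25)
        vals = [p_sex(p, 3, 24) for p in grid]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        by_repeats = [p_sex(0.05, r, 24) for r in range(2, 10)]
        assert all(b <= a for a, b in zip(by_repeats, by_repeats[1:]))

    def test_matches_binomial_monte_carlo(self):
        rng = np.random.default_rng(12)
        for pg, n_rep, n in [(0.01, 2, 24), (0.2, 3, 24), (0.05, 2, 50)]:
            exact = p_sex(pg, n_rep, n)
            draws = rng.binomial(n - 1, pg, size=200_000)
            mc = float((draws >= n_rep - 1).mean())
            se = math.sqrt(max(exact * (1 - exact), 1e-12) / 200_000)
            assert abs(mc - exact) <= 4 * se + 1e-9

    def test_binomial_n_convention(self):
        assert p_sex(0.1, 2, 10, convention="binomial-n") == pytest.approx(
            float(stats.binom.sf(1, 10, 0.1))
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            p_sex(1.5, 2, 10)
        with pytest.raises(ValueError):
            p_sex(0.5, 1, 10)
        with pytest.raises(ValueError):
            p_sex(0.5, 5, 4)


# ---------------------------------------------------------------------------
# clonal indices


class TestRichness:
    @pytest.mark.parametrize(
        "g, n, expected",
        [(13, 23, 0.55), (6, 24, 0.22), (5, 24, 0.17), (3, 24, 0.09)],
    )
    def test_study_values_round_to_printed(self, g, n, expected):
        assert round(clonal_richness(g, n), 2) == expected

    def test_bounds(self):
        assert clonal_richness(24, 24) == 1.0
        assert clonal_richness(1, 24) == 0.0

    def test_invalid(self):
        with pytest.raises(ValueError):
            clonal_richness(3, 1)
        with pytest.raises(ValueError):
            clonal_richness(25, 24)


class TestSimpson:
    def test_dominant_configuration_equals_dmin(self):
        d, d_min, d_max = simpson_complement([19, 1, 1, 1, 1, 1])
        assert d == pytest.approx(1 - 342 / 552)
        assert d == pytest.approx(d_min)

    def test_equal_counts_equal_dmax(self):
        d, _, d_max = simpson_complement([4, 4, 4])
        assert d == pytest.approx(d_max)

    def test_exhaustive_pair_enumeration_oracle(self):
        # every integer partition of every N <= 12
        for n in range(2, 13):
            for counts in partitions(n):
                d, d_min, d_max = simpson_complement(counts)
                assert d == pytest.approx(simpson_pair_oracle(counts), abs=1e-12)
                assert d_min - 1e-12 <= d <= d_max + 1e-12

    def test_invalid(self):
        with pytest.raises(ValueError):
            simpson_complement([])
        with pytest.raises(ValueError):
            simpson_complement([0, 3])


class TestEvenness:
    def test_dominant_clone_gives_zero(self):
        assert evenness_v([19, 1, 1, 1, 1, 1]) == 0.0

    def test_equal_clones_give_one(self):
        assert evenness_v([8, 8, 8]) == 1.0

    def test_intermediate_matches_direct_formula(self):
        counts = [14, 4, 3, 2, 1]
        d, d_min, d_max = simpson_complement(counts)
        v = evenness_v(counts)
        assert 0 < v < 1
        assert v == pytest.approx((d - d_min) / (d_max - d_min))

    def test_single_genet_undefined(self):
        assert math.isnan(evenness_v([24]))

    def test_permutation_invariant(self):
        assert evenness_v([14, 4, 3, 2, 1]) == evenness_v([1, 3, 14, 2, 4])


class TestParetoBeta:
    def test_recovers_power_law_slope(self):
        rng = np.random.default_rng(3)
        est = [fit_pareto_beta(rng.zipf(2.5, size=500)) for _ in range(5)]
        assert abs(float(np.mean(est)) - 1.5) < 0.2

    def test_too_few_distinct_sizes_undefined(self):
        assert math.isnan(fit_pareto_beta([4, 4, 4]))
        assert math.isnan(fit_pareto_beta([19, 1, 1, 1, 1, 1]))  # 2 distinct sizes

    def test_deterministic(self):
        counts = [10, 6, 4, 3, 2, 2, 1, 1, 1]
        assert fit_pareto_beta(counts) == fit_pareto_beta(list(counts))


# ---------------------------------------------------------------------------
# assembled partition invariants


class TestPartitionInvariants:
    def test_partition_refinement(self, paper_bundle):
        for name, (t, truth) in paper_bundle.items():
            part = clonal_partition(t)
            assert part.n_mll <= part.n_mlg <= part.n_individuals
            assert int(part.ramet_counts.sum()) == part.n_individuals
            # every MLL is a union of MLGs
            mll = part.mll_per_individual
            for g in np.unique(part.mlg_of):
                members = mll[part.mlg_of == g]
                assert len(np.unique(members)) == 1

    def test_psex_values_in_unit_interval(self, paper_bundle):
        t, _ = paper_bundle["Tc-IGB"]
        part = clonal_partition(t)
        assert part.psex_of  # the dominant clone repeats
        assert all(0.0 <= v <= 1.0 for v in part.psex_of.values())

    def test_richness_invariant_to_individual_order(self):
        rng = np.random.default_rng(13)
        t = random_table(rng, n=15, n_loci=4, n_alleles=3)
        perm = rng.permutation(t.n_individuals)
        t2 = t.take_individuals(list(perm))
        a = clonal_indices(clonal_partition(t))
        b = clonal_indices(clonal_partition(t2))
        assert a.n_mll == b.n_mll
        assert a.richness == b.richness
        assert a.evenness == pytest.approx(b.evenness)
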