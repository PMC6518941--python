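"""Karyotype calling, bootstrap test, HWE exact test, combination census."""

from math import comb, lgamma

import numpy as np
import pandas as pd
import pytest

from fjordflow import inversions, synthdata
from fjordflow.inversions import InversionRegion, KaryotypeCall

from conftest import make_matrix


def _simulated_inversion(freq=0.3, divergence=0.4, n_snps=500, n_ind=200, seed=1):
    spec = synthdata.InversionSpec("LG02", 1_000, 1_000_000, [freq], pool_divergence=divergence)
    calls, pos, states = synthdata.simulate_inversion_region(spec, [n_ind], seed=seed, n_snps=n_snps)
    g = make_matrix(calls, pos=pos, pops=["P"] * n_ind, chrom="LG02")
    return g, states


class TestRegionPca:
    def test_degenerate_region_raises(self):
        g = make_matrix(np.ones((5, 3)), chrom="LG02")
        with pytest.raises(ValueError):
            inversions.region_pca(g, InversionRegion("LG02", 1, 10_000))

    def test_pc1_dominates_for_segregating_inversion(self):
        g, _ = _simulated_inversion()
        _, explained = inversions.region_pca(g, InversionRegion("LG02", 1, 1_000_000))
        assert explained[0] > 3 * explained[1]

    def test_three_pc1_clusters(self):
        g, states = _simulated_inversion()
        scores, _ = inversions.region_pca(g, InversionRegion("LG02", 1, 1_000_000))
        pc1 = scores[:, 0]
        # truth-group separation: the three karyotype classes occupy
        # disjoint PC1 intervals with heterozygotes intermediate
        lo = max(pc1[states == s].max() for s in ("anc", "inv") if (states == s).any())
        centers = sorted(pc1[states == s].mean() for s in ("anc", "het", "inv"))
        assert centers[0] < pc1[states == "het"].mean() < centers[2]
        spread = [pc1[states == s].std() for s in ("anc", "het", "inv")]
        gaps = np.diff(centers)
        assert all(gap > 2 * max(spread) for gap in gaps)


class TestCallKaryotypes:
    def test_monomorphic_region_all_anc(self):
        g, states = _simulated_inversion(freq=0.0, seed=2)
        calls = inversions.call_region(g, InversionRegion("LG02", 1, 1_000_000))
        assert all(c.state == "anc" for c in calls)

    @pytest.mark.parametrize("seed", [3, 13, 23])
    def test_accuracy_against_truth(self, seed):
        # minority inverted arrangement: the majority-homozygote-cluster
        # orientation convention must label states correctly at any seed
        g, states = _simulated_inversion(seed=seed)
        calls = inversions.call_region(g, InversionRegion("LG02", 1, 1_000_000))
        acc = np.mean([c.state == states[i] for i, c in enumerate(calls)])
        assert acc >= 0.95

    def test_het_cluster_most_heterozygous(self):
        g, _ = _simulated_inversion(seed=4)
        calls = inversions.call_region(g, InversionRegion("LG02", 1, 1_000_000))
        het_frac = (g.calls == 1).mean(axis=1)
        by_state = {s: het_frac[[c.state == s for c in calls]].mean() for s in ("anc", "het", "inv")}
        assert by_state["het"] > by_state["anc"] and by_state["het"] > by_state["inv"]

    def test_accuracy_monotone_in_divergence(self):
        accs = []
        for div in (0.1, 0.2, 0.4):
            g, states = _simulated_inversion(divergence=div, seed=5)
            calls = inversions.call_region(g, InversionRegion("LG02", 1, 1_000_000))
            accs.append(np.mean([c.state == states[i] for i, c in enumerate(calls)]))
        assert accs[0] <= accs[1] + 0.05 and accs[1] <= accs[2] + 0.05
        assert accs[2] >= 0.95


class TestArrangementFrequencies:
    def test_all_het_counts(self):
        calls = [KaryotypeCall(f"S{i}", "LG02", "het", 0.0, 1.0) for i in range(10)]
        tab = inversions.arrangement_frequencies(calls, {f"S{i}": "A" for i in range(10)})
        row = tab.iloc[0]
        assert row["anc_chroms"] == 10 and row["inv_chroms"] == 10

    def test_counts_sum_to_2n(self):
        rng = np.random.default_rng(6)
        states = rng.choice(["anc", "het", "inv"], size=50)
        calls = [KaryotypeCall(f"S{i}", "LG02", s, 0.0, 1.0) for i, s in enumerate(states)]
        popmap = {f"S{i}": ("A" if i < 25 else "B") for i in range(50)}
        tab = inversions.arrangement_frequencies(calls, popmap)
        assert ((tab["anc_chroms"] + tab["inv_chroms"]) == 2 * tab["n"]).all()

    def test_unknown_individual_rejected(self):
        calls = [KaryotypeCall("GHOST", "LG02", "anc", 0.0, 1.0)]
        with pytest.raises(ValueError, match="GHOST"):
            inversions.arrangement_frequencies(calls, {"S0": "A"})


def _table(rows):
    df = pd.DataFrame(rows)
    df["n"] = df["anc"] + df["het"] + df["inv"]
    df["anc_chroms"] = 2 * df["anc"] + df["het"]
    df["inv_chroms"] = 2 * df["inv"] + df["het"]
    return df


class TestBootstrapOverrep:
    def test_matches_exact_binomial_tail(self):
        # two balanced populations, pooled q = 0.5, observed 10 of 20
        tab = _table([
            {"population": "A", "region": "LG02", "anc": 5, "het": 0, "inv": 5},
            {"population": "B", "region": "LG02", "anc": 5, "het": 0, "inv": 5},
        ])
        res = inversions.bootstrap_overrep_test(tab, B=200_000, seed=1)
        exact = sum(comb(20, k) * 0.5**20 for k in range(10, 21))  # 0.588...
        mc_se = np.sqrt(exact * (1 - exact) / 200_000)
        for r in res:
            assert r.p_raw == pytest.approx(exact, abs=4 * mc_se)

    def test_extreme_observation_tail(self):
        tab = _table([
            {"population": "A", "region": "LG02", "anc": 10, "het": 0, "inv": 0},
            {"population": "B", "region": "LG02", "anc": 0, "het": 0, "inv": 10},
        ])
        res = inversions.bootstrap_overrep_test(tab, B=1_000_000, seed=2)
        hit = [r for r in res if r.population == "A" and r.arrangement == "anc"][0]
        # P(X >= 20 | n=20, q=0.5) = 0.5^20 ~ 9.5e-7; +1/(B+1) keeps p > 0
        assert 0 < hit.p_raw < 1e-5

    def test_single_population_null(self):
        tab = _table([{"population": "A", "region": "LG02", "anc": 5, "het": 10, "inv": 5}])
        res = inversions.bootstrap_overrep_test(tab, B=10_000, seed=3)
        for r in res:
            # pooled frequency equals the population's own: p near P(X >= E[X])
            assert r.p_raw > 0.3

    def test_bonferroni_family(self):
        tab = _table([
            {"population": "A", "region": "LG02", "anc": 5, "het": 0, "inv": 5},
            {"population": "B", "region": "LG02", "anc": 5, "het": 0, "inv": 5},
        ])
        res = inversions.bootstrap_overrep_test(tab, B=2_000, seed=4)
        assert all(r.family_size == 4 for r in res)
        for r in res:
            assert r.p_bonferroni == pytest.approx(min(1.0, r.p_raw * 4))

    def test_small_b_rejected(self):
        tab = _table([{"population": "A", "region": "LG02", "anc": 5, "het": 0, "inv": 5}])
        with pytest.raises(ValueError):
            inversions.bootstrap_overrep_test(tab, B=500)


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert inversions.hwe_exact(25, 0, 0) == 1.0

    def test_matches_enumeration_oracle(self):
        # independent oracle: direct enumeration of the conditional law
        def oracle(n_aa, n_ab, n_bb):
            n = n_aa + n_ab + n_bb
            nb = n_ab + 2 * n_bb
            na = 2 * n - nb
            rare = min(na, nb)

            def log_prob(h):
                hom_rare = (rare - h) // 2
                hom_common = n - h - hom_rare
                return (h * np.log(2) + lgamma(n + 1)
                        - lgamma(hom_common + 1) - lgamma(h + 1) - lgamma(hom_rare + 1))

            hs = [h for h in range(rare % 2, rare + 1, 2) if (n - h - (rare - h) // 2) >= 0]
            logs = np.array([log_prob(h) for h in hs])
            probs = np.exp(logs - logs.max())
            probs /= probs.sum()
            p_obs = probs[hs.index(n_ab)]
            return probs[probs <= p_obs * (1 + 1e-12)].sum()

        for counts in [(21, 48, 31), (5, 10, 5), (60, 30, 10), (2, 5, 40)]:
            assert inversions.hwe_exact(*counts) == pytest.approx(oracle(*counts), abs=1e-12)

    def test_label_swap_symmetry(self):
        assert inversions.hwe_exact(21, 48, 31) == pytest.approx(
            inversions.hwe_exact(31, 48, 21), abs=1e-12
        )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            inversions.hwe_exact(0, 0, 0)


class TestCombinationCensus:
    def test_enumeration_size_27(self):
        calls = [KaryotypeCall("S0", r, "anc", 0.0, 1.0) for r in ("LG02", "LG07", "LG12")]
        _, n_obs, n_possible = inversions.combination_census(calls, ["LG02", "LG07", "LG12"])
        assert n_possible == 27 and n_obs == 1

    def test_full_coverage(self):
        regions = ["LG02", "LG07", "LG12"]
        calls = []
        i = 0
        for a in ("anc", "het", "inv"):
            for b in ("anc", "het", "inv"):
                for c in ("anc", "het", "inv"):
                    for region, s in zip(regions, (a, b, c)):
                        calls.append(KaryotypeCall(f"S{i}", region, s, 0.0, 1.0))
                    i += 1
        observed, n_obs, _ = inversions.combination_census(calls, regions)
        assert n_obs == 27

    def test_incomplete_individual_excluded(self):
        calls = [KaryotypeCall("S0", "LG02", "anc", 0.0, 1.0)]
        _, n_obs, _ = inversions.combination_census(calls, ["LG02", "LG07", "LG12"])
        assert n_obs == 0


class TestComboCoverage:
    def test_zero_frequency_gives_zero(self):
        freqs = [np.array([1.0, 0.0, 0.0])] * 3
        p, se = inversions.combo_coverage_probability(freqs, N=204, B=1000, seed=1)
        assert p == 0.0

    def test_pigeonhole_zero(self):
        freqs = [np.array([0.25, 0.5, 0.25])] * 3
        p, _ = inversions.combo_coverage_probability(freqs, N=26, B=1000, seed=2)
        assert p == 0.0

    def test_matches_independent_monte_carlo(self):
        freqs = [np.array([0.25, 0.5, 0.25])] * 3
        p, se = inversions.combo_coverage_probability(freqs, N=204, B=40_000, seed=3)

        # independent oracle: multinomial occupancy via inclusion-exclusion
        # bound is loose; use a second, independently seeded MC instead
        rng = np.random.default_rng(987654)
        p_combo = np.kron(np.kron(freqs[0], freqs[1]), freqs[2])
        B2 = 40_000
        hits = 0
        for start in range(0, B2, 2000):
            b = min(2000, B2 - start)
            counts = rng.multinomial(204, p_combo, size=b)
            hits += int((counts > 0).all(axis=1).sum())
        p2 = hits / B2
        se2 = np.sqrt(p2 * (1 - p2) / B2)
        assert p == pytest.approx(p2, abs=3 * np.sqrt(se**2 + se2**2))


class TestAssignGenotypeClass:
    def test_individual_at_centroid(self):
        scores = np.array([[0, 0], [0.1, 0], [10, 0], [10.1, 0], [0.0, 0.05]])
        samples = ["a1", "a2", "b1", "b2", "query"]
        ref = {"a1": "TVEf", "a2": "TVEf", "b1": "TVEn", "b2": "TVEn"}
        out = inversions.assign_genotype_class(scores, samples, ref)
        assert out["query"] == "TVEf"

    def test_equidistant_intermediate(self):
        scores = np.array([[0, 0], [10, 0], [5, 0]])
        out = inversions.assign_genotype_class(
            scores, ["a", "b", "mid"], {"a": "TVEf", "b": "TVEn"}
        )
        assert out["mid"] == "intermediate"

    def test_admixed_mostly_intermediate(self):
        rng = np.random.default_rng(11)
        a = rng.normal([0, 0], 0.5, size=(30, 2))
        b = rng.normal([10, 0], 0.5, size=(30, 2))
        admixed = rng.normal([5, 0], 0.5, size=(20, 2))
        scores = np.vstack([a, b, admixed])
        samples = [f"a{i}" for i in range(30)] + [f"b{i}" for i in range(30)] + [
            f"m{i}" for i in range(20)
        ]
        ref = {f"a{i}": "TVEf" for i in range(30)}
        ref.update({f"b{i}": "TVEn" for i in range(30)})
        out = inversions.assign_genotype_class(scores, samples, ref)
        frac_mid = np.mean([out[f"m{i}"] == "intermediate" for i in range(20)])
        assert frac_mid >= 0.8
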