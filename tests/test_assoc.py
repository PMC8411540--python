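"""Population scans, enrichment, sketch distances, MDS, and phenotype GWAS."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from strainpop import assoc
from strainpop.assoc import (
    SketchConfig,
    enrichment_test,
    filter_variants,
    fisher_exact_greater,
    fisher_exact_twosided,
    mash_distance,
    mds_covariates,
    merge_hits,
    phenotype_gwas,
    population_scan,
)
from strainpop.coresnp import AlignedGenomeSet, DistanceMatrix, encode_bases
from strainpop.errors import ParameterError
from strainpop.popstruct import PopulationAssignment


def fraction_fisher_oracle(a, b, c, d, alternative="two-sided"):
    """Brute-force Fisher p using exact rational arithmetic."""
    row1, row2, col1 = a + b, c + d, a + c
    lo, hi = max(0, col1 - row2), min(row1, col1)
    probs = {k: Fraction(math.comb(row1, k) * math.comb(row2, col1 - k),
                         math.comb(row1 + row2, col1))
             for k in range(lo, hi + 1)}
    if alternative == "greater":
        return float(sum(p for k, p in probs.items() if k >= a))
    obs = probs[a]
    return float(sum(p for p in probs.values() if p <= obs))


class TestFisherExact:
    @given(st.tuples(st.integers(0, 12), st.integers(0, 12),
                     st.integers(0, 12), st.integers(0, 12)))
    def test_matches_rational_enumeration_oracle(self, table):
        a, b, c, d = table
        if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
            return
        assert fisher_exact_twosided(a, b, c, d) == pytest.approx(
            fraction_fisher_oracle(a, b, c, d), abs=1e-12)
        assert fisher_exact_greater(a, b, c, d) == pytest.approx(
            fraction_fisher_oracle(a, b, c, d, "greater"), abs=1e-12)

    def test_scipy_cross_check(self):
        from scipy.stats import fisher_exact
        rng = np.random.default_rng(0)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 15, 4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            assert fisher_exact_twosided(a, b, c, d) == pytest.approx(
                fisher_exact([[a, b], [c, d]])[1], rel=1e-6)


class TestFilterVariants:
    def test_ubiquitous_variant_removed(self):
        m = pd.DataFrame({"v": np.ones(20)})
        assert filter_variants(m, 0.05, 0.95).shape[1] == 0

    def test_ten_percent_variant_kept(self):
        m = pd.DataFrame({"v": [1.0] * 10 + [0.0] * 90})
        assert filter_variants(m, 0.05, 0.95).shape[1] == 1

    def test_bounds_are_exclusive(self):
        m = pd.DataFrame({"v": [1.0] * 5 + [0.0] * 95})
        assert filter_variants(m, 0.05, 0.95).shape[1] == 0  # exactly 5%

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ParameterError):
            filter_variants(pd.DataFrame({"v": [0, 1]}), 0.5, 0.5)


class TestPopulationScan:
    @staticmethod
    def _assignment(n1=10, n2=10):
        labels = {f"s{i}": ("A" if i < n1 else "B") for i in range(n1 + n2)}
        return PopulationAssignment(labels)

    def test_perfectly_separating_variant(self):
        v = pd.DataFrame({"v": [1] * 10 + [0] * 10},
                         index=[f"s{i}" for i in range(20)])
        res = population_scan(v, self._assignment(), "A")
        assert res.loc[0, "p"] == pytest.approx(2 / math.comb(20, 10), abs=1e-15)
        # significant whenever the Bonferroni family has m <= 4600 variants
        assert res.loc[0, "p"] < 0.05 / 4600
        assert bool(res.loc[0, "significant"])

    def test_equal_carriage_gives_p_one(self):
        v = pd.DataFrame({"v": [1] * 5 + [0] * 5 + [1] * 5 + [0] * 5},
                         index=[f"s{i}" for i in range(20)])
        res = population_scan(v, self._assignment(), "A")
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_strain_order_and_label_swap_invariance(self):
        rng = np.random.default_rng(1)
        idx = [f"s{i}" for i in range(20)]
        v = pd.DataFrame(rng.integers(0, 2, (20, 4)), index=idx,
                         columns=list("wxyz"))
        res1 = population_scan(v, self._assignment(), "A")
        res2 = population_scan(v.iloc[::-1], self._assignment(), "A")
        assert np.allclose(res1["p"], res2["p"])
        res3 = population_scan(1 - v, self._assignment(), "A")
        assert np.allclose(res1["p"], res3["p"], atol=1e-12)
        assert np.allclose(res1["log_odds"], -res3["log_odds"], atol=1e-12)

    def test_missing_population_rejected(self):
        v = pd.DataFrame({"v": [0, 1]}, index=["s0", "s10"])
        with pytest.raises(ParameterError):
            population_scan(v, self._assignment(), "Z")


class TestMergeHits:
    def _result(self, pop, variants, ps=None):
        return pd.DataFrame({
            "variant": variants, "population": pop,
            "p": ps or [1e-9] * len(variants),
            "significant": [True] * len(variants)})

    def test_disjoint_sets_union(self):
        merged = merge_hits([self._result("A", ["v1", "v2", "v3"]),
                             self._result("B", ["v4", "v5"]),
                             self._result("C", ["v6"])])
        assert len(merged) == 6

    def test_shared_variant_tagged_twice(self):
        merged = merge_hits([self._result("A", ["v1"]), self._result("B", ["v1"])])
        assert len(merged) == 1
        assert merged.loc[0, "populations"] == "A,B"

    def test_empty_inputs(self):
        assert merge_hits([pd.DataFrame(columns=["variant", "population",
                                                 "p", "significant"])]).empty


class TestEnrichment:
    @staticmethod
    def _annotation(n=100, term_size=5):
        genes = [f"g{i}" for i in range(n)]
        cogs = ["G" if i < term_size else "J" for i in range(n)]
        return pd.DataFrame({"gene_id": genes, "cog": cogs,
                             "kegg": ["ko00010"] * n}).set_index("gene_id", drop=False)

    def test_bonferroni_threshold_value(self):
        ann = self._annotation()
        res = enrichment_test(["g0"], ann, list(ann.index))
        assert res["threshold"].iloc[0] == pytest.approx(0.01 / 220)

    def test_all_hits_in_small_term(self):
        ann = self._annotation(100, 5)
        hits = [f"g{i}" for i in range(5)]
        res = enrichment_test(hits, ann, list(ann.index))
        row = res[(res["kind"] == "COG") & (res["term"] == "G")].iloc[0]
        assert row["p"] == pytest.approx(1 / math.comb(100, 5), rel=1e-9)
        assert row["significant"]

    def test_proportional_hits_not_enriched(self):
        ann = self._annotation(100, 50)
        hits = [f"g{i}" for i in range(45, 55)]  # 5 in-term, 5 out
        res = enrichment_test(hits, ann, list(ann.index))
        assert not res["significant"].any()

    def test_hits_outside_background_dropped(self):
        ann = self._annotation(10, 2)
        res = enrichment_test(["g0", "unknown"], ann, list(ann.index))
        assert (res["n_hits"] == 1).all()


class TestMashDistance:
    @staticmethod
    def _genomes(seqs):
        ids = list(seqs)
        return AlignedGenomeSet(ids, ids[0],
                                np.vstack([encode_bases(seqs[i]) for i in ids]))

    def test_identical_sequences_give_zero(self):
        s = "ACGTTGCAACGGTTAACCGGTA"
        g = self._genomes({"ref": s, "a": s, "b": s})
        with pytest.warns(UserWarning):
            d = mash_distance(g, SketchConfig(k=7, sketch_size=4096))
        assert d.loc("a", "b") == 0.0

    def test_exact_jaccard_closed_form(self):
        s1 = "ACGTACGGTCAGTCCAATGG"
        s2 = "ACGTACGTTCAGTCCAATGG"
        comp = str.maketrans("ACGT", "TGCA")

        def canon(s, k):
            return {min(s[i:i + k], s[i:i + k].translate(comp)[::-1])
                    for i in range(len(s) - k + 1)}

        k = 5
        j = len(canon(s1, k) & canon(s2, k)) / len(canon(s1, k) | canon(s2, k))
        expected = -math.log(2 * j / (1 + j)) / k
        g = self._genomes({"ref": s1, "a": s1, "b": s2})
        with pytest.warns(UserWarning):
            d = mash_distance(g, SketchConfig(k=k, sketch_size=100_000))
        assert d.loc("a", "b") == pytest.approx(expected, abs=1e-12)

    def test_disjoint_kmer_sets_capped_at_one(self):
        g = self._genomes({"ref": "AAAAAAAAAA", "a": "AAAAAAAAAA",
                           "b": "CGCGCGCGCG"})
        with pytest.warns(UserWarning):
            d = mash_distance(g, SketchConfig(k=5, sketch_size=100))
        assert d.loc("a", "b") == 1.0

    def test_sequence_shorter_than_k_names_strain(self):
        g = self._genomes({"ref": "ACGTACGTACGTACGTACGTACGT",
                           "tiny": "ACGTACGTACGTACGTACGTACGT"})
        with pytest.raises(ParameterError, match="tiny"):
            mash_distance(g, SketchConfig(k=25, sketch_size=10))

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            SketchConfig(k=33).validate()


class TestMdsCovariates:
    def test_equilateral_triangle_eigenvalues(self):
        d = DistanceMatrix(list("xyz"), np.array(
            [[0, 1, 1], [1, 0, 1], [1, 1, 0]], float))
        coords = mds_covariates(d)
        vals = coords.attrs["eigenvalues"]
        # centered Gram matrix of an equilateral triangle: two equal
        # positive eigenvalues 1/2 x side^2 x ... = 0.5, third zero
        assert vals[0] == pytest.approx(0.5, abs=1e-9)
        assert vals[1] == pytest.approx(0.5, abs=1e-9)
        assert abs(vals[2]) < 1e-9

    def test_collinear_points_need_one_axis(self):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        D = np.abs(x[:, None] - x[None, :])
        d = DistanceMatrix(list("abcd"), D)
        coords = mds_covariates(d, var_frac=0.999)
        assert coords.shape[1] == 1
        rec = np.abs(coords.iloc[:, 0].to_numpy()[:, None]
                     - coords.iloc[:, 0].to_numpy()[None, :])
        assert np.allclose(rec, D, atol=1e-9)

    def test_euclidean_input_has_no_negative_mass(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords = mds_covariates(DistanceMatrix([f"s{i}" for i in range(10)], D))
        vals = coords.attrs["eigenvalues"]
        assert (vals > -1e-9 * max(vals)).all()


class TestPhenotypeGwas:
    def test_ols_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(0)
        idx = [f"s{i}" for i in range(40)]
        V = pd.DataFrame(rng.integers(0, 2, (40, 3)).astype(float),
                         index=idx, columns=list("uvw"))
        C = pd.DataFrame(rng.normal(size=(40, 2)), index=idx, columns=["m1", "m2"])
        y = pd.Series(rng.normal(size=40), index=idx)
        res = phenotype_gwas(V, y, covariates=C).set_index("variant")
        for var in "uvw":
            X = sm.add_constant(np.column_stack([V[var], C]))
            fit = sm.OLS(y.to_numpy(), X).fit()
            assert res.loc[var, "beta"] == pytest.approx(fit.params[1], abs=1e-10)
            assert res.loc[var, "p"] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_planted_effect_detected(self):
        rng = np.random.default_rng(1)
        idx = [f"s{i}" for i in range(150)]
        V = pd.DataFrame(rng.integers(0, 2, (150, 200)).astype(float), index=idx)
        causal = (rng.random(150) < 0.4).astype(float)
        V["causal"] = causal
        y = pd.Series(20 + 40 * causal + rng.normal(0, 5, 150), index=idx)
        res = phenotype_gwas(V, y).set_index("variant")
        assert bool(res.loc["causal", "significant"])

    def test_confounded_variant_rescued_by_mds_covariates(self):
        # phenotype driven by population; variant correlated with population
        # but orthogonal to phenotype given structure
        rng = np.random.default_rng(2)
        n = 120
        pop = np.repeat([0, 1], n // 2)
        idx = [f"s{i}" for i in range(n)]
        variant = ((pop + (rng.random(n) < 0.1)) % 2).astype(float)
        y = pd.Series(10.0 * pop + rng.normal(0, 1, n), index=idx)
        V = pd.DataFrame({"v": variant}, index=idx)
        # structure covariate: MDS of a distance matrix separating populations
        D = np.abs(pop[:, None] - pop[None, :]).astype(float) + \
            rng.uniform(0, 0.05, (n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        coords = mds_covariates(DistanceMatrix(idx, D), max_dims=2)
        uncorrected = phenotype_gwas(V, y)
        corrected = phenotype_gwas(V, y, covariates=coords)
        assert bool(uncorrected.loc[0, "significant"])
        assert not bool(corrected.loc[0, "significant"])

    def test_binary_phenotype_logistic_and_firth_on_separation(self):
        rng = np.random.default_rng(3)
        idx = [f"s{i}" for i in range(60)]
        y = pd.Series(np.repeat([0.0, 1.0], 30), index=idx)
        V = pd.DataFrame({
            "noise": rng.integers(0, 2, 60).astype(float),
            "separator": y.to_numpy(),  # perfect separation
        }, index=idx)
        res = phenotype_gwas(V, y, binary=True).set_index("variant")
        assert np.isfinite(res.loc["noise", "p"])
        assert np.isfinite(res.loc["separator", "p"])  # Firth fallback
        assert res.loc["separator", "p"] < res.loc["noise", "p"]

    def test_missing_phenotypes_dropped_casewise(self):
        idx = [f"s{i}" for i in range(10)]
        V = pd.DataFrame({"v": [0, 1] * 5}, index=idx, dtype=float)
        y = pd.Series([1.0, 2, 3, 4, 5, 6, 7, 8, np.nan, np.nan], index=idx)
        res = phenotype_gwas(V, y)
        assert len(res) == 1  # runs on the 8 complete strains


class TestGenotypeEffectsizes:
    def test_constant_covariate_excluded_and_saturated_r2(self):
        rng = np.random.default_rng(4)
        idx = [f"s{i}" for i in range(30)]
        grp = np.repeat([0.0, 1.0], 15)
        V = pd.DataFrame(np.column_stack([grp] * 6), index=idx)
        cov = pd.DataFrame({"grp": grp, "flat": np.ones(30)}, index=idx)
        res = assoc.genotype_effectsizes(V, cov, permutations=49, seed=0)
        assert "flat" not in set(res["term"])
        r2 = res[(res["method"] == "RDA") & (res["term"] == "grp")]["R2"].iloc[0]
        assert r2 == pytest.approx(1.0, abs=1e-9)
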