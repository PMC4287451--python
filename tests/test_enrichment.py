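"""Family contingency building, fold enrichment, multinomial goodness-of-fit,
enrichment calls, attribution and gene-set profiling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from te_stress.enrichment import (
    attribute_response,
    build_contingency,
    call_enriched_families,
    family_enrichment_table,
    fold_enrichment,
    multinomial_gof_test,
    percent_up,
    profile_gene_sets,
)


def _assoc(rows):
    return pd.DataFrame(rows, columns=["gene_id", "te_id", "family",
                                       "signed_distance", "same_strand"])


def _contrasts(classes, activated=None):
    genes = list(classes)
    df = pd.DataFrame({
        "gene_id": genes,
        "genotype": "B73",
        "stress": "cold",
        "response_class": [classes[g] for g in genes],
    })
    df["activated"] = [bool(activated and g in activated) for g in genes]
    return df


class TestContingency:
    def test_counts_partition_expressed_genes(self):
        assoc = _assoc([("g1", "t1", "famA", 10, True),
                        ("g2", "t2", "famA", 20, True),
                        ("g3", "t3", "famA", 30, False)])
        contrasts = _contrasts({"g1": "up", "g2": "up", "g3": "nonDE", "g4": "down",
                                "g5": "nonDE"})
        c = build_contingency(assoc, contrasts).set_index("family").loc["famA"]
        assert (c.n_up, c.n_down, c.n_nde, c.n_expressed) == (2, 0, 1, 3)
        assert (c.bg_up, c.bg_down, c.bg_nde) == (2, 1, 2)

    def test_gene_with_three_insertions_counted_once(self):
        assoc = _assoc([("g1", f"t{i}", "famA", 10 * i, True) for i in range(1, 4)])
        contrasts = _contrasts({"g1": "up"})
        c = build_contingency(assoc, contrasts).set_index("family").loc["famA"]
        assert c.n_up == 1 and c.n_expressed == 1

    def test_not_expressed_genes_excluded_everywhere(self):
        assoc = _assoc([("g1", "t1", "famA", 10, True),
                        ("g2", "t2", "famA", 20, True)])
        contrasts = _contrasts({"g1": "up", "g2": "not_expressed", "g3": "not_expressed"})
        c = build_contingency(assoc, contrasts).set_index("family").loc["famA"]
        assert c.n_expressed == 1
        assert c.bg_up + c.bg_down + c.bg_nde == 1

    def test_all_genes_background_folds_silent_genes_into_nde(self):
        assoc = _assoc([("g1", "t1", "famA", 10, True)])
        contrasts = _contrasts({"g1": "up", "g2": "not_expressed"})
        c = build_contingency(assoc, contrasts, background="all_genes").iloc[0]
        assert c.bg_nde == 1

    def test_disjoint_namespaces_error(self):
        assoc = _assoc([("gX", "t1", "famA", 10, True)])
        with pytest.raises(ValueError, match="share no gene ids"):
            build_contingency(assoc, _contrasts({"g1": "up"}))

    def test_matches_flat_recount_oracle(self, small_genome, small_counts):
        from te_stress.experiments import run_enrichment_pipeline

        contrasts, associations, _ = run_enrichment_pipeline(
            small_genome, small_counts, n_mc=1000
        )
        table = build_contingency(associations, contrasts)
        cls = dict(zip(contrasts.gene_id, contrasts.response_class))
        seen = {}
        for row in associations.itertuples(index=False):
            seen.setdefault(row.family, set()).add(row.gene_id)
        for row in table.itertuples(index=False):
            genes = seen[row.family]
            exp = {k: sum(1 for g in genes if cls[g] == k) for k in ("up", "down", "nonDE")}
            assert (row.n_up, row.n_down, row.n_nde) == (exp["up"], exp["down"], exp["nonDE"])


class TestFoldEnrichment:
    def test_arithmetic(self):
        fe_up, _ = fold_enrichment(10, 5, 5, 100, 100, 800)
        assert fe_up == pytest.approx((10 / 20) / (100 / 1000))

    def test_background_against_itself_is_one(self):
        fe_up, fe_down = fold_enrichment(100, 100, 800, 100, 100, 800)
        assert fe_up == pytest.approx(1.0)
        assert fe_down == pytest.approx(1.0)

    def test_zero_background_rate_is_nan_not_error(self):
        fe_up, fe_down = fold_enrichment(3, 0, 7, 0, 10, 90)
        assert np.isnan(fe_up) and fe_down == pytest.approx(0.0)

    def test_matches_scalar_oracle_on_random_contingencies(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n_up, n_down, n_nde = rng.integers(0, 40, 3)
            bg = rng.integers(1, 500, 3)
            if n_up + n_down + n_nde == 0:
                continue
            fe_up, fe_down = fold_enrichment(n_up, n_down, n_nde, *bg)
            n = n_up + n_down + n_nde
            assert fe_up == pytest.approx((n_up / n) / (bg[0] / bg.sum()))
            assert fe_down == pytest.approx((n_down / n) / (bg[1] / bg.sum()))


def _enumeration_oracle(observed, props):
    """Full enumeration of Multinomial(n, props): tail sum of G >= G_obs."""
    n = sum(observed)

    def g_stat(o):
        tot = 0.0
        for oi, pi in zip(o, props):
            if oi > 0:
                tot += oi * np.log(oi / (n * pi))
        return 2 * tot

    g_obs = g_stat(observed)
    p = 0.0
    for a, b in itertools.product(range(n + 1), repeat=2):
        if a + b > n:
            continue
        o = (a, b, n - a - b)
        if g_stat(o) >= g_obs - 1e-9:
            p += stats.multinomial.pmf(o, n, props)
    return p


class TestMultinomialGOF:
    def test_observed_proportional_to_expected_gives_one(self):
        assert multinomial_gof_test((10, 10, 80), (0.1, 0.1, 0.8)) == pytest.approx(1.0)

    def test_extreme_three_zero_zero_matches_enumeration(self):
        p = multinomial_gof_test((3, 0, 0), (1 / 3, 1 / 3, 1 / 3), method="exact")
        assert p == pytest.approx(_enumeration_oracle((3, 0, 0), (1 / 3, 1 / 3, 1 / 3)))
        # (3,0,0) and its two permutations are the most extreme outcomes
        assert p == pytest.approx(3 * (1 / 3) ** 3)

    @pytest.mark.parametrize("trial", range(100))
    def test_exact_equals_enumeration_for_small_n(self, trial):
        rng = np.random.default_rng(trial)
        props = rng.dirichlet([1, 1, 1])
        n = int(rng.integers(1, 13))
        obs = rng.multinomial(n, props)
        p = multinomial_gof_test(obs, props, method="exact")
        assert p == pytest.approx(_enumeration_oracle(tuple(obs), tuple(props)), rel=1e-9)

    @pytest.mark.parametrize("trial", range(30))
    def test_monte_carlo_agrees_with_exact(self, trial):
        rng = np.random.default_rng(100 + trial)
        props = rng.dirichlet([2, 2, 6])
        n = int(rng.integers(5, 40))
        obs = rng.multinomial(n, props)
        p_exact = multinomial_gof_test(obs, props, method="exact")
        n_mc = 20_000
        p_mc = multinomial_gof_test(obs, props, method="monte_carlo", n_mc=n_mc,
                                    seed=trial)
        se = np.sqrt(p_exact * (1 - p_exact) / n_mc)
        assert abs(p_mc - p_exact) <= 3 * se + 2 / n_mc

    def test_chisq_approximates_exact_at_moderate_n(self):
        obs, props = (30, 10, 60), (0.2, 0.2, 0.6)
        p_exact = multinomial_gof_test(obs, props, method="exact")
        p_chi = multinomial_gof_test(obs, props, method="chisq")
        assert p_chi == pytest.approx(p_exact, rel=0.5)

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            multinomial_gof_test((1, 2, 3), (0.5, 0.4, 0.2))

    def test_zero_probability_cell_with_observation(self):
        # impossible observation under the null: p-value 0 by exact enumeration
        p = multinomial_gof_test((1, 1, 8), (0.0, 0.1, 0.9), method="exact")
        assert p == pytest.approx(0.0)


class TestEnrichmentCalls:
    def _frame(self, n_expressed=20, fe_up=5.0, p=1e-5, n_up=15):
        return pd.DataFrame([
            {"family": "famA", "n_up": n_up, "n_down": 0,
             "n_nde": n_expressed - n_up, "n_expressed": n_expressed,
             "fe_up": fe_up, "fe_down": 0.0, "p_multinomial": p}
        ])

    def test_over_ten_genes_is_strict(self):
        out = call_enriched_families(self._frame(n_expressed=10, n_up=8))
        assert not out.enriched_up.iloc[0]
        out = call_enriched_families(self._frame(n_expressed=11, n_up=8))
        assert out.enriched_up.iloc[0]

    def test_fold_enrichment_threshold_is_strict(self):
        assert not call_enriched_families(self._frame(fe_up=2.0)).enriched_up.iloc[0]
        assert call_enriched_families(self._frame(fe_up=2.001)).enriched_up.iloc[0]

    def test_p_threshold_is_strict(self):
        assert not call_enriched_families(self._frame(p=0.001)).enriched_up.iloc[0]
        assert call_enriched_families(self._frame(p=0.0009)).enriched_up.iloc[0]

    def test_planted_family_with_strong_effect_called(self, small_genome, small_counts):
        from te_stress.experiments import run_enrichment_pipeline

        _, _, enrichment = run_enrichment_pipeline(small_genome, small_counts, n_mc=20_000)
        called = set(enrichment.loc[enrichment.enriched_up, "family"])
        assert set(small_genome.planted_families) <= called


class TestPercentUp:
    def test_joemon_style_worked_example(self):
        assert percent_up(59, 68) == 87

    def test_zero_up(self):
        assert percent_up(0, 10) == 0

    def test_three_quarters(self):
        assert percent_up(18, 24) == 75

    def test_empty_family_unavailable(self):
        assert np.isnan(percent_up(0, 0))


class TestAttribution:
    def test_no_enriched_families_gives_zero(self):
        contrasts = _contrasts({"g1": "up", "g2": "nonDE"})
        assoc = _assoc([("g1", "t1", "famA", 10, True)])
        out = attribute_response(contrasts, assoc, [])
        assert out["prop_up_attributed"] == 0.0

    def test_all_up_genes_associated_gives_one(self):
        contrasts = _contrasts({"g1": "up", "g2": "up"}, activated={"g1"})
        assoc = _assoc([("g1", "t1", "famA", 10, True),
                        ("g2", "t2", "famA", 20, True)])
        out = attribute_response(contrasts, assoc, ["famA"])
        assert out["prop_up_attributed"] == 1.0
        assert out["prop_activated_attributed"] == 1.0

    def test_gene_near_two_enriched_families_counts_once(self):
        contrasts = _contrasts({"g1": "up", "g2": "up"})
        assoc = _assoc([("g1", "t1", "famA", 10, True),
                        ("g1", "t2", "famB", 20, True)])
        out = attribute_response(contrasts, assoc, ["famA", "famB"])
        assert out["prop_up_attributed"] == 0.5

    def test_no_up_genes_unavailable(self):
        contrasts = _contrasts({"g1": "nonDE"})
        out = attribute_response(contrasts, _assoc([]), ["famA"])
        assert np.isnan(out["prop_up_attributed"])

    def test_matches_generator_truth_proportion(self, small_genome, small_counts):
        from te_stress.experiments import run_recovery_simulation

        res = run_recovery_simulation(small_genome.config)
        truth = res.synthetic.truth.set_index("gene_id")
        up_genes = res.contrasts.loc[res.contrasts.response_class == "up", "gene_id"]
        truth_prop = truth.loc[up_genes, "planted_hit"].mean()
        assert res.attribution["prop_up_attributed"] == pytest.approx(
            truth_prop, abs=0.05
        )


class TestProfileGeneSets:
    def _attrs(self):
        return pd.DataFrame(
            {
                "length": [1000, 3000, 2000],
                "exon_count": [1, 4, 2],
                "tissues_expressed": [2, 20, 6],
                "fgs": [False, True, True],
                "has_paralog": [False, True, False],
                "has_ortholog": [False, True, True],
                "has_go": [False, True, False],
            },
            index=["g1", "g2", "g3"],
        )

    def test_singleton_groups_equal_single_values(self):
        out = profile_gene_sets(["g1"], ["g2"], self._attrs())
        assert out.loc["te_influenced", "mean_length_bp"] == 1000
        assert out.loc["non_te_influenced", "mean_exon_number"] == 4
        assert out.loc["non_te_influenced", "pct_expressed_gt5_tissues"] == 100.0

    def test_identical_groups_identical_rows(self):
        out = profile_gene_sets(["g1", "g2"], ["g1", "g2"], self._attrs())
        assert (out.loc["te_influenced"] == out.loc["non_te_influenced"]).all()

    def test_missing_column_listed(self):
        attrs = self._attrs().drop(columns=["has_go", "fgs"])
        with pytest.raises(ValueError) as err:
            profile_gene_sets(["g1"], ["g2"], attrs)
        assert "has_go" in str(err.value) and "fgs" in str(err.value)

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(5)
        n = 60
        attrs = pd.DataFrame(
            {
                "length": rng.integers(300, 6000, n),
                "exon_count": rng.integers(1, 9, n),
                "tissues_expressed": rng.integers(0, 25, n),
                "fgs": rng.random(n) < 0.5,
                "has_paralog": rng.random(n) < 0.3,
                "has_ortholog": rng.random(n) < 0.4,
                "has_go": rng.random(n) < 0.4,
            },
            index=[f"g{i}" for i in range(n)],
        )
        a = [f"g{i}" for i in range(0, n, 2)]
        b = [f"g{i}" for i in range(1, n, 2)]
        out = profile_gene_sets(a, b, attrs)
        assert out.loc["te_influenced", "mean_length_bp"] == pytest.approx(
            attrs.loc[a, "length"].mean()
        )
        assert out.loc["non_te_influenced", "pct_fgs"] == pytest.approx(
            100 * attrs.loc[b, "fgs"].mean()
        )
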