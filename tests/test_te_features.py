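"""Strand bias, distance decay, motif scanning, positional enrichment, and
start-site classification."""

import itertools
import re

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from te_stress.annotations import GenomicInterval, assign_te_to_genes, associations_to_frame
from te_stress.te_features import (
    ExemplarAlignment,
    classify_start_sites,
    distance_decay,
    motif_family_summary,
    positional_enrichment,
    reverse_complement,
    scan_motif,
    strand_bias_all_families,
    strand_bias_test,
)

from conftest import make_gene, make_te


def _assoc(rows):
    return pd.DataFrame(rows, columns=["gene_id", "te_id", "family",
                                       "signed_distance", "same_strand"])


def _contrasts(classes):
    df = pd.DataFrame({"gene_id": list(classes), "response_class": list(classes.values())})
    df["activated"] = False
    return df


def _strand_fixture(up_same, up_opp, nde_same, nde_opp, family="famA"):
    rows, classes = [], {}
    i = 0
    for n, cls, same in [(up_same, "up", True), (up_opp, "up", False),
                         (nde_same, "nonDE", True), (nde_opp, "nonDE", False)]:
        for _ in range(n):
            g = f"g{i}"
            rows.append((g, f"t{i}", family, 100, same))
            classes[g] = cls
            i += 1
    return _assoc(rows), _contrasts(classes)


class TestStrandBias:
    def test_balanced_table_no_association(self):
        assoc, contrasts = _strand_fixture(5, 5, 5, 5)
        r = strand_bias_test(assoc, contrasts, "famA")
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1.0)

    def test_matches_hypergeometric_tail_oracle(self):
        assoc, contrasts = _strand_fixture(9, 1, 5, 5)
        r = strand_bias_test(assoc, contrasts, "famA")
        # oracle: sum hypergeometric probabilities of tables as or less likely
        M, n, N = 20, 14, 10  # total, same-strand total, up margin
        probs = [stats.hypergeom.pmf(k, M, n, N) for k in range(max(0, n + N - M), min(n, N) + 1)]
        p_obs = stats.hypergeom.pmf(9, M, n, N)
        expected = sum(p for p in probs if p <= p_obs + 1e-12)
        assert r.p_value == pytest.approx(expected, rel=1e-6)

    def test_swapping_rows_inverts_odds_preserves_p(self):
        a1, c1 = _strand_fixture(9, 1, 5, 5)
        r1 = strand_bias_test(a1, c1, "famA")
        a2, c2 = _strand_fixture(5, 5, 9, 1)
        r2 = strand_bias_test(a2, c2, "famA")
        assert r1.odds_ratio == pytest.approx(1 / r2.odds_ratio)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_empty_row_gives_nan_p(self):
        assoc, contrasts = _strand_fixture(3, 2, 0, 0)
        r = strand_bias_test(assoc, contrasts, "famA")
        assert np.isnan(r.p_value)

    def test_bh_applied_across_families(self):
        a1, c1 = _strand_fixture(9, 1, 1, 9, family="famA")
        a2, c2 = _strand_fixture(5, 5, 5, 5, family="famB")
        assoc = pd.concat([a1, a2.assign(gene_id=a2.gene_id + "_b")], ignore_index=True)
        classes = dict(zip(c1.gene_id, c1.response_class))
        classes.update({g + "_b": c for g, c in zip(c2.gene_id, c2.response_class)})
        out = strand_bias_all_families(assoc, _contrasts(classes), ["famA", "famB"])
        assert (out.p_adjusted >= out.p_value - 1e-12).all()

    @pytest.mark.parametrize("margins", list(itertools.product(range(1, 16, 4), repeat=2)))
    def test_fisher_equals_tail_sum_for_small_margins(self, margins):
        r1, r2 = margins
        for same_up in range(r1 + 1):
            for same_nde in range(r2 + 1):
                table = np.array([[same_up, r1 - same_up], [same_nde, r2 - same_nde]])
                _, p = stats.fisher_exact(table)
                M = r1 + r2
                n = table[:, 0].sum()
                p_obs = stats.hypergeom.pmf(same_up, M, n, r1)
                tail = sum(
                    stats.hypergeom.pmf(k, M, n, r1)
                    for k in range(max(0, n - r2), min(n, r1) + 1)
                    if stats.hypergeom.pmf(k, M, n, r1) <= p_obs + 1e-12
                )
                assert p == pytest.approx(min(1.0, tail), rel=1e-8, abs=1e-12)


class TestDistanceDecay:
    def test_bins_partition_associations(self):
        assoc = _assoc([(f"g{i}", f"t{i}", "famA", d, True)
                        for i, d in enumerate([0, 100, 499, 500, 999, 1500, 4999])])
        contrasts = _contrasts({f"g{i}": "up" for i in range(7)})
        out = distance_decay(assoc, contrasts, bin_edges=[0, 500, 1000, 5000])
        assert out.n_genes.sum() == 7
        assert out.set_index("bin_lo").n_genes.to_dict() == {0: 3, 500: 2, 1000: 2}

    def test_empty_bins_report_nan_proportion(self):
        assoc = _assoc([("g1", "t1", "famA", 100, True)])
        out = distance_decay(assoc, _contrasts({"g1": "up"}), bin_edges=[0, 500, 1000])
        far = out[out.bin_lo == 500].iloc[0]
        assert far.n_genes == 0 and np.isnan(far.prop_up)

    def test_gene_assigned_to_bin_of_nearest_insertion(self):
        assoc = _assoc([("g1", "t1", "famA", 900, True), ("g1", "t2", "famA", 50, True)])
        out = distance_decay(assoc, _contrasts({"g1": "up"}), bin_edges=[0, 500, 1000])
        assert out[out.bin_lo == 0].iloc[0].n_genes == 1
        assert out[out.bin_lo == 500].iloc[0].n_genes == 0

    def test_monotone_decrease_with_planted_halflife(self):
        from te_stress.experiments import run_enrichment_pipeline
        from te_stress.synthetic import SimulationConfig, generate_counts, generate_genome

        # effect halves every 500 bp: pooled over planted families the
        # responsive fraction must decrease across upstream distance bins
        votes = []
        for seed in range(8):
            cfg = SimulationConfig(seed=seed, n_genes=1200, n_chromosomes=2,
                                   distance_decay_halflife=500.0, penetrance=0.95)
            genome = generate_genome(cfg)
            counts = generate_counts(genome)
            contrasts, associations, _ = run_enrichment_pipeline(genome, counts, n_mc=100)
            sub = associations[associations.family.isin(genome.planted_families)]
            out = distance_decay(sub, contrasts, bin_edges=[0, 333, 666, 1000])
            pooled = out.groupby("bin_lo").agg(n=("n_genes", "sum"), up=("n_up", "sum"))
            props = (pooled.up / pooled.n).values
            votes.append(bool(props[0] > props[1] > props[2]))
        assert sum(votes) >= 6  # majority across seeds


class TestMotifScan:
    def test_direct_expansion_hit(self):
        count, hits = scan_motif("ACCGACTT", "RCCGACNT", both_strands=False)
        assert count == 1 and hits == [(0, "+")]

    def test_no_hit(self):
        assert scan_motif("TTTTTTTT", "RCCGACNT")[0] == 0

    def test_n_in_sequence_never_matches_specific_symbol(self):
        assert scan_motif("NCCGACTT", "RCCGACNT", both_strands=False)[0] == 0
        # but pattern N accepts sequence N
        assert scan_motif("ACCGACNT", "RCCGACNT", both_strands=False)[0] == 1

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            scan_motif("ACGT", "ACZT")

    def test_overlapping_hits_counted(self):
        count, _ = scan_motif("AAAA", "AA", both_strands=False)
        assert count == 3

    def test_reverse_strand_hit_found(self):
        site = "ACCGACTT"
        seq = "GGGG" + reverse_complement(site) + "GGGG"
        count, hits = scan_motif(seq, "RCCGACNT", both_strands=True)
        assert count == 1 and hits[0][1] == "-"

    @pytest.mark.parametrize("chunk", range(4))
    def test_matches_regex_expansion_oracle(self, chunk):
        from te_stress.te_features import IUPAC

        pattern = "RCCGACNT"
        regex_fwd = re.compile("(?=(" + "".join(
            f"[{IUPAC[c].replace('N', 'ACGTN') if c == 'N' else IUPAC[c]}]" for c in pattern
        ) + "))")
        rc = reverse_complement(pattern)
        regex_rev = re.compile("(?=(" + "".join(
            f"[{IUPAC[c].replace('N', 'ACGTN') if c == 'N' else IUPAC[c]}]" for c in rc
        ) + "))")
        rng = np.random.default_rng(chunk)
        for _ in range(250):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5000)])
            expected = len(regex_fwd.findall(seq)) + len(regex_rev.findall(seq))
            assert scan_motif(seq, pattern, both_strands=True)[0] == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_reverse_complement_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3000)])
        assert (scan_motif(seq)[0] == scan_motif(reverse_complement(seq))[0])


class TestMotifSummary:
    def test_single_sequence_with_two_hits(self):
        seq = "ACCGACTT" + "G" * 50 + "GCCGACAT"
        out = motif_family_summary({"fam": [seq]}, both_strands=False)
        assert out.loc["fam", "prop_with_site"] == 1.0
        assert out.loc["fam", "mean_sites_per_element"] == 2.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="no sequences"):
            motif_family_summary({"fam": []})

    def test_hit_free_group_zeroes(self):
        out = motif_family_summary({"fam": ["TTTT" * 10]})
        assert out.loc["fam", "prop_with_site"] == 0.0
        assert out.loc["fam", "mean_sites_per_element"] == 0.0

    def test_planted_families_exceed_scrubbed_controls(self):
        from te_stress.synthetic import SimulationConfig, generate_genome, generate_sequences_and_transcripts

        wins = 0
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, n_genes=300, n_chromosomes=1,
                                   n_families=10, insertions_per_family=6,
                                   planted_families=3)
            genome = generate_genome(cfg)
            bundle = generate_sequences_and_transcripts(genome)
            groups = {
                "planted": [bundle.consensus[f] for f in genome.planted_families],
                "control": [s for f, s in bundle.consensus.items()
                            if f not in genome.planted_families],
            }
            out = motif_family_summary(groups)
            if out.loc["planted", "prop_with_site"] > out.loc["control", "prop_with_site"]:
                wins += 1
        assert wins == 20


class TestPositionalEnrichment:
    def test_identical_coverage_no_regions(self):
        alns = [ExemplarAlignment(f"r{i}", "fam", [(100, 500)], "responsive") for i in range(5)]
        alns += [ExemplarAlignment(f"n{i}", "fam", [(100, 500)], "non_responsive")
                 for i in range(5)]
        _, regions = positional_enrichment(alns, 1000)
        assert regions.empty

    def test_single_insertion_groups_give_step_curves(self):
        alns = [ExemplarAlignment("r", "fam", [(100, 300)], "responsive"),
                ExemplarAlignment("n", "fam", [(500, 700)], "non_responsive")]
        curves, _ = positional_enrichment(alns, 1000)
        assert set(curves.prop_responsive.unique()) == {0.0, 1.0}
        assert curves.loc[150, "prop_responsive"] == 1.0
        assert curves.loc[600, "prop_non_responsive"] == 1.0

    def test_planted_region_recovered_within_min_run(self):
        from te_stress.synthetic import SimulationConfig, generate_genome, generate_sequences_and_transcripts

        cfg = SimulationConfig(seed=2, n_genes=300, n_chromosomes=1,
                               n_families=10, insertions_per_family=6)
        bundle = generate_sequences_and_transcripts(generate_genome(cfg))
        _, regions = positional_enrichment(bundle.exemplar_alignments,
                                           bundle.exemplar_length)
        assert len(regions) == 1
        lo, hi = bundle.planted_region
        assert abs(regions.iloc[0].start - lo) <= 50
        assert abs(regions.iloc[0].end - hi) <= 50
        assert regions.iloc[0].fisher_p < 0.001

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        alns = []
        for i in range(30):
            lo = int(rng.integers(0, 900))
            alns.append(ExemplarAlignment(
                f"a{i}", "fam", [(lo, lo + 100)],
                "responsive" if i % 2 else "non_responsive"))
        c1, r1 = positional_enrichment(alns, 1000, ratio_threshold=1.5, min_run=10)
        c2, r2 = positional_enrichment(alns[::-1], 1000, ratio_threshold=1.5, min_run=10)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(r1, r2)

    def test_regions_are_disjoint_maximal_runs(self):
        alns = [ExemplarAlignment("r0", "fam", [(0, 100), (200, 300)], "responsive"),
                ExemplarAlignment("r1", "fam", [(0, 100), (200, 300)], "responsive"),
                ExemplarAlignment("n0", "fam", [(400, 500)], "non_responsive")]
        _, regions = positional_enrichment(alns, 600, ratio_threshold=2, min_run=50)
        spans = list(zip(regions.start, regions.end))
        assert spans == [(0, 100), (200, 300)]

    def test_bad_exemplar_length(self):
        with pytest.raises(ValueError, match="positive"):
            positional_enrichment([], 0)


class TestStartSites:
    def _setup(self):
        gene = make_gene("g1", start=5000, end=8000, strand="+")  # tss 5000
        te = make_te("te1", "famA", start=4000, end=4600)  # d = 401
        assoc = _assoc([("g1", "te1", "famA", 401, True)])
        tes_by_id = {"te1": te.interval}
        return gene, assoc, tes_by_id

    def test_control_at_tss_stress_in_te_is_novel(self):
        gene, assoc, tes = self._setup()
        (call,) = classify_start_sites([gene], assoc, {"g1": 5000}, {"g1": 4300}, tes)
        assert call.category == "novel_te_start_stress_only"

    def test_both_starts_far_upstream_is_incomplete_annotation(self):
        gene, assoc, tes = self._setup()
        (call,) = classify_start_sites([gene], assoc, {"g1": 3000}, {"g1": 3000}, tes)
        assert call.category == "upstream_both"

    def test_missing_condition_is_no_data(self):
        gene, assoc, tes = self._setup()
        (call,) = classify_start_sites([gene], assoc, {"g1": 5000}, {}, tes)
        assert call.category == "no_data"

    def test_matching_starts_concordant(self):
        gene, assoc, tes = self._setup()
        (call,) = classify_start_sites([gene], assoc, {"g1": 5000}, {"g1": 5010}, tes)
        assert call.category == "concordant"

    def test_te_slack_extends_te_interval(self):
        gene, assoc, tes = self._setup()
        (call,) = classify_start_sites([gene], assoc, {"g1": 5000}, {"g1": 4640}, tes,
                                       te_slack=50)
        assert call.category == "novel_te_start_stress_only"

    def test_genes_without_upstream_te_excluded(self):
        gene = make_gene("g1", start=5000, end=8000, strand="+")
        assoc = _assoc([("g1", "te1", "famA", 50, True)])  # closer than 100 bp
        calls = classify_start_sites([gene], assoc, {"g1": 5000}, {"g1": 5000},
                                     {"te1": GenomicInterval("chr1", 4900, 4951)})
        assert calls == []

    def test_planted_promoter_genes_recovered_exactly(self, small_genome):
        from te_stress.synthetic import generate_sequences_and_transcripts

        bundle = generate_sequences_and_transcripts(small_genome)
        assoc = associations_to_frame(
            assign_te_to_genes(small_genome.genes, small_genome.tes)
        )
        calls = classify_start_sites(
            small_genome.genes, assoc, bundle.control_starts, bundle.stress_starts,
            {t.te_id: t.interval for t in small_genome.tes},
        )
        novel = sorted(c.gene_id for c in calls
                       if c.category == "novel_te_start_stress_only")
        assert novel == bundle.promoter_gene_ids
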