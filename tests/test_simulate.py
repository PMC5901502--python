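"""Synthetic-data generator: determinism, planted structure, consistency."""

import numpy as np
import pytest

from transpoly.caller import (
    assign_genes,
    call_trans_snps,
    cpg_status,
    extract_het_sites,
)
from transpoly.errors import ConfigError
from transpoly.features import gc_content
from transpoly.simulate import (
    GeneSetSpec,
    SimConfig,
    simulate_bundle,
    simulate_reference_and_genes,
    write_bundle,
)


class TestConfigValidation:
    def test_probabilities_checked(self):
        with pytest.raises(ConfigError):
            SimConfig(poly_rate=1.5)
        with pytest.raises(ConfigError):
            SimConfig(share_prob=-0.1)

    def test_gene_sets_must_fit(self):
        with pytest.raises(ConfigError):
            SimConfig(n_genes=10, gene_sets=(GeneSetSpec("T", 11),))

    def test_infeasible_gc_target_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(gc_mean=1.2)


class TestGenome:
    def test_minimal_two_gene_genome(self):
        cfg = SimConfig(
            n_genes=2, exon_count_mean=0.0, exon_len_mean=300, exon_len_sd=0.0,
            gene_sets=(GeneSetSpec("T", 1),), seed=0,
        )
        genome = simulate_reference_and_genes(cfg)
        assert len(genome.models) == 2
        assert len(genome.reference["1"]) >= 600
        spans = [m.coding_exons for m in genome.models]
        assert all(len(s) == 1 for s in spans)
        # disjoint genes
        (a,), (b,) = spans
        assert a[1] <= b[0] or b[1] <= a[0]

    def test_gc_target_recovered_from_fasta(self):
        cfg = SimConfig(
            n_genes=4, gc_mean=0.8, gc_sd=0.0, exon_len_mean=2000, exon_len_sd=0.0,
            exon_count_mean=0.0, gene_sets=(GeneSetSpec("T", 1),), seed=1,
        )
        genome = simulate_reference_and_genes(cfg)
        for m in genome.models:
            gc = gc_content(m, genome.reference)
            assert 75.0 <= gc <= 85.0
            # features table agrees with recomputation from the sequence
            assert genome.features.loc[m.name, "gc_percent"] == pytest.approx(gc)

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = SimConfig(n_genes=30, gene_sets=(GeneSetSpec("T", 5),), seed=99)
        write_bundle(simulate_bundle(cfg), tmp_path / "a")
        write_bundle(simulate_bundle(cfg), tmp_path / "b")
        for name in ("reference.fa", "gene_models.tsv", "features.tsv",
                     "archaic.vcf", "population_counts.tsv", "annotations.tsv",
                     "truth.tsv", "geneset_T.txt", "sim_config.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


class TestPlantedStructure:
    def test_null_factor_gives_equal_sharing_rates(self):
        cfg = SimConfig(
            n_genes=400, poly_rate=0.02, share_prob=0.3,
            gene_sets=(GeneSetSpec("T", 50, 1.0),), seed=21,
        )
        bundle = simulate_bundle(cfg)
        truth = bundle.variants.truth
        het = truth[truth["archaic_het"]]
        in_set = het["set"] == "T"
        r_t = het.loc[in_set, "modern_segregating"].mean()
        r_c = het.loc[~in_set, "modern_segregating"].mean()
        n_t, n_c = in_set.sum(), (~in_set).sum()
        se = np.sqrt(r_t * (1 - r_t) / n_t + r_c * (1 - r_c) / n_c)
        assert abs(r_t - r_c) <= 3.5 * se

    def test_planted_factor_three_ratio_recovered(self):
        cfg = SimConfig(
            n_genes=1000, poly_rate=0.02, share_prob=0.2,
            gene_sets=(GeneSetSpec("T", 50, 3.0),), seed=22,
        )
        truth = simulate_bundle(cfg).variants.truth
        het = truth[truth["archaic_het"]]
        r_t = het.loc[het["set"] == "T", "modern_segregating"].mean()
        r_c = het.loc[het["set"] != "T", "modern_segregating"].mean()
        assert 2.5 <= r_t / r_c <= 3.5

    def test_cpg_density_reflects_multiplier(self):
        cfg = SimConfig(
            n_genes=400, poly_rate=0.01, cpg_multiplier=2.0, gc_mean=0.5,
            gene_sets=(GeneSetSpec("T", 10),), seed=23,
        )
        bundle = simulate_bundle(cfg)
        truth = bundle.variants.truth
        seq = bundle.genome.reference["1"]
        from transpoly.simulate import _cpg_mask

        mask = _cpg_mask(np.array(list(seq)))
        positions = np.concatenate(
            [np.arange(s, e) for m in bundle.genome.models for s, e in m.coding_exons]
        )
        n_cpg_pos = int(mask[positions].sum())
        n_other_pos = positions.size - n_cpg_pos
        n_cpg_sites = int(truth["is_cpg"].sum())
        n_other_sites = len(truth) - n_cpg_sites
        rate_ratio = (n_cpg_sites / n_cpg_pos) / (n_other_sites / n_other_pos)
        # Poisson rate-ratio check with a generous 3-SE band
        se = rate_ratio * np.sqrt(1 / n_cpg_sites + 1 / n_other_sites)
        assert abs(rate_ratio - 2.0) <= 3 * se


class TestTruthConsistency:
    def test_every_called_trans_snp_is_true_shared_site(self, small_bundle):
        bundle = small_bundle
        het = extract_het_sites(bundle.variants.archaic)
        gene_map = assign_genes([s for s, _ in het], bundle.genome.models)
        trans = call_trans_snps(
            het, bundle.variants.population, gene_map, bundle.variants.annotations
        )
        truth = bundle.variants.truth.set_index(["chrom", "pos"])
        for snp in trans:
            row = truth.loc[(snp.site.chrom, snp.site.pos)]
            assert bool(row["archaic_het"]) and bool(row["modern_segregating"])

    def test_no_true_shared_genic_site_is_missed(self, small_bundle):
        bundle = small_bundle
        het = extract_het_sites(bundle.variants.archaic)
        gene_map = assign_genes([s for s, _ in het], bundle.genome.models)
        trans = call_trans_snps(
            het, bundle.variants.population, gene_map, bundle.variants.annotations
        )
        called = {(t.site.chrom, t.site.pos) for t in trans}
        truth = bundle.variants.truth
        expected = truth[truth["archaic_het"] & truth["modern_segregating"]]
        missed = [
            (r.chrom, r.pos)
            for r in expected.itertuples()
            if (r.chrom, r.pos) not in called
        ]
        assert missed == []

    def test_cpg_exclusion_shrinks_counts_on_cpg_elevated_data(self, small_bundle):
        bundle = small_bundle
        het = extract_het_sites(bundle.variants.archaic)
        gene_map = assign_genes([s for s, _ in het], bundle.genome.models)
        cpg = cpg_status([s for s, _ in het], bundle.genome.reference)
        with_cpg = call_trans_snps(
            het, bundle.variants.population, gene_map, cpg=cpg, exclude_cpg=False
        )
        without = call_trans_snps(
            het, bundle.variants.population, gene_map, cpg=cpg, exclude_cpg=True
        )
        assert {t.site for t in without} < {t.site for t in with_cpg}
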