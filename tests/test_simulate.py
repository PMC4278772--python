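"""Synthetic-data generator: determinism, truth invariants, read structure."""

import dataclasses

import numpy as np
import pytest

from patseq.errors import ConfigurationError
from patseq.simulate import (
    GENOTYPES,
    SimulationConfig,
    generate_reference,
    sample_counts,
    simulate_tag_reads,
)
from patseq.refdb import build_extended_utr_db
from patseq.tagproc import trim_tag


@pytest.fixture(scope="module")
def tiny_config():
    return SimulationConfig(
        n_chromosomes=2, genes_per_chromosome=10, depth_per_sample=2000, seed=7
    )


@pytest.fixture(scope="module")
def tiny_dataset(tiny_config):
    genome, annotation, truth = generate_reference(tiny_config)
    reads = simulate_tag_reads(genome, annotation, truth, tiny_config)
    return genome, annotation, truth, reads


class TestDeterminism:
    def test_same_seed_reproduces_everything(self, tiny_config, tiny_dataset):
        genome, annotation, truth, reads = tiny_dataset
        genome2, annotation2, truth2 = generate_reference(tiny_config)
        assert genome2 == genome
        assert annotation2 == annotation
        for gene_id, t in truth.genes.items():
            t2 = truth2.genes[gene_id]
            assert t2.site_db_positions == t.site_db_positions
            for g in GENOTYPES:
                assert np.array_equal(t2.usage[g], t.usage[g])
        assert simulate_tag_reads(genome2, annotation2, truth2, tiny_config) == reads

    def test_different_seed_changes_the_genome(self, tiny_config, tiny_dataset):
        genome, *_ = tiny_dataset
        other = dataclasses.replace(tiny_config, seed=8)
        genome_other, _, _ = generate_reference(other)
        assert genome_other != genome


class TestTruthInvariants:
    def test_usage_vectors_sum_to_one(self, tiny_dataset):
        _, _, truth, _ = tiny_dataset
        for t in truth.genes.values():
            for g in GENOTYPES:
                assert t.usage[g].sum() == pytest.approx(1.0, abs=1e-9)
                assert (t.usage[g] >= 0).all()

    def test_apa_shifted_genes_are_restored_in_transgenes(self):
        cfg = SimulationConfig(
            n_chromosomes=1,
            genes_per_chromosome=50,
            depth_per_sample=5000,
            planted_apa_fraction=0.2,
            seed=9,
        )
        _, _, truth = generate_reference(cfg)
        shifted = [t for t in truth.genes.values() if t.planted_apa_shifted]
        assert shifted, "expected planted APA-shifted genes"
        for t in shifted:
            assert np.array_equal(t.usage["wt"], t.usage["c30g"])
            assert np.array_equal(t.usage["wt"], t.usage["c30gm"])
            assert not np.array_equal(t.usage["wt"], t.usage["oxt6"])

    def test_sites_lie_in_utr_or_extension(self, tiny_config, tiny_dataset):
        genome, annotation, truth, _ = tiny_dataset
        by_gene = {g.gene_id: g for g in annotation}
        for t in truth.genes.values():
            gene = by_gene[t.gene_id]
            for gpos in t.site_genomic_positions:
                if gene.strand == "+":
                    assert gene.utr_start <= gpos < gene.utr_end + tiny_config.extension
                else:
                    assert gene.utr_start - tiny_config.extension <= gpos < gene.utr_end

    def test_utr_inside_chromosome(self, tiny_dataset):
        genome, annotation, _, _ = tiny_dataset
        for gene in annotation:
            assert 0 <= gene.utr_start < gene.utr_end <= len(genome[gene.chromosome])

    def test_oversized_utr_is_a_configuration_error(self):
        cfg = SimulationConfig(
            utr_length_range=(900, 1000), chromosome_length=800, seed=0
        )
        with pytest.raises(ConfigurationError):
            generate_reference(cfg)


class TestReads:
    def test_read_layout_and_tag_roundtrip_without_errors(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, error_rate=0.0)
        genome, annotation, truth = generate_reference(cfg)
        reads = simulate_tag_reads(genome, annotation, truth, cfg)
        db = {
            r.gene_id: r.db_sequence
            for r in build_extended_utr_db(annotation, genome, cfg.extension)
        }
        barcode_len = len(next(iter(cfg.barcodes.values())))
        checked = 0
        for rid, seq, qual in reads[:500]:
            assert len(seq) == len(qual)
            sample, gene_id, _ = rid.split(":")
            assert seq[:barcode_len] == cfg.barcodes[sample]
            tag = trim_tag(seq[barcode_len:], cfg.adapter_5p, cfg.adapter_3p)
            if tag is None:
                continue
            assert tag in db[gene_id]
            checked += 1
        assert checked > 400

    def test_embedded_tag_recovered_exactly(self, tiny_config):
        # constructed read with remnant length 8 and a tag not ending in A
        tag = "CGTCGTAGCTAGCTAGGCTAGCTAGCTAGGATCGATCGGATCCGATCG"
        read = (
            tiny_config.barcodes["wt"]
            + tiny_config.adapter_5p
            + tag
            + "A" * 8
            + tiny_config.adapter_3p
        )
        stripped = read[len(tiny_config.barcodes["wt"]):]
        assert trim_tag(stripped, tiny_config.adapter_5p, tiny_config.adapter_3p) == tag

    def test_counts_track_planted_expression_means(self, tiny_config):
        # a cam-dependent pattern: means (wt 200, oxt6 40, c30g 200, c30gm 40)
        cfg = dataclasses.replace(tiny_config, error_rate=0.0, seed=13)
        genome, annotation, truth = generate_reference(cfg)
        target = annotation[0].gene_id
        means = {"wt": 200.0, "oxt6": 40.0, "c30g": 200.0, "c30gm": 40.0}
        truth.genes[target].expression = means
        reads = simulate_tag_reads(genome, annotation, truth, cfg)
        observed = {g: 0 for g in GENOTYPES}
        for rid, _, _ in reads:
            sample, gene_id, _ = rid.split(":")
            if gene_id == target:
                observed[sample] += 1
        for genotype, mean in means.items():
            # Poisson: sd = sqrt(mean); observed within 4 sampling sd
            assert abs(observed[genotype] - mean) <= 4 * np.sqrt(mean)

    def test_single_site_gene_tags_cluster_at_the_site(self, tiny_config):
        cfg = dataclasses.replace(tiny_config, error_rate=0.0, seed=17)
        genome, annotation, truth = generate_reference(cfg)
        single = next(
            t for t in truth.genes.values() if len(t.site_db_positions) == 1
        )
        records = build_extended_utr_db(annotation, genome, cfg.extension)
        db = {r.gene_id: r for r in records}
        reads = simulate_tag_reads(genome, annotation, truth, cfg)
        rec = db[single.gene_id]
        site = single.site_db_positions[0]
        n = within = 0
        barcode_len = len(next(iter(cfg.barcodes.values())))
        for rid, seq, _ in reads:
            _, gene_id, _ = rid.split(":")
            if gene_id != single.gene_id:
                continue
            tag = trim_tag(seq[barcode_len:], cfg.adapter_5p, cfg.adapter_3p)
            if tag is None:
                continue
            start = rec.db_sequence.find(tag)
            assert start >= 0
            junction = start + len(tag) - 1
            n += 1
            # tolerance: 3 sigma of cleavage jitter plus up to 4 genuine
            # terminal A's that remnant trimming cannot distinguish
            if abs(junction - site) <= 3 * cfg.cluster_sigma + 4:
                within += 1
        assert n > 0
        assert within / n > 0.99


class TestCountSampling:
    def test_poisson_counts_have_truth_means(self, tiny_dataset, tiny_config):
        _, _, truth, _ = tiny_dataset
        counts = sample_counts(truth, tiny_config.samples, seed=7)
        assert counts.shape == (len(truth.genes), len(tiny_config.samples))
        for sample, genotype in tiny_config.samples.items():
            means = np.array(
                [truth.genes[g].expression[genotype] for g in counts.index]
            )
            sd = np.sqrt(np.maximum(means, 1.0))
            assert (np.abs(counts[sample].values - means) <= 5 * sd + 5).all()
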