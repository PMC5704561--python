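import json

import numpy as np
import pytest

from phyloscope._codon import STOP_CODONS, translate
from phyloscope.errors import EmptyFamilyError, InvalidArgumentError
from phyloscope.locus_context import classify_all
from phyloscope.synthetic_data import (
    SimulationConfig,
    assign_lineage_rates,
    emit_genome_tables,
    evolve_gene_family,
    simulate,
    simulate_codon_sequences,
    simulate_rrna,
    simulate_species_tree,
    write_outputs,
)
from phyloscope.tree import PhyloTree


class TestConfig:
    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidArgumentError):
            SimulationConfig(hgt_rate=-1)

    def test_locus_mix_must_sum_to_one(self):
        with pytest.raises(InvalidArgumentError):
            SimulationConfig(locus_mix=(0.5, 0.5, 0.5))

    def test_too_few_genomes(self):
        with pytest.raises(InvalidArgumentError):
            SimulationConfig(n_genomes=1)


class TestSpeciesTree:
    def test_two_genomes_ultrametric(self):
        tree = simulate_species_tree(2, 1.0, seed=0)
        depths = tree.depths()
        tips = [depths[leaf] for leaf in tree.leaves()]
        assert len(tips) == 2
        assert tips[0] == pytest.approx(tips[1])

    def test_determinism(self):
        a = simulate_species_tree(50, 1.0, seed=1).to_newick()
        b = simulate_species_tree(50, 1.0, seed=1).to_newick()
        assert a == b

    def test_internal_node_count(self):
        tree = simulate_species_tree(50, 1.0, seed=3)
        internal = sum(1 for n in tree.preorder() if not n.is_leaf)
        assert internal == 49  # binary tree with n leaves has n-1 internal nodes

    def test_positive_branch_lengths(self):
        tree = simulate_species_tree(30, 2.0, seed=5)
        assert all(
            (n.length or 0) > 0 for n in tree.preorder() if n is not tree.root
        )

    def test_rejects_single_genome(self):
        with pytest.raises(InvalidArgumentError):
            simulate_species_tree(1, 1.0, 0)


class TestGeneFamily:
    def test_no_events_recovers_species_topology(self):
        species = simulate_species_tree(20, 1.0, seed=2)
        truth = evolve_gene_family(species, 0.0, 0.0, 0.0, seed=2)
        gene = truth.gene_trees[0]
        stripped = {
            frozenset(n.split("|")[0] for n in part) for part in gene.bipartitions()
        }
        assert stripped == species.bipartitions()  # Robinson-Foulds distance 0
        assert truth.transfer_events == []

    def test_duplication_creates_multicopy_genome(self):
        species = simulate_species_tree(10, 1.0, seed=4)
        for seed in range(10):
            truth = evolve_gene_family(species, 0.0, 0.5, 0.0, seed=seed)
            genomes = [n.split("|")[0] for n in truth.gene_trees[0].leaf_names()]
            if len(genomes) > len(set(genomes)):
                return
        pytest.fail("no duplication produced a multi-copy genome in 10 seeds")

    def test_transfer_counts_scale_with_rate(self):
        species = simulate_species_tree(20, 1.0, seed=6)
        high = [
            len(evolve_gene_family(species, 2.0, seed=s).transfer_events)
            for s in range(20)
        ]
        low = [
            len(evolve_gene_family(species, 0.0, seed=s).transfer_events)
            for s in range(20)
        ]
        assert np.mean(high) > np.mean(low)
        assert all(x == 0 for x in low)

    def test_gene_tree_remains_ultrametric_after_transfers(self):
        species = simulate_species_tree(15, 1.0, seed=7)
        truth = evolve_gene_family(species, 3.0, seed=7)
        gene = truth.gene_trees[0]
        depths = gene.depths()
        tips = [depths[leaf] for leaf in gene.leaves()]
        assert max(tips) - min(tips) < 1e-9

    def test_total_loss_raises(self):
        species = simulate_species_tree(4, 1.0, seed=8)
        with pytest.raises(EmptyFamilyError):
            for seed in range(200):
                evolve_gene_family(species, 0.0, 0.0, 0.95, seed=seed)


class TestCodonSimulation:
    def tree(self, a=0.3, b=0.3):
        return PhyloTree.from_newick(f"(A:{a},B:{b});")

    def test_zero_branch_lengths_identical(self):
        cds, proteins = simulate_codon_sequences(self.tree(0, 0), 0.5, 2.0, 40, seed=1)
        assert cds[0].residues == cds[1].residues

    def test_frame_and_no_stops(self):
        cds, _ = simulate_codon_sequences(self.tree(1.5, 1.5), 1.0, 2.0, 100, seed=2)
        for rec in cds:
            assert len(rec.residues) % 3 == 0
            codons = [rec.residues[i : i + 3] for i in range(0, len(rec.residues), 3)]
            assert not any(c in STOP_CODONS for c in codons)

    def test_translation_consistency(self):
        cds, proteins = simulate_codon_sequences(self.tree(), 0.4, 2.0, 60, seed=3)
        for c, p in zip(cds, proteins):
            assert translate(c.residues) == p.residues

    def test_omega_zero_pure_synonymous(self):
        cds, proteins = simulate_codon_sequences(self.tree(3.0, 3.0), 0.0, 2.0, 200, seed=4)
        assert proteins[0].residues == proteins[1].residues
        assert cds[0].residues != cds[1].residues

    def test_negative_omega_rejected(self):
        with pytest.raises(InvalidArgumentError):
            simulate_codon_sequences(self.tree(), -0.1, 2.0, 10, seed=0)

    def test_nonsynonymous_fraction_monotone_in_omega(self):
        fractions = []
        for omega in (0.05, 0.5, 1.0):
            diffs = syn = non = 0
            for seed in range(10):
                cds, proteins = simulate_codon_sequences(
                    self.tree(), omega, 2.0, 150, seed=seed
                )
                pa, pb = proteins[0].residues, proteins[1].residues
                ca, cb = cds[0].residues, cds[1].residues
                for k, (x, y) in enumerate(zip(pa, pb)):
                    if ca[3 * k : 3 * k + 3] != cb[3 * k : 3 * k + 3]:
                        if x == y:
                            syn += 1
                        else:
                            non += 1
            fractions.append(non / (syn + non))
        assert fractions[0] < fractions[1] < fractions[2]


class TestRrna:
    def test_slow_marker_low_divergence(self):
        species = simulate_species_tree(10, 1.0, seed=9)
        species.scale(1.0 / species.height())
        rrna = simulate_rrna(species, 1000, seed=9, rate_multiplier=0.1)
        assert len(rrna) == 10
        a, b = rrna[0].residues, rrna[1].residues
        p = sum(1 for x, y in zip(a, b) if x != y) / len(a)
        assert p < 0.4

    def test_ids_carry_genome(self):
        species = simulate_species_tree(5, 1.0, seed=10)
        rrna = simulate_rrna(species, 100, seed=10)
        for rec in rrna:
            assert rec.id == f"{rec.genome_id}_16S"


class TestEmitTables:
    def truth_for(self, n=12, seed=11, **kw):
        species = simulate_species_tree(n, 1.0, seed=seed)
        return evolve_gene_family(species, seed=seed, **kw)

    def test_pure_operon_mix(self):
        truth = self.truth_for()
        features, labels = emit_genome_tables(truth, (1.0, 0.0, 0.0), seed=11)
        assert set(labels.values()) == {"cas_operon"}
        by_contig = {}
        for f in features:
            by_contig.setdefault(f.contig_id, []).append(f)
        for gene_id in labels:
            contig = next(f.contig_id for f in features if f.gene_id == gene_id)
            feats = sorted(by_contig[contig], key=lambda f: f.start)
            idx = next(i for i, f in enumerate(feats) if f.gene_id == gene_id)
            near = feats[max(0, idx - 2) : idx + 3]
            assert any(
                f.annotation in ("cas1", "cas2") or f.annotation == "cas4/cas1_fusion"
                for f in near
                if f.gene_id != gene_id
            ) or feats[idx].annotation == "cas4/cas1_fusion"

    def test_pure_mge_mix(self):
        truth = self.truth_for()
        features, labels = emit_genome_tables(truth, (0.0, 0.0, 1.0), seed=11)
        for gene_id in labels:
            f = next(f for f in features if f.gene_id == gene_id)
            assert f.replicon_class in ("viral", "plasmid")

    def test_classifier_recovers_labels(self):
        truth = self.truth_for(n=20, seed=12, dup_rate=0.1)
        features, labels = emit_genome_tables(truth, (0.4, 0.3, 0.3), seed=12)
        classes = classify_all(features, family_gene_ids=set(labels))
        assert len(classes) == len(labels)
        cat_map = {"cas_operon": "CAS", "solo": "solo", "mge": "MGE"}
        for cl in classes:
            assert cl.category == cat_map[labels[cl.gene_id]]

    def test_every_gene_labelled_once(self):
        truth = self.truth_for()
        _, labels = emit_genome_tables(truth, (0.5, 0.3, 0.2), seed=13)
        assert sorted(labels) == sorted(truth.gene_trees[0].leaf_names())


class TestDeterminism:
    def test_byte_identical_outputs(self, tmp_path):
        config = SimulationConfig(n_genomes=8, hgt_rate=1.0, dup_rate=0.1, seed=21)
        for d in ("a", "b"):
            write_outputs(simulate(config), tmp_path / d)
        for name in (
            "proteins.faa",
            "cds.fna",
            "rrna.fna",
            "features.tsv",
            "species_tree.nwk",
            "gene_tree.nwk",
            "ground_truth.json",
        ):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name

    def test_feature_table_parses_clean(self, tmp_path, caplog):
        import logging

        from phyloscope.sequence_io import read_feature_table

        config = SimulationConfig(n_genomes=6, seed=22)
        paths = write_outputs(simulate(config), tmp_path)
        with caplog.at_level(logging.WARNING):
            feats = read_feature_table(paths["features"])
        assert feats
        assert not caplog.records

    def test_lineage_rates_mean_near_one(self, rng):
        species = simulate_species_tree(40, 1.0, seed=30)
        assign_lineage_rates(species, 0.5, seed=30)
        rates = [n.rate for n in species.preorder() if n is not species.root]
        assert np.mean(rates) == pytest.approx(1.0, abs=0.25)
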