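"""Generator contracts: determinism, conservation, and generative truth."""

import numpy as np
import pytest

from splicedelta.alignments import compute_depth, extract_junctions, read_sam
from splicedelta.annotation import read_gff3
from splicedelta.events import intron_retention_ratio
from splicedelta.simulate import (
    ReporterLocusSpec,
    ScenarioError,
    SpliceScenario,
    generate_annotation,
    simulate_cohort,
)


class TestScenarioValidation:
    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ScenarioError):
            SpliceScenario(retention_frac=1.2)

    def test_single_replicate_rejected(self):
        with pytest.raises(ScenarioError):
            SpliceScenario(replicates=1)

    def test_read_longer_than_shortest_transcript_rejected(self):
        with pytest.raises(ScenarioError):
            SpliceScenario(exon_len=(40, 60), read_len=100)

    def test_reporter_proportions_must_sum_to_one(self):
        with pytest.raises(ScenarioError):
            ReporterLocusSpec(proportions={"wt": (0.5, 0.5, 0.5), "mut": (1, 0, 0)})


class TestAnnotationGeneration:
    def test_two_exon_scenario_yields_one_intron_per_gene(self):
        scenario = SpliceScenario(n_genes=5, exons_per_gene=(2, 2), seed=3)
        annotation, _, _ = generate_annotation(scenario)
        assert all(len(g.introns) == 1 for g in annotation)

    def test_structures_satisfy_model_invariants(self):
        scenario = SpliceScenario(n_genes=40, exons_per_gene=(2, 6), seed=5)
        annotation, chrom_lengths, _ = generate_annotation(scenario)
        assert len(annotation) == 40
        for gene in annotation:
            span = gene.span
            assert span.end < chrom_lengths[gene.chrom]
            for exons in gene.transcripts:
                for a, b in zip(exons, exons[1:]):
                    assert b.start > a.end

    def test_pinned_annotation_seed_fixes_genes_across_read_seeds(self, tmp_path):
        base = dict(n_genes=4, annotation_seed=9, expression=40.0)
        c1 = simulate_cohort(SpliceScenario(seed=1, **base), tmp_path / "a")
        c2 = simulate_cohort(SpliceScenario(seed=2, **base), tmp_path / "b")
        assert c1.gff3_path.read_bytes() == c2.gff3_path.read_bytes()
        s = next(iter(c1.sam_paths))
        assert c1.sam_paths[s].read_bytes() != c2.sam_paths[s].read_bytes()


class TestDeterminismAndConservation:
    def test_same_seed_is_byte_identical(self, tmp_path):
        scenario = dict(n_genes=5, expression=60.0, n_ir=1, seed=42,
                        reporter=ReporterLocusSpec(fragments_per_replicate=200))
        c1 = simulate_cohort(SpliceScenario(**scenario), tmp_path / "x")
        c2 = simulate_cohort(SpliceScenario(**scenario), tmp_path / "y")
        assert c1.gff3_path.read_bytes() == c2.gff3_path.read_bytes()
        for sample in c1.sam_paths:
            assert (
                c1.sam_paths[sample].read_bytes()
                == c2.sam_paths[sample].read_bytes()
            )

    def test_record_count_equals_fragment_count(self, small_cohort):
        for sample, path in small_cohort.sam_paths.items():
            n_records = sum(1 for _ in read_sam(path))
            assert n_records == int(small_cohort.fragment_counts[sample].sum())


class TestGenerativeRules:
    def _one_intron_cohort(self, tmp_path, retention, n_genes=3, seed=8,
                           expression=150.0):
        scenario = SpliceScenario(
            n_genes=n_genes,
            exons_per_gene=(2, 2),
            retention_frac=retention,
            expression=expression,
            seed=seed,
        )
        return simulate_cohort(scenario, tmp_path)

    def test_zero_retention_leaves_introns_uncovered(self, tmp_path):
        cohort = self._one_intron_cohort(tmp_path, retention=0.0)
        introns = {
            (g.chrom, i.interval.start, i.interval.end)
            for g in cohort.annotation
            for i in g.introns
        }
        for path in cohort.sam_paths.values():
            for rec in read_sam(path):
                for s, e in rec.blocks:
                    for chrom, istart, iend in introns:
                        if rec.chrom == chrom:
                            assert not (s <= iend and istart <= e)

    def test_full_retention_yields_no_junction_reads(self, tmp_path):
        cohort = self._one_intron_cohort(tmp_path, retention=1.0)
        for path in cohort.sam_paths.values():
            assert extract_junctions(read_sam(path)) == {}

    def test_depth_ratio_recovers_retention_fraction(self, tmp_path):
        """Binomial oracle on the generator: the count of reads touching an
        intron matches its closed-form binomial expectation, and the
        intron/flank depth ratio estimates the per-fragment retention
        probability (long exons keep the estimator's placement bias small
        relative to its sampling error)."""
        p = 0.3
        read_len = 100
        scenario = SpliceScenario(
            n_genes=8,
            exons_per_gene=(2, 2),
            exon_len=(2000, 2000),
            intron_len=(150, 150),
            expression=2000.0,
            expression_log2_sd=0.0,
            retention_frac=p,
            read_len=read_len,
            seed=13,
        )
        cohort = simulate_cohort(scenario, tmp_path)
        ratios = []
        observed_touching = 0
        expected_touching = 0.0
        for sample, path in cohort.sam_paths.items():
            records = list(read_sam(path))
            depth = compute_depth(records, cohort.chrom_lengths)
            by_gene: dict[str, int] = {}
            for rec in records:
                gid = rec.read_id.split(":")[0]
                by_gene[gid] = by_gene.get(gid, 0) + 1
            for gene in cohort.annotation:
                ratios.append(intron_retention_ratio(depth, gene, 0))
                iv = gene.introns[0].interval
                n = by_gene[gene.gene_id]
                t_retained = 4000 + 150  # exons + retained intron
                # a read touches the intron iff its start falls in a window
                # of (intron + read - 1) positions of the retained molecule
                window = iv.length + read_len - 1
                expected_touching += n * p * window / (t_retained - read_len + 1)
                observed_touching += sum(
                    1
                    for rec in records
                    if rec.chrom == gene.chrom
                    and any(s <= iv.end and iv.start <= e for s, e in rec.blocks)
                )
        # fragment-level binomial contract
        assert abs(observed_touching - expected_touching) <= 4 * np.sqrt(
            expected_touching
        )
        # ratio recovery: mean over gene x replicate measurements
        sem = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert sem < 0.02  # the estimator is precise at 50x
        assert abs(np.mean(ratios) - p) <= 3 * sem


class TestGroundTruthSufficiency:
    def test_truth_tables_label_every_feature(self, small_cohort):
        annotation = small_cohort.annotation
        reporter = small_cohort.scenario.reporter.gene_id
        n_introns = sum(
            len(g.introns) for g in annotation if g.gene_id != reporter
        )
        assert len(small_cohort.intron_truth) == n_introns
        planted = small_cohort.intron_truth["planted"]
        assert (planted == "IR").sum() == small_cohort.scenario.n_ir
        assert (planted == "MES").sum() == small_cohort.scenario.n_mes
        assert len(small_cohort.alt_truth) == (
            small_cohort.scenario.n_alt_acceptor + small_cohort.scenario.n_alt_donor
        )
        assert small_cohort.exon_truth["planted"].sum() == small_cohort.scenario.n_es

    def test_annotation_file_round_trips(self, small_cohort):
        reread = read_gff3(small_cohort.gff3_path)
        assert len(reread) == len(small_cohort.annotation)
        assert reread.total_introns == small_cohort.annotation.total_introns
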