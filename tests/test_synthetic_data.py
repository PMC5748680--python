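import numpy as np
import pytest

from genefam import synthetic_data as synth
from genefam.domain_scan import scan_proteome
from genefam.expression import call_degs, cluster_patterns, deg_gene_set, tissue_groups
from genefam.genome_map import detect_tandem_arrays
from genefam.io_formats import write_fasta, write_gff3


class TestSimulateGenome:
    def test_multinomial_draw_matches_truth(self):
        mix = {"1R": 0.5122, "R2R3": 0.4669, "R1R2R3": 0.0174, "ATYPICAL": 0.0035}
        _, _, truth = synth.simulate_genome(
            n_family_genes=287, n_background_genes=2000, subfamily_mix=mix, seed=3
        )
        counts = {s: 0 for s in mix}
        for label in truth.subfamily.values():
            counts[label] += 1
        assert sum(counts.values()) == 287
        # the dominant subfamilies follow the planted proportions
        assert abs(counts["1R"] / 287 - 0.5122) < 0.1
        assert abs(counts["R2R3"] / 287 - 0.4669) < 0.1

    def test_single_planted_pair(self):
        models, _, truth = synth.simulate_genome(
            n_family_genes=10, n_background_genes=100, tandem_spec=[(2, 1)], seed=4
        )
        assert len(truth.tandem_arrays) == 1
        pair = truth.tandem_arrays[0]
        by_lg = {}
        for gm in models:
            by_lg.setdefault(gm.linkage_group, []).append(gm)
        lg = next(gm.linkage_group for gm in models if gm.gene_id == pair[0])
        ordered = [g.gene_id for g in sorted(by_lg[lg], key=lambda g: g.start)]
        between = ordered.index(pair[1]) - ordered.index(pair[0]) - 1
        assert 0 <= between <= 3

    def test_seed_determinism_bytes(self, tmp_path):
        for run in ("one", "two"):
            models, proteins, _ = synth.simulate_genome(
                n_family_genes=20, n_background_genes=150, seed=9
            )
            write_fasta(proteins, tmp_path / f"{run}.fasta")
            write_gff3(models, tmp_path / f"{run}.gff3")
        assert (tmp_path / "one.fasta").read_bytes() == (tmp_path / "two.fasta").read_bytes()
        assert (tmp_path / "one.gff3").read_bytes() == (tmp_path / "two.gff3").read_bytes()

    def test_array_budget_error(self):
        with pytest.raises(ValueError, match="tandem"):
            synth.simulate_genome(
                n_family_genes=5, n_background_genes=100, tandem_spec=[(4, 2)], seed=1
            )

    def test_bad_mix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            synth.simulate_genome(
                n_family_genes=5, n_background_genes=100, subfamily_mix={"1R": 0.5}, seed=1
            )

    def test_unanchored_genes_on_scaffolds(self):
        models, _, truth = synth.simulate_genome(
            n_family_genes=20, n_background_genes=150, n_unanchored_family=4, seed=5
        )
        scaffold_genes = [m for m in models if m.linkage_group.startswith("scaffold")]
        assert len(scaffold_genes) == 4
        assert all(g.gene_id in truth.subfamily for g in scaffold_genes)

    def test_truth_json_roundtrip(self, tmp_path, small_dataset):
        _, _, truth = small_dataset
        truth.to_json(tmp_path / "truth.json")
        back = synth.SyntheticTruth.from_json(tmp_path / "truth.json")
        assert back.subfamily == truth.subfamily
        assert back.tandem_arrays == truth.tandem_arrays
        assert back.exon_counts == truth.exon_counts


class TestGeneratorDetectorClosure:
    def test_noiseless_label_recovery_is_total(self, small_dataset, profile):
        _, proteins, truth = small_dataset
        _, calls = scan_proteome(proteins, profile)
        for call in calls:
            expected = truth.subfamily.get(call.gene_id, "NOT_FAMILY")
            assert call.subfamily == expected

    def test_noisy_label_recovery_95pct(self, profile):
        _, proteins, truth = synth.simulate_genome(
            n_family_genes=80, n_background_genes=400, motif_noise=0.10, seed=31
        )
        _, calls = scan_proteome(proteins, profile)
        correct = sum(
            1
            for c in calls
            if c.subfamily == truth.subfamily.get(c.gene_id, "NOT_FAMILY")
        )
        assert correct / len(calls) >= 0.95

    def test_tandem_arrays_exact(self, small_dataset):
        models, _, truth = small_dataset
        arrays = detect_tandem_arrays(models, truth.family_genes)
        assert {a.members for a in arrays} == {tuple(a) for a in truth.tandem_arrays}


@pytest.fixture(scope="module")
def dataset():
    _, _, truth = synth.simulate_genome(
        n_family_genes=287, n_background_genes=2000, seed=41
    )
    tables = synth.simulate_expression(truth, noise_sd=0.2, seed=42)
    return truth, tables


class TestSimulateExpression:

    def test_all_five_pattern_above_one(self, dataset):
        truth, (tissues, _, _) = dataset
        frame = tissues.to_frame()
        for gene, pattern in truth.tissue_pattern.items():
            if len(pattern) == len(synth.TISSUES):
                assert (frame.loc[gene] > 1).all()

    def test_waterlogging_group_I_induced_mid(self, dataset):
        truth, (_, waterlogging, _) = dataset
        frame = waterlogging.to_frame()
        group_I = [g for g, grp in truth.waterlogging_group.items() if grp == "I"]
        assert group_I
        fold = frame.loc[group_I, "9h"] / frame.loc[group_I, "control"]
        assert (fold > 2).mean() >= 0.95

    def test_deg_recovery_95pct(self, dataset):
        truth, (_, waterlogging, drought) = dataset
        for table_, group_of, signatures in (
            (waterlogging, truth.waterlogging_group, synth.WATERLOGGING_SIGNATURES),
            (drought, truth.drought_group, synth.DROUGHT_SIGNATURES),
        ):
            calls = call_degs(table_, "control")
            degs = deg_gene_set(calls)
            planted = set(group_of)
            recovered = len(degs & planted) / len(planted)
            assert recovered >= 0.95
        clusters = cluster_patterns(call_degs(waterlogging, "control"))
        # most genes land in their planted trajectory cluster
        correct = 0
        for gene, group in truth.waterlogging_group.items():
            sig = synth.WATERLOGGING_SIGNATURES[group]
            correct += clusters.signatures.get(gene) == sig
        assert correct / len(truth.waterlogging_group) >= 0.90

    def test_unknown_group_label_rejected(self):
        _, _, truth = synth.simulate_genome(
            n_family_genes=20, n_background_genes=150, seed=43
        )
        with pytest.raises(ValueError, match="unknown stress pattern"):
            synth.simulate_expression(
                truth, stress_spec={"waterlogging": {"XX": 3}}, seed=1
            )

    def test_spec_coverage_must_match(self):
        _, _, truth = synth.simulate_genome(
            n_family_genes=20, n_background_genes=150, seed=44
        )
        with pytest.raises(ValueError, match="tissue_spec"):
            synth.simulate_expression(truth, tissue_spec=[("ALL", 3)], seed=1)


class TestSimulateQpcr:
    def test_planted_fold_22_recovered(self):
        table = synth.simulate_qpcr(["g1"], [22.0], reference_gene="ref", seed=6)
        from genefam.expression import ddct

        _, gmean = ddct(table, "g1", "ref")
        assert 18 <= gmean <= 27

    def test_fold_one_ns(self):
        from genefam.expression import classify_induction, ddct

        table = synth.simulate_qpcr(["g1"], [1.0], reference_gene="ref", seed=7)
        _, gmean = ddct(table, "g1", "ref")
        assert classify_induction(gmean) == "NS"

    def test_seed_determinism(self):
        one = synth.simulate_qpcr(["g1"], [5.0], seed=12)
        two = synth.simulate_qpcr(["g1"], [5.0], seed=12)
        assert one.equals(two)

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_qpcr(["g1"], [0.0], seed=1)

    def test_reference_fold_is_one_by_construction(self):
        from genefam.expression import ddct

        table = synth.simulate_qpcr(["g1"], [3.0], reference_gene="ref", seed=13)
        _, gmean = ddct(table, "ref", "ref")
        assert gmean == 1.0


class TestReferenceProteome:
    def test_ortholog_map_refers_to_emitted_genes(self):
        _, proteins, truth = synth.simulate_genome(
            n_family_genes=30, n_background_genes=200, seed=51
        )
        proteins, refs = synth.simulate_reference_proteome(
            proteins, truth, n_refs=5, seed=52
        )
        gene_ids = {p.gene_id for p in proteins}
        assert set(truth.orthologs) <= gene_ids
        assert set(truth.orthologs.values()) <= {r.gene_id for r in refs}
        assert set(truth.reference_labels) == {r.gene_id for r in refs}

    def test_budget_error(self):
        _, proteins, truth = synth.simulate_genome(
            n_family_genes=5, n_background_genes=100, tandem_spec=(), seed=53
        )
        with pytest.raises(ValueError, match="budget"):
            synth.simulate_reference_proteome(
                proteins, truth, n_refs=3, copy_numbers=[3, 2, 2], seed=1
            )
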