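import json

import pytest

from multiguide import (
    Exon,
    GeneModel,
    SequenceRecord,
    build_gene_sequence,
    find_sites,
    make_isoform_fixture,
    make_ohnolog_fixture,
    reverse_complement,
    transcript_sequence,
)
from multiguide.genemodel import (
    gene_models_from_json,
    gene_models_to_json,
    read_gene_models_gff3,
    truth_from_json,
    truth_to_json,
    write_gene_models_gff3,
)

from conftest import random_dna


class TestBuildGeneSequence:
    def test_disjoint_exons_concatenate(self, rng):
        genome = random_dna(rng, 40)
        seq, cmap = build_gene_sequence(
            [Exon("e1", 0, 10, "+"), Exon("e2", 20, 30, "+")], genome
        )
        assert seq == genome[0:10] + genome[20:30]
        assert cmap.to_genomic(0) == 0 and cmap.to_genomic(10) == 20

    def test_overlapping_exons_merge(self, rng):
        genome = random_dna(rng, 40)
        seq, _ = build_gene_sequence(
            [Exon("e1", 0, 15, "+"), Exon("e2", 10, 30, "+")], genome
        )
        assert seq == genome[0:30]

    def test_minus_strand_reverse_complement(self, rng):
        genome = random_dna(rng, 40)
        seq, cmap = build_gene_sequence([Exon("e1", 5, 15, "-")], genome)
        assert seq == reverse_complement(genome[5:15])
        assert cmap.to_genomic(0) == 14

    def test_mixed_strands_rejected(self, rng):
        genome = random_dna(rng, 40)
        with pytest.raises(ValueError, match="mixed"):
            build_gene_sequence(
                [Exon("e1", 0, 10, "+"), Exon("e2", 20, 30, "-")], genome
            )

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_coordinate_map_bijective_on_exonic_positions(self, rng, strand):
        genome = random_dna(rng, 500)
        exons = [
            Exon("e1", 10, 120, strand),
            Exon("e2", 200, 310, strand),
            Exon("e3", 400, 480, strand),
        ]
        seq, cmap = build_gene_sequence(exons, genome)
        assert len(seq) == len(cmap)
        for _ in range(1000):
            i = int(rng.integers(0, len(cmap)))
            assert cmap.to_gene_local(cmap.to_genomic(i)) == i

    def test_non_exonic_position_rejected(self, rng):
        genome = random_dna(rng, 100)
        _, cmap = build_gene_sequence([Exon("e1", 10, 20, "+")], genome)
        with pytest.raises(ValueError):
            cmap.to_gene_local(50)


def gene_with_transcripts(rng) -> GeneModel:
    genome = random_dna(rng, 400)
    exons = [
        Exon("e1", 10, 60, "+"),
        Exon("e2", 100, 170, "+"),
        Exon("e3", 250, 330, "+"),
    ]
    return GeneModel(
        gene_id="g1", symbol="sym", species="test", exons=exons,
        transcripts={
            "t_all": ["e1", "e2", "e3"],
            "t_skip": ["e1", "e3"],
            "t_single": ["e2"],
        },
        genome=genome,
    )


class TestTranscriptSequence:
    def test_two_exon_boundaries(self, rng):
        gene = gene_with_transcripts(rng)
        seq, bounds = transcript_sequence(gene, "t_all")
        assert bounds == [0, 50, 120, 200]
        assert len(seq) == 200

    def test_single_exon_equals_exon_sequence(self, rng):
        gene = gene_with_transcripts(rng)
        seq, bounds = transcript_sequence(gene, "t_single")
        assert seq == gene.exon_sequence("e2")
        assert bounds == [0, 70]

    def test_skipped_exon_removes_internal_junction(self, rng):
        gene = gene_with_transcripts(rng)
        _, bounds = transcript_sequence(gene, "t_skip")
        assert bounds == [0, 50, 130]

    def test_unknown_transcript_rejected(self, rng):
        with pytest.raises(KeyError):
            transcript_sequence(gene_with_transcripts(rng), "nope")

    def test_all_exon_transcript_equals_gene_sequence(self, rng):
        gene = gene_with_transcripts(rng)
        assert transcript_sequence(gene, "t_all")[0] == gene.gene_sequence

    def test_unknown_exon_in_transcript_rejected(self, rng):
        genome = random_dna(rng, 100)
        with pytest.raises(ValueError):
            GeneModel(
                gene_id="g", symbol="g", species="t",
                exons=[Exon("e1", 0, 50, "+")],
                transcripts={"t1": ["e1", "missing"]}, genome=genome,
            )


class TestOhnologFixture:
    def test_construction_contract(self):
        (ga, gb), truth = make_ohnolog_fixture(
            seed=1, length=1000, divergence=0.1, n_common=3, n_unique_each=2
        )
        assert len(ga.gene_sequence) == len(gb.gene_sequence) == 1000
        assert len(truth.common) == 3
        assert len(truth.unique["gene_a"]) == len(truth.unique["gene_b"]) == 2
        assert {ga.strand, gb.strand} == {"+", "-"}

    def test_deterministic_for_seed(self):
        a = make_ohnolog_fixture(seed=9)
        b = make_ohnolog_fixture(seed=9)
        assert json.dumps(gene_models_to_json(list(a[0]))) == json.dumps(
            gene_models_to_json(list(b[0]))
        )
        assert truth_to_json(a[1]) == truth_to_json(b[1])

    def test_zero_divergence_no_uniques_gives_identical_copies(self):
        (ga, gb), _ = make_ohnolog_fixture(
            seed=2, divergence=0.0, n_unique_each=0, n_common=2
        )
        assert ga.gene_sequence == gb.gene_sequence

    def test_unique_truth_distances_at_least_three(self):
        _, truth = make_ohnolog_fixture(seed=3)
        for pa, pb in zip(truth.unique["gene_a"], truth.unique["gene_b"]):
            d = sum(x != y for x, y in zip(pa.protospacer, pb.protospacer))
            assert d >= 3

    def test_background_carries_only_planted_sites(self, spec):
        (ga, gb), truth = make_ohnolog_fixture(seed=4)
        want_a = {(p.start, p.strand) for p in truth.unique["gene_a"]} | {
            (c.per_sequence["gene_a"].start, c.per_sequence["gene_a"].strand)
            for c in truth.common
        }
        got_a = {
            (s.start, s.strand)
            for s in find_sites(SequenceRecord("gene_a", ga.gene_sequence), spec)
        }
        assert got_a == want_a

    def test_impossible_placement_rejected(self):
        with pytest.raises(ValueError, match="length"):
            make_ohnolog_fixture(seed=1, length=120, n_common=5, n_unique_each=5)

    def test_divergence_out_of_range(self):
        with pytest.raises(ValueError):
            make_ohnolog_fixture(seed=1, divergence=0.5)


class TestIsoformFixture:
    def test_construction_contract(self):
        gene, truth = make_isoform_fixture(seed=7, n_exons=5, n_transcripts=3)
        assert len(gene.transcripts) == 3
        for tid in gene.transcripts:
            assert len(truth.unique[tid]) >= 1
        assert len(truth.common) == 1

    def test_deterministic_for_seed(self):
        a = make_isoform_fixture(seed=11)
        b = make_isoform_fixture(seed=11)
        assert gene_models_to_json([a[0]]) == gene_models_to_json([b[0]])

    def test_planted_sites_inside_single_exons(self):
        gene, truth = make_isoform_fixture(seed=13)
        for tid, planted in truth.unique.items():
            _, bounds = gene.transcript_sequence(tid)
            for p in planted:
                assert any(
                    a <= p.start and p.end <= b
                    for a, b in zip(bounds[:-1], bounds[1:])
                )

    def test_no_private_exon_rejected(self):
        with pytest.raises(ValueError, match="private"):
            make_isoform_fixture(seed=1, n_exons=3, n_transcripts=3)

    def test_too_short_alt_exon_rejected(self):
        with pytest.raises(ValueError, match="alt_exon_length"):
            make_isoform_fixture(seed=1, alt_exon_length=30)


class TestGeneModelIO:
    def test_json_round_trip(self):
        (ga, gb), _ = make_ohnolog_fixture(seed=21)
        payload = json.loads(json.dumps(gene_models_to_json([ga, gb])))
        back = gene_models_from_json(payload)
        assert [g.gene_id for g in back] == ["gene_a", "gene_b"]
        assert back[0].gene_sequence == ga.gene_sequence
        assert back[1].gene_sequence == gb.gene_sequence
        assert back[1].transcripts == gb.transcripts

    def test_truth_json_round_trip(self):
        _, truth = make_ohnolog_fixture(seed=22)
        assert truth_from_json(truth_to_json(truth)).unique == truth.unique

    def test_gff3_round_trip(self, tmp_path):
        gene, _ = make_isoform_fixture(seed=23)
        gff, fasta = tmp_path / "g.gff3", tmp_path / "g.fasta"
        write_gene_models_gff3([gene], gff, fasta)
        back = read_gene_models_gff3(gff, fasta)
        assert len(back) == 1
        assert back[0].gene_sequence == gene.gene_sequence
        assert set(back[0].transcripts) == set(gene.transcripts)
        for tid in gene.transcripts:
            assert back[0].transcript_sequence(tid) == gene.transcript_sequence(tid)

    def test_gff3_round_trip_minus_strand(self, tmp_path):
        (ga, gb), _ = make_ohnolog_fixture(seed=24)
        gff, fasta = tmp_path / "g.gff3", tmp_path / "g.fasta"
        write_gene_models_gff3([ga, gb], gff, fasta)
        back = {g.gene_id: g for g in read_gene_models_gff3(gff, fasta)}
        assert back["gene_b"].strand == "-"
        assert back["gene_b"].gene_sequence == gb.gene_sequence
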