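import pytest

from multiguide import (
    Exon,
    GeneModel,
    MultiAlignment,
    SequenceRecord,
    TargetSite,
    TargetSpec,
    filter_within_exon,
    find_common_sites,
    find_unique_sites,
    hamming_compare,
    progressive_align,
)

from conftest import plant, random_dna
from oracles import naive_find_sites, naive_unique_sites


def gapless_alignment(seqs: dict[str, str]) -> MultiAlignment:
    return MultiAlignment(list(seqs.items()))


class TestHammingCompare:
    def test_identical(self):
        assert hamming_compare("A" * 20, "A" * 20) == (0, False)

    def test_three_mismatches_stop_early(self):
        a = list("A" * 20)
        for i in (1, 5, 9):
            a[i] = "C"
        assert hamming_compare("".join(a), "A" * 20) == (3, True)

    def test_two_mismatches_complete(self):
        a = list("A" * 20)
        for i in (0, 19):
            a[i] = "G"
        assert hamming_compare("".join(a), "A" * 20) == (2, False)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hamming_compare("ACG", "AC")


SITE = "TATTATAATTATTAATATAT" + "AGG"


class TestFindCommonSites:
    def test_identical_pair_single_common(self, records_pair, spec):
        records, site = records_pair
        aln = gapless_alignment({r.id: r.residues for r in records})
        commons = find_common_sites(aln, spec)
        assert len(commons) == 1
        cs = commons[0]
        assert cs.mismatch_column is None
        assert cs.strand == "+"
        assert set(cs.per_sequence_sites) == {"s1", "s2"}
        for rid, s in cs.per_sequence_sites.items():
            assert (s.start, s.end, s.protospacer) == (20, 43, site[:20])

    def test_seed_substitution_recovered_with_mismatch_option(self, at_background):
        seq1 = plant(at_background(60), 20, SITE)
        seq2 = list(seq1)
        seq2[23] = "C"  # protospacer position 3: inside the 8-nt seed
        aln = gapless_alignment({"s1": seq1, "s2": "".join(seq2)})
        assert find_common_sites(aln, TargetSpec()) == []
        commons = find_common_sites(aln, TargetSpec(allow_seed_mismatch=True))
        assert len(commons) == 1
        assert commons[0].mismatch_column == 23
        assert commons[0].per_sequence_sites["s2"].protospacer[3] == "C"

    def test_pam_substitution_never_common(self, at_background):
        seq1 = plant(at_background(60), 20, SITE)
        seq2 = seq1[:41] + "T" + seq1[42:]  # AGG -> ATG
        aln = gapless_alignment({"s1": seq1, "s2": seq2})
        assert find_common_sites(aln, TargetSpec(allow_seed_mismatch=True)) == []

    def test_disagreement_at_unconstrained_pam_position_still_common(
        self, at_background
    ):
        seq1 = plant(at_background(60), 20, SITE)
        seq2 = seq1[:40] + "T" + seq1[41:]  # AGG -> TGG: the N of NGG
        aln = gapless_alignment({"s1": seq1, "s2": seq2})
        commons = find_common_sites(aln, TargetSpec())
        assert len(commons) == 1
        assert commons[0].mismatch_column is None
        assert commons[0].per_sequence_sites["s1"].pam_observed == "AGG"
        assert commons[0].per_sequence_sites["s2"].pam_observed == "TGG"

    def test_gap_column_blocks_window(self, at_background):
        seq = plant(at_background(60), 20, SITE)
        with_gap = seq[:30] + "-" + seq[31:]
        aln = MultiAlignment([("s1", seq), ("s2", with_gap)])
        assert find_common_sites(aln, TargetSpec(allow_seed_mismatch=True)) == []

    def test_sites_map_through_row_coordinates(self, at_background):
        # a 10-nt insertion upstream shifts s2's site coordinates
        core = plant(at_background(60), 20, SITE)
        s2 = "GTCA" * 3 + core[2:]
        recs = [SequenceRecord("s1", core), SequenceRecord("s2", s2)]
        aln = progressive_align(recs)
        commons = find_common_sites(aln, TargetSpec())
        assert len(commons) == 1
        got = commons[0].per_sequence_sites
        assert got["s1"].start == 20
        assert got["s2"].start == 30
        for rid, rec in (("s1", recs[0]), ("s2", recs[1])):
            got[rid].check_round_trip(rec)

    def test_requires_two_rows(self, spec):
        with pytest.raises(ValueError):
            find_common_sites(MultiAlignment([("a", "ACGT")]), spec)

    def test_consensus_equivalence_on_random_gapless_families(self, rng, spec):
        """0-mismatch consensus hits equal per-sequence enumeration +
        agreement at aligned coordinates (independent oracle)."""
        from oracles import naive_common_sites

        for _ in range(25):
            n = int(rng.integers(120, 260))
            base = random_dna(rng, n)
            seqs = {}
            for i in range(int(rng.integers(2, 4))):
                s = list(base)
                for _m in range(int(rng.integers(0, 12))):
                    p = int(rng.integers(0, n))
                    s[p] = "ACGT"[int(rng.integers(0, 4))]
                seqs[f"r{i}"] = "".join(s)
            aln = gapless_alignment(seqs)
            got = {
                (c.strand, c.consensus_start) for c in find_common_sites(aln, spec)
            }
            assert got == naive_common_sites(seqs, spec)


class TestFindUniqueSites:
    def make_pair(self, at_background, proto2: str):
        seq1 = plant(at_background(80), 30, SITE)
        seq2 = plant(at_background(80), 30, proto2 + "AGG")
        return [SequenceRecord("s1", seq1), SequenceRecord("s2", seq2)]

    def test_distant_planted_sites_both_unique(self, at_background, spec):
        # distance 5 from SITE's protospacer
        proto2 = list(SITE[:20])
        for i in (2, 6, 10, 14, 18):
            proto2[i] = "A" if proto2[i] == "T" else "T"
        records = self.make_pair(at_background, "".join(proto2))
        uniques = find_unique_sites(records, spec)
        assert {(u.owner_sequence_id, u.site.start) for u in uniques} == {
            ("s1", 30), ("s2", 30),
        }
        assert all(u.min_cross_distance == 5 for u in uniques)

    def test_distance_two_not_unique(self, at_background, spec):
        proto2 = list(SITE[:20])
        for i in (2, 6):
            proto2[i] = "A" if proto2[i] == "T" else "T"
        records = self.make_pair(at_background, "".join(proto2))
        assert find_unique_sites(records, spec) == []

    def test_identical_sites_not_unique(self, records_pair, spec):
        records, _ = records_pair
        assert find_unique_sites(records, spec) == []

    def test_within_owner_duplicate_remains_eligible(self, at_background, spec):
        seq1 = plant(plant(at_background(120), 10, SITE), 60, SITE)
        seq2 = at_background(120)
        records = [SequenceRecord("s1", seq1), SequenceRecord("s2", seq2)]
        uniques = find_unique_sites(records, spec)
        assert {(u.owner_sequence_id, u.site.start) for u in uniques} == {
            ("s1", 10), ("s1", 60),
        }
        # no competing sites at all in s2
        assert all(u.min_cross_distance is None for u in uniques)

    def test_requires_two_records(self, spec):
        with pytest.raises(ValueError):
            find_unique_sites([SequenceRecord("a", "ACGT" * 10)], spec)

    def test_equals_full_hamming_brute_force(self, rng, spec):
        """Early-terminating screen equals all-pairs full-Hamming oracle."""
        for _ in range(30):
            records = [
                SequenceRecord(f"r{i}", random_dna(rng, 200)) for i in range(3)
            ]
            got = {
                (u.owner_sequence_id, u.site.strand, u.site.start)
                for u in find_unique_sites(records, spec)
            }
            site_lists = {
                r.id: sorted(naive_find_sites(r.residues, spec)) for r in records
            }
            assert got == naive_unique_sites(site_lists)
            # every reported unique site is >=3 from every other-sequence site
            for u in find_unique_sites(records, spec):
                assert u.min_cross_distance is None or u.min_cross_distance >= 3


def two_exon_gene() -> GeneModel:
    """One transcript of two 50-nt exons separated by an intron."""
    genome = random_dna(__import__("numpy").random.default_rng(5), 160)
    exons = [Exon("e1", 10, 60, "+"), Exon("e2", 100, 150, "+")]
    return GeneModel(
        gene_id="g", symbol="g", species="test", exons=exons,
        transcripts={"t1": ["e1", "e2"]}, genome=genome,
    )


def make_site(seq_id: str, start: int, gene: GeneModel, context: str) -> TargetSite:
    if context == "transcript":
        seq, _ = gene.transcript_sequence("t1")
    else:
        seq = gene.gene_sequence
    window = seq[start : start + 23]
    return TargetSite(
        sequence_id=seq_id, strand="+", start=start, end=start + 23,
        protospacer=window[:20], pam_observed=window[20:],
    )


class TestFilterWithinExon:
    @pytest.mark.parametrize("context", ["transcript", "gene"])
    def test_contained_site_retained_with_index(self, context):
        gene = two_exon_gene()
        sid = "t1" if context == "transcript" else "g"
        site = make_site(sid, 10, gene, context)
        kept = filter_within_exon([site], gene, context=context)
        assert kept == [site]
        assert site.annotations["exon_index"] == 0

    @pytest.mark.parametrize("context", ["transcript", "gene"])
    def test_junction_straddling_site_removed(self, context):
        gene = two_exon_gene()
        sid = "t1" if context == "transcript" else "g"
        site = make_site(sid, 40, gene, context)  # spans the 50|50 junction
        assert filter_within_exon([site], gene, context=context) == []

    def test_flush_boundary_site_retained(self):
        gene = two_exon_gene()
        site = make_site("t1", 27, gene, "transcript")  # ends exactly at 50
        kept = filter_within_exon([site], gene, context="transcript")
        assert kept and site.annotations["exon_index"] == 0

    def test_second_exon_index(self):
        gene = two_exon_gene()
        site = make_site("t1", 60, gene, "transcript")
        filter_within_exon([site], gene, context="transcript")
        assert site.annotations["exon_index"] == 1

    def test_out_of_bounds_rejected(self):
        gene = two_exon_gene()
        site = make_site("t1", 27, gene, "transcript")
        site.start, site.end = 90, 113  # past the 100-nt transcript
        with pytest.raises(ValueError):
            filter_within_exon([site], gene, context="transcript")

    def test_invalid_context_rejected(self):
        with pytest.raises(ValueError):
            filter_within_exon([], two_exon_gene(), context="genome")

    def test_removed_sites_are_exactly_junction_spanners(self):
        """Exhaustive over every start: removals intersect >=2 exons."""
        gene = two_exon_gene()
        for start in range(0, 78):
            site = make_site("t1", start, gene, "transcript")
            kept = filter_within_exon([site], gene, context="transcript")
            spans_junction = start < 50 and start + 23 > 50
            assert bool(kept) == (not spans_junction)
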