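"""ORF finding and conserved-domain validation."""

import random

import pytest

from mgecds import (
    DomainHit,
    DomainTable,
    MergedRegion,
    MgecdsError,
    OrfRecord,
    find_orfs,
    project_to_genome,
    translate,
    validate_orfs,
)
from mgecds.formats import reverse_complement

from .conftest import random_dna
from .oracles import orf_oracle


def as_tuples(orfs):
    return {(o.start, o.end, o.strand, o.frame, o.has_stop) for o in orfs}


class TestFindOrfs:
    def test_minimal_atg_orf(self):
        orfs = find_orfs("ATGAAATAA", min_len=9, start_policy="atg_only")
        assert len(orfs) == 1
        orf = orfs[0]
        assert (orf.start, orf.end) == (0, 9)
        assert orf.aa_seq == "MK"
        assert orf.has_stop

    def test_no_atg_no_stop_sequence(self):
        assert find_orfs("TTTTTTTTT", min_len=9, start_policy="atg_only") == []
        orfs = find_orfs("TTTTTTTTT", min_len=9, start_policy="any_sense")
        assert as_tuples(orfs) == {(0, 9, "+", 0, False)}

    def test_defaults_match_conventional_policy(self):
        import inspect

        sig = inspect.signature(find_orfs)
        assert sig.parameters["min_len"].default == 1000
        assert sig.parameters["genetic_code"].default == 1
        assert sig.parameters["start_policy"].default == "atg_only"
        assert sig.parameters["strand_policy"].default == "plus_only"

    def test_unknown_genetic_code(self):
        with pytest.raises(MgecdsError, match="genetic code"):
            find_orfs("ATGAAATAA", min_len=9, genetic_code=7)

    def test_stop_span_and_translation_accounting(self):
        # span includes the stop; translation excludes it
        seq = "ATG" + "GCT" * 10 + "TGA"
        (orf,) = find_orfs(seq, min_len=6)
        assert orf.span == 36
        assert orf.aa_seq == "M" + "A" * 10
        assert len(orf.aa_seq) == orf.span // 3 - 1

    def test_first_atg_after_stop_is_chosen(self):
        # two ATGs in the same stop-free run: the first (maximal) wins
        seq = "TAA" + "ATGCCCATGAAA" + "TAG"
        (orf,) = find_orfs(seq, min_len=3)
        assert (orf.start, orf.end) == (3, 18)

    def test_minus_strand_orfs_under_both_policy(self):
        core = "ATG" + "GGT" * 20 + "TAA"
        seq = reverse_complement(core)
        assert find_orfs(seq, min_len=30, strand_policy="plus_only") == []
        orfs = find_orfs(seq, min_len=30, strand_policy="both")
        minus = [o for o in orfs if o.strand == "-"]
        assert len(minus) == 1
        assert minus[0].nt_seq == core
        # coordinates are on the input plus strand
        assert (minus[0].start, minus[0].end) == (0, len(core))

    @pytest.mark.parametrize("start_policy", ["atg_only", "any_sense"])
    @pytest.mark.parametrize("strand_policy", ["plus_only", "both"])
    @pytest.mark.parametrize("min_len", [30, 300])
    def test_oracle_equivalence_random_sequences(self, start_policy, strand_policy, min_len):
        """The scanner must equal brute-force predicate enumeration exactly."""
        rng = random.Random(f"{start_policy}-{strand_policy}-{min_len}")
        for _ in range(60):
            seq = random_dna(rng, rng.randint(200, 2000))
            got = as_tuples(find_orfs(seq, min_len, 1, start_policy, strand_policy))
            want = orf_oracle(seq, min_len, start_policy, strand_policy)
            assert got == want

    def test_atg_only_subset_of_any_sense_termini(self):
        rng = random.Random(7)
        for _ in range(25):
            seq = random_dna(rng, rng.randint(200, 1500))
            atg = find_orfs(seq, 30, start_policy="atg_only")
            any_ = find_orfs(seq, 3, start_policy="any_sense")
            any_termini = {(o.end, o.strand, o.frame) for o in any_}
            for o in atg:
                assert (o.end, o.strand, o.frame) in any_termini
                assert o.nt_seq[:3] == "ATG"

    def test_translation_is_codon_by_codon(self):
        rng = random.Random(11)
        for _ in range(20):
            seq = random_dna(rng, 600)
            for orf in find_orfs(seq, 60, start_policy="any_sense"):
                assert orf.aa_seq == translate(orf.nt_seq)
                assert "*" not in orf.aa_seq


def _orf(start, end, match_id="m1", strand="+"):
    return OrfRecord(
        match_id=match_id, frame=start % 3, strand=strand, start=start, end=end,
        nt_seq="A" * (end - start), aa_seq="X" * ((end - start) // 3 - 1), has_stop=True,
    )


def _hit(qs, qe, pssm, evalue, query_id="m1", reverse=False):
    return DomainHit(
        query_id=query_id, pssm_id=pssm, q_start=qs, q_end=qe,
        evalue=evalue, bitscore=100.0, reverse_frame=reverse,
    )


RT_EN = DomainTable(required_domains={"RT": {"pfam00078"}, "EN": {"cd09076"}})


class TestValidateOrfs:
    def test_both_domains_contained_and_passing(self):
        orf = _orf(100, 2100)
        hits = [_hit(300, 900, "pfam00078", 1e-30), _hit(1500, 2000, "cd09076", 1e-10)]
        (v,) = validate_orfs([orf], hits, RT_EN, 0.01)
        assert v.supporting_hits["RT"].pssm_id == "pfam00078"
        assert v.supporting_hits["EN"].evalue == 1e-10

    def test_evalue_failure_rejects(self):
        orf = _orf(100, 2100)
        hits = [_hit(300, 900, "pfam00078", 1e-30), _hit(1500, 2000, "cd09076", 0.5)]
        assert validate_orfs([orf], hits, RT_EN, 0.01) == []

    def test_containment_failure_rejects(self):
        orf = _orf(100, 2100)
        hits = [_hit(300, 900, "pfam00078", 1e-30), _hit(2000, 2300, "cd09076", 1e-10)]
        assert validate_orfs([orf], hits, RT_EN, 0.01) == []

    def test_best_hit_per_type_is_lowest_evalue(self):
        orf = _orf(0, 2100)
        hits = [
            _hit(300, 900, "pfam00078", 1e-5),
            _hit(1000, 1600, "pfam00078", 1e-30),
            _hit(1700, 2000, "cd09076", 1e-10),
        ]
        (v,) = validate_orfs([orf], hits, RT_EN, 0.01)
        assert v.supporting_hits["RT"].evalue == 1e-30

    def test_reverse_frame_hits_only_support_minus_orfs(self):
        plus = _orf(100, 2100)
        hits = [
            _hit(300, 900, "pfam00078", 1e-30, reverse=True),
            _hit(1500, 2000, "cd09076", 1e-10),
        ]
        assert validate_orfs([plus], hits, RT_EN, 0.01) == []
        minus = _orf(100, 2100, strand="-")
        hits_rev = [
            _hit(300, 900, "pfam00078", 1e-30, reverse=True),
            _hit(1500, 2000, "cd09076", 1e-10, reverse=True),
        ]
        (v,) = validate_orfs([minus], hits_rev, RT_EN, 0.01)
        assert set(v.supporting_hits) == {"RT", "EN"}

    def test_unknown_match_id_skipped_with_warning(self, caplog):
        orf = _orf(100, 2100)
        hits = [
            _hit(300, 900, "pfam00078", 1e-30),
            _hit(1500, 2000, "cd09076", 1e-10),
            _hit(0, 100, "pfam00078", 1e-30, query_id="ghost"),
        ]
        with caplog.at_level("WARNING"):
            v = validate_orfs([orf], hits, RT_EN, 0.01, known_match_ids={"m1"})
        assert len(v) == 1
        assert "ghost" in caplog.text

    def test_threshold_monotonicity(self):
        orf = _orf(100, 2100)
        hits = [_hit(300, 900, "pfam00078", 1e-30), _hit(1500, 2000, "cd09076", 0.5)]
        sets = [
            len(validate_orfs([orf], hits, RT_EN, e)) for e in (1e-5, 0.01, 1.0)
        ]
        assert sets == sorted(sets)


class TestProjectToGenome:
    def test_plus_region_offset(self):
        region = MergedRegion("ctg1", 1000, 3000, "+")
        orf = project_to_genome(_orf(100, 400, match_id=region.region_id), region)
        assert (orf.genome_start, orf.genome_end, orf.genome_strand) == (1100, 1400, "+")

    def test_minus_region_mirror(self):
        region = MergedRegion("ctg1", 1000, 3000, "-")
        orf = project_to_genome(_orf(100, 400, match_id=region.region_id), region)
        assert (orf.genome_start, orf.genome_end, orf.genome_strand) == (2600, 2900, "-")

    def test_orf_beyond_region_errors(self):
        region = MergedRegion("ctg1", 1000, 1300, "+")
        with pytest.raises(MgecdsError):
            project_to_genome(_orf(100, 400), region)

    @pytest.mark.parametrize("region_strand", "+-")
    @pytest.mark.parametrize("strand_policy", ["plus_only", "both"])
    def test_reexcision_roundtrip(self, region_strand, strand_policy):
        """Re-excising the projected interval reproduces the ORF sequence."""
        rng = random.Random(f"{region_strand}{strand_policy}")
        core = "ATG" + "".join(rng.choice(["GCT", "AAA", "GGG", "TGC"]) for _ in range(60)) + "TAA"
        element = random_dna(rng, 90) + "TAA" + core + random_dna(rng, 90)
        contig = random_dna(rng, 500) + (
            element if region_strand == "+" else reverse_complement(element)
        ) + random_dna(rng, 500)
        region = MergedRegion("c", 500, 500 + len(element), region_strand)
        excised = contig[region.start : region.end]
        if region_strand == "-":
            excised = reverse_complement(excised)
        assert excised == element
        orfs = find_orfs(excised, min_len=60, strand_policy=strand_policy, match_id=region.region_id)
        assert orfs
        for orf in orfs:
            project_to_genome(orf, region)
            seq = contig[orf.genome_start : orf.genome_end]
            if orf.genome_strand == "-":
                seq = reverse_complement(seq)
            assert seq == orf.nt_seq
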