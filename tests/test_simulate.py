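"""Simulator: reference generation, planted truth sets, read placement
geometry and FASTQ emission."""

import collections

import pytest

from rnmpmap.coordinate import calc_site, screen_site
from rnmpmap.genome import InputError
from rnmpmap.preprocess import read_fastq
from rnmpmap.simulate import (
    SimSpec,
    TruthSite,
    emit_fastq,
    end_aligned_alignments,
    generate_reference,
    plant_rnmps,
    simulate_alignments,
    write_fasta,
)

ALL_TECHNIQUES = ("ribose-seq", "HydEn-seq", "Pu-seq", "emRiboSeq")


class TestGenerateReference:
    def test_same_seed_same_sequence(self):
        spec = [("chrN", 20_000, "nuclear", 0.40)]
        a = generate_reference(spec, seed=7)
        b = generate_reference(spec, seed=7)
        assert a.sequence("chrN") == b.sequence("chrN")
        assert a.sequence("chrN") != generate_reference(spec, seed=8).sequence(
            "chrN"
        )

    def test_gc_one_yields_only_g_and_c(self):
        genome = generate_reference([("c", 2_000, "nuclear", 1.0)], seed=1)
        assert set(genome.sequence("c")) <= {"G", "C"}

    def test_gc_fraction_concentrates_near_request(self):
        genome = generate_reference([("c", 50_000, "nuclear", 0.5)], seed=3)
        seq = genome.sequence("c")
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.47 <= gc <= 0.53

    def test_duplicate_names_rejected(self):
        with pytest.raises(InputError):
            generate_reference(
                [("c", 10, "nuclear", 0.5), ("c", 10, "nuclear", 0.5)], seed=0
            )

    def test_fasta_round_trips_through_loader(self, tmp_path):
        from rnmpmap.genome import load_reference

        genome = generate_reference([("c", 500, "nuclear", 0.4)], seed=2)
        path = tmp_path / "ref.fa"
        write_fasta(genome, path)
        loaded = load_reference(path, {"c": "nuclear"})
        assert loaded.sequence("c") == genome.sequence("c")


class TestPlantRnmps:
    def test_zero_sites(self, sim_genome):
        assert plant_rnmps(sim_genome, 0, seed=1) == []

    def test_base_identity_follows_reference_with_t_as_u(self, sim_genome):
        for site in plant_rnmps(sim_genome, 500, seed=5):
            ref = sim_genome.sequence(site.chrom)[site.pos]
            if site.strand == "+":
                expected = "U" if ref == "T" else ref
            else:
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}[ref]
                expected = "U" if comp == "T" else comp
            assert site.base == expected

    def test_sampling_is_without_replacement(self, sim_genome):
        sites = plant_rnmps(sim_genome, 5_000, seed=9)
        assert len({s.key for s in sites}) == 5_000

    def test_degenerate_bias_forces_one_base(self, sim_genome):
        sites = plant_rnmps(
            sim_genome, 100, seed=4, base_bias={"C": 1.0}
        )
        assert len(sites) == 100
        assert {s.base for s in sites} == {"C"}

    def test_too_many_sites_rejected(self, toy_genome):
        with pytest.raises(InputError):
            plant_rnmps(toy_genome, 10_000, seed=0)


class TestReadPlacement:
    # Each case inverts the technique's coordinate arithmetic: the read
    # placed for a + strand site at zero-based 100 with L=50 must map back
    # to 100 under calc_site.
    @pytest.mark.parametrize(
        "technique,start,end,strand",
        [
            ("ribose-seq", 51, 101, "-"),
            ("HydEn-seq", 101, 151, "+"),
            ("Pu-seq", 101, 151, "+"),
            ("emRiboSeq", 50, 100, "-"),
        ],
    )
    def test_plus_strand_placement_and_round_trip(
        self, sim_genome, technique, start, end, strand
    ):
        base = sim_genome.sequence("chrN")[100]
        truth = [TruthSite("chrN", 100, "+", "U" if base == "T" else base)]
        spec = SimSpec(technique=technique, read_length=50)
        alignments, kept, skipped = simulate_alignments(truth, spec, sim_genome)
        assert not skipped
        (aln,) = alignments
        assert (aln.start, aln.end, aln.strand) == (start, end, strand)
        site = calc_site(aln, technique)
        assert (site.chrom, site.start, site.strand) == ("chrN", 100, "+")

    @pytest.mark.parametrize("technique", ALL_TECHNIQUES)
    def test_round_trip_both_strands(self, sim_genome, technique):
        truth = plant_rnmps(sim_genome, 2_000, seed=13)
        spec = SimSpec(technique=technique, read_length=50)
        alignments, kept, skipped = simulate_alignments(truth, spec, sim_genome)
        recovered = collections.Counter(
            calc_site(a, technique).key for a in alignments
        )
        assert recovered == collections.Counter(t.key for t in kept)
        assert all(v == 1 for v in recovered.values())

    @pytest.mark.parametrize("technique", ALL_TECHNIQUES)
    def test_end_adjacent_sites_are_skipped_not_mangled(self, sim_genome, technique):
        # sites in the first/last read-length window of a chromosome may be
        # unreachable for the technique; they must be dropped from truth
        sites = [
            TruthSite("chrM", 0, "+", "A"),
            TruthSite("chrM", 0, "-", "A"),
            TruthSite("chrM", 9_999, "+", "A"),
            TruthSite("chrM", 9_999, "-", "A"),
        ]
        spec = SimSpec(technique=technique, read_length=50)
        alignments, kept, skipped = simulate_alignments(sites, spec, sim_genome)
        assert len(kept) + len(skipped) == 4
        assert len(alignments) == len(kept)
        for aln in alignments:
            assert 0 <= aln.start < aln.end <= sim_genome.length(aln.chrom)

    def test_end_aligned_reads_make_offend_sites_for_emriboseq(self, sim_genome):
        reads = end_aligned_alignments(sim_genome, 50, "chrN", "chrM")
        assert (reads[0].start, reads[0].end, reads[0].strand) == (0, 50, "+")
        assert (reads[1].start, reads[1].end, reads[1].strand) == (
            9_950,
            10_000,
            "-",
        )
        for read in reads:
            site = calc_site(read, "emRiboSeq")
            assert not screen_site(site, sim_genome)


class TestEmitFastq:
    def make_alignments(self, sim_genome, spec, n=20):
        truth = plant_rnmps(sim_genome, n, seed=21)
        alignments, _, _ = simulate_alignments(truth, spec, sim_genome)
        return alignments

    def test_bare_reads_without_umi_or_barcode(self, sim_genome, tmp_path):
        spec = SimSpec(technique="ribose-seq", read_length=30)
        alignments = self.make_alignments(sim_genome, spec)
        path = tmp_path / "r.fq"
        emit_fastq(alignments, spec, sim_genome, seed=1, fastq_path=path)
        reads = list(read_fastq(path))
        assert len(reads) == len(alignments)
        for read in reads:
            assert len(read.sequence) == 30
            assert set(read.quality) == {"I"}

    def test_duplication_rate_one_doubles_records(self, sim_genome, tmp_path):
        spec = SimSpec(
            technique="emRiboSeq",
            read_length=30,
            umi_length=6,
            duplication_rate=1.0,
            seed=5,
        )
        alignments = self.make_alignments(sim_genome, spec)
        path = tmp_path / "r.fq"
        n = emit_fastq(alignments, spec, sim_genome, seed=2, fastq_path=path)
        reads = list(read_fastq(path))
        assert n == len(reads) == 2 * len(alignments)
        # PCR copies are verbatim: distinct molecules == distinct UMIs+names
        assert len({r.name for r in reads}) == len(alignments)
        assert len({r.sequence[:6] + r.name for r in reads}) == len(alignments)

    def test_fixed_seed_gives_byte_identical_fastq(self, sim_genome, tmp_path):
        spec = SimSpec(
            technique="HydEn-seq",
            read_length=30,
            barcode="TCA",
            umi_length=4,
            duplication_rate=0.5,
            seed=6,
        )
        alignments = self.make_alignments(sim_genome, spec)
        p1, p2 = tmp_path / "a.fq", tmp_path / "b.fq"
        emit_fastq(alignments, spec, sim_genome, seed=9, fastq_path=p1)
        emit_fastq(alignments, spec, sim_genome, seed=9, fastq_path=p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_read_sequence_matches_reference_on_strand(self, sim_genome, tmp_path):
        spec = SimSpec(technique="Pu-seq", read_length=25)
        alignments = self.make_alignments(sim_genome, spec, n=10)
        path = tmp_path / "r.fq"
        emit_fastq(alignments, spec, sim_genome, seed=3, fastq_path=path)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for read, aln in zip(read_fastq(path), alignments):
            ref = sim_genome.sequence(aln.chrom)[aln.start : aln.end]
            if aln.strand == "-":
                ref = "".join(comp[b] for b in reversed(ref))
            assert read.sequence == ref
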