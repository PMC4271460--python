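"""Gene-model engine: parsing, flattening, event extraction, synthesis."""

import pytest

from splicebench.gene_models import (
    AnnotationError,
    GeneModel,
    Transcript,
    SIMPLE_CLASSES,
    classify_gene,
    extract_events,
    flatten_gene,
    make_incomplete_annotation,
    parse_annotation,
    synth_annotation,
    write_gff3,
    write_gtf,
)
import pandas as pd


def _genes_equal(a: list[GeneModel], b: list[GeneModel]) -> bool:
    key = lambda gs: [
        (g.gene_id, g.chrom, g.strand,
         [(t.transcript_id, t.exons) for t in g.transcripts])
        for g in sorted(gs, key=lambda x: x.gene_id)
    ]
    return key(a) == key(b)


class TestParsing:
    def test_minimal_gff3_identity(self, tmp_path):
        p = tmp_path / "mini.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\t.\tgene\t100\t200\t.\t+\t.\tID=g1\n"
            "chr1\t.\tmRNA\t100\t200\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\t.\texon\t100\t200\t.\t+\t.\tParent=t1\n"
        )
        genes = parse_annotation(str(p), "GFF3")
        assert len(genes) == 1
        (g,) = genes
        assert g.gene_id == "g1" and g.strand == "+"
        assert g.transcripts[0].exons == ((100, 200),)

    def test_gff3_round_trip(self, mixed_genes, tmp_path):
        p = tmp_path / "rt.gff3"
        write_gff3(mixed_genes, str(p))
        assert _genes_equal(parse_annotation(str(p), "GFF3"), mixed_genes)

    def test_gtf_round_trip(self, mixed_genes, tmp_path):
        p = tmp_path / "rt.gtf"
        write_gtf(mixed_genes, str(p))
        assert _genes_equal(parse_annotation(str(p), "GTF"), mixed_genes)

    def test_malformed_record_names_line(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text(
            "chr1\t.\tgene\t100\t200\t.\t+\t.\tID=g1\n"
            "chr1\tgene only four columns\n"
        )
        with pytest.raises(AnnotationError, match="line 2"):
            parse_annotation(str(p), "GFF3")

    def test_orphan_exon_is_structural_error(self, tmp_path):
        p = tmp_path / "orphan.gff3"
        p.write_text(
            "chr1\t.\tgene\t100\t200\t.\t+\t.\tID=g1\n"
            "chr1\t.\texon\t100\t200\t.\t+\t.\tID=e1\n"
        )
        with pytest.raises(AnnotationError, match="parent"):
            parse_annotation(str(p), "GFF3")


class TestFlatten:
    def test_single_transcript(self):
        g = GeneModel("g", "c", "+", [Transcript("t", ((1, 100), (201, 300)))])
        units = flatten_gene(g, 100)
        kinds = sorted(u.kind for u in units)
        assert kinds == ["exonic_bin", "exonic_bin", "junction"]
        j = next(u for u in units if u.kind == "junction")
        assert (j.start, j.end) == (100, 201)
        assert j.effective_length == 99

    def test_alternative_acceptor_boundaries(self):
        # boundary set {1, 100, 151, 201, 300} enumerated by hand
        g = GeneModel(
            "g",
            "c",
            "+",
            [
                Transcript("t1", ((1, 100), (201, 300))),
                Transcript("t2", ((1, 100), (151, 300))),
            ],
        )
        units = flatten_gene(g, 100)
        bins = [(u.start, u.end) for u in units if u.kind == "exonic_bin"]
        juncs = [(u.start, u.end) for u in units if u.kind == "junction"]
        assert bins == [(1, 100), (151, 200), (201, 300)]
        assert sorted(juncs) == [(100, 151), (100, 201)]
        mid = next(u for u in units if (u.start, u.end) == (151, 200))
        assert mid.member_transcripts == {"t2"}

    def test_read_length_validated(self, se_gene):
        with pytest.raises(ValueError, match="read_length"):
            flatten_gene(se_gene, 1)

    def test_partition_property(self, mixed_genes):
        """Bins are disjoint, sorted, and cover exactly the exon union."""
        for g in mixed_genes:
            units = flatten_gene(g, 100)
            bins = sorted(
                (u.start, u.end) for u in units if u.kind == "exonic_bin"
            )
            for (s1, e1), (s2, e2) in zip(bins, bins[1:]):
                assert e1 < s2  # disjoint
            covered = sum(e - s + 1 for s, e in bins)
            union = set()
            for t in g.transcripts:
                for s, e in t.exons:
                    union.update(range(s, e + 1))
            assert covered == len(union)
            assert all(u.effective_length > 0 for u in units)


def _mirror(t: Transcript, L: int) -> Transcript:
    return Transcript(
        t.transcript_id, tuple((L + 1 - e, L + 1 - s) for s, e in t.exons)
    )


class TestEvents:
    def test_skipped_exon(self, se_gene):
        t1, t2 = se_gene.transcripts
        events = extract_events(t1, t2, "+", "gSE")
        assert [e.type for e in events] == ["SE"]
        ev = events[0]
        assert ev.region == (201, 300)
        assert "gSE:E201-300" in ev.inclusion_units
        assert ev.exclusion_units == {"gSE:J100-401"}

    def test_intron_retention(self, ir_gene):
        t1, t2 = ir_gene.transcripts
        events = extract_events(t1, t2, "+", "gIR")
        assert [e.type for e in events] == ["IR"]
        assert events[0].region == (101, 200)

    def test_alt_donor_strand_aware(self):
        t1 = Transcript("a", ((1, 100), (201, 300)))
        t2 = Transcript("b", ((1, 130), (201, 300)))
        assert [e.type for e in extract_events(t1, t2, "+")] == ["A5SS"]
        assert [e.type for e in extract_events(t1, t2, "-")] == ["A3SS"]

    def test_identical_transcripts_no_events(self):
        t = Transcript("a", ((1, 100), (201, 300)))
        assert extract_events(t, Transcript("b", t.exons), "+") == []

    def test_tss_tes_differences_ignored(self):
        t1 = Transcript("a", ((1, 100), (201, 300)))
        t2 = Transcript("b", ((50, 100), (201, 350)))
        assert extract_events(t1, t2, "+") == []

    def test_strand_duality_on_synthetic_genes(self, mixed_genes):
        """Mirroring coordinates on the same strand swaps A3SS and A5SS
        (donor and acceptor trade sides); mirroring plus a strand flip is
        a reverse complement and fixes every type."""
        swap = {"A3SS": "A5SS", "A5SS": "A3SS"}
        L = 10_000_000
        checked = 0
        for g in mixed_genes:
            if g.n_transcripts != 2:
                continue
            t1, t2 = g.transcripts
            fwd = extract_events(t1, t2, g.strand, g.gene_id)
            m1, m2 = _mirror(t1, L), _mirror(t2, L)
            mirrored = extract_events(m1, m2, g.strand, g.gene_id)
            assert sorted(swap.get(e.type, e.type) for e in fwd) == sorted(
                e.type for e in mirrored
            )
            flipped = "-" if g.strand == "+" else "+"
            revcomp = extract_events(m1, m2, flipped, g.gene_id)
            assert sorted(e.type for e in fwd) == sorted(
                e.type for e in revcomp
            )
            checked += 1
        assert checked > 10


class TestClassify:
    def test_simple_fixtures(self, se_gene, ir_gene):
        c = classify_gene(se_gene)
        assert (c.as_class, c.n_transcripts) == ("SE", 2)
        assert classify_gene(ir_gene).as_class == "IR"

    def test_donor_acceptor_merged(self):
        g = GeneModel(
            "g", "c", "-",
            [
                Transcript("t1", ((1, 100), (201, 300))),
                Transcript("t2", ((1, 130), (201, 300))),
            ],
        )
        assert classify_gene(g).as_class == "A3A5SS"

    def test_two_separate_events_is_multi_event(self):
        # one skipped exon plus one alt-donor change in a different region
        g = GeneModel(
            "g", "c", "+",
            [
                Transcript("t1", ((1, 100), (201, 300), (401, 500), (601, 700))),
                Transcript("t2", ((1, 100), (401, 530), (601, 700))),
            ],
        )
        assert classify_gene(g).as_class == "multi_event"

    def test_single_transcript(self):
        g = GeneModel("g", "c", "+", [Transcript("t", ((1, 100),))])
        assert classify_gene(g).as_class == "single_isoform"


class TestIncompleteAnnotation:
    @staticmethod
    def _truth(genes, true_ids):
        rows = []
        for g in genes:
            if g.gene_id in true_ids:
                rows.append((g.gene_id, True, g.transcripts[-1].transcript_id))
            else:
                rows.append((g.gene_id, False, None))
        return pd.DataFrame(rows, columns=["gene_id", "is_true_as",
                                           "alt_transcript_id"])

    def test_alt_transcript_removed(self, mixed_genes):
        multi = [g for g in mixed_genes if g.n_transcripts == 2]
        truth = self._truth(mixed_genes, {g.gene_id for g in multi[:5]})
        out = make_incomplete_annotation(mixed_genes, truth)
        by_id = {g.gene_id: g for g in out}
        for g in multi[:5]:
            assert by_id[g.gene_id].n_transcripts == 1
        # transcript count drops by exactly the number of true-AS genes
        before = sum(g.n_transcripts for g in mixed_genes)
        after = sum(g.n_transcripts for g in out)
        assert before - after == 5

    def test_non_as_genes_untouched(self, mixed_genes, tmp_path):
        truth = self._truth(mixed_genes, set())
        out = make_incomplete_annotation(mixed_genes, truth)
        p1, p2 = tmp_path / "a.gff3", tmp_path / "b.gff3"
        write_gff3(mixed_genes, str(p1))
        write_gff3(out, str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_idempotent(self, mixed_genes):
        multi = [g for g in mixed_genes if g.n_transcripts == 2]
        truth = self._truth(mixed_genes, {multi[0].gene_id})
        once = make_incomplete_annotation(mixed_genes, truth)
        with pytest.raises(AnnotationError):
            # the transcript is already gone: a second pass must not
            # silently succeed
            make_incomplete_annotation(once, truth)
        # but with a truth restricted to remaining alternatives it is a no-op
        empty = self._truth(once, set())
        again = make_incomplete_annotation(once, empty)
        assert _genes_equal(once, again)

    def test_missing_alt_transcript_errors(self, mixed_genes):
        truth = self._truth(mixed_genes, set())
        truth.loc[0, ["is_true_as", "alt_transcript_id"]] = True, "nope"
        with pytest.raises(AnnotationError):
            make_incomplete_annotation(mixed_genes, truth)


class TestSynthAnnotation:
    def test_pure_mix_all_classify(self):
        genes = synth_annotation(100, {"SE": 1.0}, seed=5)
        assert len(genes) == 100
        assert all(classify_gene(g).as_class == "SE" for g in genes)

    def test_deterministic_output(self, tmp_path):
        a, b = tmp_path / "a.gff3", tmp_path / "b.gff3"
        write_gff3(synth_annotation(50, seed=9), str(a))
        write_gff3(synth_annotation(50, seed=9), str(b))
        assert a.read_bytes() == b.read_bytes()

    def test_exact_allocation(self):
        mix = {"SE": 0.25, "IR": 0.25, "A3A5SS": 0.25, "complex": 0.25}
        genes = synth_annotation(400, mix, seed=1)
        counts = {}
        for g in genes:
            c = classify_gene(g).as_class
            counts[c] = counts.get(c, 0) + 1
        assert counts == {"SE": 100, "IR": 100, "A3A5SS": 100, "complex": 100}

    def test_generator_classifier_round_trip(self):
        for cls in SIMPLE_CLASSES + ("MXE", "complex", "multi_event"):
            genes = synth_annotation(20, {cls: 1.0}, seed=3, verify=False)
            assert all(classify_gene(g).as_class == cls for g in genes), cls

    def test_infeasible_lengths_rejected(self):
        with pytest.raises(ValueError):
            synth_annotation(10, {"SE": 1.0}, {"exon": (10, 5)}, seed=0)

    def test_genes_do_not_overlap(self, mixed_genes):
        spans = sorted(g.span for g in mixed_genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2


def test_bed_and_event_exports(se_gene, tmp_path):
    """Units export as 0-based half-open BED; events as TSV."""
    from splicebench.gene_models import write_events_tsv, write_units_bed

    units = flatten_gene(se_gene, 100)
    bed = tmp_path / "units.bed"
    write_units_bed(units, {"gSE": "chr1"}, str(bed))
    first = bed.read_text().splitlines()[0].split("\t")
    u0 = units[0]
    assert (int(first[1]), int(first[2])) == (u0.start - 1, u0.end)

    events = extract_events(*se_gene.transcripts, "+", "gSE")
    tsv = tmp_path / "events.tsv"
    write_events_tsv(events, str(tsv))
    body = tsv.read_text().splitlines()
    assert body[0].startswith("event_id\t") and "\tSE\t" in body[1]
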