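"""Gene-model loading, reference-set construction and sequence extraction."""

import numpy as np
import pytest

from splicemap.exons import (
    CassetteExonEvent,
    GtfParseError,
    build_reference_sets,
    events_to_bed,
    extract_event_sequences,
    load_gene_models,
    read_event_table,
    reverse_complement,
    write_event_table,
)

from conftest import write_fasta, write_gtf


def test_gtf_coordinates_become_zero_based_half_open(tmp_path):
    gtf = write_gtf(tmp_path / "a.gtf", [
        ("chr1", 1, 100, "+", "g1", "t1"),
        ("chr1", 201, 300, "+", "g1", "t1"),
    ])
    (model,) = load_gene_models(gtf)
    assert model.transcripts["t1"] == ((0, 100), (200, 300))


def test_empty_gtf_yields_empty_collection(tmp_path):
    p = tmp_path / "empty.gtf"
    p.touch()
    assert load_gene_models(p) == []


def test_gene_on_both_strands_rejected(tmp_path):
    gtf = write_gtf(tmp_path / "b.gtf", [
        ("chr1", 1, 100, "+", "g1", "t1"),
        ("chr1", 201, 300, "-", "g1", "t2"),
    ])
    with pytest.raises(GtfParseError, match="both strands"):
        load_gene_models(gtf)


def test_malformed_gtf_raises_parse_error(tmp_path):
    p = tmp_path / "bad.gtf"
    p.write_text('chr1\tx\texon\tnotanumber\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n')
    with pytest.raises(GtfParseError):
        load_gene_models(p)


def _three_exon_gene(tmp_path, skip_in_t2=True, gene="g1"):
    rows = []
    exons = [(101, 200), (301, 400), (501, 600)]
    for i, (s, e) in enumerate(exons):
        rows.append(("chr1", s, e, "+", gene, f"{gene}.t1"))
        if not (skip_in_t2 and i == 1):
            rows.append(("chr1", s, e, "+", gene, f"{gene}.t2"))
    gtf = write_gtf(tmp_path / f"{gene}.gtf", rows)
    return load_gene_models(gtf)


def test_skipped_middle_exon_is_reference_cassette(tmp_path):
    models = _three_exon_gene(tmp_path, skip_in_t2=True)
    cassette, constitutive = build_reference_sets(models, {"g1"}, [])
    assert [e.exon for e in cassette] == [(300, 400)]
    assert constitutive == []
    # flanking introns adjacent to the exon
    (ev,) = cassette
    assert ev.upstream_intron == (200, 300)
    assert ev.downstream_intron == (400, 500)


def test_middle_exon_in_all_transcripts_is_constitutive(tmp_path):
    models = _three_exon_gene(tmp_path, skip_in_t2=False)
    cassette, constitutive = build_reference_sets(models, {"g1"}, [])
    assert cassette == []
    # terminal exons are in neither set
    assert [e.exon for e in constitutive] == [(300, 400)]


def test_regulated_gene_contributes_nothing(tmp_path):
    models = _three_exon_gene(tmp_path, skip_in_t2=True)
    regulated = [CassetteExonEvent(
        "ev1", "g1", "chr1", "+", (300, 400), (200, 300), (400, 500),
        "down", -0.3)]
    cassette, constitutive = build_reference_sets(models, {"g1"}, regulated)
    assert cassette == [] and constitutive == []


def test_reference_sets_are_disjoint(small_bundle):
    from splicemap.exons import load_gene_models
    _, bundle = small_bundle
    models = load_gene_models(bundle.gtf_path)
    regulated = bundle.regulated_events
    cassette, constitutive = build_reference_sets(
        models, {m.gene_id for m in models}, regulated)
    ids_c = {e.event_id for e in cassette}
    ids_k = {e.event_id for e in constitutive}
    assert ids_c and ids_k and not (ids_c & ids_k)


def _event(strand, exon, up, down):
    return CassetteExonEvent("e", "g", "chrT", strand, exon, up, down,
                             "reference_cassette")


def test_plus_strand_extraction(tmp_path):
    seq = "ACGTACGTACGTACGTACGTACGT"  # 24 nt
    genome = write_fasta(tmp_path / "g.fa", {"chrT": seq})
    ev = _event("+", (10, 16), (4, 10), (16, 22))
    s = extract_event_sequences(genome, ev, 4)
    assert s.exon_seq == seq[10:16]
    assert s.upstream_flank == seq[6:10]
    assert s.downstream_flank == seq[16:20]
    assert not s.truncated


def test_minus_strand_is_reverse_complement_with_roles_swapped(tmp_path):
    seq = "ACGTTGCAACGGTTACGTGCATCA"
    genome = write_fasta(tmp_path / "g.fa", {"chrT": seq})
    plus = _event("+", (10, 16), (4, 10), (16, 22))
    minus = _event("-", (10, 16), (16, 22), (4, 10))
    sp = extract_event_sequences(genome, plus, 4)
    sm = extract_event_sequences(genome, minus, 4)
    assert sm.exon_seq == reverse_complement(sp.exon_seq)
    assert sm.upstream_flank == reverse_complement(sp.downstream_flank)
    assert sm.downstream_flank == reverse_complement(sp.upstream_flank)


def test_strand_symmetry_on_random_fixtures(tmp_path):
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), size=400))
    genome = write_fasta(tmp_path / "r.fa", {"chrT": seq})
    for _ in range(25):
        a = int(rng.integers(40, 150))
        b = a + int(rng.integers(20, 60))
        up = (a - int(rng.integers(10, 40)), a)
        down = (b, b + int(rng.integers(10, 40)))
        flank = int(rng.integers(2, 30))
        plus = _event("+", (a, b), up, down)
        minus = _event("-", (a, b), down, up)
        sp = extract_event_sequences(genome, plus, flank)
        sm = extract_event_sequences(genome, minus, flank)
        assert sm.exon_seq == reverse_complement(sp.exon_seq)
        assert sm.upstream_flank == reverse_complement(sp.downstream_flank)
        assert sm.downstream_flank == reverse_complement(sp.upstream_flank)
        assert sm.truncated == sp.truncated


def test_short_intron_truncates_flank(tmp_path):
    seq = "A" * 50
    genome = write_fasta(tmp_path / "t.fa", {"chrT": seq})
    ev = _event("+", (10, 16), (7, 10), (16, 40))
    s = extract_event_sequences(genome, ev, 250)
    assert len(s.upstream_flank) == 3
    assert s.truncated


def test_missing_contig_raises(tmp_path):
    genome = write_fasta(tmp_path / "m.fa", {"chrT": "A" * 50})
    ev = CassetteExonEvent("e", "g", "chrX", "+", (10, 16), (4, 10), (16, 22),
                           "reference_cassette")
    with pytest.raises(KeyError):
        extract_event_sequences(genome, ev, 4)


def _sample_events():
    return [
        CassetteExonEvent("e1", "g1", "c1", "+", (10, 20), (5, 10), (20, 30),
                          "up", 0.25),
        CassetteExonEvent("e2", "g2", "c2", "-", (10, 20), (20, 30), (5, 10),
                          "down", -0.4),
        CassetteExonEvent("e3", "g3", "c3", "+", (10, 20), (5, 10), (20, 30),
                          "reference_cassette"),
    ]


def test_event_table_roundtrip(tmp_path):
    events = _sample_events()
    path = tmp_path / "events.tsv"
    write_event_table(events, path)
    back = read_event_table(path)
    assert back == events


def test_regulation_label_is_case_normalized(tmp_path):
    events = _sample_events()[:1]
    path = tmp_path / "events.tsv"
    write_event_table(events, path)
    text = path.read_text().replace("\tup\t", "\tUP\t")
    path.write_text(text)
    (ev,) = read_event_table(path)
    assert ev.regulation == "up"


def test_unknown_regulation_label_rejected(tmp_path):
    path = tmp_path / "events.tsv"
    write_event_table(_sample_events()[:1], path)
    path.write_text(path.read_text().replace("\tup\t", "\tsideways\t"))
    with pytest.raises(ValueError, match="unknown regulation label"):
        read_event_table(path)


def test_delta_psi_required_iff_regulated():
    with pytest.raises(ValueError, match="delta_psi"):
        CassetteExonEvent("e", "g", "c", "+", (10, 20), (5, 10), (20, 30), "up")
    with pytest.raises(ValueError, match="delta_psi"):
        CassetteExonEvent("e", "g", "c", "+", (10, 20), (5, 10), (20, 30),
                          "reference_cassette", 0.3)


def test_bed_export_preserves_intervals(tmp_path):
    events = _sample_events()
    path = tmp_path / "events.bed"
    events_to_bed(events, path)
    rows = [line.split("\t") for line in path.read_text().splitlines()]
    assert [(r[0], int(r[1]), int(r[2]), r[5]) for r in rows] == [
        ("c1", 10, 20, "+"), ("c2", 10, 20, "-"), ("c3", 10, 20, "+"),
    ]
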