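"""Genome record I/O: GenBank parsing (including origin-wrapping joined
CDS), anchored-coordinate transforms, translation, and FASTA/GFF3 round
trips."""

import logging

import pytest

from baculoannot.errors import GeneNotFoundError, UnsupportedInputError
from baculoannot.genome_io import (
    GenomeRecord,
    OrfAnnotation,
    anchor_to_gene,
    extract_proteins,
    read_fasta,
    read_genbank,
    read_gff3,
    reverse_complement_record,
    rotate_record,
    write_fasta,
    write_genbank,
    write_gff3,
)
from baculoannot.synthetic import SimulationConfig, simulate_genome

from conftest import orf_keys

# 24-nt circular genome: forward CDS 4..12 (ATGAAATAA), reverse CDS
# complement(13..21) (revcomp = ATGTTTTAA rev-complemented into genome),
# and a wrapping CDS join(22..24,1..3) would collide, so the wrap case
# gets its own record below.
MINI_GB = """\
LOCUS       MINI                      24 bp    DNA     circular VRL 01-JAN-2000
DEFINITION  synthetic mini genome.
ACCESSION   MINI
FEATURES             Location/Qualifiers
     CDS             4..12
                     /gene="fwd1"
     CDS             complement(13..21)
                     /gene="rev1"
ORIGIN
        1 cccatgaaat aattaaaaca tccc
//
"""

# 15-nt circular genome with a CDS joined across the origin:
# positions 13..15 = ATG, then 1..6 = GGGTAA.
WRAP_GB = """\
LOCUS       WRAP                      15 bp    DNA     circular VRL 01-JAN-2000
DEFINITION  synthetic wrap genome.
ACCESSION   WRAP
FEATURES             Location/Qualifiers
     CDS             join(13..15,1..6)
                     /gene="wrap1"
ORIGIN
        1 gggtaacccc ccatg
//
"""


@pytest.fixture
def mini_gb(tmp_path):
    p = tmp_path / "mini.gb"
    p.write_text(MINI_GB)
    return p


def test_read_genbank_minimal_record(mini_gb):
    rec = read_genbank(mini_gb)
    assert rec.circular
    assert len(rec) == 24
    assert len(rec.features) == 2
    fwd = rec.feature_by_name("fwd1")
    assert (fwd.start, fwd.end, fwd.strand, fwd.length_nt) == (4, 12, 1, 9)
    rev = rec.feature_by_name("rev1")
    assert (rev.start, rev.end, rev.strand) == (21, 13, -1)
    assert rev.coding_sequence(rec.sequence).startswith("ATG")


def test_read_genbank_wrapping_cds_translates_like_concatenated_spans(tmp_path):
    p = tmp_path / "wrap.gb"
    p.write_text(WRAP_GB)
    rec = read_genbank(p)
    (f,) = rec.features
    assert f.wraps and f.end < f.start
    # manual translation of the concatenated spans 13..15 + 1..6
    manual = rec.sequence[12:15] + rec.sequence[0:6]
    assert f.coding_sequence(rec.sequence) == manual == "ATGGGGTAA"
    assert extract_proteins(rec) == [("wrap1", "MG")]


def test_read_genbank_rejects_multi_record(tmp_path):
    p = tmp_path / "two.gb"
    p.write_text(MINI_GB + WRAP_GB)
    with pytest.raises(UnsupportedInputError):
        read_genbank(p)


def test_reverse_strand_translation_equals_manual_revcomp():
    # reverse CDS: genome holds revcomp(ATGAAGTAA) = TTACTTCAT at 3..11
    seq = "GG" + "TTACTTCAT" + "GGGG"
    rec = GenomeRecord("r", seq, circular=False)
    f = OrfAnnotation.from_start("g", 11, -1, 9, len(seq))
    rec.features.append(f)
    assert f.coding_sequence(seq) == "ATGAAGTAA"
    assert extract_proteins(rec) == [("g", "MK")]


def test_internal_stop_triggers_warning_and_truncation(caplog):
    seq = "ATGTAAAAATAA"  # M * K *
    rec = GenomeRecord("s", seq, circular=False)
    rec.features.append(OrfAnnotation.from_start("g", 1, 1, 12, len(seq)))
    with caplog.at_level(logging.WARNING):
        prots = extract_proteins(rec)
    assert prots == [("g", "M")]
    assert any("internal stop" in m for m in caplog.messages)


class TestAnchoring:
    def test_anchor_places_gene_at_position_one(self, sim_genome):
        _, rec, truth = sim_genome
        for gene in (truth.orfs[0].name, truth.orfs[9].name):
            anchored = anchor_to_gene(rec, gene)
            f = anchored.feature_by_name(gene)
            assert (f.start, f.strand) == (1, 1)

    def test_anchor_is_idempotent(self, sim_genome):
        _, rec, truth = sim_genome
        a1 = anchor_to_gene(rec, truth.orfs[5].name)
        a2 = anchor_to_gene(a1, truth.orfs[5].name)
        assert a2.sequence == a1.sequence
        assert orf_keys(a2.features) == orf_keys(a1.features)

    def test_anchor_inverts_arbitrary_rotation_and_flip(self, sim_genome):
        """Anchoring recovers one canonical record from any rotated or
        reflected version of the same genome."""
        _, rec, truth = sim_genome
        gene = truth.orfs[3].name
        canon = anchor_to_gene(rec, gene)
        for variant in (
            rotate_record(rec, 1234),
            rotate_record(rec, len(rec) - 7),
            reverse_complement_record(rec),
            rotate_record(reverse_complement_record(rec), 4321),
        ):
            again = anchor_to_gene(variant, gene)
            assert again.sequence == canon.sequence
            assert orf_keys(again.features) == orf_keys(canon.features)

    def test_anchor_missing_gene_raises(self, sim_genome):
        _, rec, _ = sim_genome
        with pytest.raises(GeneNotFoundError):
            anchor_to_gene(rec, "granulin")

    def test_rotation_preserves_composition_and_orf_lengths(self, sim_genome):
        _, rec, _ = sim_genome
        rot = rotate_record(rec, 5000)
        assert len(rot) == len(rec)
        assert sorted(rot.sequence) == sorted(rec.sequence)
        assert sorted(f.length_nt for f in rot.features) == sorted(
            f.length_nt for f in rec.features
        )

    def test_wrapping_features_translate_identically_after_anchoring(self):
        rec, truth = simulate_genome(
            SimulationConfig(genome_length=9000, n_orfs=8, seed=2)
        )
        # rotate the origin into the middle of an ORF to force a wrap
        cut = truth.orfs[4].left(len(rec)) + 30
        rot = rotate_record(rec, cut)
        assert any(f.wraps for f in rot.features)
        assert dict(extract_proteins(rot)) == dict(extract_proteins(rec))


class TestRoundTrips:
    def test_genbank_round_trip(self, tmp_path, sim_genome):
        _, rec, _ = sim_genome
        path = tmp_path / "g.gb"
        write_genbank(rec, path)
        back = read_genbank(path)
        assert back.sequence == rec.sequence
        assert back.circular == rec.circular
        assert orf_keys(back.features) == orf_keys(rec.features)

    def test_fasta_round_trip_60_column(self, tmp_path, sim_genome):
        _, rec, _ = sim_genome
        path = tmp_path / "g.fasta"
        write_fasta([("g1", rec.sequence[:150]), ("g2", "ACGT")], path)
        lines = path.read_text().splitlines()
        assert max(len(l) for l in lines if not l.startswith(">")) == 60
        assert read_fasta(path) == [("g1", rec.sequence[:150]), ("g2", "ACGT")]

    def test_gff3_round_trip(self, tmp_path, sim_genome):
        _, rec, truth = sim_genome
        path = tmp_path / "g.gff3"
        write_gff3(rec, truth.orfs, path)
        back = read_gff3(path)
        assert orf_keys(back) == orf_keys(truth.orfs)
        assert {f.name for f in back} == {f.name for f in truth.orfs}

    def test_gff3_wrapping_orf_two_parts_shared_id(self, tmp_path):
        rec, truth = simulate_genome(
            SimulationConfig(genome_length=9000, n_orfs=8, seed=2)
        )
        rot = rotate_record(rec, truth.orfs[4].left(len(rec)) + 30)
        path = tmp_path / "w.gff3"
        write_gff3(rot, rot.features, path)
        wrapped = [f for f in rot.features if f.wraps]
        assert wrapped
        lines = [l for l in path.read_text().splitlines() if "\tCDS\t" in l]
        for f in wrapped:
            assert sum(f"ID={f.name};" in l for l in lines) == 2
        assert orf_keys(read_gff3(path)) == orf_keys(rot.features)

    def test_gff3_empty_orfset_is_header_only(self, tmp_path, sim_genome):
        _, rec, _ = sim_genome
        path = tmp_path / "e.gff3"
        write_gff3(rec, [], path)
        lines = path.read_text().splitlines()
        assert lines[0] == "##gff-version 3"
        assert all(l.startswith("#") for l in lines)
        assert read_gff3(path) == []
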