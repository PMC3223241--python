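"""Genome records, annotation coordinates, and standard-format I/O.

Coordinate convention
---------------------
All public coordinates are 1-based inclusive (GenBank/GFF3 style).  An
:class:`OrfAnnotation` stores ``start`` = first nucleotide of the start
codon and ``end`` = last nucleotide of the stop codon, both measured on
the genome's forward (anchored) coordinate axis.  On the forward strand
transcription runs toward increasing coordinates; on the reverse strand
toward decreasing coordinates.  Features may wrap past the origin of a
circular genome; wrapping is recorded with an explicit ``wraps`` flag in
addition to the coordinate inversion it causes.

The anchoring convention of small circular viral genomes — position 1 is
the first nucleotide of the start codon of a chosen reference gene (for
granuloviruses, granulin), numbered in its direction of transcription —
is implemented by :func:`anchor_to_gene`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import DNA_ALPHABET, circular_slice, revcomp, translate_codons
from .errors import GeneNotFoundError, InputError, UnsupportedInputError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrfAnnotation:
    """A protein-coding feature on a genome.

    ``start``/``end`` follow the convention in the module docstring;
    ``length_nt`` includes the stop codon and is a multiple of 3 for a
    complete CDS.
    """

    name: str
    start: int
    end: int
    strand: int  # +1 forward (anchored sense), -1 reverse
    length_nt: int
    wraps: bool = False

    @classmethod
    def from_start(
        cls, name: str, start: int, strand: int, length_nt: int, genome_length: int
    ) -> "OrfAnnotation":
        """Build a feature from its 5' genomic position, deriving ``end``
        and the wrap flag from the genome length."""
        if strand not in (1, -1):
            raise InputError(f"strand must be +1 or -1, got {strand!r}")
        if not 1 <= start <= genome_length:
            raise InputError(f"start {start} outside [1, {genome_length}]")
        end = (start - 1 + strand * (length_nt - 1)) % genome_length + 1
        if strand == 1:
            wraps = start + length_nt - 1 > genome_length
        else:
            wraps = start - length_nt + 1 < 1
        return cls(name, start, end, strand, length_nt, wraps)

    def genomic_intervals(self, genome_length: int) -> list[tuple[int, int]]:
        """The 1 or 2 forward-axis intervals (lo, hi), 1-based inclusive,
        covered by this feature; 2 intervals iff it wraps the origin."""
        L, s, e, n = genome_length, self.start, self.end, self.length_nt
        if self.strand == 1:
            if not self.wraps:
                return [(s, e)]
            return [(s, L), (1, n - (L - s + 1))]
        if not self.wraps:
            return [(e, s)]
        r = n - s  # bases taken from the top end of the axis
        return [(1, s), (L - r + 1, L)]

    def left(self, genome_length: int) -> int:
        """Smallest forward-axis coordinate covered (1 for wrapping features)."""
        return min(lo for lo, _ in self.genomic_intervals(genome_length))

    def coding_sequence(self, sequence: str) -> str:
        """The CDS read 5'→3' in transcription order, stop codon included."""
        L = len(sequence)
        if self.strand == 1:
            return circular_slice(sequence, self.start - 1, self.length_nt)
        s0 = (self.start - self.length_nt) % L
        return revcomp(circular_slice(sequence, s0, self.length_nt))


#: An ordered collection of called/annotated ORFs.
OrfSet = list[OrfAnnotation]


def sort_orfs(orfs: OrfSet, genome_length: int) -> OrfSet:
    """Order ORFs along the forward axis by leftmost coordinate
    (wrapping features, which touch position 1, come first), ties by
    strand (+ first) then name."""
    return sorted(
        orfs, key=lambda f: (f.left(genome_length), -f.strand, f.name)
    )


@dataclass
class GenomeRecord:
    """A (usually circular) nucleotide genome with ORF annotations."""

    id: str
    sequence: str
    circular: bool = True
    features: list[OrfAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise InputError("empty genome sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise InputError(f"sequence contains invalid characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_by_name(self, name: str) -> OrfAnnotation:
        for f in self.features:
            if f.name == name:
                return f
        raise GeneNotFoundError(f"gene {name!r} not found in record {self.id!r}")


# ---------------------------------------------------------------------------
# GenBank reading
# ---------------------------------------------------------------------------

def _start_candidates(parts, strand: int) -> list[int]:
    # transcription start of a (possibly compound) location: for the
    # forward strand the first base of some part; for the reverse strand
    # the last base.  Part order conventions differ between producers, so
    # every part terminus is tried and validated against the extracted CDS.
    if strand == 1:
        return [int(p.start) + 1 for p in parts]
    return [int(p.end) for p in parts]


def read_genbank(path) -> GenomeRecord:
    """Read a single-entry GenBank flat file into a :class:`GenomeRecord`.

    Topology is taken from the LOCUS line; every CDS feature becomes an
    :class:`OrfAnnotation` (join/origin-wrapping locations are resolved
    to the start-of-start-codon convention).
    """
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise InputError(f"malformed GenBank file {path}: {exc}") from exc
    if len(records) != 1:
        raise UnsupportedInputError(
            f"{path}: expected exactly one GenBank record, found {len(records)}"
        )
    rec = records[0]
    circular = rec.annotations.get("topology", "linear") == "circular"
    sequence = str(rec.seq).upper()
    genome = GenomeRecord(id=rec.id or rec.name, sequence=sequence, circular=circular)

    for i, feat in enumerate(f for f in rec.features if f.type == "CDS"):
        loc = feat.location
        if loc.strand not in (1, -1):
            raise UnsupportedInputError(
                f"{path}: CDS #{i} has no or mixed strand; unsupported"
            )
        name = (
            feat.qualifiers.get("gene", [None])[0]
            or feat.qualifiers.get("locus_tag", [None])[0]
            or feat.qualifiers.get("protein_id", [None])[0]
            or f"CDS_{i + 1}"
        )
        cds = str(loc.extract(rec.seq)).upper()
        length = len(cds)
        ann = None
        for cand in _start_candidates(loc.parts, loc.strand):
            trial = OrfAnnotation.from_start(
                name, cand, int(loc.strand), length, len(sequence)
            )
            if trial.coding_sequence(sequence) == cds:
                ann = trial
                break
        if ann is None:
            raise InputError(
                f"{path}: cannot resolve location of CDS {name!r} "
                f"(line containing {str(loc)!r})"
            )
        genome.features.append(ann)
    return genome


def write_genbank(record: GenomeRecord, path) -> None:
    """Write a GenomeRecord (and its CDS features) as a GenBank flat file."""
    from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation

    rec = SeqRecord(
        Seq(record.sequence),
        id=record.id,
        name=record.id.split(".")[0][:16],
        description="",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
        },
    )
    L = len(record)
    for f in record.features:
        ivals = f.genomic_intervals(L)
        strand = f.strand
        parts = [SimpleLocation(lo - 1, hi, strand) for lo, hi in ivals]
        if len(parts) == 1:
            loc = parts[0]
        else:
            # GenBank writes origin-spanning joins high-interval first for
            # the forward strand and low-interval first for the reverse.
            parts.sort(key=lambda p: p.start, reverse=(strand == 1))
            loc = CompoundLocation(parts)
        rec.features.append(
            SeqFeature(loc, type="CDS", qualifiers={"gene": [f.name]})
        )
    SeqIO.write([rec], str(path), "genbank")


# ---------------------------------------------------------------------------
# Anchoring (rotation / reverse-complement of circular records)
# ---------------------------------------------------------------------------

def reverse_complement_record(record: GenomeRecord) -> GenomeRecord:
    """Mirror the record: reverse-complement the sequence and remap all
    feature coordinates (position p → L−p+1, strands flipped)."""
    L = len(record)
    feats = [
        OrfAnnotation.from_start(
            f.name, L - f.start + 1, -f.strand, f.length_nt, L
        )
        for f in record.features
    ]
    return GenomeRecord(record.id, revcomp(record.sequence), record.circular, feats)


def rotate_record(record: GenomeRecord, new_origin: int) -> GenomeRecord:
    """Rotate a circular record so that 1-based position ``new_origin``
    becomes position 1."""
    if not record.circular:
        if new_origin == 1:
            return replace(record, features=list(record.features))
        raise InputError("cannot rotate a linear genome")
    L = len(record)
    off = (new_origin - 1) % L
    seq = record.sequence[off:] + record.sequence[:off]
    feats = [
        OrfAnnotation.from_start(
            f.name, (f.start - 1 - off) % L + 1, f.strand, f.length_nt, L
        )
        for f in record.features
    ]
    return GenomeRecord(record.id, seq, record.circular, feats)


def anchor_to_gene(record: GenomeRecord, gene: str) -> GenomeRecord:
    """Re-anchor the genome on a reference gene: rotate (and flip if the
    gene lies on the reverse strand) so the gene's start codon begins at
    position 1 on the forward strand, numbering the genome in the gene's
    direction of transcription."""
    feat = record.feature_by_name(gene)
    rec = record
    if feat.strand == -1:
        rec = reverse_complement_record(rec)
        feat = rec.feature_by_name(gene)
    return rotate_record(rec, feat.start)


# ---------------------------------------------------------------------------
# Protein extraction
# ---------------------------------------------------------------------------

def extract_proteins(record: GenomeRecord) -> list[tuple[str, str]]:
    """Translate every annotated CDS (standard genetic code, circular wrap
    handled).  The trailing stop is not included; an internal in-frame
    stop triggers a logged warning and truncation at that stop."""
    out = []
    for f in record.features:
        aa = translate_codons(f.coding_sequence(record.sequence))
        if aa.endswith("*"):
            aa = aa[:-1]
        if "*" in aa:
            log.warning(
                "internal stop codon in CDS %s (%s); translation truncated",
                f.name,
                record.id,
            )
            aa = aa.split("*", 1)[0]
        out.append((f.name, aa))
    return out


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------

def write_fasta(seqs, path) -> None:
    """Write (name, sequence) pairs as FASTA, 60-column wrapped."""
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_gff3(record: GenomeRecord, orfset: OrfSet, path) -> None:
    """Write an ORF set as GFF3 (v1.23 dialect: 1-based inclusive
    coordinates).  An origin-wrapping ORF becomes a two-part feature
    sharing one ID, parts listed in transcription order."""
    L = len(record)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {record.id} 1 {L}\n")
        for f in sort_orfs(orfset, L):
            parts = f.genomic_intervals(L)
            if f.wraps and f.strand == 1:
                parts = sorted(parts, key=lambda iv: iv[0], reverse=True)
            elif f.wraps:
                parts = sorted(parts, key=lambda iv: iv[0])
            strand = "+" if f.strand == 1 else "-"
            for lo, hi in parts:
                attrs = f"ID={f.name};Name={f.name}"
                if f.wraps:
                    attrs += ";Is_circular_part=true"
                fh.write(
                    f"{record.id}\tbaculoannot\tCDS\t{lo}\t{hi}\t.\t{strand}\t0\t{attrs}\n"
                )


def read_gff3(path, genome_length: int | None = None) -> OrfSet:
    """Read back a GFF3 file written by :func:`write_gff3` (multi-line
    features with a shared ID are reassembled, including origin wraps)."""
    from gffutils.iterators import DataIterator

    it = DataIterator(str(path))
    groups: dict[str, list] = {}
    order: list[str] = []
    for feat in it:
        fid = feat.attributes.get("ID", [feat.id])[0]
        if fid not in groups:
            groups[fid] = []
            order.append(fid)
        groups[fid].append(feat)
    if genome_length is None:
        for line in it.directives:
            if line.startswith("sequence-region"):
                genome_length = int(line.split()[-1])
    if genome_length is None:
        raise InputError(f"{path}: no ##sequence-region directive and no length given")

    orfs: OrfSet = []
    for fid in order:
        parts = groups[fid]
        strand = 1 if parts[0].strand == "+" else -1
        length = sum(p.end - p.start + 1 for p in parts)
        ivals = sorted((p.start, p.end) for p in parts)
        ann = None
        for cand in {p.start for p in parts} if strand == 1 else {p.end for p in parts}:
            trial = OrfAnnotation.from_start(fid, cand, strand, length, genome_length)
            if sorted(trial.genomic_intervals(genome_length)) == ivals:
                ann = trial
                break
        if ann is None:
            raise InputError(f"{path}: inconsistent parts for feature {fid!r}")
        orfs.append(ann)
    return orfs
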