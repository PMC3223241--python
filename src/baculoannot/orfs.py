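"""ORF enumeration and selection on circular genomes, and the genome
summary statistics (A+T content, strand distribution, coding fraction,
adjacent-ORF overlap table).

An ORF here is a maximal open reading frame: the first ATG after the
previous in-frame stop, read through the next in-frame stop, on either
strand, wrapping the origin on circular genomes.  The length threshold
counts the stop codon, so the conventional "50 or more codons" rule is
150 nt or more including the stop (a protein of ≥49 aa).

Selection follows a deterministic greedy rule: candidates are admitted
in order of decreasing length provided they overlap every previously
admitted ORF by at most ``max_overlap_bp`` (default 47 bp, i.e. less
than 16 codons) — unless a candidate carries a homology-rescue flag, in
which case it is admitted regardless of overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import START_CODON, STOP_CODONS, at_percent, round_half_up
from .genome_io import GenomeRecord, OrfAnnotation, OrfSet, sort_orfs

MIN_CODONS_DEFAULT = 50
MAX_OVERLAP_DEFAULT = 47  # bp; "minimal overlap" = less than 16 codons


@dataclass(frozen=True)
class OrfCandidate:
    """A maximal ORF candidate in genome coordinates (see OrfAnnotation
    for the start/end convention).  ``frame`` is start position mod 3 on
    the candidate's own strand."""

    start: int
    end: int
    strand: int
    frame: int
    length_nt: int
    wraps: bool = False

    def to_annotation(self, name: str, genome_length: int) -> OrfAnnotation:
        return OrfAnnotation.from_start(
            name, self.start, self.strand, self.length_nt, genome_length
        )


def _strand_orfs(seq: str, circular: bool, min_nt: int):
    """Maximal ORFs on one strand, in that strand's own 0-based
    coordinates: yields (t0, length_nt).  For every stop codon the
    longest ORF ending at it is kept (equivalently: first ATG after the
    previous in-frame stop)."""
    n = len(seq)
    ext = seq + seq[: min(n, 2)] if circular else seq
    max_codons = n // 3  # an ORF cannot wrap onto itself
    best: dict[int, tuple[int, int]] = {}  # stop position -> (length, t0)
    for t0 in range(n):
        if ext[t0 : t0 + 3] != START_CODON:
            continue
        t = t0
        for _ in range(max_codons):
            codon = ext[t % n : t % n + 3] if circular else seq[t : t + 3]
            if not circular and t + 3 > n:
                break
            if codon in STOP_CODONS:
                length = t - t0 + 3 if t >= t0 else t + n - t0 + 3
                stop_pos = t % n if circular else t
                if length >= min_nt:
                    prev = best.get(stop_pos)
                    if prev is None or length > prev[0]:
                        best[stop_pos] = (length, t0)
                break
            t += 3
            if circular:
                t %= n
    return [(t0, length) for _, (length, t0) in sorted(best.items())]


def enumerate_orfs(
    record: GenomeRecord, min_codons: int = MIN_CODONS_DEFAULT
) -> list[OrfCandidate]:
    """All maximal ORFs of ≥ ``min_codons`` codons (stop included) in all
    six frames, crossing the origin when the genome is circular."""
    if min_codons < 2:
        raise ValueError("min_codons must be ≥ 2")
    from ._seq import revcomp

    L = len(record)
    min_nt = 3 * min_codons
    out: list[OrfCandidate] = []
    for strand, seq in ((1, record.sequence), (-1, revcomp(record.sequence))):
        for t0, length in _strand_orfs(seq, record.circular, min_nt):
            # map strand-local 0-based t0 to genomic 1-based start
            start = t0 + 1 if strand == 1 else L - t0
            ann = OrfAnnotation.from_start("", start, strand, length, L)
            out.append(
                OrfCandidate(start, ann.end, strand, t0 % 3, length, ann.wraps)
            )
    out.sort(key=lambda c: (c.start, -c.strand, c.length_nt))
    return out


# ---------------------------------------------------------------------------
# Overlap geometry on the circle
# ---------------------------------------------------------------------------

def _interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    return max(0, hi - lo + 1)


def circular_overlap_bp(
    a: OrfCandidate | OrfAnnotation, b: OrfCandidate | OrfAnnotation, genome_length: int
) -> int:
    """Number of genome positions covered by both features (strand-blind),
    with origin wraps resolved."""

    def ivals(f):
        if isinstance(f, OrfCandidate):
            f = f.to_annotation("", genome_length)
        return f.genomic_intervals(genome_length)

    return sum(
        _interval_overlap(ia, ib) for ia in ivals(a) for ib in ivals(b)
    )


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select_orfs(
    candidates: list[OrfCandidate],
    genome_length: int,
    max_overlap_bp: int = MAX_OVERLAP_DEFAULT,
    rescued: set[tuple[int, int]] | None = None,
    name_prefix: str = "ORF",
) -> OrfSet:
    """Greedy longest-first ORF selection.

    A candidate is admitted iff its overlap with every already-admitted
    ORF is ≤ ``max_overlap_bp``, or it is homology-rescued.  ``rescued``
    holds (start, strand) keys of candidates exempt from the overlap rule
    (typically because they share significant similarity with known
    genes).  Ties in length are broken by smaller start, then forward
    strand first.  Admitted ORFs are named ``{prefix}1..n`` in order of
    position along the genome.
    """
    rescued = rescued or set()
    ordered = sorted(
        candidates, key=lambda c: (-c.length_nt, c.start, -c.strand)
    )
    admitted: list[OrfCandidate] = []
    for c in ordered:
        if (c.start, c.strand) in rescued or all(
            circular_overlap_bp(c, a, genome_length) <= max_overlap_bp
            for a in admitted
        ):
            admitted.append(c)
    anns = [c.to_annotation("", genome_length) for c in admitted]
    anns = sort_orfs(anns, genome_length)
    return [
        OrfAnnotation(
            f"{name_prefix}{i + 1}", a.start, a.end, a.strand, a.length_nt, a.wraps
        )
        for i, a in enumerate(anns)
    ]


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

@dataclass
class GenomeSummary:
    length_bp: int
    at_content: float  # percent, half-up rounded to 1 decimal
    orf_count: int
    coding_percent_sum: float  # Σ ORF lengths / genome length
    coding_percent_union: float  # union of ORF footprints / genome length
    forward_count: int
    reverse_count: int
    overlap_pairs: list[tuple[str, str, int]]
    minimal_overlap_pair_count: int


def overlap_table(
    orfset: OrfSet, genome_length: int, circular: bool = True
) -> list[tuple[str, str, int]]:
    """Overlap in bp between each pair of adjacent ORFs (consecutive in
    position order along the genome; on circular genomes the last ORF is
    adjacent to the first)."""
    ordered = sort_orfs(orfset, genome_length)
    if len(ordered) < 2:
        return []
    pairs = list(zip(ordered, ordered[1:]))
    if circular:
        pairs.append((ordered[-1], ordered[0]))
    return [
        (a.name, b.name, circular_overlap_bp(a, b, genome_length))
        for a, b in pairs
    ]


def genome_stats(
    record: GenomeRecord,
    orfset: OrfSet,
    minimal_overlap_max_bp: int = MAX_OVERLAP_DEFAULT,
) -> GenomeSummary:
    """Genome summary in the style of published genome reports: size, A+T
    percent (half-up, 1 decimal), ORF count and strand split, coding
    fraction (both Σ-length and union-of-footprints definitions), and the
    adjacent-overlap table with the count of minimally overlapping pairs
    (1..``minimal_overlap_max_bp`` bp)."""
    L = len(record)
    covered = np.zeros(L, dtype=bool)
    total = 0
    fwd = rev = 0
    for f in orfset:
        total += f.length_nt
        if f.strand == 1:
            fwd += 1
        else:
            rev += 1
        for lo, hi in f.genomic_intervals(L):
            covered[lo - 1 : hi] = True
    pairs = overlap_table(orfset, L, record.circular)
    n_min = sum(1 for _, _, ov in pairs if 1 <= ov <= minimal_overlap_max_bp)
    return GenomeSummary(
        length_bp=L,
        at_content=round_half_up(at_percent(record.sequence), 1),
        orf_count=len(orfset),
        coding_percent_sum=round_half_up(100.0 * total / L, 1),
        coding_percent_union=round_half_up(100.0 * int(covered.sum()) / L, 1),
        forward_count=fwd,
        reverse_count=rev,
        overlap_pairs=pairs,
        minimal_overlap_pair_count=n_min,
    )
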